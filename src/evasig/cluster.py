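"""Sample clustering with the gap statistic, and cluster/stage enrichment.

The discovery pipeline clusters samples in the space of the selected probes
with k-means, choosing the number of clusters by the gap statistic: the
within-cluster dispersion of the data is compared, on the log scale, with its
expectation under reference datasets drawn uniformly over the feature-aligned
bounding box, and the smallest k is chosen whose gap is within one reference
standard error of the next gap.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .datasets import PhenotypeVector
from .eva import hypergeom_tail

__all__ = ["GapKMeans", "cluster_stage_enrichment", "pick_eva_samples"]


class GapKMeans(BaseEstimator, ClusterMixin):
    """K-means with the number of clusters chosen by the gap statistic.

    Parameters
    ----------
    k_max : int
        Largest number of clusters considered (capped at n_samples).
    n_refs : int
        Number of uniform reference datasets per k.
    n_init : int
        K-means restarts per fit.
    random_state : int
        Seed for k-means initialisation and reference draws.

    Attributes
    ----------
    n_clusters_ : int
        Chosen number of clusters (smallest k with
        ``Gap(k) >= Gap(k+1) - s_{k+1}``; ``k_max`` if none qualifies).
    labels_ : ndarray of shape (n_samples,)
        Cluster assignment at the chosen k.
    gap_ : ndarray of shape (k_max,)
        Gap values for k = 1..k_max.
    sk_ : ndarray of shape (k_max,)
        Reference standard errors ``s_k``.
    """

    def __init__(self, k_max: int = 10, n_refs: int = 50, n_init: int = 10, random_state: int = 0):
        self.k_max = k_max
        self.n_refs = n_refs
        self.n_init = n_init
        self.random_state = random_state

    @staticmethod
    def _within_dispersion(X: np.ndarray, k: int, n_init: int, seed: int) -> tuple[float, np.ndarray]:
        if k == 1:
            centre = X.mean(axis=0)
            return float(((X - centre) ** 2).sum()), np.zeros(X.shape[0], dtype=int)
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        return float(km.inertia_), km.labels_

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be 2-D with at least 2 samples")
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        ks = np.arange(1, min(self.k_max, n) + 1)
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)

        log_w = np.empty(len(ks))
        labels: list[np.ndarray] = []
        log_w_ref = np.empty((len(ks), self.n_refs))
        ref_seeds = rng.integers(0, 2**31 - 1, size=self.n_refs)
        km_seed = int(rng.integers(0, 2**31 - 1))
        refs = [
            lo + np.random.default_rng(int(s)).random(X.shape) * span for s in ref_seeds
        ]
        tiny = np.finfo(float).tiny
        for i, k in enumerate(ks):
            w, lab = self._within_dispersion(X, int(k), self.n_init, km_seed)
            log_w[i] = np.log(max(w, tiny))
            labels.append(lab)
            for b, R in enumerate(refs):
                wb, _ = self._within_dispersion(R, int(k), self.n_init, km_seed)
                log_w_ref[i, b] = np.log(max(wb, tiny))

        gap = log_w_ref.mean(axis=1) - log_w
        sk = log_w_ref.std(axis=1) * np.sqrt(1.0 + 1.0 / self.n_refs)

        chosen = len(ks) - 1
        for i in range(len(ks) - 1):
            if gap[i] >= gap[i + 1] - sk[i + 1]:
                chosen = i
                break
        self.n_clusters_ = int(ks[chosen])
        self.labels_ = labels[chosen]
        self.gap_ = gap
        self.sk_ = sk
        self.log_w_ = log_w
        return self


def cluster_stage_enrichment(selected: Sequence[str] | set[str], phenotype: PhenotypeVector) -> float:
    """Probability that a random subset this size is at least this depleted of
    low-stage samples.

    Exact lower hypergeometric tail: the chance that ``|selected|`` samples
    drawn uniformly from the cohort contain at most the observed number of
    low-stage samples.  Small values mean the selected set is significantly
    biased toward high-stage samples.
    """
    selected = set(selected)
    if not selected:
        raise ValueError("empty selection")
    unknown = selected - set(phenotype.sample_ids)
    if unknown:
        raise ValueError(f"selected samples not in phenotype: {sorted(unknown)[:5]}")
    n_low = len(selected & phenotype.low_samples)
    return float(10.0 ** hypergeom_tail(n_low, phenotype.M, phenotype.N, len(selected)))


def pick_eva_samples(
    labels: Sequence[int],
    phenotype: PhenotypeVector,
    submatrix: Optional[np.ndarray] = None,
) -> set[str]:
    """Samples of the cluster most associated with the high-stage phenotype.

    The winning cluster minimises the hypergeometric enrichment probability of
    :func:`cluster_stage_enrichment`; ties break toward the cluster with
    higher mean expression of the selected probes (``submatrix``, probes x
    samples), then by cluster label.
    """
    labels = np.asarray(labels)
    if labels.shape != (phenotype.M,):
        raise ValueError("cluster assignment must cover every sample")
    ids = np.asarray(phenotype.sample_ids, dtype=object)
    best: Optional[tuple] = None
    best_set: set[str] = set()
    for c in np.unique(labels):
        members = set(ids[labels == c])
        p = cluster_stage_enrichment(members, phenotype)
        mean_expr = float(submatrix[:, labels == c].mean()) if submatrix is not None else 0.0
        key = (p, -mean_expr, c)
        if best is None or key < best:
            best, best_set = key, members
    return best_set
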