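"""B-spline mutual information, synergy, and Gumbel permutation p-values.

The estimator follows the classic B-spline generalisation of the binned
plug-in MI estimator: each observation is min-max scaled to the spline domain
and distributes its unit weight over ``bins`` histogram cells through
order-``k`` B-spline basis functions (a fuzzy, overlapping binning).  The
weighted marginal/joint histograms are normalised to probabilities and the
plug-in mutual information is reported in bits.  Defaults are six bins and
spline order 3 (quadratic basis).

Synergy of a gene pair (G1, G2) with respect to a target G3 is

    syn = I(G1, G2; G3) - I(G1; G3) - I(G2; G3),

the part of the pair's association with the target beyond the sum of the
individual associations.  Significance of maxima over large search spaces is
assessed with a permutation null: the maximum score over the search space is
recorded for each label permutation and a Gumbel (type-I extreme value)
distribution is fitted to the maxima by maximum likelihood, giving p-values
already corrected for the multiplicity of the search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import gumbel_r

from .datasets import ExpressionDataset

__all__ = [
    "MiEstimate",
    "SynergyScore",
    "GumbelNull",
    "bspline_weights",
    "bspline_mi",
    "synergy",
    "mi_rank_against_proxy",
    "exhaustive_synergy_search",
    "permutation_maxima",
    "fit_gumbel_null",
    "gumbel_pvalue",
]


@dataclass
class MiEstimate:
    """Mutual information estimate in bits."""

    value: float
    n_samples: int
    bins: int = 6
    spline_order: int = 3


@dataclass
class SynergyScore:
    """Synergy of a probe pair with a target; ``synergy = joint_mi - mi_1 - mi_2``."""

    pair: tuple[str, str]
    target: str
    synergy: float
    joint_mi: float
    mi_1: float
    mi_2: float


def _knots(bins: int, order: int) -> np.ndarray:
    """Clamped uniform knot vector with ``bins`` basis functions."""
    interior = np.arange(1, bins - order + 1, dtype=float)
    return np.concatenate([np.zeros(order), interior, np.full(order, bins - order + 1)])


def bspline_weights(x: Sequence[float], bins: int = 6, order: int = 3) -> np.ndarray:
    """Per-sample bin weights, shape (n, bins), each row summing to 1.

    ``x`` is min-max scaled to the spline support; a constant vector puts all
    weight in the first bin.  ``order`` is the B-spline order (degree + 1):
    order 3 gives a quadratic basis.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D value vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if bins < order:
        raise ValueError("need bins >= spline order")
    if len(x) < order + 1:
        raise ValueError(f"need at least order+1={order + 1} samples")
    lo, hi = x.min(), x.max()
    domain = bins - order + 1
    if hi > lo:
        z = (x - lo) / (hi - lo) * domain
    else:
        z = np.zeros_like(x)
    # keep the right edge inside the last knot span
    z = np.clip(z, 0.0, np.nextafter(domain, 0.0))
    t = _knots(bins, order)
    W = BSpline.design_matrix(z, t, order - 1).toarray()
    return W


def _mi_from_weights(Wx: np.ndarray, Wy: np.ndarray) -> float:
    n = Wx.shape[0]
    p1 = Wx.mean(axis=0)
    p2 = Wy.mean(axis=0)
    p12 = Wx.T @ Wy / n
    mask = p12 > 0
    ratio = p12[mask] / np.outer(p1, p2)[mask]
    return float(np.sum(p12[mask] * np.log2(ratio)))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def bspline_mi(
    x: Sequence[float], y: Sequence[float], bins: int = 6, order: int = 3
) -> MiEstimate:
    """B-spline-weighted plug-in mutual information between two vectors, in bits.

    A constant input has zero information by convention.  The estimate is
    bounded by ``log2(bins)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return MiEstimate(0.0, len(x), bins, order)
    Wx = bspline_weights(x, bins, order)
    Wy = bspline_weights(y, bins, order)
    return MiEstimate(max(_mi_from_weights(Wx, Wy), 0.0), len(x), bins, order)


def synergy(
    g1: Sequence[float],
    g2: Sequence[float],
    g3: Sequence[float],
    bins: int = 6,
    order: int = 3,
    pair: tuple[str, str] = ("g1", "g2"),
    target: str = "g3",
) -> SynergyScore:
    """Synergy of (g1, g2) with respect to target g3.

    ``joint_mi = H(g1,g2) + H(g3) - H(g1,g2,g3)`` over the B-spline-weighted
    joint histograms (bins^2 and bins^3 cells); the synergy is then
    ``joint_mi - mi_1 - mi_2`` exactly.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    g3 = np.asarray(g3, dtype=float)
    if not (g1.shape == g2.shape == g3.shape):
        raise ValueError("g1, g2, g3 must have equal length")
    n = len(g1)
    W = [
        bspline_weights(g, bins, order) if np.ptp(g) > 0 else None
        for g in (g1, g2, g3)
    ]
    const = np.zeros((n, bins))
    const[:, 0] = 1.0
    W1, W2, W3 = (w if w is not None else const for w in W)
    p12 = np.einsum("ia,ib->ab", W1, W2) / n
    p3 = W3.mean(axis=0)
    p123 = np.einsum("ia,ib,ic->abc", W1, W2, W3) / n
    joint = max(_entropy(p12.ravel()) + _entropy(p3) - _entropy(p123.ravel()), 0.0)
    mi_1 = bspline_mi(g1, g3, bins, order).value
    mi_2 = bspline_mi(g2, g3, bins, order).value
    return SynergyScore(
        pair=pair,
        target=target,
        synergy=joint - mi_1 - mi_2,
        joint_mi=joint,
        mi_1=mi_1,
        mi_2=mi_2,
    )


def mi_rank_against_proxy(
    dataset: ExpressionDataset | Sequence[ExpressionDataset],
    proxy: str,
    bins: int = 6,
    order: int = 3,
) -> pd.DataFrame:
    """MI of every probe against a proxy probe, sorted descending.

    Accepts a single dataset or a sequence of datasets; with several, the MI
    is averaged over datasets restricted to the shared probe set.  The proxy
    itself is excluded.  Ties break by probe identifier.
    """
    datasets = [dataset] if isinstance(dataset, ExpressionDataset) else list(dataset)
    shared: Optional[set[str]] = None
    for ds in datasets:
        shared = set(ds.probe_ids) if shared is None else shared & set(ds.probe_ids)
    assert shared is not None
    if proxy not in shared:
        raise KeyError(f"proxy probe {proxy!r} not present in all datasets")
    probes = sorted(shared - {proxy})
    scores = np.zeros(len(probes))
    for ds in datasets:
        proxy_vals = ds.probe_values(proxy)
        Wp = bspline_weights(proxy_vals, bins, order) if np.ptp(proxy_vals) > 0 else None
        for j, pid in enumerate(probes):
            v = ds.probe_values(pid)
            if Wp is None or np.ptp(v) == 0:
                continue
            scores[j] += _mi_from_weights(bspline_weights(v, bins, order), Wp)
    scores /= len(datasets)
    df = pd.DataFrame({"probe_id": probes, "mi": np.maximum(scores, 0.0)})
    return df.sort_values(["mi", "probe_id"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )


def exhaustive_synergy_search(
    dataset: ExpressionDataset,
    target: str,
    candidate_probes: Optional[Sequence[str]] = None,
    top_v: Optional[int] = None,
    bins: int = 6,
    order: int = 3,
    top: int = 20,
) -> pd.DataFrame:
    """Evaluate the synergy of every candidate pair with the target.

    ``candidate_probes`` defaults to all probes except the target; ``top_v``
    optionally restricts the O(V^2) search to the V candidates with highest
    variance.  Returns the ``top`` pairs sorted by synergy descending (ties by
    pair identifiers); deterministic for fixed inputs.
    """
    if target not in dataset.probe_ids:
        raise KeyError(f"target probe {target!r} not in dataset")
    cands = [p for p in (candidate_probes or dataset.probe_ids) if p != target]
    if len(cands) < 2:
        raise ValueError("need at least 2 candidate probes")
    if top_v is not None and top_v < len(cands):
        var = {p: float(np.var(dataset.probe_values(p))) for p in cands}
        cands = sorted(sorted(cands), key=lambda p: -var[p])[:top_v]
    cands = sorted(cands)
    n = dataset.n_samples
    tvals = dataset.probe_values(target)
    Wt = bspline_weights(tvals, bins, order) if np.ptp(tvals) > 0 else None
    const = np.zeros((n, bins))
    const[:, 0] = 1.0
    if Wt is None:
        Wt = const
    Ws = {}
    mi_t = {}
    for p in cands:
        v = dataset.probe_values(p)
        Ws[p] = bspline_weights(v, bins, order) if np.ptp(v) > 0 else const
        mi_t[p] = _mi_from_weights(Ws[p], Wt)
    Ht = _entropy(Wt.mean(axis=0))
    rows = []
    for i, a in enumerate(cands):
        Wa = Ws[a]
        for b in cands[i + 1 :]:
            Wab = np.einsum("ia,ib->iab", Wa, Ws[b]).reshape(n, bins * bins)
            pab = Wab.mean(axis=0)
            pabt = Wab.T @ Wt / n
            joint = max(_entropy(pab) + Ht - _entropy(pabt.ravel()), 0.0)
            rows.append(
                {
                    "probe_1": a,
                    "probe_2": b,
                    "synergy": joint - mi_t[a] - mi_t[b],
                    "joint_mi": joint,
                    "mi_1": mi_t[a],
                    "mi_2": mi_t[b],
                }
            )
    df = pd.DataFrame(rows).sort_values(
        ["synergy", "probe_1", "probe_2"], ascending=[False, True, True], kind="mergesort"
    )
    return df.head(top).reset_index(drop=True)


@dataclass
class GumbelNull:
    """Gumbel null of the permutation maxima of a search score.

    ``pvalue(x0) = 1 - F(x0)`` with F the fitted Gumbel CDF; because the null
    models the maximum over the whole search space, the p-value is already
    corrected for the search's multiplicity.  At ``x0 = location`` the p-value
    is ``1 - exp(-1)``.
    """

    location: float
    scale: float
    n_permutations: int
    max_scores: np.ndarray = field(repr=False)

    def pvalue(self, x0: float) -> float:
        return float(gumbel_r.sf(x0, loc=self.location, scale=self.scale))


def permutation_maxima(
    score_fn: Callable[[np.ndarray], float],
    labels: Sequence,
    n_permutations: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Maximum search score under each of ``n_permutations`` label shuffles.

    ``score_fn`` receives a permuted copy of ``labels`` (the class labels, or
    the target gene's values when the target plays the class role) and must
    return the maximum score over the search space.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    return np.array([score_fn(rng.permutation(labels)) for _ in range(n_permutations)])


def fit_gumbel_null(
    score_fn: Callable[[np.ndarray], float] | None,
    labels: Optional[Sequence] = None,
    n_permutations: int = 100,
    seed: int = 0,
    maxima: Optional[Sequence[float]] = None,
) -> GumbelNull:
    """Fit a Gumbel distribution to permutation maxima by maximum likelihood.

    Either supply ``score_fn`` and ``labels`` (maxima are generated by
    permuting the labels with a seeded generator) or precomputed ``maxima``.
    """
    if maxima is None:
        if score_fn is None or labels is None:
            raise ValueError("supply score_fn and labels, or precomputed maxima")
        if n_permutations < 20:
            raise ValueError("need at least 20 permutations for a stable fit")
        maxima = permutation_maxima(score_fn, labels, n_permutations, seed)
    maxima = np.asarray(maxima, dtype=float)
    if np.ptp(maxima) == 0:
        raise ValueError(
            "degenerate permutation maxima (all equal); increase the number of permutations"
        )
    loc, scale = gumbel_r.fit(maxima)
    return GumbelNull(float(loc), float(scale), len(maxima), maxima)


def gumbel_pvalue(x0: float, null: GumbelNull) -> float:
    """Multiplicity-corrected p-value of an observed score under the fitted null."""
    return null.pvalue(x0)
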