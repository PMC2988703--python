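"""Extreme-value association (EVA) between a gene and a binary stage phenotype.

For a gene measured on ``M`` samples of which ``N`` are low-stage, sort the
samples by the gene's expression and, for every prefix of the ``m`` samples
with the highest values, compute the cumulative hypergeometric probability
``h(x <= n; M, N, m)`` that a random subset of size ``m`` would contain at
most the ``n`` low-stage samples actually observed in the prefix.  The EVA
metric is ``-log10`` of the minimum of these probabilities over all
``m = 1..M``.  Because only the top of the sorted list contributes, the
statistic deliberately ignores the expression levels of samples outside the
region of over- (or under-) expression, which makes it sensitive to genes
overexpressed in only a subset of the high-stage samples.

The "mixture" direction evaluates both tails (overexpressed: descending sort;
silenced: ascending sort) and keeps the stronger.

Everything is computed in log space; probabilities around 1e-300 and below
are handled without underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .datasets import ExpressionDataset, PhenotypeVector

__all__ = [
    "EvaResult",
    "hypergeom_tail",
    "eva_metric",
    "eva_metric_bruteforce",
    "eva_rank_all",
    "EvaScorer",
]

Direction = Literal["overexpressed", "silenced", "mixture"]

_LN10 = np.log(10.0)


def _check_hypergeom_args(n: int, M: int, N: int, m: int) -> None:
    if not (0 <= N <= M):
        raise ValueError(f"require 0 <= N <= M, got N={N}, M={M}")
    if not (1 <= m <= M):
        raise ValueError(f"require 1 <= m <= M, got m={m}, M={M}")
    if not (0 <= n <= min(m, N)):
        raise ValueError(f"require 0 <= n <= min(m, N), got n={n}, m={m}, N={N}")


def _log_pmf_grid(M: int, N: int, m: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Natural-log hypergeometric pmf ln C(N,k) C(M-N,m-k) / C(M,m), vectorised.

    Invalid (m, k) combinations get -inf.
    """
    m = np.asarray(m)
    k = np.asarray(k)
    valid = (k >= 0) & (k <= N) & (m - k >= 0) & (m - k <= M - N)
    mk = np.where(valid, m - k, 0)
    kk = np.where(valid, k, 0)
    out = (
        gammaln(N + 1) - gammaln(kk + 1) - gammaln(N - kk + 1)
        + gammaln(M - N + 1) - gammaln(mk + 1) - gammaln(M - N - mk + 1)
        - (gammaln(M + 1) - gammaln(m + 1) - gammaln(M - m + 1))
    )
    return np.where(valid, out, -np.inf)


def hypergeom_tail(n: int, M: int, N: int, m: int) -> float:
    """log10 of the lower hypergeometric tail ``h(x <= n; M, N, m)``.

    Probability that a uniformly random size-``m`` subset of ``M`` items,
    ``N`` of which are marked, contains at most ``n`` marked items.  Returned
    in log10 so that values far below double-precision underflow remain exact
    enough for ranking.
    """
    _check_hypergeom_args(n, M, N, m)
    kmin = max(0, m - (M - N))
    ks = np.arange(kmin, n + 1)
    if ks.size == 0:
        # n < kmin cannot happen given the precondition n >= 0 and kmin <= n
        # whenever the draw is feasible; defensive anyway.
        return -np.inf
    logs = _log_pmf_grid(M, N, np.full_like(ks, m), ks)
    from scipy.special import logsumexp

    return float(min(logsumexp(logs) / _LN10, 0.0))


def _log10_cdf_table(M: int, N: int) -> np.ndarray:
    """Table ``T[m-1, n] = log10 h(x <= n; M, N, m)`` for m=1..M, n=0..N.

    Built once per phenotype and reused for every probe: the EVA scan then
    reduces to an argsort plus a cumulative-count lookup.
    """
    m = np.arange(1, M + 1)[:, None]
    k = np.arange(0, N + 1)[None, :]
    logpmf = _log_pmf_grid(M, N, np.broadcast_to(m, (M, N + 1)), np.broadcast_to(k, (M, N + 1)))
    logcdf = np.logaddexp.accumulate(logpmf, axis=1)
    return np.minimum(logcdf / _LN10, 0.0)


@dataclass
class EvaResult:
    """EVA statistic for one probe.

    ``metric`` is ``-log10`` of the minimum tail probability, attained with a
    prefix of ``best_m`` samples containing ``best_n`` low-stage samples, in
    the stated ``direction``.  ``tail_curve`` optionally stores the per-m
    ``-log10 h`` values of the winning direction for plotting.
    """

    probe_id: str
    metric: float
    best_m: int
    best_n: int
    direction: str
    tail_curve: Optional[np.ndarray] = None


def _scan_sorted(low_sorted: np.ndarray, table: np.ndarray) -> tuple[float, int, int, np.ndarray]:
    """Minimum log10 tail over prefixes of an already-sorted label vector."""
    ncum = np.cumsum(low_sorted)
    M = low_sorted.size
    curve = table[np.arange(M), ncum]
    best = int(np.argmin(curve))  # smallest m on ties
    return float(curve[best]), best + 1, int(ncum[best]), curve


def _sort_order(values: np.ndarray, sample_ids: Sequence[str], descending: bool) -> np.ndarray:
    """Stable sort order; ties in expression broken by sample identifier."""
    ids = np.asarray(sample_ids, dtype=object)
    key = -values if descending else values
    return np.lexsort((ids, key))


def eva_metric(
    values: Sequence[float],
    phenotype: PhenotypeVector,
    direction: Direction = "mixture",
    probe_id: str = "",
    keep_curve: bool = False,
    _table: Optional[np.ndarray] = None,
) -> EvaResult:
    """EVA statistic of one probe's expression vector against the phenotype.

    Parameters
    ----------
    values
        Expression of the probe for each sample, aligned with
        ``phenotype.sample_ids``.
    direction
        ``"overexpressed"`` scans prefixes of the descending sort,
        ``"silenced"`` of the ascending sort, ``"mixture"`` evaluates both and
        keeps the larger metric (ties go to overexpressed).
    keep_curve
        Store the per-m ``-log10 h`` curve of the winning direction.
    """
    values = np.asarray(values, dtype=float)
    M, N = phenotype.M, phenotype.N
    if values.shape != (M,):
        raise ValueError(f"expected {M} values, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite")
    if M < 2 or N == 0 or N == M:
        raise ValueError("phenotype must contain both classes and at least 2 samples")
    table = _table if _table is not None else _log10_cdf_table(M, N)
    low = (~phenotype.high_stage).astype(np.intp)

    results = {}
    dirs = ("overexpressed", "silenced") if direction == "mixture" else (direction,)
    for d in dirs:
        order = _sort_order(values, phenotype.sample_ids, descending=(d == "overexpressed"))
        log10p, best_m, best_n, curve = _scan_sorted(low[order], table)
        results[d] = (-log10p, best_m, best_n, curve)
    # ties broken toward overexpressed
    win = max(dirs, key=lambda d: (results[d][0], d == "overexpressed"))
    metric, best_m, best_n, curve = results[win]
    return EvaResult(
        probe_id=probe_id,
        metric=metric,
        best_m=best_m,
        best_n=best_n,
        direction=win,
        tail_curve=(-curve if keep_curve else None),
    )


def eva_metric_bruteforce(
    values: Sequence[float],
    phenotype: PhenotypeVector,
    direction: Direction = "overexpressed",
) -> float:
    """Reference EVA metric via exact rational arithmetic.

    Independently re-derives the statistic: for every prefix size ``m`` it
    sums exact ``Fraction`` hypergeometric terms and takes the minimum.  Slow
    (exact big-integer combinatorics) but immune to floating-point error; used
    to validate the fast log-space scan.
    """
    values = np.asarray(values, dtype=float)
    M, N = phenotype.M, phenotype.N
    low = (~phenotype.high_stage).astype(int)

    def tail(n: int, m: int) -> Fraction:
        total = Fraction(0)
        for k in range(max(0, m - (M - N)), n + 1):
            total += Fraction(comb(N, k) * comb(M - N, m - k), comb(M, m))
        return total

    dirs = ("overexpressed", "silenced") if direction == "mixture" else (direction,)
    best = Fraction(1)
    for d in dirs:
        order = _sort_order(values, phenotype.sample_ids, descending=(d == "overexpressed"))
        n = 0
        for m in range(1, M + 1):
            n += int(low[order[m - 1]])
            p = tail(n, m)
            if p < best:
                best = p
    return float(-np.log10(float(best.numerator) / float(best.denominator))) if best > 0 else np.inf


def eva_rank_all(
    dataset: ExpressionDataset,
    phenotype: PhenotypeVector,
    direction: Direction = "mixture",
) -> pd.DataFrame:
    """EVA metric for every probe, sorted by metric descending.

    Ties are broken by probe identifier so the ranking is deterministic.
    Returns a DataFrame with columns ``probe_id, gene_symbol, metric, best_m,
    best_n, direction``.
    """
    phen = phenotype.aligned_to(dataset.sample_ids)
    table = _log10_cdf_table(phen.M, phen.N)
    rows = []
    for i, pid in enumerate(dataset.probe_ids):
        r = eva_metric(dataset.matrix[i], phen, direction, probe_id=pid, _table=table)
        rows.append(
            {
                "probe_id": pid,
                "gene_symbol": dataset.gene_symbols[i] if dataset.gene_symbols else pid,
                "metric": r.metric,
                "best_m": r.best_m,
                "best_n": r.best_n,
                "direction": r.direction,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["metric", "probe_id"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )


class EvaScorer(BaseEstimator):
    """Scikit-learn style univariate feature scorer using the EVA statistic.

    Parameters
    ----------
    direction : {"overexpressed", "silenced", "mixture"}
        Which expression tail(s) to scan.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        EVA metric (``-log10`` minimum tail probability) per feature.
    results_ : list of EvaResult
        Full per-feature results.
    """

    def __init__(self, direction: Direction = "mixture"):
        self.direction = direction

    def fit(self, X, y):
        """Score features of ``X`` (n_samples, n_features) against binary ``y``.

        ``y`` is 1/True for high-stage samples.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(bool)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValueError("X must be (n_samples, n_features) with matching y")
        phen = PhenotypeVector([f"s{i:06d}" for i in range(X.shape[0])], y)
        table = _log10_cdf_table(phen.M, phen.N)
        self.results_ = [
            eva_metric(X[:, j], phen, self.direction, probe_id=str(j), _table=table)
            for j in range(X.shape[1])
        ]
        self.scores_ = np.array([r.metric for r in self.results_])
        return self
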