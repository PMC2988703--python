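"""Core containers: expression matrices and binary stage phenotypes.

An :class:`ExpressionDataset` holds a probes x samples matrix of log2-scale
intensities with probe (and optionally gene-symbol) annotations.  A
:class:`PhenotypeVector` holds the per-sample binary high-stage / low-stage
label derived from an ordinal tumour stage and a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "PhenotypeVector"]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))[:10]}")


@dataclass
class ExpressionDataset:
    """Probes x samples log2 expression matrix.

    Parameters
    ----------
    probe_ids
        Unique probe identifiers, one per matrix row.
    sample_ids
        Unique sample identifiers, one per matrix column.
    matrix
        2-D float array of shape ``(len(probe_ids), len(sample_ids))`` holding
        log-scale intensities.  All values must be finite.
    gene_symbols
        Optional per-probe gene symbols (same length as ``probe_ids``).
    """

    probe_ids: list[str]
    sample_ids: list[str]
    matrix: np.ndarray
    gene_symbols: Optional[list[str]] = None

    _probe_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (probes x samples)")
        if self.matrix.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe_ids")
        _check_unique(self.sample_ids, "sample_ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("expression matrix contains non-finite values")
        if self.gene_symbols is not None and len(self.gene_symbols) != len(self.probe_ids):
            raise ValueError("gene_symbols length does not match probe_ids")
        self._probe_index = {p: i for i, p in enumerate(self.probe_ids)}

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_values(self, probe_id: str) -> np.ndarray:
        """Expression vector (one value per sample) for one probe."""
        try:
            return self.matrix[self._probe_index[probe_id]]
        except KeyError:
            raise KeyError(f"probe {probe_id!r} not in dataset") from None

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionDataset":
        idx = [self._probe_index[p] for p in probe_ids]
        symbols = [self.gene_symbols[i] for i in idx] if self.gene_symbols else None
        return ExpressionDataset(
            probe_ids=[self.probe_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            matrix=self.matrix[idx],
            gene_symbols=symbols,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionDataset(
            probe_ids=list(self.probe_ids),
            sample_ids=[self.sample_ids[j] for j in idx],
            matrix=self.matrix[:, idx],
            gene_symbols=list(self.gene_symbols) if self.gene_symbols else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class PhenotypeVector:
    """Binary high/low-stage label per sample.

    ``M`` is the total sample count and ``N`` the number of low-stage samples,
    matching the usual hypergeometric notation for the association statistic.
    """

    sample_ids: list[str]
    high_stage: np.ndarray  # bool, True = high stage

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.high_stage = np.asarray(self.high_stage, dtype=bool)
        if self.high_stage.shape != (len(self.sample_ids),):
            raise ValueError("labels length does not match sample_ids")
        _check_unique(self.sample_ids, "sample_ids")

    @property
    def M(self) -> int:
        """Total number of samples."""
        return len(self.sample_ids)

    @property
    def N(self) -> int:
        """Number of low-stage samples."""
        return int((~self.high_stage).sum())

    @property
    def n_high(self) -> int:
        return int(self.high_stage.sum())

    @property
    def high_samples(self) -> set[str]:
        return {s for s, h in zip(self.sample_ids, self.high_stage) if h}

    @property
    def low_samples(self) -> set[str]:
        return {s for s, h in zip(self.sample_ids, self.high_stage) if not h}

    def aligned_to(self, sample_ids: Sequence[str]) -> "PhenotypeVector":
        """Reorder to match ``sample_ids``; error on any mismatch."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        extra = sorted(set(self.sample_ids) - set(sample_ids))
        if missing or extra:
            raise ValueError(
                "phenotype/expression sample mismatch: "
                f"missing from phenotype {missing[:5]}, "
                f"absent from expression {extra[:5]}"
            )
        idx = [pos[s] for s in sample_ids]
        return PhenotypeVector(list(sample_ids), self.high_stage[idx])
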