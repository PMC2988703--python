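"""Reading and writing the plain-text formats used by the tool.

Expression matrices travel as TSV: a header row of sample identifiers, first
column the probe identifier, optional second column a gene symbol, remaining
cells log-scale intensities.  Phenotypes travel as two-column TSV
(sample_id, stage); ordinal stage labels are binarised against a cutoff from
a configurable ordered stage vocabulary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, PhenotypeVector

__all__ = [
    "OVARIAN_STAGES",
    "COLORECTAL_STAGES",
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "binarize_stage",
    "read_truth",
    "write_truth",
]

OVARIAN_STAGES = ["I", "II", "IIIa", "IIIb", "IIIc", "IV"]
COLORECTAL_STAGES = ["I", "II", "III", "IV"]


class ParseError(ValueError):
    """Malformed input file; the message carries the location."""


def read_expression(
    path: str | Path,
    log_transform: bool = False,
    geo_style: bool = False,
    symbol_column: Optional[bool] = None,
) -> ExpressionDataset:
    """Parse an expression TSV.

    ``log_transform`` applies log2(x+1) on load for matrices not already on
    the log scale.  ``geo_style`` skips comment lines starting with ``!`` (the
    GEO series-matrix convention).  ``symbol_column`` forces interpretation of
    the second column as gene symbols; by default it is auto-detected (second
    column named ``gene_symbol``).
    """
    path = Path(path)
    lines = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if geo_style and raw.startswith("!"):
                continue
            if raw.strip() == "":
                continue
            lines.append((lineno, raw.rstrip("\n").split("\t")))
    if not lines:
        raise ParseError(f"{path}: empty file")
    header_no, header = lines[0]
    if len(header) < 2:
        raise ParseError(f"{path}:{header_no}: header must list at least one sample")
    has_symbols = (
        symbol_column if symbol_column is not None else (len(header) > 1 and header[1] == "gene_symbol")
    )
    first_data = 2 if has_symbols else 1
    sample_ids = header[first_data:]
    dup = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dup:
        raise ParseError(f"{path}:{header_no}: duplicated sample column(s) {sorted(dup)}")

    probe_ids: list[str] = []
    symbols: list[str] = []
    rows: list[list[float]] = []
    width = len(header)
    for lineno, parts in lines[1:]:
        if len(parts) != width:
            raise ParseError(
                f"{path}:{lineno}: expected {width} fields, found {len(parts)} (ragged row)"
            )
        probe_ids.append(parts[0])
        if has_symbols:
            symbols.append(parts[1])
        try:
            rows.append([float(v) for v in parts[first_data:]])
        except ValueError:
            bad = [v for v in parts[first_data:] if not _is_float(v)]
            raise ParseError(f"{path}:{lineno}: non-numeric cell(s) {bad[:3]}") from None
    dup_p = {p for p in probe_ids if probe_ids.count(p) > 1} if len(probe_ids) < 5000 else set()
    if len(set(probe_ids)) != len(probe_ids):
        dup_p = dup_p or {"(many)"}
        raise ParseError(f"{path}: duplicate probe id(s) {sorted(dup_p)[:5]}")
    matrix = np.asarray(rows, dtype=float)
    if log_transform:
        if (matrix < 0).any():
            raise ParseError(f"{path}: negative values cannot be log2(x+1)-transformed")
        matrix = np.log2(matrix + 1.0)
    if not np.all(np.isfinite(matrix)):
        raise ParseError(f"{path}: non-finite values after loading")
    return ExpressionDataset(probe_ids, sample_ids, matrix, symbols if has_symbols else None)


def _is_float(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False


def write_expression(dataset: ExpressionDataset, path: str | Path, fmt: str = "%.6g") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        cols = ["probe_id"]
        if dataset.gene_symbols is not None:
            cols.append("gene_symbol")
        fh.write("\t".join(cols + list(dataset.sample_ids)) + "\n")
        for i, pid in enumerate(dataset.probe_ids):
            row = [pid]
            if dataset.gene_symbols is not None:
                row.append(dataset.gene_symbols[i])
            row += [fmt % v for v in dataset.matrix[i]]
            fh.write("\t".join(row) + "\n")


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Two-column TSV ``sample_id, stage`` (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "stage"]:
        raise ParseError(f"{path}: expected columns sample_id, stage; got {list(df.columns)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample_id(s) {dups[:5]}")
    return df


def write_phenotype(sample_ids: Sequence[str], stages: Sequence[str], path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "stage": list(stages)}).to_csv(
        path, sep="\t", index=False
    )


def binarize_stage(
    pheno: pd.DataFrame,
    threshold: str,
    vocabulary: Sequence[str] = OVARIAN_STAGES,
) -> PhenotypeVector:
    """Binary phenotype: stage strictly above ``threshold`` is high-stage.

    ``vocabulary`` is the ordered stage scale; e.g. with the ovarian scale and
    threshold ``IIIb``, stages IIIc and IV are high.  Stages may also already
    be the literal labels ``high``/``low``, in which case the threshold is
    ignored.
    """
    stages = pheno["stage"].astype(str)
    if set(stages) <= {"high", "low"}:
        return PhenotypeVector(list(pheno["sample_id"]), (stages == "high").to_numpy())
    order = {s: i for i, s in enumerate(vocabulary)}
    if threshold not in order:
        raise ValueError(f"threshold {threshold!r} not in stage vocabulary {list(vocabulary)}")
    unknown = sorted(set(stages) - set(order))
    if unknown:
        raise ValueError(f"unknown stage label(s) {unknown}; accepted vocabulary: {list(vocabulary)}")
    high = stages.map(order).to_numpy() > order[threshold]
    return PhenotypeVector(list(pheno["sample_id"]), high)


def read_truth(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_truth(probe_ids: Sequence[str] | set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(probe_ids):
            fh.write(pid + "\n")
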