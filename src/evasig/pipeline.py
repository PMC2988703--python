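"""The signature-discovery pipeline.

Per dataset: rank probes by extreme-value association with the binary stage
phenotype and keep the top K; cluster the samples (features = the selected
probes, z-scored per probe) with gap-statistic k-means; call the cluster most
enriched in high-stage samples the "EVA-based" samples; form the "clean"
phenotype contrasting (EVA-based AND high-stage) cases against (non-EVA-based
AND low-stage) controls; rank all genes by a two-sided Wilcoxon rank-sum test
under the clean phenotype with Bonferroni correction.  Across datasets,
intersect the significant gene sets and order by mean log2 fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import GapKMeans, cluster_stage_enrichment, pick_eva_samples
from .datasets import ExpressionDataset, PhenotypeVector
from .eva import eva_rank_all

__all__ = [
    "CleanPhenotype",
    "DiscoveryParams",
    "SignatureReport",
    "make_clean_phenotype",
    "rank_genes_clean",
    "intersect_and_rank",
    "discover",
    "pearson_rank_all",
]

logger = logging.getLogger("evasig")


@dataclass
class CleanPhenotype:
    """Case/control/excluded partition of the samples.

    Cases are both EVA-based and high-stage; controls are both non-EVA-based
    and low-stage; everything else is excluded from the contrast.
    """

    case_samples: set[str]
    control_samples: set[str]
    excluded_samples: set[str]

    def __post_init__(self) -> None:
        if self.case_samples & self.control_samples:
            raise ValueError("case and control sets overlap")


def make_clean_phenotype(eva_samples: set[str], phenotype: PhenotypeVector) -> CleanPhenotype:
    """Clean phenotype from the EVA-based sample set.

    Raises if either side of the contrast is empty (the dataset then cannot
    contribute to discovery).
    """
    eva_samples = set(eva_samples)
    unknown = eva_samples - set(phenotype.sample_ids)
    if unknown:
        raise ValueError(f"eva_samples not in phenotype: {sorted(unknown)[:5]}")
    high, low = phenotype.high_samples, phenotype.low_samples
    case = eva_samples & high
    control = (set(phenotype.sample_ids) - eva_samples) & low
    if not case:
        raise ValueError("clean phenotype has an empty case group")
    if not control:
        raise ValueError("clean phenotype has an empty control group")
    excluded = set(phenotype.sample_ids) - case - control
    return CleanPhenotype(case, control, excluded)


def rank_genes_clean(
    dataset: ExpressionDataset,
    clean: CleanPhenotype,
    alpha: float = 1e-3,
) -> pd.DataFrame:
    """Per-probe Wilcoxon rank-sum test under the clean phenotype.

    Two-sided; exact enumeration when the combined group size is at most 12,
    otherwise the tie- and continuity-corrected normal approximation.  The
    Bonferroni factor is the number of probes tested in this dataset.  The
    log2 fold change is mean(case) - mean(control) on the already-log2 scale.
    Probes constant across both groups get p = 1 by convention.
    """
    case = sorted(clean.case_samples)
    control = sorted(clean.control_samples)
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need at least 2 case and 2 control samples")
    Xc = dataset.subset_samples(case).matrix
    Xk = dataset.subset_samples(control).matrix
    method = "exact" if len(case) + len(control) <= 12 else "asymptotic"
    pooled = np.hstack([Xc, Xk])
    constant = np.ptp(pooled, axis=1) == 0
    pvals = np.ones(dataset.n_probes)
    if (~constant).any():
        res = stats.mannwhitneyu(
            Xc[~constant], Xk[~constant], axis=1, alternative="two-sided", method=method
        )
        pvals[~constant] = np.minimum(res.pvalue, 1.0)
    if constant.any():
        logger.info("rank_genes_clean: %d constant probes set to p=1", int(constant.sum()))
    log_fc = Xc.mean(axis=1) - Xk.mean(axis=1)
    n_tests = dataset.n_probes
    df = pd.DataFrame(
        {
            "probe_id": dataset.probe_ids,
            "gene_symbol": dataset.gene_symbols if dataset.gene_symbols else dataset.probe_ids,
            "p_raw": pvals,
            "p_bonferroni": np.minimum(pvals * n_tests, 1.0),
            "log_fc": log_fc,
        }
    )
    df["significant"] = df["p_bonferroni"] < alpha
    return df


@dataclass
class SignatureReport:
    """Cross-dataset intersected signature.

    ``table`` has one row per gene significant in *all* member datasets, with
    per-dataset corrected p-values and log2 fold changes, ordered by mean log2
    fold change descending.
    """

    table: pd.DataFrame
    alpha: float
    n_datasets: int

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])


def intersect_and_rank(tables: Mapping[str, pd.DataFrame], alpha: float = 1e-3) -> SignatureReport:
    """Genes with corrected p < alpha in every dataset, ranked by mean log FC."""
    if not tables:
        raise ValueError("need at least one gene table")
    names = list(tables)
    shared: Optional[set[str]] = None
    for name in names:
        probes = set(tables[name]["probe_id"])
        shared = probes if shared is None else shared & probes
    assert shared is not None
    if not shared:
        sizes = {k: len(v) for k, v in tables.items()}
        raise ValueError(f"probe spaces share 0 identifiers across datasets {sizes}")

    sig: Optional[set[str]] = None
    for name in names:
        t = tables[name]
        s = set(t.loc[t["p_bonferroni"] < alpha, "probe_id"]) & shared
        sig = s if sig is None else sig & s
    assert sig is not None

    first = tables[names[0]].set_index("probe_id")
    rows = []
    for pid in sorted(sig):
        row: dict = {"probe_id": pid, "gene_symbol": first.loc[pid, "gene_symbol"]}
        fcs = []
        for name in names:
            t = tables[name].set_index("probe_id")
            row[f"p_{name}"] = float(t.loc[pid, "p_bonferroni"])
            fc = float(t.loc[pid, "log_fc"])
            row[f"log_fc_{name}"] = fc
            fcs.append(fc)
        row["mean_log_fc"] = float(np.mean(fcs))
        rows.append(row)
    cols = ["probe_id", "gene_symbol", "mean_log_fc"] + [
        c for name in names for c in (f"p_{name}", f"log_fc_{name}")
    ]
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        table = table.sort_values(
            ["mean_log_fc", "probe_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return SignatureReport(table=table, alpha=alpha, n_datasets=len(names))


def pearson_rank_all(dataset: ExpressionDataset, phenotype: PhenotypeVector) -> pd.DataFrame:
    """Alternative probe selector: |Pearson r| with the binary label.

    Provided to check that discovery is robust to swapping the association
    measure, since coordinated overexpression also produces a strong overall
    correlation with the phenotype.
    """
    phen = phenotype.aligned_to(dataset.sample_ids)
    y = phen.high_stage.astype(float)
    y = y - y.mean()
    X = dataset.matrix - dataset.matrix.mean(axis=1, keepdims=True)
    denom = np.sqrt((X**2).sum(axis=1) * (y**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, X @ y / denom, 0.0)
    df = pd.DataFrame(
        {
            "probe_id": dataset.probe_ids,
            "gene_symbol": dataset.gene_symbols if dataset.gene_symbols else dataset.probe_ids,
            "metric": np.abs(r),
        }
    )
    return df.sort_values(["metric", "probe_id"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )


@dataclass
class DiscoveryParams:
    """Tunable parameters of the discovery pipeline."""

    top_k: int = 100
    alpha: float = 1e-3
    k_max: int = 10
    gap_refs: int = 50
    n_init: int = 10
    selector: str = "eva"  # or "pearson"
    seed: int = 0


@dataclass
class DatasetArtifacts:
    """Per-dataset intermediate results of one discovery run."""

    eva_table: pd.DataFrame
    selected_probes: list[str]
    cluster_labels: np.ndarray
    n_clusters: int
    eva_samples: set[str]
    enrichment_p: float
    clean: CleanPhenotype
    gene_table: pd.DataFrame


@dataclass
class DiscoveryResult:
    report: SignatureReport
    per_dataset: dict[str, DatasetArtifacts] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


def _run_one(
    name: str,
    dataset: ExpressionDataset,
    phenotype: PhenotypeVector,
    params: DiscoveryParams,
    seed: int,
) -> DatasetArtifacts:
    phen = phenotype.aligned_to(dataset.sample_ids)
    if params.selector == "pearson":
        eva_table = pearson_rank_all(dataset, phen)
    else:
        eva_table = eva_rank_all(dataset, phen)
    top_k = params.top_k
    if top_k > dataset.n_probes:
        logger.warning("%s: top_k=%d exceeds probe count %d; clamped", name, top_k, dataset.n_probes)
        top_k = dataset.n_probes
    selected = list(eva_table["probe_id"].head(top_k))
    sub = dataset.subset_probes(selected).matrix  # probes x samples

    # z-score per probe before clustering samples
    sd = sub.std(axis=1, keepdims=True)
    z = (sub - sub.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    gk = GapKMeans(
        k_max=params.k_max, n_refs=params.gap_refs, n_init=params.n_init, random_state=seed
    ).fit(z.T)
    if gk.n_clusters_ == 1:
        logger.warning(
            "%s: gap statistic chose k=1; the clean phenotype reduces to the raw stage contrast",
            name,
        )
    eva_samples = pick_eva_samples(gk.labels_, phen, sub)
    enr = cluster_stage_enrichment(eva_samples, phen)
    clean = make_clean_phenotype(eva_samples, phen)
    gene_table = rank_genes_clean(dataset, clean, params.alpha)
    logger.info(
        "%s: M=%d N_low=%d k=%d |eva|=%d enrichment_p=%.3g case=%d control=%d excluded=%d sig=%d",
        name,
        phen.M,
        phen.N,
        gk.n_clusters_,
        len(eva_samples),
        enr,
        len(clean.case_samples),
        len(clean.control_samples),
        len(clean.excluded_samples),
        int(gene_table["significant"].sum()),
    )
    return DatasetArtifacts(
        eva_table=eva_table,
        selected_probes=selected,
        cluster_labels=gk.labels_,
        n_clusters=gk.n_clusters_,
        eva_samples=eva_samples,
        enrichment_p=enr,
        clean=clean,
        gene_table=gene_table,
    )


def discover(
    datasets: Mapping[str, tuple[ExpressionDataset, PhenotypeVector]],
    params: Optional[DiscoveryParams] = None,
) -> DiscoveryResult:
    """Run the full discovery algorithm over one or more datasets.

    A dataset whose pipeline fails (e.g. an empty clean-phenotype side) is
    dropped with a warning; discovery proceeds as long as at least one dataset
    survives.
    """
    params = params or DiscoveryParams()
    if not datasets:
        raise ValueError("no datasets supplied")
    seeds = np.random.SeedSequence(params.seed).spawn(len(datasets))
    result = DiscoveryResult(report=SignatureReport(pd.DataFrame(), params.alpha, 0))
    tables: dict[str, pd.DataFrame] = {}
    for (name, (ds, phen)), ss in zip(datasets.items(), seeds):
        try:
            art = _run_one(name, ds, phen, params, int(ss.generate_state(1)[0] % (2**31 - 1)))
        except ValueError as exc:
            logger.warning("%s: dataset dropped from discovery: %s", name, exc)
            result.failures[name] = str(exc)
            continue
        result.per_dataset[name] = art
        tables[name] = art.gene_table
    if not tables:
        logger.warning("every dataset failed (%s); report is empty", result.failures)
        result.report = SignatureReport(
            table=pd.DataFrame(columns=["probe_id", "gene_symbol", "mean_log_fc"]),
            alpha=params.alpha,
            n_datasets=0,
        )
        return result
    if result.failures:
        logger.warning("discovery proceeding with %d of %d datasets", len(tables), len(datasets))
    result.report = intersect_and_rank(tables, params.alpha)
    return result
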