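# evasig

Gene-signature discovery from tumour staging by **extreme-value association
(EVA)**, with B-spline mutual information, information-theoretic synergy, and
Gumbel permutation p-values.

## The problem

In several carcinomas a block of stromal genes (collagens such as *COL11A1*,
*THBS2*, *INHBA*, ...) is coordinately overexpressed — but only in a *subset*
of the samples that have progressed past a cancer-specific invasive stage, and
in essentially none of the lower-stage samples. Ordinary differential
expression between "high stage" and "low stage" groups dilutes this signal,
because most high-stage samples do not carry the block. `evasig` implements a
statistic and a discovery pipeline designed for exactly this pattern, for
computational biologists working with log-scale expression matrices (probes ×
samples) and per-sample staging annotations.

## The EVA statistic

Suppose there are *M* samples, *N* of them low-stage. Sort the samples by a
gene's expression and consider the prefix of the *m* highest-expressing
samples, containing *n* low-stage samples. If expression were unrelated to
stage, the probability of seeing at most *n* low-stage samples in the prefix
is the cumulative hypergeometric tail

&nbsp;&nbsp;&nbsp;&nbsp;*h*(*x* ≤ *n*; *M*, *N*, *m*) = Σ<sub>k≤n</sub> C(*N*,k) · C(*M−N*, *m−k*) / C(*M*, *m*).

The EVA metric is **−log₁₀ of the minimum of these tails over all
m = 1..M**. It depends only on the sample ordering (rank-invariant) and
deliberately ignores expression outside the extreme region, so a gene
overexpressed in, say, 100 of 300 samples — all of them high-stage — scores
highly even though the other 150 high-stage samples look unremarkable. A
"mixture" analysis scans both tails (overexpression and silencing) and keeps
the stronger. For example, if the top 100 of 300 samples (50 low-stage
overall) contain a single low-stage sample, *h*(*x* ≤ 1; 300, 50, 100) ≈
5 × 10⁻⁹, an EVA metric of at least 8.3.

The discovery pipeline then, per dataset:

1. keeps the top *K* = 100 probes by EVA metric;
2. clusters the samples in that probe space (k-means, number of clusters by
   the gap statistic) and takes the cluster most enriched in high-stage
   samples (exact hypergeometric enrichment) — the "EVA-based" samples;
3. forms a **clean phenotype**: cases = EVA-based ∩ high-stage, controls =
   non-EVA-based ∩ low-stage, everything else excluded;
4. ranks all genes by a two-sided Wilcoxon rank-sum test under the clean
   phenotype with Bonferroni correction (corrected p < 10⁻³);
5. intersects the significant sets across datasets and orders by mean log₂
   fold change.

The information-theoretic half of the package ranks genes by B-spline mutual
information with a proxy gene, searches gene pairs for **synergy**
I(G₁,G₂;G₃) − I(G₁;G₃) − I(G₂;G₃) with respect to a target, and converts
search maxima into multiplicity-corrected p-values by fitting a Gumbel
distribution to permutation maxima.

Because real staged cohorts are large downloads, the package ships a
first-class synthetic-data module that plants exactly the structure above
(a coordinated overexpression block in a subset of high-stage samples, a
proxy gene, an XOR gate triple, and a matched uncoordinated control matrix),
so every stage is testable end to end against known ground truth.

## Worked example

```python
from evasig import (SimulationConfig, generate_dataset, eva_rank_all,
                    discover, DiscoveryParams)

cfg = SimulationConfig(n_probes=1000, n_samples=300, seed=1)   # 250 high-stage,
sim = generate_dataset(cfg)                                    # 100 carriers, 20 planted probes

table = eva_rank_all(sim.expression, sim.phenotype)
print(table.head(3))
top100 = set(table["probe_id"].head(100))
print(f"planted probes in top 100: {len(top100 & sim.truth)}/20")

res = discover({"cohort": (sim.expression, sim.phenotype)}, DiscoveryParams(seed=0))
art = res.per_dataset["cohort"]
print(f"k={art.n_clusters}, EVA-based samples={len(art.eva_samples)}, "
      f"enrichment p={art.enrichment_p:.3g}")
print(f"signature genes: {len(res.report.table)}")
```

prints

```
probe_id gene_symbol   metric  best_m  best_n     direction
 P000343     P000343 7.953893      97       1 overexpressed
 P000700     P000700 7.610947      94       1 overexpressed
 P000857     P000857 7.177409     163      10 overexpressed
planted probes in top 100: 20/20
k=2, EVA-based samples=96, enrichment p=4.53e-10
signature genes: 20
```

The top-ranked probe's minimum tail occurs at a prefix of 97 samples
containing one low-stage sample (metric ≈ 7.95 = −log₁₀ of that tail
probability). The gap statistic finds two sample clusters; the 96 samples of
the winning cluster contain no low-stage samples (enrichment p ≈ 5 × 10⁻¹⁰),
and the clean-phenotype Wilcoxon stage returns exactly the 20 planted probes.

The same operations are available from the shell:

```bash
evasig simulate --out sim --seed 1
evasig eva-rank --expression sim/expression.tsv --phenotype sim/phenotype.tsv --out rank
evasig discover --expression sim/expression.tsv --phenotype sim/phenotype.tsv --out disc --seed 0
evasig mi-rank --expression sim/expression.tsv --proxy P000343 --out mi
```

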