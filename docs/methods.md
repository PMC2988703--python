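# Methods

## The extreme-value association statistic

For a binary stage phenotype over *M* samples with *N* low-stage, and a gene's
expression vector, the statistic is

EVA = −log₁₀ min<sub>m=1..M</sub> *h*(*x* ≤ *n(m)*; *M*, *N*, *m*),

where the samples are sorted by expression (descending for the overexpression
tail, ascending for the silencing tail) and *n(m)* is the number of low-stage
samples among the top *m*. The "mixture" direction evaluates both tails and
keeps the larger metric, breaking ties toward overexpression. The statistic is
invariant under strictly increasing transforms of the expression values and is
nonnegative by construction (at *m* = *M* the tail probability is 1).

**Numerics.** All probabilities are accumulated in natural-log space from
`gammaln`-based hypergeometric log-pmf terms with a running `logaddexp`, so
tails around 10⁻³⁰⁰ and far below remain usable for ranking (verified to
*M* = 10⁴). When a whole matrix is ranked against one phenotype, the full
log-CDF table over (m, n) is precomputed once — the per-probe scan then
reduces to an argsort, a cumulative label count, and a table lookup — unless
the table would exceed ~2 × 10⁷ entries. Expression ties are broken by sample
identifier so rankings are reproducible; ranking ties across probes break by
probe identifier. When several prefix sizes attain the same minimum, the
smallest *m* is reported.

**Validation.** A deliberately independent reference implementation computes
every tail with exact rational arithmetic (`fractions.Fraction` over integer
binomial coefficients) and takes the minimum by direct enumeration; the fast
scan is required to agree with it on thousands of random instances, and the
tail itself is checked against `scipy.stats.hypergeom`.

## Discovery pipeline

Per dataset: the top *K* = 100 probes by mixture-direction EVA (the value used
throughout; exposed as a parameter) define the feature space in which samples
are clustered. Features are z-scored per probe before k-means, since k-means
is scale-sensitive. The number of clusters is chosen by the gap statistic:
B = 50 reference datasets drawn uniformly over the per-feature bounding box,
k = 1..10, 10 k-means restarts per fit, choosing the smallest k with
Gap(k) ≥ Gap(k+1) − s₍k+1₎. These defaults are the standard published ones;
they are exposed (`k_max`, `gap_refs`, `n_init`) and the test suite runs some
experiments at reduced settings (k ≤ 6, 10–20 references) where the clustering
is unambiguous anyway.

The "EVA-based" sample set is the cluster minimising the exact hypergeometric
probability that a random subset of its size contains at most its observed
number of low-stage samples (the same enrichment computation reported for
selected sample sets generally); ties break toward the cluster with higher
mean expression of the selected probes. The clean phenotype contrasts
(EVA-based ∩ high-stage) cases against (non-EVA-based ∩ low-stage) controls.
If the gap statistic returns k = 1 the EVA-based set is the whole cohort, the
control side is empty, and the dataset is dropped with a diagnostic — with no
coordinated block present this is the expected (and tested) outcome, and a
run in which every dataset drops returns an empty report rather than an error.

Gene ranking under the clean phenotype uses the two-sided Wilcoxon rank-sum
test (`scipy.stats.mannwhitneyu`): exact enumeration when the combined group
size is ≤ 12, otherwise the tie- and continuity-corrected normal
approximation. Probes constant across both groups get p = 1 by convention.
The Bonferroni factor is the number of probes tested in that dataset (each
dataset is corrected before intersection). The cross-dataset report keeps
genes significant in **all** datasets and orders them by the unweighted mean
of the per-dataset log₂ fold changes (mean(case) − mean(control) on the
already-log₂ scale).

A Pearson-based selector (|r| with the binary label) can be swapped in for the
EVA ranking; on planted data the final reports overlap almost completely,
because coordinated overexpression also produces strong overall correlation —
the EVA statistic's added value is the estimate (best *m*) of the size of the
overexpressing subset.

## B-spline mutual information and synergy

MI is estimated with the classic B-spline generalisation of the binned
plug-in estimator: each variable is min-max scaled to the spline support, and
each observation spreads its unit weight over **6 bins** through B-spline
basis functions of **order 3** (quadratic; order 1 recovers hard binning) on
a clamped uniform knot vector. Weighted marginal/joint histograms are
normalised and the plug-in MI is reported in **bits** (the log base is a
convention choice; nothing downstream depends on it). Constant inputs carry
zero information by convention. The 2-variable-vs-target joint MI is computed
as H(G₁,G₂) + H(G₃) − H(G₁,G₂,G₃) over bins² and bins³ weighted histograms,
and synergy as joint − I(G₁;G₃) − I(G₂;G₃), exactly by construction.

**What the estimator does and does not measure.** Like any fixed-resolution
binned estimator, it estimates the mutual information *of the binned joint
distribution*, not the differential MI of the underlying continuous
variables. At 6 bins the binned MI of a ρ = 0.9 bivariate Gaussian is well
below the analytic −½·log₂(1−ρ²) ≈ 1.20 bits — by numerical integration the
population binned value is ≈ 0.93 bits for equiprobable bins and ≈ 0.70 for
equal-width bins, and the quadratic-spline smoothing lowers the estimate
further (≈ 0.2 bits at n = 5000). This is inherent to the estimator's
resolution, not a sample-size artefact. It is immaterial for the package's
uses — ranking and permutation testing — which depend only on relative
ordering: independence calibration is sharp (≈ 10⁻⁴ bits at n = 5000, bias
well under 0.02), estimates increase monotonically with dependence strength,
and two-state (on/off) expression patterns, the regime the pipeline targets,
are resolved essentially losslessly: the planted XOR gate measures ≈ 0.996 of
its 1 construction bit.

Proxy ranking computes MI of every probe against a designated proxy,
descending, ties by probe identifier; across several datasets the MI is the
unweighted mean over datasets restricted to the shared probe set. The synergy
search evaluates all candidate pairs (optionally prefiltered to the top-V by
variance to bound the O(V²) cost) and is deterministic for fixed inputs.

## Gumbel permutation p-values

Significance of a maximum over a large search space is assessed by permuting
the class labels (or the target gene's values, which play the class role in a
synergy search), recording the maximum score over the search space per
permutation (default 100, minimum 20), and fitting a Gumbel (type-I extreme
value) distribution to the maxima by maximum likelihood
(`scipy.stats.gumbel_r.fit`). The p-value of an observed score x₀ is
1 − F(x₀) = 1 − exp(−exp(−(x₀ − location)/scale)); because the null models the
search maximum, this is already corrected for the search's multiplicity. At
x₀ = location the p-value is 1 − e⁻¹ ≈ 0.632. Degenerate (all-equal) maxima
are rejected with a pointer toward more permutations.

## Synthetic data

The generator emulates the discovery target: an i.i.d. Normal(baseline, σ)
log₂ matrix (default baseline 6.0, σ = 1.0 — typical microarray log-intensity
scales) with `n_signature_probes` = 20 planted probes gaining a
+2.0 log₂ shift in `carriers` — a random 40% subset of the high-stage
samples (5/6 of 300 samples high-stage by default, mirroring cohorts where
low-stage samples are the minority). Low-stage samples never carry the block.
With `include_proxy`, the planted block additionally shares a latent
Normal(0, 0.5) factor within carriers (within-block carrier correlation
≈ 0.2; the real-data value is unknown, so it is a parameter, and the proxy
analyses depend mainly on the shared on/off pattern rather than its value).
The matched control matrix applies the same marginal shift independently per
probe and sample at the cancer matrix's overall carrier rate, so block genes
are marginally similar but mutually uncorrelated — coordination without a
shared cause, the non-cancerous contrast.

The XOR gate triple (A, B, T) uses median-thresholded latent Gaussians for
the two input states and elevates T exactly when one input is elevated and
the other is not. Gate probes use their own shift (4.0 log₂) and tight noise
(σ = 0.25) so each state is unambiguous and the triple's joint information
content is ~1 bit by construction while both marginal associations vanish by
the XOR symmetry — a derivable calibration point for the synergy estimator,
not a model of realistic effect sizes. A `layout_seed` decouples which
probes/samples are planted from the noise stream, so independently-noised
cohorts can share one ground truth for intersection experiments.

**What passing tests show.** Recovery results on this generator demonstrate
correctness of the machinery under the planted model: Gaussian noise,
exchangeable samples, a clean two-cluster structure, no batch effects, no
probe-level artefacts, no correlated null genes. Real cohorts violate all of
these to some degree, so planted precision/recall says nothing quantitative
about sensitivity on real tumours — only that each stage does what it claims
on data with the assumed structure.

## Problem sizes and determinism

The reference experiment scale is 1000 probes × 300 samples per cohort, four
cohorts per discovery, ten replicates for recovery statistics, n = 5000 for
MI calibrations, 500 maxima for Gumbel parameter recovery, and 1000 random
instances for the exact-arithmetic cross-check — sizes at which every
reported quantity is stable to the tolerances asserted. All pipeline
randomness fans out deterministically from a single seed
(`numpy.random.SeedSequence`); identical inputs and seed give byte-identical
output tables.

## Known limitations

- Binary phenotypes only; no continuous, multi-class, or survival endpoints.
- The gap statistic inherits k-means' preference for spherical clusters in
  the z-scored probe space; elongated or nested sample structure may pick the
  wrong k and hence a blunted clean phenotype.
- The MI/synergy estimator's absolute values are resolution-limited (above);
  compare scores only within one (bins, order, n) configuration.
- Probe-to-gene collapsing across platforms, normalisation, and batch
  correction are out of scope; inputs are assumed already log-scale and
  comparable within each matrix.
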