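# Methods

## The screening model

The pipeline treats miRNA-mediated repression as a linear signal in
cross-sample expression: if miRNA *m* represses gene *g*, then across a
cohort the probe-level signal of *g* co-varies negatively with the
abundance of *m*. The screen therefore computes, for each marker probe ×
miRNA pair, the product-moment correlation *r* over the pairwise-complete
samples and converts it to a two-sided p-value through the exact null
distribution of *r* under bivariate normality: *t = r·√(n−2)/√(1−r²)*
with *n−2* degrees of freedom. No multiplicity correction gates the
significance flag — the screen is a nomination step, not an inference — but
Benjamini–Hochberg adjusted p-values are reported alongside for users who
want the grid-wide FDR view (`adjust=True`, the default).

### Significance profile

The default rule is the conjunction |r| ≥ 0.258 AND p ≤ 0.05. These two
clauses are deliberately not collapsed: at n = 57 the exact inversion of
the t transform at α = 0.05 gives |r| ≈ 0.2609, so an |r| in
[0.258, 0.2609) passes the correlation clause but not the p clause. The
`AnalysisThresholds.mode` switch (`both`, `alpha_only`, `r_only`) exposes
each clause separately for sensitivity analysis. `critical_r(n, alpha)`
returns the exact boundary for any cohort size.

### Scale of the inputs

Pearson correlation on raw linear microarray signal is dominated by
high-intensity outliers, so the ingest path defaults to log2(x+1) on
linear mRNA signal, with `--transform none` to correlate the raw values
instead. miRNA profiles measured as qPCR Ct are *inversely* related to
abundance; `ct_to_log2_abundance` (CLI `--mirna-scale ct`) negates them so
that every downstream correlation sign reads as abundance-vs-abundance.
Both choices are explicit configuration, never silent.

### Consensus rule

Genes are identified by official symbol (upper-cased; matching is
case-insensitive), the common key across the four prediction sources and
marker panels. The inclusion rule is "predicted by at least one source
AND at least one probe with significant negative correlation"; per-source
support is retained on each `ConsensusTarget` so a stricter k-of-4 rule
is a downstream filter, not a code change. Pairs whose only significant
correlations are positive are excluded, but the screen output itself
reports signs, so positively correlated significant pairs remain visible
upstream. Validation status (TarBase-style catalogue) and binding-site
counts are annotations; neither gates inclusion. Binding sites use
1-based inclusive UTR-relative coordinates; sites at identical
coordinates collapse to one, overlapping-but-distinct sites count
separately; both score cutoffs (mirSVR ≤ 0, PhastCons ≥ 0) are
inclusive.

## Quantification arithmetic

ΔCt = Ct(target) − Ct(endogenous control) is computed per replicate
(replicate ids pair the two wells), averaged per condition, and
ΔΔCt = mean ΔCt(treated) − mean ΔCt(control); fold = 2^−ΔΔCt. The
replicate ΔCt sets feed an unpaired t-test — Welch by default, pooled
variance available for strict reproduction of legacy analyses. Endogenous
controls are arguments (U47 for miRNA, UBC for mRNA in the motivating
study). Ct values at the detection limit (`max_cycles`, default 40) flag
the result `censored`: its fold is a bound, not a point estimate. A single
replicate still yields a fold, with p reported unavailable rather than
fabricated.

Relative protein level is (raw/loading) ÷ (raw/loading of the reference
condition) per protein, which makes it invariant to per-lane exposure
scaling; percent change is 100·(1 − relative level). The confirmation
call is the disjunction: mRNA fold < 1 with p ≤ 0.05, OR protein down by
≥ 15% (inclusive at the boundary, so 15.0% confirms and 14.9% does not).

Tumor-vs-normal fold change is the ratio of group means on the linear
scale (log2 matrices are back-transformed first); the t-test runs on the
analysis scale as given.

## Synthetic cohorts

The generator reproduces the statistical structure the screen assumes,
not array chemistry (no MAS5 probe-level effects, no TaqMan amplification
curves, no between-batch structure, no heavy-tailed noise). Passing tests
therefore demonstrate correctness of the pipeline's arithmetic and its
operating characteristics under the stated model — not robustness to the
artifacts of real platforms.

On the log2 scale, miRNA abundance is Normal(baseline + shift·[tumor],
`mirna_sd`²) per sample. Each gene has a latent signal of fixed variance
`gene_sd`²; planting (m, g, r) gives the signal a slope
β = r·√(gene_sd² + noise_sd²)/mirna_sd on the miRNA's deviations and
removes the matching variance from the residual, so the *probe-level*
population correlation equals r exactly (probes add independent
Normal(0, `noise_sd`²) on top of the shared signal). Because the variance
budget is fixed, attainable |r| is bounded by
gene_sd/√(gene_sd² + noise_sd²); infeasible requests raise with that
bound. Probes of one gene share the latent signal, reproducing the strong
within-gene probe dependence seen on real arrays.

Defaults are the study conditions: 57 matched tumor samples (the screen
cohort; `n_normal` defaults to 0 because the motivating screen ran on
tumors only — set it positive to exercise tumor-vs-normal folds), 1–3
probes per gene uniform, 20 miRNAs of which the first three are
miR-200a/b/c carrying tumor shifts of log2(2.56), log2(2.94), log2(3.16)
— the fold changes reported for these miRNAs in squamous-cell lung
tumors. `mirna_sd = 0.7` (log2 units) puts the simulated tumor-vs-normal
t-tests in the same significance range as those reports; `noise_sd = 0.3`
reflects the modest discordance between probe sets of one gene;
`gene_baseline_mean = 8` with SD 1.5 is a typical log2 microarray signal
range. All randomness flows from one seed through deterministically
spawned child streams, so a seed fixes every byte of output.

Prediction tables include each truth pair with probability 1 − fn and
each non-truth pair with probability fp, independently per source;
synthetic Ct tables place the treated target −log2(true fold) cycles from
its control baseline so the expected ΔΔCt inverts exactly.

## Problem sizes

The shipped tests and the acceptance script run the recovery benchmark at
the study scale (57 samples, 200 genes, 20 miRNAs, 30 planted pairs at
r = −0.5, per-source fn = 0.2/fp = 0.01) across 50 fixed seeds in the
test suite and 25 seed-derived replicates in the acceptance script;
null calibration uses 2,000 independent probe–miRNA pairs; ΔΔCt recovery
averages 200 simulated tables; fold-change recovery uses 25 cohorts of
57 tumors + 10 normals and reports the geometric mean (ratios of sample
means are right-skewed, which the arithmetic mean would inherit).

## Numerical choices and edge cases

* r is clipped to [−1, 1] after the dot-product formula to absorb
  floating-point overshoot; |r| = 1 returns p = 0 exactly and marks the
  result `p_exact`.
* Constant vectors and pairs with < 3 complete samples are explicit
  errors (`UndefinedCorrelationError`) or skip-log entries in the grid
  screen — never a silent NaN or r = 0.
* Pairwise-complete n is stored per result and never assumed equal to the
  cohort n.
* The complete-data screen is a single standardized matrix product;
  matrices containing missing cells fall back to a per-pair loop.
* Duplicate feature/sample ids, non-numeric cells (with row/column
  coordinates), negative values under log transform, and double log
  transforms are hard errors at the I/O boundary.

## Known limitations

* Pearson-only: no rank-based or partial correlation, no network
  inference beyond pairwise screening.
* The four prediction algorithms are consumed as tables, never
  re-implemented; no seed-match scanning or duplex energetics.
* No amplification-efficiency correction for qPCR (pure 2^−ΔΔCt), no
  image densitometry (band intensities are inputs).
* The simulator's Gaussian, batch-free noise model understates the messiness
  of real cohorts; recovery numbers are best read as upper bounds.
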