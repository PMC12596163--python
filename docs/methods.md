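# Methods

This note documents the statistical model behind `ecnorm`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing
results.

## Model and workflow

Counts `y_ij` for gene *i* in sample *j* are modelled as negative binomial
with mean `mu_ij` and dispersion `alpha_i`, in the mean–dispersion
parameterization used consistently throughout the codebase:

    Var(y) = mu + alpha * mu^2        (alpha = 0 is the Poisson limit)

The mean is log-linear in a two-level group factor with a per-sample size
factor `s_j` as multiplicative offset:

    mu_ij = s_j * exp(beta0_i + beta1_i * x_j),   x_j in {0, 1}

`x_j = 1` marks the non-reference group; the reference level defaults to
the lexicographically first group label and can be overridden
(`--reference-level`) — the sign of every reported log2FC = `beta1/ln 2`
depends on it.

### Size factors (median-of-ratios)

For each gene with strictly positive counts in every sample, compute the
geometric mean across samples; each sample's factor is the median over
those reference genes of count/geometric-mean, rescaled so the factors
have geometric mean 1. Conventions:

* genes containing any zero are excluded from the reference set (a zero
  forces the geometric mean to zero, making the ratio undefined);
* the median over an even number of reference genes is the arithmetic
  midpoint of the two central ratios;
* if every gene contains a zero the estimation fails loudly rather than
  silently switching schemes; the documented `pseudo_reference` option
  adds 1 to every cell *for this estimation only* (both to the geometric
  means and to the ratio numerators — using raw zeros in the numerators
  would drag sample medians toward zero and defeat the fallback).
  Normalized counts are never pseudocounted.

Rescaling to geometric mean 1 keeps normalized counts on the raw-count
scale, which the default expression floor (mean normalized count >= 100)
presumes.

### Dispersion estimation

Gene-wise dispersions come from a pooled method-of-moments estimator on
normalized counts: with group-wise means `m_g`, variances `v_g` (ddof 1)
and weights `w_g = (n_g - 1)/(n - 2)`,

    alpha_raw = max(0, sum_g w_g * (v_g - m_g) / m_g^2)

Groups with zero mean contribute nothing. With shrinkage enabled (the
default), a robust (Huber) regression of `alpha_raw` on `1/base_mean`
over genes with `alpha_raw > 0` gives a parametric trend
`alpha_trend(mu) = a0 + a1/mu` (clipped below at 1e-8), and the working
dispersion is the geometric interpolation

    alpha = exp(0.5*log(alpha_trend) + 0.5*log(max(alpha_raw, 1e-8)))

This is a deliberately simple, fully documented pipeline rather than a
clone of Cox–Reid/MAP machinery: the quantities the package is validated
on are parameter recovery and test calibration, and a transparent
estimator makes the EC stability ranking (which sorts on `alpha`)
auditable. With fewer than 10 informative genes the trend degenerates to
the median positive `alpha_raw`.

### Wald test

Per gene, the NB GLM is fit by iteratively reweighted least squares with
the dispersion fixed: Fisher-scoring weights `w = mu/(1 + alpha*mu)`,
initialization `beta0 = log(max(mean normalized count, 1e-8))` and
`beta1` from the log-ratio of group means, convergence when
`max |delta beta| < 1e-8`, at most 100 iterations. Because the two-group
design is saturated, each update reduces to weighted group means of the
working response, which vectorizes over all genes at once. No dispersion
floor is applied inside the weights (every denominator is
`1 + alpha*mu >= 1`); flooring alpha would bias the fit away from the
exact Poisson limit at `alpha = 0`.

The standard error of `beta1` comes from the inverse *observed* Fisher
information at the optimum, whose per-sample weight for the log link is
`mu*(1 + alpha*y)/(1 + alpha*mu)^2`; the Wald statistic `beta1/SE` is
referred to the standard normal, two-sided. FDR is Benjamini–Hochberg
over the non-NA p-values. Edge cases:

* genes all-zero in both groups are untestable: every statistic NA;
* non-convergent fits (typically one group entirely zero, so beta1
  diverges) are flagged `converged = False` with NA se/p/FDR; the last
  log2fc iterate is reported as a large-magnitude finite estimate;
* no fold-change shrinkage is applied anywhere: the EC filter thresholds
  |log2FC| at 0.02, a scale that shrinkage would distort.

### Selection

DEGs: raw p <= `deg_p_max` (default 0.05), |log2FC| >= `deg_lfc_min`
(default 0), mean normalized count >= `min_mean_norm` (default 100);
sorted by p ascending, ties by |log2FC| descending, then gene id.

ECs: |log2FC| < `ec_lfc_max` (default 0.02, strict inequality),
raw p >= `ec_p_min` (default 0.8; relaxing to 0.6 is reasonable for small
cohorts), mean normalized count >= `min_mean_norm`; ranked by dispersion
ascending (rank 1 = most stable), ties by |log2FC| ascending, then gene
id. Dispersion is a ranking key only, not a hard filter — the filters
already bound between-group movement, and a hard dispersion cut-off would
need an arbitrary threshold. The expression floor applies to EC selection
too: a reference with near-zero counts cannot anchor a PCR assay.

Both filters use **raw** Wald p-values, not FDR. The EC criterion rewards
*large* p-values, and adjusted p-values are pushed toward 1 by the
correction itself, which would make the EC filter nearly vacuous; the
column names in the output (`pvalue` vs `fdr`) keep the distinction
visible. NA p-values are never selected.

### In-silico qPCR/ddPCR normalization

Per-sample ratios `y[biomarker, j] / y[ec, j]` use **raw** counts: the
per-sample size factor cancels in the ratio, exactly as in a ddPCR well,
so the readout needs no normalization. Samples with EC count 0 are
dropped and logged under the default `exclude` policy (an undetected
reference invalidates a ddPCR well); the `pseudocount` policy adds 0.5 to
both counts instead. Groups are compared with a two-sided Wilcoxon
rank-sum test: exact enumeration when the pooled sample size is <= 20 and
there are no ties, otherwise a normal approximation with mid-ranks,
tie-corrected variance and continuity correction (exact mode refuses tied
data and falls back with a warning). Stars follow the conventional
mapping *** p <= .001, ** p <= .01, * p <= .05, ns otherwise.

A biomarker × EC pair *recapitulates* the sequencing result when the
ratio test is significant at 0.05 **and** the sign of the median ratio
difference matches the sign of the biomarker's log2FC. This explicit rule
(printed in the output header) operationalizes "the PCR readout would
reproduce the NGS finding"; an EC that is itself differentially expressed
in the biomarker's direction cancels the ratio signal and fails it. The
`direction` field can be flipped (`flip_direction`) to match the delta-Ct
convention, where lower values mean higher expression.

## Synthetic-data generator

`simulate_dataset` draws exactly the generative model above: size factors
log-uniform in [0.5, 2] (rescaled to geometric mean 1), baseline means
log-uniform in [50, 5000], NB noise at constant dispersion 0.1 (or an
`a0 + a1/mu` trend), 5% DE genes at |log2FC| = 2 split evenly between up-
and down-regulation (so median-of-ratios estimation stays unbiased;
an all-up design shifts the per-sample medians and absorbs part of the
fold change into the size factors), and 50 planted stable genes with
dispersion 0.01, log2FC 0 and mean 500 — a realistic abundance for a
moderately expressed housekeeping candidate. An optional confounded
control plants a gene with its own fold change to emulate a canonical
reference that is itself disease-regulated. The default test bed is
2000 genes × (20 + 20) samples; all draws flow through numpy's PCG64 from
one integer seed, so matrices are bit-identical across platforms.

What the generator does **not** emulate: batch effects beyond per-sample
scaling, sample-to-sample correlation, gene–gene correlation, zero
inflation beyond the NB, library-preparation biases, or hemolysis-type
artefacts in biofluid miRNA data. Passing the validation suite therefore
demonstrates correctness of the estimators under the model the pipeline
assumes, not robustness to every failure mode of real cohorts.

## Numerical conventions and degenerate inputs

* BH adjustment: step-up over non-NA entries, NA in -> NA out, `m` counts
  only non-NA p-values; inputs outside [0, 1] are an error.
* Heatmaps z-score `log2(normalized count + 1)` per row; a constant gene
  gets an all-zero row. Volcano plots drop NA p-values and clamp p = 0 to
  the smallest positive float before `-log10`.
* Strict input validation: counts must be non-negative integers (a
  `strict=False` mode rounds fractional expected counts, e.g. from RSEM,
  with a warning); the group factor must have exactly two levels with at
  least two samples each; sample sets of matrix and metadata must agree
  exactly (mismatches are reported as a symmetric difference).
* Determinism: given identical inputs, configuration and seed, every CSV
  output is byte-identical across runs; the run manifest records the full
  configuration.

## Validation scenarios and problem sizes

The scenarios in `ecnorm.benchmarks` (used by the test suite and
`scripts/acceptance.py`) run at sizes chosen to make their statistical
assertions sharp while keeping the whole suite fast on a single core:
size-factor recovery and null calibration on 2000 genes × 40 samples;
oracle agreement on 100 random small matrices; log2FC recovery with 200
planted genes at n = 50/group; exact-Wilcoxon enumeration for all
partitions up to pooled n = 8; ratio-test power over 200 replicates at
n = 20/group.

## Known limitations

* The dispersion estimator is method-of-moments with a fixed 50/50
  log-scale blend toward the trend; it is noisier than likelihood-based
  shrinkage at very small n, which mostly widens the EC candidate list
  rather than corrupting its ranking.
* The planted-EC ranking experiment is intrinsically marginal at its
  default conditions: with dispersion 0.01, mean 500 and n = 20/group,
  the sampling SD of a stable gene's estimated log2FC is ~0.05, so the
  strict |log2FC| < 0.02 filter admits each planted gene with probability
  only ~0.3; how many of the 50 planted genes reach the top 20 therefore
  varies noticeably from seed to seed, even though the genes that do pass
  are ranked correctly (lowest dispersion first).
* Only two-group designs are supported: no covariates, interactions,
  continuous predictors, outlier refitting or independent filtering.
* Wilcoxon exact mode is limited to tie-free data; tied data always use
  the corrected normal approximation.
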