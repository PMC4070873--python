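# Methods

This document describes the statistical methods implemented in
`stablemeth`, the numerical choices behind them, and the known limits of
the synthetic data generator.

## Data model and scales

Methylation is measured as a beta value in (0, 1) per probe and sample.
All hypothesis testing happens on M values, M = log2(β / (1 − β)), which
are approximately homoscedastic across the beta range — the constant-
variance assumption of the per-probe linear models. Effect sizes are
reported as delta-beta on the proportion scale, where thresholds such as
|Δβ| ≥ 0.10 have a direct biological reading. Betas are clipped into
[eps, 1 − eps] (default eps = 0.001) before the log-odds transform;
`m_to_beta` inverts `beta_to_m` exactly on clipped inputs.

## Quality control

A probe is removed when its detection p-value exceeds 0.05 in more than
`max_fail_fraction` of samples (default 0: fail anywhere, the strictest
reading), when its bead count falls below 3 in any sample, or when it is
flagged cross-reactive. Each removed probe is counted once, under the
first triggering reason in the fixed order detection → beads →
cross-reactive, so QC reports are reproducible and add up.

## Quantile normalization

`quantile_normalize` forces every sample onto the across-sample mean
quantile function; ties within a sample receive the mean target value over
their rank range. The post-condition is exact: sorted columns agree to
machine precision.

**Limits.** Quantile normalization assumes exchangeable sample
distributions. In simulations where ~15% of probes shift coherently under
treatment (three planted effect classes at 5% each, |Δβ| = 0.15), this
assumption fails in a measurable way: rank coupling between treated and
control samples both shrinks true deltas (by roughly 15–20%) and
manufactures small artifactual deltas at null probes in the sparse region
between the two beta modes. The differential chain run on raw betas (QC →
M values → SVA → moderated models) is exactly calibrated in the same
simulations. This is why the pipeline exposes `run_quantile_norm` /
`run_bmiq` as first-class toggles, and why the calibration and recovery
checks in the test suite exercise the analysis chain directly. For real
arrays — where technical intensity distortions usually dominate coherent
biological shifts — normalization remains the sensible default.

## Probe-type correction

Infinium arrays mix two probe chemistries; type II betas are compressed
toward 0.5. Per sample, a three-component beta mixture (unmethylated /
hemimethylated / methylated) is fitted by EM separately to type I and
type II probes, and type II values are remapped onto the type I reference
state by state.

Numerical design choices:

- **Constrained M step.** Each component's shape parameters are updated by
  a damped projected Newton step on the weighted beta log-likelihood; a
  step is accepted only if it increases the component objective, making
  the procedure a generalized EM with a provably non-decreasing observed
  log-likelihood (asserted in tests). Components are constrained to
  semantic mean ranges (unmethylated ∈ [0, 0.4], hemi ∈ [0.3, 0.7],
  methylated ∈ [0.6, 1]) with the concentration a+b preserved under
  projection. Without the constraint, EM can land in different local
  optima for different samples — e.g. when a treated sample's shifted
  probes form a bump near one mode — and the resulting sample-specific
  state segmentation turns the correction itself into a spurious group
  difference.
- **State-wise empirical quantile matching.** Within each state, source
  values are mapped through the reference state's empirical quantile
  function, with interpolation knots anchored at the state-interval
  endpoints. Every piece is monotone and pinned to the shared thresholds,
  so the composed map is continuous and monotone in the input: a probe
  near a state boundary maps to nearly the same value whichever side it
  falls on. An empty reference state falls back to a linear dilation
  between thresholds.
- **Failure handling.** A sample whose EM does not converge is left
  uncorrected (identity transform) and flagged in the diagnostics table,
  never silently altered.

## Moderated linear models

Per probe, ordinary least squares against a shared design matrix:
intercept, cell-line dummy, timepoint main effects, one treatment-effect
column per timepoint, and any surrogate variables. Using one joint design
across both timepoints pools the residual variance over all bulk samples
(residual df 16 with triplicates instead of 8 per separate timepoint)
while each timepoint keeps its own contrast; both contrasts share one
design, hence one SVA pass and one set of surrogates.

Residual variances are shrunk toward a prior by empirical Bayes: with
s² the residual variance on d degrees of freedom and a scaled
inverse-chi-square prior (d0, s0²),

    s̃² = (d0·s0² + d·s²) / (d0 + d),

and the moderated t = effect / (se·s̃/s) is referred to t with d + d0
degrees of freedom. The prior is fitted by moment matching on log s²
against its scaled-F sampling distribution; d0 comes from inverting the
trigamma function (Newton iteration). With `trend=True` (the pipeline
default) the prior scale follows a smooth trend in each probe's mean M
value — a centred running-mean over the sorted covariate, a deterministic
stand-in for lowess — so only spread *around* the mean-variance trend is
attributed to true variance heterogeneity. Setting `prior_df=0` disables
moderation and reproduces ordinary t exactly; all-equal variances yield
d0 = ∞ and fully pooled variances.

## Surrogate variables

M values are residualized on the design via a QR projection; the top
principal components of the residual matrix are retained while their
eigenvalues exceed the 95th percentile of eigenvalues from row-permuted
residuals (parallel analysis, 20 permutations). Permuted rows are
re-projected onto the residual subspace and rescaled to their original
row norms so the null spectrum carries the same energy as the observed
one; without that correction the threshold is biased and the procedure
over- or under-selects components. Surrogates estimated this way are
orthogonal to the design by construction: they absorb batch *variance*
but cannot correct a batch that is confounded with the design, which is
why confounded layouts must be fixed at the design stage, not rescued by
SVA.

## Blocked class comparison

Sorted-fraction contrasts use a randomized-block ANOVA: full model
(class + block) versus reduced model (block only), tested with the exact
F statistic; under Gaussian errors this is a monotone transform of the
likelihood-ratio statistic (also reported). For a two-level class the F
statistic equals the square of the unmoderated t statistic — asserted to
1e-10 in tests.

## Multiple testing

Benjamini–Hochberg step-up, implemented directly (sort, scale by n/rank,
reverse cumulative minimum, clip at 1) and verified against both an
independent step-up implementation and `statsmodels` on random inputs.

## Signatures, DMRs, enrichment

The persistent-treatment signature keeps probes with q < 0.05 at **both**
timepoints, the same delta-beta sign in every (cell line × timepoint)
stratum, and mean |Δβ| ≥ 0.10 across strata (a `per_stratum` mode demands
the threshold in every stratum instead). The fraction signature uses
blocked p < 0.001 with a consistent per-line |Δβ| ≥ 0.05. DMRs are
maximal runs of ≥ 2 signature probes on one chromosome with consecutive
gaps ≤ 100 bp — verified equivalent to a transitive-closure brute-force
merger on random instances.

Enrichment compares the signature against seeded random probe sets of the
same size drawn without replacement from the QC-surviving universe (the
measurable background, not the full array). Empirical p-values use the
add-one estimator p = (1 + #{null ≥ observed}) / (1 + n_draws), so p is
never zero. GC content uses a two-sided Mann–Whitney test; gene-set
over-representation uses the upper-tail hypergeometric distribution
(verified against exhaustive enumeration for small universes), BH-adjusted
across sets.

## Simulator

The generator produces: a manifest on four synthetic chromosomes with
strictly increasing positions, CGI categories with category-dependent GC
content, genes as runs of consecutive probes, enhancer and cross-reactive
flags, and optional DMR-like clusters (2–6 probes packed within a
configurable span, while background probes are spaced 200–2000 bp so only
planted clusters are mergeable at the default 100 bp gap); a bimodal
beta-distributed baseline with beta-distributed replicate noise; planted
persistent / transient / line-specific effects with one signed delta per
probe (one sign per cluster); additive batch shifts on the M scale; type
II compression toward 0.5; and optional sorted-fraction samples plus a
gene-expression table coupled to planted gene-body methylation.

Batch is assigned by replicate index — replicate r of every condition is
processed in the same run — which makes batch balanced across (and thereby
orthogonal to) treatment, cell line and timepoint by design. Random batch
assignment can alias batch with treatment in small designs, which no
residual-space surrogate method can repair; the deterministic layout
mirrors how paired designs are actually hybridized and keeps the
calibration properties of the chain testable.

**Realism limits.** Noise is beta-distributed around the target mean with
a single precision; real arrays show probe-specific variance structure
beyond the mean-variance trend. Batch effects are additive on the M scale
and shared across probes within a batch; dye-bias-like probe-type × batch
interactions are not modeled. Planted effects are constant shifts, not
mixtures of cell populations. Detection p-values and bead counts are
generated clean (failures must be injected by the caller); clipping at
the interval edge truncates planted shifts for probes whose baseline sits
near 0 or 1, so realized deltas can be slightly smaller than configured.

## Default problem sizes

Defaults (10,000 probes, triplicates, 5% of probes per effect class,
|Δβ| = 0.15, noise precision 50, 2 batches with SD 0.2, type II
distortion 1.3) are chosen so that a desk-scale run finishes in seconds
while the planted structure is neither trivial nor hopeless: the analysis
chain recovers persistent probes with sensitivity ≈ 0.83–0.86 at
empirical FDR ≈ 0.02–0.04, and admits ≤ 0.5% of transient probes. These
are simulation study conditions, not tuned values; changing them changes
difficulty, not correctness.
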