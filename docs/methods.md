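# Methods

`omicsbench` implements a pan-cancer benchmark that asks, per cancer driver
gene: how well does each functional -omics readout predict which tumors carry
a non-silent mutation in that gene? This note documents the models, the
statistics, the synthetic-data generator, and the numerical and design
choices behind them.

## Mutation-status labels

For a target gene, a sample is labeled positive when it carries a non-silent
somatic variant in that gene, or a deep copy-number gain (GISTIC call +2)
if the gene is an oncogene, or a deep loss (call −2) if it is a tumor
suppressor; genes annotated as both accept either event. The thresholds are
configurable (`gain_threshold` / `loss_threshold`) to admit shallow (±1)
events; deep-only is the default as the conservative reading of thresholded
copy-number calls. All remaining samples are negative.

Hypermutated samples — non-silent burden at least five standard deviations
above the cohort mean — are removed before labeling to limit
passenger-mutation false positives. The SD is the sample (n−1) estimator,
computed once over all samples before exclusion; the boundary is inclusive
(count ≥ mean + 5·SD). When all counts are equal (SD = 0) nothing is
excluded. Note a structural fact about this filter: the largest possible
z-score among n samples is (n−1)/√n, so a lone outlier can only be caught
when n is large enough (n ≳ 27 for 5 SD); the tests cover this explicitly.

Gene lists are built by merging curated sources (union over sources;
conflicting oncogene/TSG annotations resolve to `both`; genes annotated only
as fusion partners are dropped). Control lists are either the most
frequently mutated genes (ties broken by symbol for reproducibility) or a
seeded uniform sample from the validity-filtered pool.

A cancer type is *valid* for a gene when it contributes at least 15 and at
least 5% mutated samples (both inclusive); each gene's experiment runs only
on samples from its valid types, and genes with no valid type are skipped
with a recorded reason.

## Features

Pipeline order is fixed: variability filtering on unstandardized values,
then per-column z-scoring, then optional PCA.

- Variability filter: mean absolute deviation about the column mean
  (a literal "mean absolute deviation"; a median-based variant is a config
  switch). Ties break by column order.
- Standardization: (x − mean)/sd per column, population SD by default,
  zero-variance columns mapped to exact zeros. The default fit scope is the
  whole matrix (whole-dataset preprocessing); a leakage-safe mode fits the
  statistics on training samples only and is exercised in the tests.
- Methylation missing values: drop the 10 samples with the most missing
  entries (skipped when nothing is missing), mean-impute probes with 1–2
  missing values, drop probes with more. The output is guaranteed complete.
- PCA: top min(p, k, n−1) components on standardized input; each
  component's sign is fixed so its largest-magnitude loading is positive,
  making scores reproducible across platforms.
- Covariates: one-hot cancer type (types present among included samples)
  plus log10(non-silent count + 1); the +1 offset admits zero-burden
  samples. The covariate block is appended after all predictor columns and
  is penalized like any other column by default (an exemption switch
  exists, since the original treatment is not documented).
- Multi-omics: early integration by column-wise concatenation of the
  processed per-modality blocks, identical covariate block appended once.

## Models

Both models minimize

    mean_loss(X, y; w) + α·λ·‖w‖₁ + ½·α·(1−λ)·‖w‖₂²

with α the overall penalty strength and λ the L1 fraction (note some
libraries swap these names). The loss is the mean per-sample negative
log-likelihood for logistic regression, and the mean per-event negative
Breslow log partial likelihood for the Cox model. Mean (not sum) scaling
keeps the α grid's meaning stable across sample sizes and matches the
convention of SGD-style solvers common in this literature. The L2 term is
squared — the standard elastic net.

Optimization is FISTA (accelerated proximal gradient with soft
thresholding), with an explicit Lipschitz step for the logistic loss
(spectral norm of [X, 1] by deterministic power iteration; the unpenalized
intercept takes the larger, ridge-free step) and backtracking line search
for the Cox loss, plus gradient-scheme adaptive restart. The solver is
deterministic — no stochastic sampling — so fits are exactly reproducible
without seed bookkeeping. Convergence is declared when the relative change
of the penalized objective stays below `tol` (default 1e-9 standalone,
1e-6/1e-7 inside cross-validated benchmarks); warm starts across the
hyperparameter grid accelerate the nested search. Oracle tests pin the
solver to: unpenalized MLE agreement at α=0 (≤1e-3 relative), a dense
grid-search minimum within 1% on small instances, and a 1-D numerical
minimizer for the penalized Cox case (≤1e-4).

Cox ties use the Breslow approximation. The Cox model stores no baseline
hazard; `predict` returns the linear risk score w·x, higher meaning higher
hazard.

## Evaluation

Each (gene × modality set) experiment runs two replicates of 4-fold
cross-validation, stratified jointly by cancer type and sample type (strata
smaller than the fold count merge into the same cancer type's largest
stratum). Hyperparameters come from 3-fold nested CV on the outer-training
set: default grids α ∈ {1e-4, 1e-3, 0.01, 0.1, 1, 10} and λ ∈ {0, 0.05,
0.1, 0.3, 0.5, 0.7, 0.9, 1} (48 pairs), scored by mean inner AUPR, ties
resolved to smaller α then larger λ. The survival variant uses a wider
α grid (up to 1000) and inner c-index.

The null condition permutes labels uniformly within each (cancer type ×
train/test) cell of each split, preserving per-cell positive counts
exactly, and re-runs the full hyperparameter search so the baseline enjoys
the same model-selection flexibility. Performance is AUPR (average
precision) and AUROC; pairs of models are compared by two-sided paired
t-tests over the eight fold-matched measurements (all-zero deltas give
p = 1; near-degenerate spreads get a 1e-12 variance floor and a flag).
Benjamini–Hochberg FDR is applied within families: vs-baseline tests within
each modality set, cross-modality equivalence tests within each gene. A
gene is *well-predicted* by a modality when its vs-baseline q-value passes
the corrected threshold (default 0.001) **and** the mean AUPR delta is
positive — the sign guard keeps permuted-better-than-true flukes out. The
summary grid marks, per gene, the best modality (highest mean delta AUPR)
and every modality statistically equivalent to it (pairwise paired t-tests,
BH within gene, not significant at 0.05).

Survival models are evaluated by the censored concordance index
(event-vs-censored ties at equal times count as comparable with the event
first; score ties credit ½), against a covariate-only baseline (age, log10
burden, one-hot cancer type). Clinical endpoints follow a per-cancer-type
map: progression-free interval for the nine types with few observed deaths
(BRCA, DLBC, LGG, PCPG, PRAD, READ, TGCT, THCA, THYM), overall survival
otherwise.

## Synthetic cohorts

The generator is a Gaussian latent-factor model with additive mean shifts —
chosen so a linear classifier's detectability of a planted signal is
analytically controllable. Per modality: per-(cancer type, feature)
baseline offsets (SD `type_effect_sd`, default 1), a low-rank factor
structure (5 factors, loading SD 0.5), and i.i.d. noise (SD 1).
Methylation-like matrices squash the latent values through a logistic map
to (0, 1); signature-like matrices exponentiate a damped latent to stay
nonnegative. Missing entries appear at `missing_rate`, with an optional set
of high-missingness samples at 10× the rate.

Mutations are per-gene per-type Bernoulli draws; burden is log10-normal
(mean 2.0, SD 0.4 — a few hundred non-silent calls per exome, median 100)
with a hypermutated fraction (default 2%) multiplied by 30, which both
seeds the 5-SD filter and (via a genome-wide elevated per-gene rate
p′ = 1−(1−p)^30) creates the realistic coupling between burden and labels.
CNV gains/losses are drawn independently of point mutations (one uniform
draw, so a sample never carries both), keeping the oncogene/TSG label rules
separable in tests.

A planted gene shifts `n_signal_features` randomly chosen features by
`effect_size` noise-SD units in mutated samples. With
`signal_latent_sd > 0` the shift is instead mediated by a per-(gene,
sample) latent pathway activity shared across all modalities the gene
signals in; this is the control for cross-modality redundancy — each
modality then re-measures the same latent, and no amount of concatenation
can exceed the information the latent carries about the label. With the
default (0), modalities receive independent replicate measurements and
concatenation genuinely helps; both regimes are real phenomena, and which
one a gene exhibits is exactly what the benchmark is designed to detect.

Survival times are exponential proportional hazards on
β_age·age + β_burden·log10(burden+1) + γ·factors, with independent
exponential censoring whose rate is calibrated (by root finding on the
drawn event times) so the observed event fraction matches 1 − the requested
censoring rate. OS-like and PFI-like endpoint pairs share the linear
predictor, with PFI events on a 3× faster clock.

Every generator is a pure function of (spec, seed); a master seed expands
to named child seeds via a SHA-256 derivation, so any component can be
regenerated independently.

What the generator does **not** emulate: real marginal distributions of any
TCGA platform, probe annotations or genome coordinates, tumor purity,
subclonality, batch effects, or nonlinear mutation signatures. Passing
tests therefore certify the pipeline's statistics (calibration, power,
pairing, exactness), not performance claims about real tumors.

## Benchmark test conditions

The end-to-end suites use, as their standard conditions: 3 cancer types
(0.34/0.33/0.33), prevalence 0.20–0.25, effect size 2.0 with 20 signal
features for power checks, 50 null genes at n = 2000 for calibration, and a
reduced 3×3 hyperparameter grid (α ∈ {1e-3, 0.01, 0.1}, λ ∈ {0, 0.5, 1})
for multi-gene runs; 50–100 features per modality. Calibration and power
cohorts set the hypermutated fraction to zero: hypermutated samples that
escape the 5-SD filter couple labels to the burden covariate — genuine
signal that would contaminate a measurement of behavior under no signal.
The acceptance script (`scripts/acceptance.py`) re-runs the same measurements
at moderately smaller sizes (n = 1000, 20 null genes, 6+6 planted genes;
survival at n = 2000).

## Known limitations

- The permuted-label baseline re-searches hyperparameters per condition;
  reusing the true-label choices is not implemented as a config option yet.
- The FISTA logistic solver computes a spectral norm per fit; for very wide
  matrices (p ≫ 10⁴) a randomized sketch would be preferable.
- `call_summary_grid` assumes every modality of a gene shares the same
  non-dropped fold keys; a gene with folds dropped in one modality only
  raises rather than aligning silently (pairing integrity is a hard error
  by design).
- The neural-network classifier variant and probe-type (BMIQ-style)
  methylation normalization are out of scope.
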