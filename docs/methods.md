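# Methods

This note documents the statistical procedures oplskit implements, the
conventions it fixes where chemometrics software differs, and what the
synthetic data do and do not establish.

## Internal-standard normalization

Eleven compounds spiked at constant amount into every sample track the
common intensity factor (injection volume, extraction efficiency,
detector drift). The standards matrix is divided column-wise by its
per-standard SD (population, 1/n) and a one-component PCA is computed
**without mean-centring**; each sample's peak areas are divided by its
first-component score t1, whose sign is fixed so the mean score is
positive.

Centring is omitted deliberately: a centred t1 can be zero or negative,
making division undefined, whereas the uncentred score is a weighted
mean intensity and stays positive for positive data. A consequence is
that exact per-sample scale equivariance (multiply one sample's areas
and standards by c, expect an unchanged normalized profile) holds only
to first order: the scaled sample also moves the column SDs and the
loading vector. The deviation is ≈0.5% for a 20% perturbation at n = 80
and grows roughly quadratically, so the property is tested as a local
equivariance. Any resulting t1 ≤ 0 raises an error — the standards are
then inconsistent with a single intensity factor and normalization
would be meaningless.

## Scaling

Unit-variance (UV) scaling is used for PCA and OPLS models: column mean
0, population SD 1, computed over non-missing entries; missing entries
are imputed at the column mean (0 after scaling), which is neutral for
the cross-products both algorithms use. Zero-variance columns raise an
error naming the column.

## NIPALS PCA, projection, Hotelling T²

Components are extracted sequentially by NIPALS (deterministic start:
the residual column of largest variance; convergence 1e−10 on the score
vector, max 500 iterations; non-convergence is an error naming the
component — it occurs when successive eigenvalues are nearly tied, in
which case any convergent component is equally good and a larger
iteration cap or SVD is advisable). Loading columns are unit-norm with
the largest-magnitude entry positive. New samples are projected with
the stored centring/scaling and loadings. Hotelling T² uses the
training score variances; the (1−α) limit is A(n−1)/(n−A)·F₁₋α(A, n−A).

### Representative-sample selection (multivariate design)

Given 2-component scores, samples are picked per quadrant (boundary
scores count as positive): first the sample farthest from the origin,
then samples maximizing the minimum distance to the picks already made
in that quadrant *and to the origin*; finally `center` samples closest
to the origin. Including the origin in the spread criterion is a design
choice: without it the second pick in a dense quadrant can be the
origin itself, which duplicates the role of the centre picks instead of
spanning the periphery. Ties break by sample-id order; underfilled
quadrants yield fewer samples with a logged warning.

## OPLS-DA

X is UV-scaled and y (placebo = 0, active = 1) centred internally.
Orthogonal components are removed sequentially (w ∝ X'y normalised;
p = X't/(t't); w_o ∝ p − (w'p)w; t_o = Xw_o; deflate X by t_o p_o'),
then one predictive component is computed on the filtered matrix. With
zero orthogonal components the model is exactly one-component PLS1, and
with one orthogonal component its fitted values coincide with
two-component PLS — both identities are asserted in the tests against
an independently coded PLS1.

Default **n_orthogonal = 1** (one predictive + one orthogonal
component, the configuration the small-cohort analyses this package
targets typically settle on); `fit_opls` accepts any count and an
auto policy can be emulated by adding components while Q² improves by
more than 0.01.

* **p(corr)** — Pearson correlation of each scaled variable with the
  predictive score t, computed on the *undeflated* scaled matrix so
  values are comparable across models.
* **VIP** — total VIP over all components: squared predictive weights
  carry the y sum-of-squares explained by t, each orthogonal
  component's squared weights carry the X sum-of-squares it captures,
  normalised so Σ VIP² = K. This is the variant that modern
  chemometrics software reports for OPLS models, and the conventional
  0.8 threshold is applied to it.
* **R²X** counts predictive plus orthogonal X variation.

## Cross-validation and the predicted-Y test

Seven-fold by default. Fold assignment is deterministic: samples sorted
by (class, sample id), dealt round-robin — reproducibility is preferred
over mimicking any particular software's internal split. Each fold is
predicted by a model refit from scratch (including scaling) on the
remaining samples; Q² = 1 − PRESS/Σ(y−ȳ)². Group separation is
quantified by a Welch two-sample two-tailed t-test on the out-of-fold
predicted y values.

## Jack-knife confidence intervals

Over the G = n_folds cross-validation rounds, the per-variable
statistic (p(corr) by default; scaled coefficients b·w optionally) is
recorded with its sign aligned to the full model's score direction on
the shared samples (NIPALS sign indeterminacy would otherwise inflate
the SE). SE = √((G−1)/G · Σ(s_g−s̄)²), CI = full-model statistic ±
t₁₋α/2,G−1 · SE; a variable is significant when its CI excludes zero.
p(corr) is jack-knifed because the significance calls accompany the
p(corr) loading profile in this workflow; under a no-effect generator
the per-variable flag rate measures ≈0.08 at α = 0.05 — the CV rounds
are correlated resamples, so the procedure is mildly anti-conservative,
which is accepted and documented rather than recalibrated.

## Univariate statistics

Per-metabolite two-sample, unequal-variance, two-tailed t-tests
(Welch–Satterthwaite df) on non-missing values; metabolites with fewer
than two usable values in a group are flagged untestable and logged.
Raw p-values are reported (multiplicity adjustment is a deliberate
non-default; a Benjamini–Hochberg column is available). Baseline 2×2
tables use Pearson chi-square, df = 1, **no continuity correction** —
the convention that reproduces 11 of 12 printed baseline p-values at
two decimals; the remaining row (hypertension) does not reproduce from
its printed counts under any standard 2×2 test and is treated as a
transcription defect in the source. Rows with a zero margin or a zero
observed cell are reported as untestable (NaN), matching the "n/a"
convention of published baseline tables.

## Multi-batch and multi-study synthesis

Per-batch p(corr) vectors form a batch × metabolite matrix (metabolites
missing in a batch are mean-imputed across the batches that measured
them); its first loading from an unscaled, **uncentred** PCA is the
combined profile, sign-aligned to the first batch. Profiles must come
from normalized data: on raw areas, random group-mean dilution
differences give every metabolite a shared correlation with t, and that
batch-specific common mode dominates the uncentred meta-PCA.

Direction calls: UP/DOWN when the jack-knife CI excludes zero *and*
VIP ≥ 0.8, NONE otherwise. Concordance counts a metabolite as congruent
when its reference-study call (including NONE — "no change" is a result)
recurs in at least one comparison study; MISSING (not detected) never
matches and is excluded from pairwise denominators. Both changed-only
and all-calls pairwise agreement are exposed because summary statements
of the "X% showed the same changes" kind are ambiguous about the
denominator.

## Synthetic cohorts

Peak areas are log-normal: area = exp(base_m + log(effect)·active +
batch + dilution + noise), with internal standards sharing the batch
and dilution terms only. Treatment-affected metabolites form two
contiguous blocks — an amino-acid-like block (20% of metabolites,
effect 0.8×) and a saturated-fatty-acid-like block (8%, 1.25×) — with
within-block noise correlation 0.5 via a shared per-sample factor.
Defaults: 9 subjects per arm, 95 metabolites, 11 standards, log-dilution
SD 0.3, per-batch log-offset SD 0.1. The residual noise SD of 0.18
(≈18% between-subject CV, within the usual range for plasma GC-MS) is
calibrated so the default cohort's median seven-fold Q² matches the
≈0.4 cross-validated predictability reported for the study this
pipeline re-implements. Affected counts use floor(fraction·K) for
determinism; the seed fully determines every output.

The generator emulates the *statistical* structure only: no
chromatographic peak shapes, retention drift, censoring-by-LOD
missingness (missing metabolites are batch-level and at random), heavy
tails, or covariate structure. Passing the simulation suite therefore
shows the algorithms are correct and calibrated under the assumed
log-normal block model — not that the pipeline is robust to every
pathology of real GC-MS data.

The planted non-compliant control (`plant_outlier`) applies the active
effect multiplicatively to a placebo sample's affected metabolites —
the conditional re-draw that keeps the sample's own noise, making the
operation exactly invertible.

## Numerical conventions

Population (1/n) SDs everywhere; NIPALS tolerance 1e−10, max 500
iterations; loading sign by largest-magnitude entry positive (PCA) or
mean-score positivity (normalization) or first-batch alignment (meta);
fold assignment and quadrant/tie rules as above. All matrices are
samples-in-rows. Configuration is validated before any stage runs, and
the pipeline is a pure function of (inputs, config).

## Problem sizes

The test and acceptance simulations use the study-scale conditions
(9+9 samples, 95 metabolites) with 20–200 replicates per property —
enough for the pass bands used (rates within a factor two of nominal,
recovery/power thresholds with ≥10-point margins in expectation) while
keeping the full suite inside a few minutes on one CPU.
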