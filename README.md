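# oplskit

A chemometrics pipeline for two-arm GC-MS metabolomics intervention
studies, built around OPLS-DA: internal-standard normalization, NIPALS
PCA with multivariate-design sample selection, OPLS-DA with seven-fold
cross-validation, jack-knife confidence intervals, VIP and p(corr)
diagnostics, per-metabolite Welch t-tests, baseline chi-square tables,
and cross-study effect-direction concordance. A synthetic-cohort
generator reproduces the statistical structure of plasma peak-area data
(log-normal levels, correlated treatment-affected blocks, per-sample
dilution, batch offsets), so every stage is testable without any
external download.

The intended users are analysts of small designed nutrition /
supplementation trials (here: selenium + coenzyme Q10 in elderly men,
9–31 subjects per arm, ~95–107 identified metabolites per batch) who
need the SIMCA-style modelling chain as scriptable, tested code.

## The model

For a peak-area matrix **X** (samples × metabolites, UV-scaled) and a
centred 0/1 group vector **y**, OPLS-DA splits predictor variation into
one y-predictive component and y-orthogonal components:

    w ∝ X'y,  t = Xw,  p = X't/(t't)
    w_o ∝ p − (w'p)w,  t_o = Xw_o,  p_o = X't_o/(t_o't_o),  X ← X − t_o p_o'

After removing the orthogonal component(s), the final predictive score
t carries the between-group difference; ŷ = b·t + ȳ. Diagnostics:
R²X (fraction of X sum-of-squares modelled), R²Y(cum) (explained
y-variance), Q²(cum) = 1 − PRESS/SS from seven-fold cross-validation,
p(corr)_j = corr(x_j, t) ∈ [−1, 1], and VIP normalised so that
Σ VIP² = K (VIP ≥ 0.8 marks an influential metabolite). Significance
per metabolite comes from jack-knife 95% CIs on p(corr) computed over
the cross-validation sub-models. Normalization divides each sample by
its t1 score from an uncentred, SD-scaled PCA of the 11 internal
standards. Multi-batch results are merged by an unscaled, uncentred PCA
of the batch × metabolite p(corr) matrix, and studies are compared by
direction concordance (up / down / no change).

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/02_normalize.py
python analysis/03_fit_opls_da.py
```

prints (seed 1):

```
cohort: 18 samples × 95 metabolites (seed 1)
planted effects: 19 lowered, 7 raised metabolites
t1 scores span [5.77, 18.84] (common intensity factors)
median per-metabolite CV: 0.315 raw → 0.185 normalized
OPLS-DA (18 samples, 95 metabolites, 1 orthogonal component):
  R2X = 0.26  R2Y(cum) = 0.99  Q2(cum) = 0.76
  cross-validated predicted-Y Welch test p = 4.2e-06
  direction calls: 18 metabolites flagged, 16 consistent with the planted truth (26 planted)
```

That is: normalization halves the median coefficient of variation by
removing per-sample dilution; the OPLS-DA model separates the arms far
better than chance (Q² ≫ 0, predicted-Y test p ≈ 4×10⁻⁶); and the
jack-knife + VIP direction calls recover most of the planted effects at
n = 9 + 9. `analysis/04_baseline_tables.py` reproduces 11 of the 12
printed baseline chi-square p-values at two decimals, and
`analysis/05_cross_study_concordance.py` reports the 62/107 (57.9%)
cross-study concordance from the packaged three-study direction table.

The same stages are available as a CLI (`oplskit simulate|normalize|
select|fit|ttest|baseline|concord|combine|run|validate-tables`) and as
library functions (`oplskit.fit_opls`, `oplskit.jackknife_ci`, …).

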