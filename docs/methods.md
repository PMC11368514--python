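# Methods

## Normative reference models

For each of the 38 (sex × airway site) cells, lumen diameter (mm) is
regressed by ordinary least squares on

```
[1, rcs(TLV), rcs(age), rcs(height)]
```

where `rcs` is the restricted (natural) cubic spline in Harrell's
truncated-power form, normalised by the squared boundary-knot span. Each
predictor gets 3 knots at its 10th/50th/90th within-cell percentiles
(configurable via `KnotRule`); with 3 knots each predictor contributes a
linear plus one nonlinear column, so the design has 7 columns and stays
full-rank at modest cell sizes. A minimum cell size of 25 (configurable)
is enforced; smaller cells raise an error naming the deficient cell.
There are no interactions among TLV, age and height, and diameter is
modelled on the natural (mm) scale; a log-scale variant is deliberately
not implemented. `residual_sd` is the root mean squared residual with
denominator n − p.

Predictions outside a predictor's boundary knots are linear
extrapolations and emit a warning rather than an error: study subjects
legitimately exceed the normative covariate envelope (the default knot
rule places boundary knots at the 10th/90th percentiles, so roughly a
fifth of in-range subjects also trigger it; it is informational).

The fitted set serialises to versioned JSON (`airwayhet-reference-1`);
serialisation is byte-stable and round-trips exactly, so a manifest hash
identifies a model set.

Units are validated throughout: diameters mm, TLV litres, height cm,
age years.

## Caliber summaries

Heterogeneity is the sample SD (denominator n − 1) of the 19
percent-predicted diameters; mean caliber is their arithmetic mean by
default, with a geometric-mean option (both conventions appear in the
field; the arithmetic mean is the default and the two differ by < 1% at
typical dispersion). CoV = SD / mean. By default all 19 sites are
required (`min_sites=19`); a lower `min_sites` tolerates degraded data
and the count of used sites is carried in the output.

Quartiles use the linear-interpolation sample-quantile definition with
intervals closed on the left (a value equal to a cut point joins the
lower group); Q1 (least heterogeneous) is always the reference. The
pooled percent-predicted distribution is described by a Gaussian KDE
with Silverman's rule-of-thumb bandwidth on a grid spanning the data
± 3 bandwidths (trapezoidal integral 1 to within ~0.3%). The Spearman
correlation between heterogeneity and mean caliber uses midranks for
ties and a Fisher-z interval with the rank-correlation variance
1.06/(n − 3); Gaussianity is reported descriptively
(skewness/kurtosis), never gated.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not CT images or airway geometry.

**Covariates.** Age uniform 45–85 yr; sex balanced; height normal by sex
(162 ± 6 / 176 ± 7 cm); TLV linear in height and sex with Gaussian
scatter, floored at 1.5 L; four race-ethnicity categories; smoking
status never/former/current (0.45/0.35/0.20) with Gamma pack-years for
ever-smokers; secondhand, occupational, asthma, pipe and cigar flags.

**Normative diameters.** `d = scale_site × (TLV/4.5)^0.35 ×
(height/170)^0.30 × (1 − 0.0015(age−60)) × exp(eps)`, `eps ~ N(0, 0.08)`
on the log scale; site scales run from 16.9 mm (trachea) to ~3 mm
(subsegmental paths). The mild power-law nonlinearity is well inside
what a 3-knot spline captures. Within-site scan–rescan measurement
noise is a separate knob, default 0.

**Percent-predicted structure and its calibration.** Site values are
`p_a ~ N(m_i, sigma_i^2)` truncated positive, with `m_i` Gaussian and
`sigma_i` Gamma. The subject's *true* mean caliber and heterogeneity are
defined as the realised 19-site profile mean and SD — the measurand in
this field *is* that statistic — and outcomes are generated from the
realised values, which makes downstream regression recovery exactly
unbiased rather than attenuated by site-sampling error. The latent
mixing moments are calibrated in closed form so that the realised
summaries have the configured cohort moments (defaults: mean caliber
99 ± 10 % predicted, heterogeneity 14 ± 5 %): with `c4(19) = 0.98621`
(the normal-theory E[SD]/sigma constant),

```
E[sigma]   = het_mean / c4
Var(sigma) = het_sd^2 − (1 − c4^2) E[sigma]^2
Var(m)     = pop_sd^2 − E[sigma^2] / 19
```

Infeasible combinations (heterogeneity spread smaller than the
irreducible site-sampling variability) are rejected at config
validation. Setting `het_mean = het_sd = 0` gives the degenerate
zero-spread cohort.

**Spirometry.** Baseline FEV1 (mL) = demographic norm (linear in age,
sex, height) + 15·(m − 100) − 12·(s − 14) + smoking/asthma effects +
N(0, 400). The −12 mL per % default makes a 1-SD (≈5%) increase lower
FEV1 by ≈60 mL — the magnitude scale of the reported cross-sectional
estimates, chosen for realistic power in recovery tests, not as ground
truth about any cohort. FEV1/FVC is built analogously on the ratio
scale (−0.001 per %, residual 0.05, clipped to (0.30, 0.95) with counts
logged) and FVC = FEV1/ratio, so FEV1 ≤ FVC and the ratio lies in (0,1)
by construction. Symptom scores (CAT, mMRC, chronic bronchitis) couple
loosely to obstruction severity for the symptom-based COPD definition.

**Longitudinal visits.** Default schedule 0/3/6 yr;
`FEV1_it = FEV1_i0 + (decline + gamma (s_i − 14)) t + b_i + e_it` with
decline −33 mL/yr, interaction gamma default 0, random intercept
150 mL, stationary AR(1) residuals (sd 120 mL, rho 0.4) indexed by
visit order; smoking switches current↔former by a small Markov step per
visit (rate 0.05).

**Selection.** Strata (default: smoking ever/never × obstructed/not) are
Bernoulli-subsampled with configured inclusion probabilities; retained
subjects carry weight 1/pi_h (Horvitz–Thompson).

Ground-truth columns are prefixed `latent_`, written to a separate CSV
by the pipeline, and the design builder refuses to read them.

**What passing tests do and do not show.** The generator's site values
are exactly Gaussian within subject, covariates are independent of the
latent airway structure, effects are exactly linear, and selection is
exactly Bernoulli-stratified. Passing recovery/coverage tests therefore
certifies the estimation machinery, not robustness to real-data
features such as non-Gaussian profiles, covariate-dependent airway
structure, informative missingness or measurement drift.

## Association models

Designs are built explicitly (no formula layer): model 1 = age, age²,
sex, height, height², race-ethnicity dummies (first category
reference), mean caliber; model 2 adds smoking-status dummies,
pack-years, pipe/cigar status and years, secondhand, occupational,
asthma. Missing covariates use the indicator method when enabled
(mean-fill plus a missingness indicator; mean-fill rather than zero-fill
to limit collinearity with the intercept) and complete-case otherwise.
Rank deficiency raises an error naming aliased columns.

Exposure codings: quartiles (Q2–Q4 dummies), per-1-SD (exposure divided
by its sample SD *within the analysis set actually fitted* — so
cross-cohort comparisons must rescale), CoV (the `cov` column run
through the same per-SD code path), 3-knot restricted cubic spline, or
raw. Linear fits are (weighted) least squares; logistic fits are GLM
maximum likelihood with frequency weights for IPW. Confidence intervals
are Wald (estimate ± 1.96 SE) on both scales, matching the symmetric
intervals conventionally reported; profile likelihood is not
implemented. With weights on, standard errors are HC0 sandwich — IPW
point estimates are consistent either way and the sandwich protects
inference. Separation and non-convergence raise explicit errors, never
silent estimates. The synthetic LLN rule is the 5th percentile of the
generator's healthy ratio distribution given age (mean − 1.645
residual SD) and is injectable for real data.

The spline sensitivity check fits the linear-exposure and 3-knot-spline
models and reports the extra-sum-of-squares F test of the nonlinear
terms plus the AIC difference; verdict "no improvement" when p ≥ 0.05
and the AIC gain is < 2.

## Longitudinal model

ML (not REML, so likelihood-ratio comparisons across fixed-effect
specifications are valid) for a subject random intercept plus AR(1)
residual correlation indexed by visit order (homogeneous visit
variances; a continuous-time exponential correlation was considered and
not implemented — visit-order AR(1) is the conventional reading and is
recorded in the result object). Fixed effects: covariates + exposure +
time + time × exposure; time is years since each subject's baseline.
The likelihood profiles out beta (GLS) and the residual scale, leaving
a 2-parameter deviance in (lambda = tau²/sigma², rho) minimised by
Nelder–Mead under transforms lambda = exp(u), rho = 0.995 tanh(u);
per-subject covariance inverses depend only on the visit count and are
shared. Wald CIs use the GLS covariance at the ML variance estimates.
With at most 2 visits per subject rho is confounded with the random
intercept, so it is fixed at 0 and flagged in `notes`; `fix_rho` and
`random_intercept=False` reproduce pooled OLS exactly (verified to
1e-8). Annualised change is the per-subject OLS slope; subjects with
one visit are excluded with a reported count.

## Validation and problem sizes

The replicate studies use, as the package's own choices: 200 replicates
at n = 2500 for cross-sectional recovery (truth −60 mL per 1-SD; mean
recovered within 5%, coverage within the binomial band around 0.95),
500 null replicates for logistic, mixed-model and spline-nonlinearity
type-I error (bands [0.03, 0.07] at alpha 0.05), 1000 subjects × 3
visits for the mixed model, 60 replicates for interaction recovery
(Monte-Carlo SE ≈ 0.02 mL/yr per %, ample for a 10% band around −3),
and n = 5000 for the distributional-emulation check with 3-standard-
error tolerances. `run_validation_study` exposes the same machinery
with configurable replicate counts; with a single replicate all
Monte-Carlo SEs are flagged unusable.

## Known limitations

* The published reference-equation coefficients are not reproduced; the
  spline family, knot count and placement of the originals are not
  public, so the defaults here are documented stand-ins carried in model
  metadata.
* Multiple imputation of missing spirometry, race-ethnicity
  harmonisation across cohorts, and CT segmentation are out of scope.
* Random slopes are intentionally absent (random intercepts only);
  dropout is not jointly modelled.
* The weighted logistic sandwich treats weights as known constants, as
  is standard for design-based selection probabilities.
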