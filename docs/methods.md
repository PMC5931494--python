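# Methods

## The estimation problem

A genetic variant that raises plasma 25(OH)D, was assigned at conception,
and affects diabetes risk only through 25(OH)D is an instrumental variable:
the ratio of its effect on diabetes (log odds ratio per allele) to its
effect on 25(OH)D (nmol/l per allele) estimates the causal effect of
25(OH)D on diabetes free of classical confounding. `vitdmr` implements
that logic at two levels — individual-level (allele-score IV on cohort
tables) and summary-level (per-SNP Wald ratios pooled across studies) —
together with the observational analysis it is compared against. All
causal effects are reported per 25 nmol/l higher 25(OH)D, the unit the
field uses for vitamin D interventions.

## Synthetic cohort generator

### Model

For individual i with dosages g_ij ∈ {0,1,2} drawn Binomial(2, p_j):

```
X_i = area_baseline(a_i) + s·(season_i − 1/2) + Σ_j β_Xj (g_ij − 2p_j)
      + Σ_c γ_c (C_ic − C̄_c) + ε_i,        ε_i ~ N(0, σ²)
logit P(case_i) = b0 + θ (X_i − 62.1) + Σ_j α_j (g_ij − 2p_j)
      + Σ_c δ_c (C_ic − C̄_c)
```

Genetic, season and confounder terms are centred so that configured area
baselines are the area means and `b0` is interpretable at average
covariates. θ is the injected causal effect (log odds per nmol/l); the
α_j are per-SNP direct effects used to inject pleiotropy. Cases are split
into prevalent/incident labels with a configured fraction (default
496/1475, matching the baseline-vs-follow-up split of the cohort the
generator emulates), which exercises the prevalent-exclusion rule in the
observational stage.

### Default calibration

- Four SNPs with frequencies 0.46/0.36/0.70/0.84 and exposure effects
  2.84/0.95/3.59/0.51 nmol/l per allele; zero LD (the variants sit in
  different genomic regions and are treated as independent instruments).
- Ten equal-sized areas from 20°N to 46°N with area-mean 25(OH)D falling
  nonlinearly from 90 to 49 nmol/l; the baselines average 62.1 nmol/l.
  Season is uniform over four categories with a winter→summer contrast of
  11 nmol/l (shoulder seasons halfway).
- Residual SD 16.0 nmol/l, chosen so that area + season + genetic +
  confounder + residual variance reproduces an overall exposure SD of
  20.2 nmol/l.
- Covariates follow the published cohort characteristics (age 51.4 (10.6)
  truncated to 30–79, 60.5% women, BMI 23.7 (3.4), SBP 131.2 (21.3), DBP
  77.8 (11.2), glucose 6.1 (2.4)); body-fat % is given a mild path into
  both exposure (−0.15 nmol/l per %) and outcome (+0.045 log-odds per %)
  so crude and adjusted observational estimates demonstrably differ. Age,
  sex, SBP and physical activity get outcome-only effects. Covariates are
  mutually independent; real covariate correlation structure (e.g.
  age–SBP) is not emulated.
- The intercept b0 is set by `calibrate_intercept`, which draws one
  calibration replicate of the non-intercept linear predictor under a
  fixed internal seed and solves mean(logistic(b0 + lp)) = target by
  bisection — deterministic, and independent of analysis seeds.
- Measurement: `exposure_measured` equals the true exposure by default;
  optional additive assay noise and a multiplicative bias knob exist but
  default to off (assay bias correction is out of scope). An optional
  allele-frequency-by-latitude slope defaults to zero.

What passing tests on these cohorts do *not* show: robustness to LD
between instruments, genotyping error and missingness, covariate
correlation, survival-time structure of incidence, or assay bias — none
of which the generator emulates.

## Observational stage

Logistic regression of incident diabetes (prevalent cases excluded; the
exclusion applies only here, not to genetic analyses) on exposure/25 plus
covariates; the per-25 estimate is exactly 25× the per-1 estimate.
Tertile cut points are the empirical 1/3 and 2/3 quantiles of the analysis
sample with boundary ties assigned to the lower tertile. Floated absolute
risks convert the fitted covariance of the two non-reference tertile
coefficients (b₁, b₂) into per-category variances f₀ = Cov(b₁,b₂),
f₁ = Var(b₁) − f₀, f₂ = Var(b₂) − f₀; any negative value raises a
degenerate-covariance error rather than being clipped. Stepwise adjustment
enters the candidate with the smallest Wald p (joint χ² for multi-column
categorical candidates) while p ≤ 0.05, deterministically, ties broken by
candidate order. CIs use ±1.959964·SE and p-values the normal
approximation throughout. A quadratic-term Wald test is exposed as an
approximate non-linearity check, flagged as such.

## Instruments

Per-SNP and score analyses are run separately within each recruitment
area (adjusted for age, sex and season for exposure/trait outcomes; age
and sex for diabetes) and pooled by fixed-effect inverse variance — the
stratification guards against population stratification along the
latitude gradient. Strata need ≥ 30 rows and ≥ 2 usable areas, else the
code falls back to an unstratified fit with a warning; a stratum with
separation in a logistic fit is dropped with a warning. Instruments are
oriented after estimation so the effect allele raises 25(OH)D
(orientation is idempotent); downstream MR refuses unoriented inputs
rather than silently flipping.

Cross-validated score weights: the measured subset is split into k = 10
seeded folds; per-fold weights come from a joint adjusted linear model on
the other folds; held-out rows get scores from out-of-fold weights, which
removes the overfitting that makes naive internal weights invalid. Final
weights are the arithmetic fold average (the consolidation rule was an
open choice; averaging is the simplest symmetric one). The score is
S = Σ w_j g_j / w̄, i.e. rescaled to an allele-count scale so its
per-allele effect is comparable with single-SNP effects; this
normalisation is stated in output metadata. The first-stage F is computed
as (β/se)² of the single score term from the adjusted, area-stratified
regression of exposure on the cross-validated score. F > 10 is reported
as the conventional "strong instrument" screen. With k = n the procedure
reduces to exact leave-one-out (tested against a brute-force loop).

HWE is assessed per area with a 1-df χ² against expectations from the
sample allele frequency; areas with p < 10⁻³ are flagged (assessment, not
automatic exclusion).

## MR estimators

- **Wald ratio** — β̂ = 25·β_Y/β_X with first-order delta SE
  25·se_Y/β_X; the exposure-side term β_Y²se_X²/β_X⁴ is available behind
  a flag but off by default because the first stage is strong (F ≫ 10)
  in every supported design. Ratios with β_X < 0.1 nmol/l are refused as
  weak.
- **IVW** — fixed-effect: β̂ = Σw β / Σw, se = (Σw)^{−1/2}, w = se⁻²;
  equals intercept-free WLS of the β's on 1 (property-tested against
  that oracle).
- **MR-Egger** — WLS of β_Y on β_X with free intercept, weights se_Y⁻²;
  SEs carry the multiplicative inflation max(1, √(RSS_w/(J−2))), the
  standard random-effects convention. Requires J ≥ 3 (a 2-point weighted
  line is exact). The intercept stays per-allele; its p-value is the
  directional-pleiotropy test. A leverage caveat demonstrated in the
  test suite: a direct effect carried by the instrument with the largest
  β_X is absorbed almost entirely into the slope, so the intercept test
  has essentially no power against it; power is demonstrated with the
  low-leverage catabolism variant carrying the direct effect.
- **Weighted median** — per-SNP ratios ordered; inverse-variance weights
  placed at cumulative positions (Σ_{k≤i} w_k − w_i/2)/Σw with linear
  interpolation to 0.5 (several conventions exist; this one is stated
  explicitly and brute-force tested). SE by parametric bootstrap
  (default 2,000 draws, mandatory seed) resampling both effect sides
  from their normal sampling distributions. Consistency when < 50% of
  weight is invalid is an SE→0 property: at finite noise the estimator
  carries a quantile-shift bias proportional to the ratio noise, which
  the tests verify vanishes linearly while IVW stays biased.
- **Score IV** — area-stratified logistic score coefficient (cases =
  prevalent + incident), IVW-pooled, rescaled per 25 nmol/l by the
  score's cross-validated per-allele effect. With a single-SNP score
  this reduces exactly to the Wald ratio of that SNP's individual-level
  effects.

## Meta-analysis

Study rows are harmonised to the exposure-raising allele (swap →
sign-flip and frequency complement; opposite strand → base complement;
A/T and C/G pairs are strand-ambiguous, flagged and excluded under strict
mode). Within each study, per-SNP Wald ratios use external pooled
exposure weights by default (per-study internal weights are supported) —
summary-only studies rarely publish internal exposure effects, and the
external-weight ratio treats the weight as fixed. Within-study pooling is
per-SNP fixed-effect IVW (whether published forest plots pooled at score
or SNP level is not derivable; both are implemented, per-SNP IVW is the
default). Across studies: fixed-effect IVW overall and within latitude
subgroups split at 50°N, Q, and I² = max(0, (Q − df)/Q)·100. Fixed-effect
algebra makes subgroup-then-pool exactly equal to pooling all studies,
which is tested bit-for-bit. The bundled 10-study panel reproduces the
published *total* case/control counts (58,312 / 370,592, CKB row exact);
the per-study splits are synthetic because they are not printed anywhere.

## Reported reproduction quantities

`scripts/acceptance.py` re-simulates and re-estimates three quantities:
observational recovery (200 replicates of the 13,565-person biochemistry
design, injected OR 0.91), score-IV recovery (300 replicates of the
82,464-person genetic design, injected OR 0.86; 300 rather than the
minimal 200 for Monte-Carlo precision of the mean), and the DHCR7 allele
frequency at n = 82,464. Replicate log odds ratios are averaged on the
log scale before conversion to percent lower risk; averaging per-replicate
percentages would be Jensen-biased because single-replicate IV estimates
are noisy. Problem sizes were chosen to match the emulated study designs;
smaller cohorts appear only in unit tests, where the property under test
does not depend on scale.

## Known limitations

- First-order Wald SEs understate uncertainty if applied to weak
  instruments; the weak-instrument guard and F screen are the mitigation.
- The Egger intercept test is blind to pleiotropy aligned with
  high-leverage instruments (see above) and has modest power at J = 4.
- The published per-allele score effects (2.87/3.54 nmol/l) and
  F-statistics (21.9/93.1) of the emulated study are not derivable from
  its printed per-SNP effects under any weighting we could reconstruct;
  the package reports its own score effect and partial F and does not
  target those printed values.
- Fixed-effect pooling only; random-effects meta-analysis is out of
  scope, as are MR-PRESSO, mode-based and multivariable MR estimators.
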