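# Methods

## The risk model and its transportable components

Follow-up is modelled with a Cox proportional-hazards model on seven
terms: age (years), BMI (kg/m²), systolic blood pressure (mm Hg), heart
rate (beats/min), serum cholesterol (mmol/L), and two smoking dummies
(ex-smoker, current smoker; never-smoker is the reference with both
dummies zero). A fitted model is reduced to the transportable triple
(β, x̄, S₀): per-unit log-hazard coefficients, the fitting cohort's
covariate means, and the baseline cumulative survival at the horizon T
(25 years by default) evaluated at x̄. Absolute risk over the horizon is

    p(x) = 1 − S₀^exp(β′(x − x̄))

so p(x̄) = 1 − S₀ exactly. Because the model is fit on mean-centred
covariates, S₀ always refers to the average subject of the fitting
cohort — this is what makes substituting M (the centring vector)
between populations a meaningful operation.

Numerical choices in `riskrecal.cox`:

- Partial-likelihood maximisation uses `lifelines.CoxPHFitter` with the
  Efron tie correction (ties are common once times are reported at
  coarse resolution). Non-convergence or fewer than two events raise
  `CoxFittingError`.
- S₀ is the exponentiated negative Breslow cumulative hazard at the
  largest event time at or before the horizon. The Breslow choice is a
  design decision of this package: a single transported scalar at one
  horizon does not identify which estimator produced it, and Breslow is
  the standard companion of the Cox partial likelihood. (Kalbfleisch–
  Prentice would differ in the third decimal at these event counts.)
- Hazard-ratio tables report exp(β·δ) at user-supplied scaling steps δ;
  the built-in steps (age 5 yr, BMI 3 kg/m², SBP 20 mm Hg, heart rate
  13 bpm, cholesterol 1 mmol/L, dummies 1) are roughly one SD each.

## The GND calibration test

Calibration is assessed with the Greenwood–Nam–D'Agostino test in
Demler's formulation for survival data. Subjects are ranked by predicted
risk and split into D = 10 groups of near-equal size (rank-based with
stable tie-breaking, so tied risks never create empty groups). For group
d, the observed risk is 1 − Ŝ_d, where Ŝ_d is the Kaplan–Meier estimate
at the group's largest observed follow-up time at or before the horizon,
with Greenwood variance V_d = Ŝ_d² Σ d_i/(n_i(n_i − d_i)); the expected
risk is the group's mean predicted risk p̄_d. The statistic is

    χ² = Σ_d ((1 − Ŝ_d) − p̄_d)² / V_d

referred to a chi-squared distribution with (#groups − 1) degrees of
freedom. Conventions that the published description of the test leaves
open, fixed here as follows:

- **Sparse groups.** A group with fewer than `min_events = 5` events has
  an unstable Greenwood variance; it is merged into its higher-risk
  neighbour (the top group merges downward), iterating from the
  lowest-risk group upward, before the statistic is computed. Degrees of
  freedom shrink accordingly. A group with zero variance after merging
  raises `DegenerateDataError` rather than returning an arbitrary value.
- **Degrees of freedom** follow the external-validation convention
  (#groups − 1). In-sample use (the SELF scheme) is therefore slightly
  conservative; the measured type-I error at n = 2000 over 400
  replicates is ≈4.8% at α = 0.05, inside the 5% ± 2.5% band the test
  suite asserts.
- p-values below 1e-4 are rendered "<0.0001" in reports; CSV outputs
  keep full precision.

## Re-calibration schemes

With `own` the validation population's fitted components and `other` the
derivation population's, `compose_model` builds:

| scheme | S₀    | C (coefficients) | M (means) |
|--------|-------|------------------|-----------|
| SELF   | own   | own              | own       |
| SCM    | other | other            | other     |
| CM     | own   | other            | other     |
| C      | own   | other            | own       |
| WC     | own   | fixed widest-HR constants | own |
| ALTS   | altered | own            | own       |

The WC constants are, per risk factor, the largest hazard ratio among
four cohorts of the same study fitted with the same covariates and
horizon (age 1.50/5 yr, BMI 1.21/3, SBP 1.55/20, heart rate 1.05/13,
cholesterol 1.28/1, ex-smoker 1.31/1, smoker 2.18/1, converted to
per-unit coefficients as ln(HR)/δ). WC is defined here as a
coefficient-only substitution: the validation population keeps its own
S₀ and means. ALTS
defaults nudge S₀ from 0.7698 to 0.8098 (NE) and from 0.9354 to 0.9254
(SE); the sources conflict on the NE value (0.8098 in the running text,
0.9098 in a table footnote), so the default follows the running text and
an override (`--alts-s0-ne`) reproduces the other reading. Substituting
M swaps only the centring vector; covariate values are never
transformed.

`run_suite` fits each cohort's own model once, then scores every scheme
in both transport directions (validation ← derivation), yielding a
12-row summary (6 schemes × 2 directions) with mean observed/expected
risk, bottom- and top-decile expected risk, their ratio, and the GND
p-value, plus per-decile detail for observed-versus-expected plots.

## The synthetic cohort generator

No individual-level data from the motivating study are publicly
available, so the generator emulates its two pooled cohorts from the
published summary statistics alone:

- **Covariates.** Independent truncated normals for the five continuous
  risk factors with the published means and SDs (NE: age 49.3 (5.54),
  BMI 23.8 (3.05), SBP 143.7 (20.08), heart rate 69.1 (13.07),
  cholesterol 6.5 (1.32); SE: 49.14 (5.31), 24.0 (3.67), 140.3 (20.97),
  68.4 (13.10), 5.25 (1.09)), truncated at mean ± 4 SD and floored at
  physiologic minima (age 30, BMI 14, SBP 80, heart rate 35, cholesterol
  2.0). No correlation matrix was published, so independence is the
  default; a user-supplied correlation matrix is honoured through a
  Gaussian copula. Smoking is multinomial (never/ex/current = 0.153/
  0.180/0.667 in NE, 0.250/0.143/0.607 in SE).
- **Event times.** Exponential with rate λ·exp(β′(x − x̄)), where
  λ = −ln(S₀)/T is the constant baseline hazard implied by the published
  S₀ (0.7698 NE, 0.9354 SE at T = 25) — the simplest baseline consistent
  with a single printed survival value at one horizon — and β are the
  published hazard ratios converted to per-unit coefficients
  (ln(HR)/δ; e.g. NE age ln(1.36)/5, SE smoker ln(2.02)).
- **Censoring.** Competing non-CHD death is an independent exponential
  time; administrative censoring at the horizon. The default rates,
  0.0229/yr (NE) and 0.0245/yr (SE), were calibrated once by
  root-finding the competing-risks event fraction
  E[λm/(λm+c)·(1−e^−(λm+c)T)] over the covariate distribution so that
  the crude CHD death rates match the published 197 and 59 per 1000 over
  25 years. Under these rates the group-wise Kaplan–Meier mean observed
  risks also land near the published 0.2519 (NE) and 0.0801 (SE) —
  the gap between crude rate and KM risk is exactly what heavy
  competing mortality produces, and ~2–2.5%/yr non-CHD mortality is
  realistic for men aged 40–59 followed 25 years from around 1960.
- **Seeding.** One master seed per cohort, split deterministically
  (`numpy.random.SeedSequence.spawn`) between covariate and survival
  sampling; the same seed reproduces a cohort CSV byte-for-byte.

What the generator does *not* emulate: covariate correlations (unless
supplied), measurement error, non-proportional hazards, time-varying
covariates, cause-of-death adjudication, or the 50-year follow-up of the
original study. Passing tests on this generator therefore show that the
pipeline recovers its own generating parameters and detects transported
miscalibration of the documented size — not that the original field data
would reproduce numerically.

## Problem sizes and verified behaviour

The test suite and the acceptance script run everything at the study's
own scale (n = 2360 and 2789; 20 replicates for parameter recovery, 400
replicates at n = 2000 for the type-I error of the GND test, 10
replicates for directional transport properties), chosen as the sizes
the method is meant for. Verified there: fitted S₀(25) on NE cohorts
averages within 0.02 of 0.7698; the NE age HR per 5 years within 0.06 of
1.36 and the SE smoker HR within 0.25 of 2.02; SELF-model GND rejection
≈5% at α = 0.05; SCM transport onto NE rejected at p < 0.0001 with
under-estimation in NE and over-estimation by CM in ≥90% of replicates.
The ALTS perturbations (±0.01–0.04 on S₀) are small enough that their
rejection frequency at these sample sizes is well below 1, so no test
asserts near-certain rejection for ALTS.

## Known limitations

- The constant-baseline-hazard generator makes the proportional-hazards
  assumption exactly true; the pipeline's behaviour under model
  misspecification is untested.
- The GND statistic's chi-squared reference is asymptotic; with fewer
  than ~5 events per group it is unreliable, which is what the merging
  rule mitigates but cannot eliminate.
- Bootstrap confidence intervals, competing-risks (Fine–Gray) modelling,
  shrinkage-based model revision and discrimination indices are out of
  scope.
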