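# Methods

## The measurement problem

Self-reported dietary intake carries two kinds of error that matter for
diet–disease epidemiology: within-person noise, which averages away over
repeated administrations, and person-specific bias, which does not.  In a
cohort analysis that regresses disease on a noisy exposure, the log relative
risk is shrunk by the *attenuation factor* λ (the slope of regressing true
intake on the measured value), and analyses based on ranked or categorised
intake are degraded according to the *correlation with true intake* ρ.
Estimating λ and ρ for a short dietary instrument requires a validation
study with an objective reference whose errors are independent of the
self-reports — recovery biomarkers (24-hour urinary nitrogen for protein,
urinary potassium), a calibrated predictive biomarker (urinary
sucrose + fructose for total sugars), and total energy expenditure from
calorimetry plus accelerometry as the energy reference.

## Model

For participant *i* on occasion *j* (all measures on the natural-log
scale):

    Q_ij = μ_Qj + β_Q0 + β_Q1 T_i + r_i + ε_ij      (online questionnaire)
    F_ij = μ_Fj + β_F0 + β_F1 T_i + s_i + u_ij      (interviewer recall)
    M_ij = μ_Mj +             T_i        + v_ij     (biomarker)

with latent true intake T_i ~ N(μ_T, σ²_T); person-specific biases
(r_i, s_i) jointly normal with correlation ρ_rs (the same psychology can
distort both self-reports); and mutually independent within-person errors
ε, u, v.  The biomarker has no person-specific bias and its unit slope
fixes the scale of T.

Identification: additive tool biases, occasion drifts, and μ_T are jointly
unidentified, so the occasion-1 intercepts μ_Q1 = μ_F1 = μ_M1 = 0 are fixed
(the minimal anchoring; drifts at later occasions remain free by default,
with the constrained-to-zero option available).  J ≥ 2 occasions are
required to separate within- from between-person variance.

For the mean of k administrations of a self-report tool only the
within-person variance divides by k, giving the closed forms

    λ_k = β₁ σ²_T / (β₁² σ²_T + σ²_b + σ²_w / k)
    ρ_k = β₁ σ_T / sqrt(β₁² σ²_T + σ²_b + σ²_w / k)

with (β₁, σ²_b, σ²_w) the tool's slope, person-bias variance and
within-person variance.  Two consequences used throughout: the identity
(ρ_k/ρ_1)² = λ_k/λ_1, and the extrapolation rule — from printed
(λ₁, λ₂, ρ₁) alone, x = σ²_w/(β₁²σ²_T + σ²_b) solves
(1+x)/(1+x/2) = λ₂/λ₁, whence λ_k = λ₁(1+x)/(1+x/k) and
ρ_k = ρ₁√(λ_k/λ₁).  The ratio λ₂/λ₁ must lie in [1, 2); outside that range
no nonnegative variance ratio exists and the package raises an
`InfeasibleRatioError` rather than extrapolating.

## Estimation

The stacked observation (Q₁..Q_J, F₁..F_J, M₁..M_J) is jointly Gaussian, so
the model is fitted by full-information maximum likelihood: each
participant contributes the multivariate-normal log-density of their
observed subvector under the implied moments restricted to observed
coordinates, which is valid when missingness is missing-at-random.
Participants contribute whatever occasions they completed; there is no
imputation and no listwise deletion (a listwise mode exists for
comparison).  Participants with no observed values are dropped with a
logged warning.

Implementation notes:

* Participants are grouped by missingness pattern and the likelihood
  evaluated from per-pattern sufficient statistics using the standard
  embedding (covariance masked to observed coordinates, unit diagonal on
  missing ones), batched across patterns; the cost per evaluation is
  independent of cohort size.
* Variances are optimised as logs and ρ_rs through arctanh, so the search
  is unconstrained up to wide box bounds (log-variances bounded at
  [ln 1e-8, ln 1e6] to keep degenerate, error-free data finite); gradients
  are analytic, exploiting that the covariance is linear in nine basis
  coefficients.
* Initialisation is deterministic method-of-moments: σ²_T from the mean
  off-diagonal biomarker covariance, slopes from cross-covariances with the
  biomarker, residual variances from sample variances minus explained
  parts, floored at 1e-4.  The optimiser is L-BFGS-B with gradient
  tolerance 1e-8 and at most 500 iterations; fitting the same cohort twice
  is bit-identical.  An optional seeded multi-start mode (5 jittered
  starts) exists as a robustness check; the fit never accepts a point worse
  than its start.
* Variance estimates at the 1e-8 floor are flagged as boundary estimates;
  the observed-information covariance (numerical Hessian of the analytic
  gradient, pseudo-inverted and projected to PSD) is reported on the
  transformed scale.

### Uncertainty for derived metrics

The primary 95% interval for λ_k and ρ_k is a nonparametric bootstrap over
participants (default B = 500, seeded), refitting the model per replicate
and taking the percentile interval; this is robust to boundary estimates.
A delta-method interval from the observed information is reported
alongside; no claim is made that either matches the intervals of any
published analysis, whose method is unstated.  Replicates that fail to
converge are dropped and counted (warning above 20%).  Bootstrap refits are
warm-started at the full-data optimum in coordinates whitened by its
Hessian and use looser stopping rules (gradient 1e-4) — replicate metric
values agree with fully converged refits to ~1e-5, two orders of magnitude
below their sampling variation.  Percentile intervals are expanded, if
necessary, to include the point estimate.

### Subgroups

`fit_subgroups` refits independently within the two strata of sex, age
(<40 vs ≥40 years) or BMI (<25 vs ≥25), skipping strata below a
configurable minimum (default 20 participants) with a warning.

## Biomarker construction

* Protein intake (g/day) = nitrogen (g/24h) / 0.81 × 6.25.  The 0.81 is the
  assumed 24-hour nitrogen recovery; 6.25 is the standard Kjeldahl
  nitrogen-to-protein factor (the conversion step is implied rather than
  stated by the validation design; both constants are configurable).
* Potassium intake (g/day) = urinary potassium (g/24h) / 0.80.
* Total sugars use the feeding-study calibration
  M\* = M − 1.67 − 0.02·S + 0.71·A (S = 0 men / 1 women, A = log age),
  applied to natural-log sucrose + fructose excretion — the constants are
  only dimensionally coherent on a log scale, and all measures are
  log-transformed before analysis; the scale and coefficients are
  configurable.  M\* substitutes for M in the model.
* TEE = (REE + AEE) / 0.9, so that the thermic effect of food equals 10% of
  TEE and TEE = REE + AEE + TEF holds exactly.  Dividing by 0.9 (rather
  than multiplying by 1.1) follows from TEF being defined as a fraction of
  TEE.  Records with |weight change| > 5% are excluded (not in energy
  balance).
* Urine completeness: collections with ≥2 missed voids are always
  excluded.  The main analysis keeps all remaining collections; the
  sensitivity analysis keeps PABA recovery 85–110% as complete, rescales
  50–85% proportionally to the 93% target (analyte × 93/recovery), and
  excludes the rest.  Boundary points (50, 85, 110) are inclusive toward
  the more permissive status; the sources do not specify open/closed
  bounds.  Rescaling is not idempotent, so prepared records carry a
  `rescaled` flag and the pipeline refuses flagged input.
* Nutrient density = intake (g/day) / energy intake (MJ/day); biomarker
  densities use TEE as denominator, per occasion.
* Agreement between a tool and its reference is the Bland–Altman mean
  difference of per-participant mean logs, back-transformed to a
  percentage: 100·(exp(mean(tool − ref)) − 1), with a t-based CI.

## Synthetic cohorts

The generator draws cohorts with exactly the statistical structure the
model assumes: per nutrient, T_i, correlated (r_i, s_i), occasion drifts,
independent within-person errors, then independent Bernoulli cell
missingness (MAR by construction).  Covariates (sex ≈ 57.5% women, age
truncated-normal 43 ± 16 on 18–65, BMI ≈ N(25.5, 4.2²)) are drawn
independently of T by default, with optional dependence knobs for subgroup
experiments.  Within-cycle assessment order is randomised but carries no
effect unless the optional order-effect knob is set.

Default parameter values are anchored to a published validation study of an
online 24-hour questionnaire, using only its printed tables:

* the questionnaire's (β_Q1, σ²_r, σ²_eps) are solved exactly from the
  printed (λ₁, λ₂, ρ₁) per nutrient, using β₁ = ρ₁²/λ₁;
* the recall's slope comes from its printed (λ₁, ρ₁), with its
  bias/error split taken at the questionnaire's within/between ratio (only
  a single-administration pair is printed for the recall);
* σ²_T and σ²_v are backed out of the printed geometric-mean confidence
  intervals (total single-occasion variances), and μ_T and the tool
  intercepts from the printed geometric means;
* ρ_rs = 0.3, a moderate positive value reflecting the motivation for
  modelling correlated self-report biases; drifts alternate ±0.02;
* per-occasion questionnaire missingness (5%, 8.75%, 8.125%) matches the
  reported completion counts 152/146/147 of 160; recall and biomarker rates
  are 3.75% and 5%;
* PABA recovery is a two-component normal mixture (95 ± 5 and 70 ± 10,
  incomplete weight 0.4693) placing ≈45% of collections below 85%
  recovery; missed voids are 0/1/≥2 with probabilities 0.90/0.07/0.03;
  weight change after occasion 1 is N(0, 2.2²)%, putting ≈4% of
  participants past the 5% limit.

`generate_raw_records` inverts the biomarker conversions (nitrogen =
protein×0.81/6.25, potassium×0.8, the calibration equation, TEE split into
REE/AEE at a sampled resting share of 55–70%), so running the preparation
pipeline on the raw tables reproduces the cohort's biomarker columns for
complete records to 1e-10 — the preparation stage is testable end-to-end
without any external data.

What the generator does **not** emulate: food- or item-level reporting,
non-normal error distributions, seasonality or time-varying true intake,
informative (MNAR) missingness, assay-level variance structure, or any
coupling between urine completeness and the measurement errors.  Passing
tests therefore demonstrate correctness of the estimator and pipeline under
the model's own assumptions, not robustness of the model to real-data
violations of them.

## Problem sizes used by the test suite

Closed-form checks are instantaneous.  The Monte-Carlo moments oracle uses
five random parameter sets at 10⁶ participants (3-SE tolerance).  Parameter
recovery and bootstrap coverage use 100 replications of the default study
conditions (n = 160, J = 3) with B = 200 bootstrap replicates, judged
against a Binomial(100, 0.95) 3σ band; the ML/method-of-moments agreement
check uses one n = 50,000 cohort.  Unit-level simulation tests use
2×10⁵–4×10⁵ participants where empirical moments are compared at 3-SE
tolerance.

## Known limitations

* One error-prone exposure at a time; with several error-prone covariates
  in one disease model the bias structure is more complex (densities are
  provided as a partial answer).
* A single long-term latent intake per person; no seasonal or age drift in
  T itself.
* Covariate-dependent bias (e.g. BMI-dependent misreporting) is not
  modelled — subgroup refits are the provided tool for exploring it.
* The bootstrap refits each replicate from a warm start; in pathological,
  strongly multimodal fits the percentile interval could inherit the parent
  basin.  The seeded multi-start mode exists to detect such cases.
* Boundary variance estimates (exactly zero components) make the delta
  interval unreliable; the bootstrap interval is primary for this reason.
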