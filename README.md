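# dietval

Measurement-error validation of short-term dietary assessment tools against
objective biomarkers.

Self-reported dietary intake is noisy and systematically biased, which
attenuates diet–disease associations and erodes statistical power in cohort
studies.  `dietval` implements the standard validation analysis for a
repeated-measures design in which each participant provides, on each of J
occasions, an online 24-hour dietary questionnaire, an
interviewer-administered multiple-pass 24-hour recall, and an objective
reference (recovery biomarkers such as 24-hour urinary nitrogen and
potassium, a calibrated urinary sucrose+fructose biomarker for total
sugars, and total energy expenditure from calorimetry + accelerometry).  It
is aimed at nutritional epidemiologists running or re-analysing such
validation studies, and at methodologists studying regression calibration.

## The model

On the natural-log scale, with latent true intake `T_i ~ N(μ_T, σ²_T)`:

```
Q_ij = μ_Qj + β_Q0 + β_Q1·T_i + r_i + ε_ij     (questionnaire)
F_ij = μ_Fj + β_F0 + β_F1·T_i + s_i + u_ij     (recall)
M_ij = μ_Mj +        T_i            + v_ij     (biomarker, slope fixed at 1)
```

`r_i, s_i` are correlated person-specific reporting biases; `ε, u, v` are
independent within-person errors; `μ_*j` are occasion drifts (anchored to 0
at occasion 1).  The model is fitted by full-information maximum likelihood
(missing-at-random), and the key validity metrics follow in closed form for
the mean of k administrations:

```
λ_k = β₁σ²_T / (β₁²σ²_T + σ²_b + σ²_w/k)        attenuation factor
ρ_k = β₁σ_T / sqrt(β₁²σ²_T + σ²_b + σ²_w/k)     correlation with true intake
```

λ_k is the multiplicative shrinkage applied to log relative risks when the
tool measures the exposure; ρ_k governs power and ranked/categorised
analyses.  Because only the within-person variance averages away, both
metrics can also be extrapolated to any k from a published
(λ₁, λ₂, ρ₁) triple alone.

The package also houses the biomarker construction rules (nitrogen → protein
via 0.81 recovery and the 6.25 Kjeldahl factor, potassium via 0.80
recovery, the sex/log-age sugar calibration, TEE = (REE+AEE)/0.9 with the
thermic effect as 10% of TEE, PABA completeness classification and
rescaling, nutrient densities, Bland–Altman agreement) and a synthetic
cohort generator whose defaults emulate a 160-adult, 3-cycle validation
study.  See `docs/methods.md` for the full account.

## Worked example

Predict how the questionnaire's validity for protein improves with repeat
administrations, starting from single- and double-administration metrics
(λ₁ = 0.27, λ₂ = 0.37, ρ₁ = 0.40):

```python
>>> import dietval as dv
>>> print(dv.extrapolation_table(0.27, 0.37, 0.40, k_max=5).to_string(index=False))
 k  attenuation  correlation  attenuation_2dp  correlation_2dp
 1     0.270000     0.400000             0.27             0.40
 2     0.370000     0.468251             0.37             0.47
 3     0.422113     0.500141             0.42             0.50
 4     0.454091     0.518740             0.45             0.52
 5     0.475714     0.530947             0.48             0.53
```

Averaging three administrations raises the attenuation factor from 0.27 to
0.42 — a log relative risk estimated through the questionnaire would be
shrunk to 42% rather than 27% of its true value — and the correlation with
true intake from 0.40 to 0.50.

Simulate a validation cohort under those protein conditions, fit the model,
and bootstrap the uncertainty:

```python
>>> sc = dv.SimulationScenario(seed=1)
>>> sim = dv.generate_cohort(sc)
>>> fit = dv.fit_model(sim.cohorts["protein"])
>>> mi = dv.metric_uncertainty(fit, "attenuation", k=1, n_boot=200, seed=1)
>>> print(f"lambda_1 = {mi.estimate:.3f} (95% CI {mi.ci_low:.3f}, {mi.ci_high:.3f})")
lambda_1 = 0.287 (95% CI 0.190, 0.388)
```

The fitted λ₁ of 0.287 sits within sampling error of the generating value
0.27 at the study size (n = 160, three occasions, realistic missingness).

The same operations are available from the shell:

```
dietval extrapolate 0.27 0.37 0.40 -k 5
dietval --seed 1 --out-dir run simulate
dietval --seed 1 --out-dir run report
```

`report` renders geometric-mean, single-administration, and
repeat-administration validity tables (TSV, two-decimal render, full
precision in `fitted_parameters.json`) plus a run manifest with the seed
and config hash; identical inputs give byte-identical outputs.

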