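# lipivar

Visit-to-visit **lipid variability** and **renal outcomes** in type-2
diabetes: a tested, reusable pipeline for estimating each patient's usual
lipid level and regression-dilution-corrected variability from sparse
repeated measurements, and linking that variability to kidney disease,
renal function decline and end-stage renal disease with Cox
proportional-hazards models.

Intended users are biostatisticians and epidemiologists analysing
longitudinal EHR-style cohorts: 3–5 dated lipid panels per subject in a
24-month exposure window, baseline covariates, post-baseline eGFR/ACR
trajectories, and death/censoring dates.

## The model

With `y_ij` the j-th reading of subject *i*:

```
y_ij       ~ Normal(mu_i, sigma_i^2)        within-subject
mu_i       ~ Normal(mu0, tau^2)             usual levels
ln sigma_i ~ Normal(eta, omega^2)           log-variabilities
```

fitted by an in-repo MCMC sampler (conjugate Gibbs steps for the means,
Metropolis steps for the subject-specific residual SDs and scale
hyperparameters). The posterior means of `mu_i` and `sigma_i` are the
subject's *usual level* and *variability*. Because a 3-reading sample SD
is a very noisy exposure, regressing outcomes on it attenuates hazard
ratios toward 1 (regression dilution); the shrunken posterior-mean SD
largely removes that bias, which the test suite demonstrates by
simulation against known ground truth.

The survival stage provides variability quintiles, incidence rates with
exact Poisson CIs per 1,000 person-years, Cox models (Efron ties) with
both conventional and floating-absolute-risk CIs, 3-knot restricted cubic
splines, Schoenfeld/VIF diagnostics, subgroup analyses with Bonferroni
correction, multiple imputation (chained equations, m = 5) with Rubin
pooling, and three sensitivity variants. A synthetic-cohort generator
with known subject-level truth makes everything testable without any
external data.

## Worked example

Run the packaged demo (2,000 synthetic subjects, LDL-C variability as the
exposure, five imputations):

```bash
lipivar run --config examples/demo.yaml
```

This writes ~18 artifacts (measurement/profile/trajectory tables,
variability estimates, convergence report, imputed datasets, descriptive
and outcome tables, per-unit HR JSON, diagnostics, manifest with content
hashes). The outcome table (`table2_outcomes.md`) begins:

```
| outcome        | group | events | rate (95% CI)        | HR (95% CI)       |
|----------------|-------|--------|----------------------|-------------------|
| kidney_disease | Q1    | 240    | 103.2 (90.5, 117.1)  | 1.00 (0.88, 1.14) |
| kidney_disease | Q2    | 239    | 102.4 (89.8, 116.2)  | 0.99 (0.87, 1.12) |
| kidney_disease | Q3    | 233    | 100.1 (87.7, 113.8)  | 1.00 (0.87, 1.13) |
| kidney_disease | Q4    | 250    | 110.5 (97.2, 125.0)  | 1.09 (0.97, 1.24) |
| kidney_disease | Q5    | 250    | 119.3 (105.0, 135.1) | 1.17 (1.03, 1.32) |
```

Each row gives the quintile's event count, incidence per 1,000
person-years with its exact Poisson CI, and the adjusted hazard ratio
with a *floated* CI — note the reference quintile Q1 carries an interval
too, which is the point of floating absolute risk. The rising gradient
across quintiles reflects the positive variability effect built into the
generator. The per-unit summary (`per_unit_hr.json`) reports, e.g., for
kidney disease an adjusted HR of 1.66 (95% CI 1.09–2.52) per 1 mmol/L of
LDL-C variability on this 2,000-subject demo — the generated effect is
HR 1.5, and at demo scale the estimate is within sampling error of it.
The convergence report shows split-R̂ ≤ 1.02 for all hyperparameters.

The same analysis is available as a library:

```python
from lipivar import GeneratorConfig, generate_cohort, fit_hierarchical
from lipivar import HierarchicalModelSpec
from lipivar.cohort import resolve_ldl_series

measurements, profiles, trajectories, truth = generate_cohort(
    GeneratorConfig(n_subjects=2000, seed=7))
series = resolve_ldl_series(measurements)
estimates, report = fit_hierarchical(series, HierarchicalModelSpec(seed=1))
print(estimates[["subject_id", "usual_level", "variability",
                 "naive_sd"]].head())
```

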