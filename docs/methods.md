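# Methods

## The problem

Visit-to-visit variability of a biomarker — how much a patient's repeated
lipid measurements fluctuate around their own usual level — is an exposure
of growing epidemiological interest. Estimating it from sparse data is the
hard part: with only 3–5 readings per subject, the sample standard
deviation is an extremely noisy estimate of the true within-subject SD
(its own sampling SD is roughly half its value at n = 3), and using it
directly as a regressor attenuates hazard ratios toward the null
(regression dilution). `lipivar` implements the standard remedy: a
hierarchical Bayesian model that borrows strength across subjects and uses
the posterior mean of each subject's within-subject SD — a shrunken,
regression-calibrated exposure — in the downstream Cox models.

## Hierarchical variability model

For subject *i* with readings *y*<sub>ij</sub> (mmol/L):

```
y_ij       ~ Normal(mu_i, sigma_i^2)
mu_i       ~ Normal(mu0, tau^2)          (usual levels)
ln sigma_i ~ Normal(eta, omega^2)        (log-variabilities)
```

The log-normal law on `sigma_i` guarantees positivity and lets the
population of within-subject SDs have its own spread; `omega = 0`
collapses the model to a standard shared-residual random-intercept model.
Hyperpriors are weakly informative and data-located:
`mu0 ~ N(data mean, 10^2)`, `tau, omega ~ Half-Normal(0, 5^2)`,
`eta ~ N(ln pooled SD, 2^2)`. A prior-sensitivity test in the suite
confirms that doubling all hyperprior scales moves subject-level estimates
by far less than their posterior SDs (n ≥ 3 readings per subject).

Estimands are the posterior means of `mu_i` (usual level) and `sigma_i`
(variability). Naive per-subject sample SD, CV (= SD/mean) and VIM are
also produced; VIM fits `ln SD = a + b ln mean` across subjects and
rescales `VIM_i = SD_i (M/mean_i)^b` (M the cohort mean level), which
removes the SD–mean correlation by construction.

### Sampler

An in-repo Metropolis-within-Gibbs sampler, fully vectorised across
subjects: conjugate normal updates for `mu_i`, `mu0` and `eta`; joint
independent random-walk Metropolis for the `ln sigma_i`; random-walk
Metropolis on `ln tau` and `ln omega`. Proposal scales adapt toward 44%
acceptance during burn-in only (Robbins–Monro), so retained draws form a
valid Markov chain. Defaults: 2 chains, 2,000 burn-in, 8,000 kept draws.
Convergence is summarised by split-R̂ and a Geyer-initial-sequence ESS for
each sampled hyperparameter; fits are flagged when any R̂ > 1.05.
Correctness is guarded by two oracles: dense 2-D grid integration of the
exact per-subject posterior (hyperparameters pinned) on a 2-subject toy,
and the REML pooled residual SD of a standard random-intercept model in
the `omega = 0` limit.

Degenerate inputs: a subject with zero spread across readings keeps a
prior-dominated `sigma_i` posterior and is flagged `prior_dominated`
rather than dropped (dropping would bias the variability distribution
downward).

## Synthetic cohort generator

The generator is first-class, tested code: it emulates a primary-care
type-2-diabetes cohort with normal baseline kidney function and known
ground truth, so every downstream stage is validated by recovery.

* **Lipids.** 3–5 fasting panels in a 24-month window
  (P(3,4,5) = 0.92/0.06/0.02, mean 3.1; annual slots 0/12/24 months plus
  interim 6/18, jittered ≤ 2 months). LDL-C follows the hierarchy above
  with defaults `mu0 = 3.0`, `tau = 0.55`, `eta = ln 0.45`,
  `omega = 0.4` (population mean variability ≈ 0.49 mmol/L). HDL-C and TG
  are drawn per subject; TC is built as LDL + HDL + TG/2.2 so the
  Friedewald path is exact; the direct LDL assay is missing whenever
  TG > 4.0 mmol/L, exercising the resolution rule.
* **Covariates.** Age 63.7 ± 9.5 truncated to 45–84, 47.3% male, BMI
  25.3 ± 3.8, HbA1c 7.2 ± 1.2, baseline eGFR 106.7 ± 24.2 truncated at
  60, baseline ACR truncated below 3, four drug-class groups at realistic
  use rates. Only age, sex and HbA1c actually drive the hazard; the rest
  are noise covariates that exercise the adjustment machinery.
* **Events.** Exponential event times with log-hazard
  `bv (sigma_i − E sigma) + bu (mu_i − mu0) + x'gamma`, defaults
  `bv = ln 1.5` per mmol/L, `bu = ln 1.10`; marginal baseline rates
  anchored at 92.6 / 46.7 / 2.5 events per 1,000 person-years for the
  composite kidney-disease, 30%-decline and ESRD outcomes. Death
  (20/1,000 py) and an administrative horizon of 120 months act as
  independent censoring.
* **Trajectories.** Post-baseline eGFR/ACR records are constructed so
  ascertainment recovers the drawn times exactly: safe semi-annual visits
  that cross no threshold, one record at each event time crossing exactly
  the intended threshold (ESRD: eGFR 12; decline: eGFR = 0.7 × baseline;
  standalone kidney disease: ACR 3.5), and a final record at the
  censoring time. eGFR thresholds nest the outcomes (ESRD ⇒ decline and
  composite); when 0.7 × baseline < 60 the decline record itself triggers
  the composite, which makes the composite's marginal hazard mildly
  heterogeneous across subjects. Replicate studies therefore use the
  decline outcome, whose generated hazard is exactly proportional.
* **Missingness.** MCAR masking of DM duration (5.1%), BMI (6.7%) and
  baseline ACR (37.7%), matching the study's completion rates.

What the generator does **not** emulate: transcription noise and unit
errors, informative or outcome-dependent censoring, competing risks,
medication-driven lipid trends, or correlation between variability and
drug use. Passing tests demonstrate that the pipeline's estimators do
what they claim under the stated model — not that the model captures
every feature of real EHR data.

## Cohort assembly

Thresholds follow the study definitions literally: direct LDL-C unless
TG strictly exceeds 4.0 mmol/L (then Friedewald; readings with a
non-positive Friedewald value, or missing the direct assay at TG ≤ 4, are
dropped with a log entry); eligibility requires age 45–84, ≥ 3 readings
in the window ending at baseline, eGFR ≥ 60 and (missing or) ACR < 3.
Baseline is the date of the latest lipid panel in the window — the
reproducible half of the study's EHR-specific dual definition. Missing
baseline ACR does not exclude (treated as non-albuminuric, imputed as a
covariate). Outcomes are ascertained independently as the first record
meeting each criterion, ties counting as events for the ≥ 30% decline;
otherwise censoring at min(last visit, death, administrative end). Time
is months (days/30.4375).

## Survival analysis

* **Quintiles**: rank-based, sizes differing by at most one, stable tie
  order; boundary values reported as cut-points.
* **Incidence**: exact Poisson CIs via chi-square quantiles
  (`lower = χ²(α/2, 2k)/2`, `upper = χ²(1−α/2, 2k+2)/2`, per 1,000 py).
* **Cox models**: lifelines partial likelihood with Efron tie handling
  (ties are certain at monthly resolution). The full adjustment set is
  age, sex, DM duration, smoking, BMI, SBP, DBP, HbA1c, baseline eGFR and
  ACR, four drug-class flags, Charlson index and the usual level of the
  exposure parameter. Continuous HRs are per 1 mmol/L (per 1 unit for the
  TC/HDL ratio).
* **Floating absolute risk**: floated variances `λ_0..λ_4` fit by
  least squares on log-variances (initialised at the mean-off-diagonal
  heuristic) so that `Var(β_i − β_j) ≈ λ_i + λ_j` for all level pairs,
  reference included; the maximum relative error of that identity is
  reported as a quality index (exactly solvable for 2-level factors;
  < 10% on 5-level quintile fits in the suite).
* **Splines**: Harrell restricted cubic basis, 3 knots at the
  10th/50th/90th percentiles → 2 columns, linear beyond the boundary
  knots (checked by numerical second differences).
* **Diagnostics**: scaled-Schoenfeld rank-time correlation test per
  covariate; the global p-value is the Bonferroni-adjusted minimum (a
  valid, conservative level-α global test — lifelines exposes no global
  chi-square); VIF from the covariate design with intercept.
* **Subgroups**: per-stratum refits (matching per-stratum forest-plot
  presentation) plus likelihood-ratio interaction tests, Bonferroni
  adjusted across subgroup variables.
* **Sensitivity**: complete-case analysis, exclusion of follow-up
  < 12 months, 36-month exposure window, and the decomposition of the
  composite endpoint into eGFR-only and ACR-only definitions.

## Multiple imputation

Five chained-equation imputations (statsmodels MICE, predictive mean
matching, 10 sweeps) conditioning on all covariates and the outcome
indicators/times; downstream log-HRs pooled with Rubin's rules
(`T = W + (1 + 1/m)B`, t-interval with Barnard–Rubin df when a
complete-data df is supplied). `death_month` encodes 'alive' as NaN and
is excluded from the chained equations. For pooled quintile factors the
floated variances are computed from the average covariance matrix with
the diagonal replaced by the Rubin total variances — a pragmatic
combination documented here because no standard exists.

## Problem sizes and numerical choices

Recovery checks run one n = 5,000 cohort with full-length chains;
replicate studies (regression dilution at true HR 1.5, null calibration
at HR 1) use 50 cohorts of n = 1,000 with 2 × (400 + 1,200) chains — the
per-subject posterior means from the short chains match the full-length
defaults well within Monte-Carlo error. Per-stage seeds derive from the
global seed by a fixed counter scheme; identical configuration and seed
give byte-identical artifacts. Observed behaviour at these sizes: naive
3-reading SD biased ≈ −11% (the c₄ = 0.886 finite-sample factor) with
RMSE ≈ 0.25 against truth, posterior-mean SD essentially unbiased with
RMSE ≈ 0.16; naive-exposure HR attenuated to ≈ 1.15 against a generated
1.5 while the posterior-exposure HR is ≈ 1.41 and covers 1.5 in ≈ 100%
of replicates.

## Known limitations

* The composite kidney-disease outcome's generated hazard is only
  approximately proportional (nested-threshold collision above); effect
  recovery for that outcome is correspondingly slightly conservative.
* The floated-variance fit is a heuristic approximation; its quality
  index should be checked before quoting floated CIs.
* The exact prior specification of the original JAGS analysis is not
  public; equivalence is claimed at the level of the estimands (posterior
  means of the random intercept and residual SD), and the suite enforces
  prior robustness rather than prior identity. Likewise VIM is the
  power-model (Rothwell-style) form; the suite enforces its defining
  decorrelation property rather than a particular published formula.
* CV and VIM are computed from the model-based SD and usual level by
  default; the naive sample SD is reported alongside.
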