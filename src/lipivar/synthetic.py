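"""Synthetic longitudinal diabetes cohort with known ground truth.

The generator emulates the data structure of a primary-care EHR cohort of
type-2 diabetes patients with normal baseline kidney function: 3-5 fasting
lipid panels per subject inside a 24-month exposure window, baseline
covariates, and post-baseline eGFR/ACR trajectories that deterministically
encode the subject's renal event times.  Because the true subject-level
usual level ``mu_i``, within-subject SD ``sigma_i`` and hazard coefficients
are known, every downstream stage (outcome ascertainment, hierarchical
shrinkage, Cox modelling) can be validated by parameter recovery.

Generative model
----------------
* lipid readings   ``y_ij ~ N(mu_i, sigma_i^2)``
* usual levels     ``mu_i ~ N(mu0, tau^2)``
* variabilities    ``ln sigma_i ~ N(eta, omega^2)``
* event times      exponential with hazard
  ``lambda_o * exp(bv*(sigma_i - E[sigma]) + bu*(mu_i - mu0) + x_i'gamma)``
* death and administrative end of follow-up act as independent censoring.

Renal outcomes are nested by construction: an eGFR record below 15
(end-stage renal disease) also satisfies the kidney-disease (<60) and
30%-decline criteria, so the resolved event times obey
``t_kidney <= t_esrd`` and ``t_decline <= t_esrd``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError, GeneratorConfig

__all__ = ["generate_cohort", "inject_missingness", "true_sigma_mean"]

OUTCOMES = ("kidney_disease", "renal_decline_30pct", "esrd")

# columns of the baseline profile table, in output order
PROFILE_COLUMNS = [
    "subject_id", "age", "male", "smoker", "dm_duration", "bmi",
    "sbp", "dbp", "hba1c", "egfr_baseline", "acr_baseline", "charlson",
    "insulin", "metformin", "sulphonylurea", "other_antidiabetic",
    "acei_arb", "beta_blocker", "ccb", "diuretic", "other_antihypertensive",
    "statin", "fibrate",
    "antidiabetic_any", "antihypertensive_any",
    "baseline_month", "death_month",
]


def true_sigma_mean(cfg: GeneratorConfig) -> float:
    """Population mean of the true within-subject SD, E[sigma] under the
    log-normal law exp(eta + omega^2/2)."""
    return float(np.exp(cfg.eta + cfg.omega**2 / 2))


def _measurement_times(rng: np.random.Generator, counts: np.ndarray,
                       window: float) -> list[np.ndarray]:
    """Visit times inside the exposure window: annual assessments at months
    0/12/24 with extra interim visits at 6/18, all jittered by <= 2 months."""
    slots = np.array([0.0, 12.0, 24.0, 6.0, 18.0]) * window / 24.0
    out = []
    for c in counts:
        t = slots[:c] + rng.uniform(-2.0, 2.0, size=c)
        t = np.sort(np.clip(t, 0.0, window))
        out.append(t)
    return out


def _draw_profiles(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Baseline covariates calibrated to a middle-aged T2DM primary-care
    population (mean age 63.7, 47.3% male, BMI 25.3, HbA1c 7.2%...)."""
    def tnorm(mean, sd, lo, hi, size):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                                   random_state=rng)

    p = pd.DataFrame({"subject_id": np.arange(n)})
    p["age"] = tnorm(63.7, 9.5, 45.0, 84.0, n)
    p["male"] = (rng.random(n) < 0.473).astype(int)
    p["smoker"] = (rng.random(n) < 0.097).astype(int)
    # gamma with mean 8.0 y, SD 6.4 y
    p["dm_duration"] = rng.gamma(shape=(8.0 / 6.4) ** 2,
                                 scale=6.4**2 / 8.0, size=n)
    p["bmi"] = tnorm(25.3, 3.8, 15.0, 50.0, n)
    p["sbp"] = rng.normal(133.7, 16.6, n)
    p["dbp"] = rng.normal(74.5, 9.8, n)
    p["hba1c"] = tnorm(7.2, 1.2, 4.0, 15.0, n)
    p["egfr_baseline"] = tnorm(106.7, 24.2, 60.0, 200.0, n)
    p["acr_baseline"] = tnorm(1.1, 0.7, 0.0, 2.999, n)
    p["charlson"] = np.clip(np.round(rng.normal(3.1, 1.3, n)), 0, 12).astype(int)
    for col, rate in [
        ("insulin", 0.12), ("metformin", 0.70), ("sulphonylurea", 0.50),
        ("other_antidiabetic", 0.10), ("acei_arb", 0.45),
        ("beta_blocker", 0.25), ("ccb", 0.30), ("diuretic", 0.12),
        ("other_antihypertensive", 0.05), ("statin", 0.339),
        ("fibrate", 0.039),
    ]:
        p[col] = (rng.random(n) < rate).astype(int)
    p["antidiabetic_any"] = (
        p[["insulin", "metformin", "sulphonylurea", "other_antidiabetic"]]
        .max(axis=1)
    )
    p["antihypertensive_any"] = (
        p[["acei_arb", "beta_blocker", "ccb", "diuretic",
           "other_antihypertensive"]].max(axis=1)
    )
    return p


def _linear_predictor(profiles: pd.DataFrame, cfg: GeneratorConfig) -> np.ndarray:
    """Centred covariate contribution to the log hazard."""
    transforms = {
        "age_per10": (profiles["age"].to_numpy() - 63.7) / 10.0,
        "male": profiles["male"].to_numpy() - 0.473,
        "hba1c": profiles["hba1c"].to_numpy() - 7.2,
    }
    lp = np.zeros(len(profiles))
    for key, beta in cfg.covariate_log_hrs.items():
        if key not in transforms:
            raise ConfigurationError(f"no hazard transform for covariate {key!r}")
        lp += beta * transforms[key]
    return lp


def _resolve_event_times(raw: dict[str, np.ndarray],
                         egfr_baseline: np.ndarray) -> dict[str, np.ndarray]:
    """Enforce the nesting implied by shared eGFR thresholds.

    An eGFR record < 15 also triggers the < 60 and 30%-decline criteria, so
    ESRD implies both other outcomes.  When 0.7 * baseline eGFR < 60, the
    decline-crossing record itself falls below 60 and triggers kidney
    disease at the same visit.
    """
    t_esrd = raw["esrd"]
    t_dec = np.minimum(raw["renal_decline_30pct"], t_esrd)
    t_kd = np.minimum(raw["kidney_disease"], t_esrd)
    collide = 0.7 * egfr_baseline < 60.0
    t_kd = np.where(collide, np.minimum(t_kd, t_dec), t_kd)
    return {"kidney_disease": t_kd, "renal_decline_30pct": t_dec, "esrd": t_esrd}


def generate_cohort(
    cfg: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns
    -------
    measurements : one row per lipid panel — ``subject_id, month`` (relative
        to the start of the exposure window), ``ldl_direct`` (missing when
        TG > 4 mmol/L, as direct LDL-C is not assayed then), ``tc, hdl, tg``.
    profiles : one row per subject, baseline covariates plus
        ``baseline_month`` (date of the latest lipid panel) and
        ``death_month`` (months after baseline; NaN if beyond follow-up).
    trajectories : post-baseline renal records — ``subject_id, month``
        (months after baseline), ``egfr``, ``acr``.
    truth : ground-truth per subject — ``mu_true, sigma_true``, resolved
        latent event time per outcome (NaN when the exponential draw exceeds
        follow-up by construction is kept as-is), the censoring time and the
        observed event flag/time per outcome.  Test-only; excluded from
        pipeline inputs by default.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    # -- latent subject states
    mu = rng.normal(cfg.mu0, cfg.tau, n)
    sigma = np.exp(rng.normal(cfg.eta, cfg.omega, n))

    # -- measurement series
    counts_support = np.array(sorted(cfg.n_meas_probs))
    probs = np.array([cfg.n_meas_probs[k] for k in counts_support], float)
    counts = rng.choice(counts_support, size=n, p=probs / probs.sum())
    times = _measurement_times(rng, counts, cfg.window_months)

    subj_rep = np.repeat(np.arange(n), counts)
    month = np.concatenate(times)
    y = rng.normal(np.repeat(mu, counts), np.repeat(sigma, counts))
    y = np.clip(y, 0.1, None)  # concentrations are positive

    hdl_subj = np.clip(rng.normal(1.3, 0.25, n), 0.6, None)
    tg_subj = np.exp(rng.normal(np.log(1.3), 0.45, n))
    hdl = np.clip(np.repeat(hdl_subj, counts) + rng.normal(0, 0.08, len(y)),
                  0.4, None)
    tg = np.repeat(tg_subj, counts) * np.exp(rng.normal(0, 0.15, len(y)))
    tc = y + hdl + tg / 2.2  # Friedewald-consistent total cholesterol
    measurements = pd.DataFrame({
        "subject_id": subj_rep,
        "month": month,
        "ldl_direct": np.where(tg > 4.0, np.nan, y),
        "tc": tc,
        "hdl": hdl,
        "tg": tg,
    })

    # -- baseline profiles
    profiles = _draw_profiles(rng, n)
    profiles["baseline_month"] = np.array([t[-1] for t in times])

    # -- event and censoring times (months after baseline)
    lp = _linear_predictor(profiles, cfg)
    rel_risk = np.exp(
        cfg.beta_variability * (sigma - true_sigma_mean(cfg))
        + cfg.beta_usual * (mu - cfg.mu0)
        + lp
    )
    raw = {}
    for outcome in OUTCOMES:
        lam = cfg.baseline_hazards_per_1000py[outcome] / 1000.0 / 12.0
        raw[outcome] = rng.exponential(1.0 / (lam * rel_risk))
    resolved = _resolve_event_times(raw, profiles["egfr_baseline"].to_numpy())

    death = (
        rng.exponential(12000.0 / cfg.death_rate_per_1000py, n)
        if cfg.death_rate_per_1000py > 0
        else np.full(n, np.inf)
    )
    censor = np.minimum(death, cfg.max_followup_months)
    profiles["death_month"] = np.where(death <= cfg.max_followup_months,
                                       death, np.nan)

    # -- renal trajectories encoding the event times
    trajectories = _build_trajectories(rng, cfg, profiles, resolved, censor)

    truth = pd.DataFrame({
        "subject_id": np.arange(n),
        "mu_true": mu,
        "sigma_true": sigma,
        "censor_month": censor,
        "death_month": profiles["death_month"],
    })
    for outcome in OUTCOMES:
        t = resolved[outcome]
        ev = t < censor
        truth[f"t_{outcome}"] = t
        truth[f"event_{outcome}"] = ev.astype(int)
        truth[f"obs_time_{outcome}"] = np.where(ev, t, censor)

    return measurements, profiles, trajectories, truth


def _build_trajectories(rng, cfg, profiles, resolved, censor) -> pd.DataFrame:
    """Post-baseline eGFR/ACR records.

    Scheduled visits every ``visit_interval_months`` carry 'safe' values
    that cross no outcome threshold; one extra record is placed exactly at
    each resolved event time before censoring, with a value that crosses
    exactly the intended threshold(s); a final record at the censoring time
    realises the last-visit censoring rule.
    """
    n = len(profiles)
    b = profiles["egfr_baseline"].to_numpy()
    rows_subject, rows_month, rows_egfr, rows_acr = [], [], [], []

    def add(i, t, egfr, acr):
        rows_subject.append(i)
        rows_month.append(t)
        rows_egfr.append(egfr)
        rows_acr.append(acr)

    interval = cfg.visit_interval_months
    for i in range(n):
        c = censor[i]
        safe_floor = max(0.75 * b[i], 62.0)
        t_kd = resolved["kidney_disease"][i]
        t_dec = resolved["renal_decline_30pct"][i]
        t_esrd = resolved["esrd"][i]
        t = interval
        while t < c:
            add(i, t, safe_floor + rng.uniform(0.0, 6.0),
                rng.uniform(0.3, 2.4))
            t += interval
        add(i, c, safe_floor + rng.uniform(0.0, 6.0), rng.uniform(0.3, 2.4))
        if t_esrd < c:
            add(i, t_esrd, 12.0, rng.uniform(0.3, 2.4))
        if t_dec < c and t_dec < t_esrd:
            add(i, t_dec, 0.7 * b[i], rng.uniform(0.3, 2.4))
        # a kidney-disease event not already realised by the ESRD record or
        # by a decline record falling below 60 is reached through
        # new-onset albuminuria
        realised_by_decline = 0.7 * b[i] < 60.0 and t_kd == t_dec
        if t_kd < c and t_kd < t_esrd and not realised_by_decline:
            add(i, t_kd, safe_floor + rng.uniform(0.0, 6.0), 3.5)

    traj = pd.DataFrame({
        "subject_id": rows_subject,
        "month": rows_month,
        "egfr": rows_egfr,
        "acr": rows_acr,
    })
    return traj.sort_values(["subject_id", "month"], kind="stable",
                            ignore_index=True)


def inject_missingness(
    profiles: pd.DataFrame,
    fractions: dict[str, float],
    seed: int,
) -> pd.DataFrame:
    """Mask covariate cells completely at random.

    ``fractions`` maps column name to the probability that a cell is set to
    missing; each fraction must lie in [0, 1).  Returns a copy.
    """
    for col, frac in fractions.items():
        if not 0.0 <= frac < 1.0:
            raise ConfigurationError(
                f"missingness fraction for {col!r} must be in [0, 1)"
            )
        if col not in profiles.columns:
            raise ConfigurationError(f"no column {col!r} in profiles")
    rng = np.random.default_rng(seed)
    out = profiles.copy()
    for col, frac in fractions.items():
        if frac > 0:
            mask = rng.random(len(out)) < frac
            out.loc[mask, col] = np.nan
    return out
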