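"""Survival-analysis stage: quintile construction, exact Poisson incidence
CIs, Cox proportional-hazards models with floated (floating-absolute-risk)
confidence intervals, restricted cubic splines, proportional-hazards and
collinearity diagnostics, and subgroup/sensitivity machinery.

Conventions: follow-up durations are months (person-years = months / 12);
incidence rates are reported per 1000 person-years; tied event times are
handled with the Efron approximation (ties are certain at monthly
resolution).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import optimize, stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

logger = logging.getLogger(__name__)

__all__ = [
    "assign_quintiles",
    "poisson_rate_ci",
    "incidence_table",
    "fit_cox",
    "floated_ci",
    "rcs_basis",
    "rcs_knots",
    "ph_diagnostics",
    "subgroup_analysis",
    "bonferroni",
    "CoxResult",
    "IncidenceResult",
    "DiagnosticsReport",
    "ADJUSTMENT_COVARIATES",
]

MONTHS_PER_YEAR = 12.0

#: full adjustment set for the main Cox models: demographics, diabetes
#: severity, renal function, drug classes, comorbidity and the usual lipid
#: level of the exposure parameter (merged in as ``usual_level``)
ADJUSTMENT_COVARIATES = [
    "age", "male", "dm_duration", "smoker", "bmi", "sbp", "dbp", "hba1c",
    "egfr_baseline", "acr_baseline", "antidiabetic_any",
    "antihypertensive_any", "statin", "fibrate", "charlson", "usual_level",
]


# -- quintiles -----------------------------------------------------------------


def assign_quintiles(values, subject_ids=None) -> tuple[pd.DataFrame, np.ndarray]:
    """Rank-based split of an exposure vector into five balanced groups.

    Group sizes are ``ceil(n/5)`` or ``floor(n/5)`` (never differing by
    more than one); ties are broken by stable input order.  Returns the
    assignment table (``subject_id, exposure, quintile`` with quintile in
    1..5) and the four boundary cut-points (the smallest exposure value of
    each upper group).
    """
    values = np.asarray(values, float)
    n = values.size
    if n < 5:
        raise ValueError("need at least 5 subjects for quintiles")
    if not np.all(np.isfinite(values)):
        raise ValueError("exposure values must be finite")
    if subject_ids is None:
        subject_ids = np.arange(n)

    order = np.argsort(values, kind="stable")
    sizes = np.full(5, n // 5)
    sizes[: n % 5] += 1
    labels = np.repeat(np.arange(1, 6), sizes)
    quintile = np.empty(n, int)
    quintile[order] = labels

    bounds = np.cumsum(sizes)[:-1]
    cutpoints = values[order][bounds]
    ties = values[order][bounds - 1] == cutpoints
    if ties.any():
        logger.warning(
            "assign_quintiles: %d boundary value(s) tied across groups",
            int(ties.sum()),
        )
    out = pd.DataFrame({
        "subject_id": np.asarray(subject_ids),
        "exposure": values,
        "quintile": quintile,
    })
    return out, cutpoints


# -- incidence -----------------------------------------------------------------


@dataclass
class IncidenceResult:
    group: str
    events: int
    person_years: float
    rate_per_1000py: float
    ci_lower: float
    ci_upper: float
    level: float = 0.95


def poisson_rate_ci(events: int, person_years: float,
                    level: float = 0.95, group: str = "") -> IncidenceResult:
    """Exact Poisson incidence rate and CI per 1000 person-years.

    Lower bound ``chi2.ppf(alpha/2, 2k) / 2`` (0 when k = 0), upper bound
    ``chi2.ppf(1 - alpha/2, 2k + 2) / 2``, scaled by person-time.
    """
    if events < 0 or person_years <= 0:
        raise ValueError("need events >= 0 and person_years > 0")
    alpha = 1.0 - level
    scale = 1000.0 / person_years
    lower = 0.0 if events == 0 else stats.chi2.ppf(alpha / 2, 2 * events) / 2
    upper = stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2
    return IncidenceResult(group, int(events), person_years,
                           events * scale, lower * scale, upper * scale,
                           level)


def incidence_table(outcomes: pd.DataFrame, quintiles: pd.DataFrame,
                    outcome: str) -> pd.DataFrame:
    """Per-quintile (plus overall) event counts, person-years and exact
    Poisson CIs for one outcome."""
    df = outcomes.merge(quintiles[["subject_id", "quintile"]], on="subject_id")
    rows = []
    groups = [(f"Q{q}", df[df["quintile"] == q]) for q in range(1, 6)]
    groups.append(("overall", df))
    for name, sub in groups:
        events = int(sub[f"event_{outcome}"].sum())
        py = float(sub[f"time_{outcome}"].sum()) / MONTHS_PER_YEAR
        if py <= 0:
            rows.append(IncidenceResult(name, events, 0.0, 0.0, 0.0, 0.0))
            continue
        rows.append(poisson_rate_ci(events, py, group=name))
    return pd.DataFrame([vars(r) for r in rows])


# -- Cox models ----------------------------------------------------------------


@dataclass
class CoxResult:
    """One fitted Cox model: per-term log-HRs, SEs and covariance."""

    terms: list[str]
    log_hr: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    n: int
    n_events: int
    log_likelihood: float
    fitter: CoxPHFitter = field(repr=False, default=None)
    level: float = 0.95

    def hazard_table(self) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + self.level / 2)
        return pd.DataFrame({
            "term": self.terms,
            "log_hr": self.log_hr,
            "se": self.se,
            "hr": np.exp(self.log_hr),
            "ci_lower": np.exp(self.log_hr - z * self.se),
            "ci_upper": np.exp(self.log_hr + z * self.se),
        })

    def term_index(self, term: str) -> int:
        return self.terms.index(term)


def fit_cox(df: pd.DataFrame, duration_col: str, event_col: str,
            covariates: list[str]) -> CoxResult:
    """Cox partial-likelihood fit (Efron ties) of ``covariates`` on the
    given duration/event columns.

    Raises on constant covariate columns or zero events; separation or
    convergence warnings from the optimiser are logged and re-raised as
    warnings, not errors.
    """
    if df[event_col].sum() < 1:
        raise ValueError("Cox model requires at least one event")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    model_df = df[[duration_col, event_col] + covariates].astype(float)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        cph.fit(model_df, duration_col=duration_col, event_col=event_col)
    params = cph.params_.reindex(covariates)
    cov = cph.variance_matrix_.reindex(index=covariates, columns=covariates)
    return CoxResult(
        terms=list(covariates),
        log_hr=params.to_numpy(),
        se=np.sqrt(np.diag(cov.to_numpy())),
        cov=cov.to_numpy(),
        n=len(model_df),
        n_events=int(model_df[event_col].sum()),
        log_likelihood=float(cph.log_likelihood_),
        fitter=cph,
    )


def quintile_design(df: pd.DataFrame, quintile_col: str = "quintile",
                    prefix: str = "q") -> tuple[pd.DataFrame, list[str]]:
    """Dummy-code a 5-level quintile factor against Q1."""
    out = df.copy()
    cols = []
    for q in range(2, 6):
        col = f"{prefix}{q}"
        out[col] = (out[quintile_col] == q).astype(float)
        cols.append(col)
    return out, cols


# -- floating absolute risk ----------------------------------------------------


def floated_ci(cov: np.ndarray, level: float = 0.95
               ) -> tuple[np.ndarray, float]:
    """Floated variances for a reference-coded factor.

    Given the covariance matrix of the k-1 log-HR contrasts against the
    reference level, returns k floated variances ``lambda_0..lambda_{k-1}``
    (reference included) such that ``Var(beta_i - beta_j) ~= lambda_i +
    lambda_j`` for every level pair, together with a quality index (the
    maximum relative error of that identity over all pairs).

    The fit starts from the classic heuristic (``lambda_0`` = mean
    off-diagonal covariance, ``lambda_i = V_ii - lambda_0``) and refines it
    by least squares on the log-variances.  For a 2-level factor the
    identity is exactly solvable and the variance is split evenly.
    """
    cov = np.atleast_2d(np.asarray(cov, float))
    k1 = cov.shape[0]
    if cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance block must be square")
    if np.any(np.linalg.eigvalsh(cov) <= 0):
        raise ValueError("covariance block must be positive definite")

    if k1 == 1:
        lam = np.full(2, cov[0, 0] / 2.0)
        return lam, 0.0

    # pairwise contrast variances: index 0 is the reference level
    pairs, targets = [], []
    for j in range(1, k1 + 1):
        pairs.append((0, j))
        targets.append(cov[j - 1, j - 1])
    for i in range(1, k1 + 1):
        for j in range(i + 1, k1 + 1):
            pairs.append((i, j))
            targets.append(cov[i - 1, i - 1] + cov[j - 1, j - 1]
                           - 2 * cov[i - 1, j - 1])
    targets = np.asarray(targets)

    off = cov[~np.eye(k1, dtype=bool)]
    lam0 = max(float(off.mean()), 1e-3 * float(np.diag(cov).mean()))
    init = np.concatenate([[lam0],
                           np.maximum(np.diag(cov) - lam0, 1e-3 * lam0)])

    def resid(log_lam):
        lam = np.exp(log_lam)
        return np.log([lam[i] + lam[j] for i, j in pairs]) - np.log(targets)

    sol = optimize.least_squares(resid, np.log(init), method="lm")
    lam = np.exp(sol.x)
    fitted = np.array([lam[i] + lam[j] for i, j in pairs])
    quality = float(np.max(np.abs(fitted / targets - 1.0)))
    return lam, quality


def floated_hazard_table(log_hr_levels: np.ndarray, cov: np.ndarray,
                         level: float = 0.95) -> pd.DataFrame:
    """HRs with floated CIs for every level of a factor, reference
    included (reference log-HR = 0 but with a positive floated SE)."""
    lam, quality = floated_ci(cov, level)
    z = stats.norm.ppf(0.5 + level / 2)
    log_hr = np.concatenate([[0.0], np.asarray(log_hr_levels, float)])
    se = np.sqrt(lam)
    out = pd.DataFrame({
        "level": [f"Q{q}" for q in range(1, len(log_hr) + 1)],
        "log_hr": log_hr,
        "floated_se": se,
        "hr": np.exp(log_hr),
        "ci_lower": np.exp(log_hr - z * se),
        "ci_upper": np.exp(log_hr + z * se),
    })
    out.attrs["floated_quality_index"] = quality
    return out


# -- restricted cubic splines --------------------------------------------------


def rcs_knots(x, n_knots: int = 3) -> np.ndarray:
    """Default knot placement at the 10th/50th/90th percentiles (3 knots)
    or evenly-spaced quantiles between the 5th and 95th otherwise."""
    x = np.asarray(x, float)
    if n_knots == 3:
        q = [0.10, 0.50, 0.90]
    else:
        q = np.linspace(0.05, 0.95, n_knots)
    return np.quantile(x, q)


def rcs_basis(x, n_knots: int = 3, knots=None) -> np.ndarray:
    """Restricted cubic spline basis (Harrell parameterisation).

    ``k`` knots give ``k - 1`` columns: the identity plus ``k - 2``
    nonlinear terms that are exactly linear beyond the boundary knots
    (three knots -> two columns).  Raises on coincident knots.
    """
    x = np.asarray(x, float)
    t = np.asarray(rcs_knots(x, n_knots) if knots is None else knots, float)
    k = t.size
    if k < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")

    def pos3(u):
        return np.where(u > 0, u, 0.0) ** 3

    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (
            pos3(x - t[j])
            - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


# -- diagnostics ---------------------------------------------------------------


@dataclass
class DiagnosticsReport:
    schoenfeld_p: dict[str, float]
    global_p: float
    vif: dict[str, float]

    def to_dict(self) -> dict:
        return {"schoenfeld_p": self.schoenfeld_p, "global_p": self.global_p,
                "vif": self.vif}


def ph_diagnostics(result: CoxResult, df: pd.DataFrame,
                   duration_col: str, event_col: str) -> DiagnosticsReport:
    """Scaled-Schoenfeld-residual PH tests and variance inflation factors.

    Per-covariate p-values come from the rank-time correlation test of the
    scaled Schoenfeld residuals; the global p-value is the smallest
    per-covariate p after Bonferroni adjustment (a valid level-alpha
    global test).  VIFs are computed from the covariate design matrix with
    an intercept.
    """
    model_df = df[[duration_col, event_col] + result.terms].astype(float)
    test = proportional_hazard_test(result.fitter, model_df,
                                    time_transform="rank")
    pvals = test.summary["p"]
    # lifelines indexes by (variable, transform) in newer versions
    if isinstance(pvals.index, pd.MultiIndex):
        pvals = pvals.droplevel(-1)
    sch = {t: float(pvals.loc[t]) for t in result.terms}
    global_p = min(1.0, min(sch.values()) * len(sch))

    x = np.column_stack([np.ones(len(df))]
                        + [df[t].to_numpy(float) for t in result.terms])
    vifs = {}
    for i, t in enumerate(result.terms, start=1):
        with np.errstate(divide="ignore"):
            v = variance_inflation_factor(x, i)
        vifs[t] = float(v)
        if not np.isfinite(v) or v > 100:
            logger.warning("severe collinearity: VIF(%s) = %.3g", t, v)
    return DiagnosticsReport(sch, global_p, vifs)


# -- subgroups -----------------------------------------------------------------


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    return min(1.0, p * n_tests)


def default_subgroups(df: pd.DataFrame) -> dict[str, pd.Series]:
    """The study's subgroup splits expressed on the merged analysis table."""
    cuts = {
        "gender": np.where(df["male"] == 1, "male", "female"),
        "age_band": pd.cut(df["age"], [44, 54, 64, 74, 84],
                           labels=["45-54", "55-64", "65-74", "75-84"]),
        "smoking": np.where(df["smoker"] == 1, "smoker", "non-smoker"),
        "dm_duration_band": np.where(df["dm_duration"] < 5, "<5y", ">=5y"),
        "bmi_band": np.where(df["bmi"] < 25, "<25", ">=25"),
        "usual_level_band": pd.cut(df["usual_level"],
                                   [-np.inf, 2.6, 4.3, np.inf],
                                   labels=["<2.6", "2.6-4.3", ">=4.3"]),
        "sbp_band": np.where(df["sbp"] < 130, "<130", ">=130"),
        "hba1c_band": np.where(df["hba1c"] < 7, "<7%", ">=7%"),
        "egfr_band": np.where(df["egfr_baseline"] < 90, "<90", ">=90"),
        "charlson_band": np.where(df["charlson"] < 4, "<4", ">=4"),
        "antihypertensive": np.where(df["antihypertensive_any"] == 1,
                                     "yes", "no"),
        "antidiabetic": np.where(df["antidiabetic_any"] == 1, "yes", "no"),
        "statin_use": np.where(df["statin"] == 1, "yes", "no"),
        "fibrate_use": np.where(df["fibrate"] == 1, "yes", "no"),
    }
    return {k: pd.Series(v, index=df.index) for k, v in cuts.items()}


def subgroup_analysis(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    exposure: str,
    covariates: list[str],
    subgroups: dict[str, pd.Series] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-estimate the exposure HR inside each subgroup stratum.

    Returns ``(per_stratum, interactions)``: per-stratum HRs with
    conventional CIs, and per-subgroup-variable interaction p-values
    (likelihood-ratio test of exposure x stratum terms) with Bonferroni
    adjustment across the subgroup variables.  Strata without events are
    skipped with a log entry.
    """
    if subgroups is None:
        subgroups = default_subgroups(df)
    rows, inter_rows = [], []
    all_covs = [exposure] + [c for c in covariates if c != exposure]
    for name, labels in subgroups.items():
        levels = [lv for lv in pd.unique(labels.dropna())]
        for lv in levels:
            sub = df[labels == lv]
            if len(sub) == 0 or sub[event_col].sum() < 1:
                logger.info("subgroup %s=%s skipped (no events)", name, lv)
                continue
            usable = [c for c in all_covs if sub[c].nunique() > 1]
            if exposure not in usable:
                continue
            try:
                res = fit_cox(sub, duration_col, event_col, usable)
            except Exception as exc:  # noqa: BLE001 - stratum-level fit issues
                logger.info("subgroup %s=%s failed: %s", name, lv, exc)
                continue
            i = res.term_index(exposure)
            z = 1.959963984540054
            rows.append({
                "subgroup": name, "level": str(lv), "n": res.n,
                "events": res.n_events,
                "hr": float(np.exp(res.log_hr[i])),
                "ci_lower": float(np.exp(res.log_hr[i] - z * res.se[i])),
                "ci_upper": float(np.exp(res.log_hr[i] + z * res.se[i])),
            })
        # interaction LRT: exposure x stratum dummies added to the base model
        mask = labels.notna()
        sub = df[mask]
        lab = labels[mask]
        if sub[event_col].sum() < 2 or lab.nunique() < 2:
            continue
        base_covs = [c for c in all_covs if sub[c].nunique() > 1]
        work = sub.copy()
        inter_cols = []
        for lv in list(pd.unique(lab))[1:]:
            col = f"_int_{name}_{lv}"
            work[col] = work[exposure] * (lab == lv).astype(float)
            inter_cols.append(col)
        try:
            base = fit_cox(work, duration_col, event_col, base_covs)
            full = fit_cox(work, duration_col, event_col,
                           base_covs + inter_cols)
            lr = 2.0 * (full.log_likelihood - base.log_likelihood)
            p = float(stats.chi2.sf(max(lr, 0.0), df=len(inter_cols)))
        except Exception as exc:  # noqa: BLE001
            logger.info("interaction test for %s failed: %s", name, exc)
            continue
        inter_rows.append({"subgroup": name, "p": p})

    interactions = pd.DataFrame(inter_rows)
    if len(interactions):
        n_tests = len(interactions)
        interactions["p_bonferroni"] = [
            bonferroni(p, n_tests) for p in interactions["p"]
        ]
    return pd.DataFrame(rows), interactions
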