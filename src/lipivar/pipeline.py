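"""Pipeline orchestration: generate -> assemble -> estimate -> impute ->
analyse -> report, with deterministic per-stage seeding and a hashed
artifact manifest.

Each stage reads and writes plain CSV/JSON artifacts in the run's output
directory, so stages can be re-run individually from the CLI.  The truth
table written by the generator is test-only and is never read by later
stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import survival
from .cohort import ascertain_outcomes_table, resolve_ldl_series, screen_cohort
from .config import PipelineConfig
from .imputation import mice_impute, rubin_pool
from .synthetic import generate_cohort, inject_missingness
from .variability import fit_hierarchical

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "analyse_cohort", "run_sensitivity",
           "render_tables"]

OUTCOMES = ("kidney_disease", "renal_decline_30pct", "esrd")


# -- helpers -------------------------------------------------------------------


def _covariate_nan(df: pd.DataFrame) -> pd.DataFrame:
    """NaN mask over genuinely missing covariates (``death_month`` uses
    NaN to encode 'alive at end of follow-up')."""
    return df.drop(columns=["death_month"], errors="ignore").isna()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def exposure_series(measurements: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Long series (subject_id, month, value) for the requested lipid
    parameter: resolved LDL-C, TC/HDL-C ratio, or triglyceride."""
    if parameter == "ldl":
        out = resolve_ldl_series(measurements)
        return out.rename(columns={"ldl": "value"})[
            ["subject_id", "month", "value"]]
    if parameter == "tc_hdl_ratio":
        value = measurements["tc"] / measurements["hdl"]
    elif parameter == "tg":
        value = measurements["tg"]
    else:
        raise ValueError(f"unknown exposure parameter {parameter!r}")
    return pd.DataFrame({
        "subject_id": measurements["subject_id"],
        "month": measurements["month"],
        "value": value,
    })


def _metric_column(metric: str) -> str:
    return {"sd": "variability", "cv": "cv", "vim": "vim"}[metric]


# -- analysis ------------------------------------------------------------------


def analyse_cohort(
    profiles: pd.DataFrame,
    estimates: pd.DataFrame,
    outcomes: pd.DataFrame,
    cfg: PipelineConfig,
    imputed_profiles: list[pd.DataFrame] | None = None,
) -> dict:
    """Main survival analysis on one assembled cohort.

    Builds variability quintiles, per-quintile incidence with exact
    Poisson CIs, the quintile Cox model with conventional and floated CIs,
    the per-unit continuous-exposure HR, diagnostics, and (optionally)
    subgroup results.  When ``imputed_profiles`` has more than one entry,
    each Cox quantity is estimated on every completed dataset and pooled
    with Rubin's rules on the log-HR scale.
    """
    metric_col = _metric_column(cfg.analysis.variability_metric)
    exp_df = estimates[["subject_id", "usual_level", metric_col]].rename(
        columns={metric_col: "exposure_value"}
    )
    quintiles, cutpoints = survival.assign_quintiles(
        exp_df["exposure_value"].to_numpy(),
        exp_df["subject_id"].to_numpy(),
    )
    if exp_df["exposure_value"].std() < 1e-12:
        logger.warning("degenerate exposure: zero spread across subjects; "
                       "hazard ratios for variability are unidentifiable")

    incidence = {
        o: survival.incidence_table(outcomes, quintiles, o) for o in OUTCOMES
    }

    datasets = imputed_profiles or [profiles]
    m = len(datasets)

    covariates = [c for c in survival.ADJUSTMENT_COVARIATES
                  if c != "usual_level"]
    per_unit: dict[str, dict] = {}
    quintile_hr: dict[str, dict] = {}
    diagnostics: dict[str, dict] = {}
    for outcome in OUTCOMES:
        dur, ev = f"time_{outcome}", f"event_{outcome}"
        cont_est, cont_var = [], []
        level_est = {q: [] for q in range(2, 6)}
        level_var = {q: [] for q in range(2, 6)}
        cov_sum = np.zeros((4, 4))
        diag = None
        for prof in datasets:
            df = (
                prof.merge(outcomes, on="subject_id")
                .merge(exp_df, on="subject_id")
                .merge(quintiles[["subject_id", "quintile"]], on="subject_id")
            )
            usable = [c for c in covariates if df[c].nunique() > 1]
            # continuous per-unit model
            res = survival.fit_cox(df, dur, ev,
                                   ["exposure_value", "usual_level"] + usable)
            i = res.term_index("exposure_value")
            cont_est.append(res.log_hr[i])
            cont_var.append(res.se[i] ** 2)
            if diag is None:
                diag = survival.ph_diagnostics(res, df, dur, ev)
            # quintile factor model
            dfq, qcols = survival.quintile_design(df)
            resq = survival.fit_cox(dfq, dur, ev,
                                    qcols + ["usual_level"] + usable)
            idx = [resq.term_index(c) for c in qcols]
            for q, j in zip(range(2, 6), idx):
                level_est[q].append(resq.log_hr[j])
                level_var[q].append(resq.se[j] ** 2)
            cov_sum += resq.cov[np.ix_(idx, idx)]

        if m > 1:
            pooled = rubin_pool(cont_est, cont_var)
            per_unit[outcome] = {
                "log_hr": pooled.point, "se": pooled.se,
                "hr": float(np.exp(pooled.point)),
                "ci_lower": float(np.exp(pooled.ci_lower)),
                "ci_upper": float(np.exp(pooled.ci_upper)),
                "pooled": True, "m": m,
            }
            qlog = np.array([rubin_pool(level_est[q], level_var[q]).point
                             for q in range(2, 6)])
            # floated CIs from the average covariance with the diagonal
            # replaced by the Rubin total variances
            cov_q = cov_sum / m
            for k, q in enumerate(range(2, 6)):
                cov_q[k, k] = rubin_pool(level_est[q], level_var[q]).total
        else:
            b, v = cont_est[0], cont_var[0]
            z = 1.959963984540054
            per_unit[outcome] = {
                "log_hr": float(b), "se": float(np.sqrt(v)),
                "hr": float(np.exp(b)),
                "ci_lower": float(np.exp(b - z * np.sqrt(v))),
                "ci_upper": float(np.exp(b + z * np.sqrt(v))),
                "pooled": False, "m": 1,
            }
            qlog = np.array([level_est[q][0] for q in range(2, 6)])
            cov_q = cov_sum

        floated = survival.floated_hazard_table(qlog, cov_q)
        z = 1.959963984540054
        conventional = pd.DataFrame({
            "level": [f"Q{q}" for q in range(1, 6)],
            "log_hr": np.concatenate([[0.0], qlog]),
            "se": np.concatenate(
                [[np.nan], np.sqrt(np.diag(cov_q))]),
        })
        conventional["hr"] = np.exp(conventional["log_hr"])
        conventional["ci_lower"] = np.exp(
            conventional["log_hr"] - z * conventional["se"])
        conventional["ci_upper"] = np.exp(
            conventional["log_hr"] + z * conventional["se"])
        quintile_hr[outcome] = {
            "floated": floated,
            "conventional": conventional,
            "floated_quality_index": floated.attrs["floated_quality_index"],
        }
        diagnostics[outcome] = diag.to_dict()

    bundle = {
        "quintiles": quintiles,
        "cutpoints": cutpoints.tolist(),
        "incidence": incidence,
        "per_unit": per_unit,
        "quintile_hr": quintile_hr,
        "diagnostics": diagnostics,
        "metric": cfg.analysis.variability_metric,
        "exposure_parameter": cfg.analysis.exposure_parameter,
    }
    if cfg.analysis.run_subgroups:
        prof = datasets[0]
        df = (
            prof.merge(outcomes, on="subject_id")
            .merge(exp_df, on="subject_id")
        )
        dur, ev = "time_kidney_disease", "event_kidney_disease"
        per_stratum, interactions = survival.subgroup_analysis(
            df, dur, ev, "exposure_value",
            ["usual_level"] + covariates)
        bundle["subgroups"] = {"per_stratum": per_stratum,
                               "interactions": interactions}
    return bundle


# -- sensitivity ---------------------------------------------------------------


def run_sensitivity(
    measurements: pd.DataFrame,
    profiles_missing: pd.DataFrame,
    trajectories: pd.DataFrame,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Re-run the per-unit analysis under the three sensitivity variants
    plus the kidney-disease decomposition.

    Variants: (1) complete-case analysis instead of multiple imputation;
    (2) exclusion of subjects followed for under 12 months; (3) exposure
    window widened from 24 to 36 months.  The decomposition splits the
    composite kidney-disease endpoint into its eGFR-only (< 60) and
    ACR-only (>= 3) components.  Returns a side-by-side per-unit HR table.
    """
    rows = []

    def one_variant(name, prof_missing, window, complete_case=False,
                    min_followup=0.0, outcome_filter=None):
        series = exposure_series(measurements, cfg.analysis.exposure_parameter)
        prof = prof_missing
        screened, _ = screen_cohort(
            prof.dropna(subset=["egfr_baseline"]),
            series.rename(columns={"value": "ldl"}), window,
        )
        outcomes = ascertain_outcomes_table(screened, trajectories)
        if outcome_filter is not None:
            outcomes = outcome_filter(screened, trajectories, outcomes)
        keep = screened["subject_id"]
        series = series[series["subject_id"].isin(keep)]
        spec = dataclasses.replace(cfg.model, seed=cfg.stage_seed("estimate"))
        estimates, _ = fit_hierarchical(series, spec, value_col="value")
        if min_followup > 0:
            fu = outcomes[[f"time_{o}" for o in OUTCOMES]].max(axis=1)
            outcomes = outcomes[fu >= min_followup]
            screened = screened[screened["subject_id"]
                                .isin(outcomes["subject_id"])]
        if complete_case:
            datasets = [screened[~_covariate_nan(screened).any(axis=1)]]
            screened = datasets[0]
            outcomes = outcomes[outcomes["subject_id"]
                                .isin(screened["subject_id"])]
        elif _covariate_nan(screened).any().any():
            spec_imp = dataclasses.replace(
                cfg.imputation, seed=cfg.stage_seed("impute"))
            datasets = mice_impute(
                screened.merge(outcomes, on="subject_id"), spec_imp)
            datasets = [d[screened.columns] for d in datasets]
        else:
            datasets = [screened]
        bundle = analyse_cohort(screened, estimates, outcomes, cfg,
                                imputed_profiles=datasets)
        for outcome, res in bundle["per_unit"].items():
            rows.append({"variant": name, "outcome": outcome, **res})

    def egfr_only(screened, trajectories, outcomes):
        traj = trajectories.copy()
        traj["acr"] = 0.0  # silence the albuminuria criterion
        return ascertain_outcomes_table(screened, traj)

    def acr_only(screened, trajectories, outcomes):
        traj = trajectories.copy()
        traj["egfr"] = 1000.0  # silence every eGFR criterion
        out = ascertain_outcomes_table(screened, traj)
        # only the composite is reinterpreted; decline/ESRD are meaningless
        base = ascertain_outcomes_table(screened, trajectories)
        for o in ("renal_decline_30pct", "esrd"):
            for c in (f"event_{o}", f"time_{o}", f"censor_reason_{o}"):
                out[c] = base[c]
        return out

    window = float(cfg.analysis.window_months)
    one_variant("main", profiles_missing, window)
    one_variant("complete_case", profiles_missing, window, complete_case=True)
    one_variant("min_followup_12m", profiles_missing, window,
                min_followup=12.0)
    one_variant("window_36m", profiles_missing, 36.0)
    one_variant("kidney_egfr_only", profiles_missing, window,
                outcome_filter=egfr_only)
    one_variant("kidney_acr_only", profiles_missing, window,
                outcome_filter=acr_only)
    return pd.DataFrame(rows)


# -- reporting -----------------------------------------------------------------

_TABLE1_ROWS = [
    ("male", "pct"), ("age", "mean_sd"), ("smoker", "pct"),
    ("sbp", "mean_sd"), ("dbp", "mean_sd"), ("hba1c", "mean_sd"),
    ("bmi", "mean_sd"), ("dm_duration", "mean_sd"),
    ("egfr_baseline", "mean_sd"), ("acr_baseline", "mean_sd"),
    ("charlson", "mean_sd"), ("antidiabetic_any", "pct"),
    ("antihypertensive_any", "pct"), ("statin", "pct"), ("fibrate", "pct"),
    ("usual_level", "mean_sd"), ("exposure_value", "mean_sd"),
]


def render_tables(bundle: dict, profiles: pd.DataFrame,
                  estimates: pd.DataFrame, outcomes: pd.DataFrame,
                  out_dir: Path) -> list[Path]:
    """Write descriptive (Table-1-style) and outcome (Table-2-style)
    tables, in full-precision CSV and display-rounded Markdown."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    quintiles = bundle["quintiles"]
    metric_col = _metric_column(bundle["metric"])
    desc_src = (
        profiles.merge(estimates[["subject_id", "usual_level", metric_col]],
                       on="subject_id")
        .rename(columns={metric_col: "exposure_value"})
        .merge(quintiles[["subject_id", "quintile"]], on="subject_id")
    )
    rows = []
    for var, kind in _TABLE1_ROWS:
        if var not in desc_src.columns:
            continue
        row = {"characteristic": var, "kind": kind}
        for q in range(1, 6):
            sub = desc_src[desc_src["quintile"] == q][var]
            row[f"Q{q}"] = (100 * sub.mean() if kind == "pct" else sub.mean())
            row[f"Q{q}_sd"] = (np.nan if kind == "pct" else sub.std())
        allv = desc_src[var]
        row["overall"] = 100 * allv.mean() if kind == "pct" else allv.mean()
        row["overall_sd"] = np.nan if kind == "pct" else allv.std()
        rows.append(row)
    table1 = pd.DataFrame(rows)
    written.append(_write_csv(table1, out_dir / "table1_descriptives.csv"))

    t2_rows = []
    for outcome in OUTCOMES:
        inc = bundle["incidence"][outcome].set_index("group")
        floated = bundle["quintile_hr"][outcome]["floated"].set_index("level")
        for grp in [f"Q{q}" for q in range(1, 6)] + ["overall"]:
            r = inc.loc[grp]
            row = {
                "outcome": outcome, "group": grp,
                "events": int(r["events"]),
                "person_years": r["person_years"],
                "rate_per_1000py": r["rate_per_1000py"],
                "rate_ci_lower": r["ci_lower"],
                "rate_ci_upper": r["ci_upper"],
            }
            if grp in floated.index:
                f = floated.loc[grp]
                row.update(hr=f["hr"], hr_ci_lower=f["ci_lower"],
                           hr_ci_upper=f["ci_upper"])
            t2_rows.append(row)
    table2 = pd.DataFrame(t2_rows)
    written.append(_write_csv(table2, out_dir / "table2_outcomes.csv"))

    # display-rounded Markdown rendering (rates 1 dp, HRs 2 dp)
    md = ["| outcome | group | events | rate (95% CI) | HR (95% CI) |",
          "|---|---|---|---|---|"]
    for _, r in table2.iterrows():
        rate = (f"{r['rate_per_1000py']:.1f} "
                f"({r['rate_ci_lower']:.1f}, {r['rate_ci_upper']:.1f})")
        hr = ("" if pd.isna(r.get("hr", np.nan)) else
              f"{r['hr']:.2f} ({r['hr_ci_lower']:.2f}, {r['hr_ci_upper']:.2f})")
        md.append(f"| {r['outcome']} | {r['group']} | {int(r['events'])} "
                  f"| {rate} | {hr} |")
    md_path = out_dir / "table2_outcomes.md"
    md_path.write_text("\n".join(md) + "\n")
    written.append(md_path)

    per_unit_path = out_dir / "per_unit_hr.json"
    per_unit_path.write_text(json.dumps(bundle["per_unit"], indent=2))
    written.append(per_unit_path)
    diag_path = out_dir / "diagnostics.json"
    diag_path.write_text(json.dumps(bundle["diagnostics"], indent=2))
    written.append(diag_path)
    if "subgroups" in bundle:
        written.append(_write_csv(bundle["subgroups"]["per_stratum"],
                                  out_dir / "subgroup_forest.csv"))
        written.append(_write_csv(bundle["subgroups"]["interactions"],
                                  out_dir / "subgroup_interactions.csv"))
    return written


# -- orchestration -------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig, output_dir: str | Path | None = None
                 ) -> dict:
    """Execute every stage in order and return the artifact manifest."""
    cfg.validate()
    out_dir = Path(output_dir or cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    # generate
    gen = dataclasses.replace(cfg.generator, seed=cfg.stage_seed("generate"))
    measurements, profiles, trajectories, truth = generate_cohort(gen)
    profiles_missing = inject_missingness(
        profiles, gen.missingness, seed=cfg.stage_seed("generate") + 1)
    artifacts += [
        _write_csv(measurements, out_dir / "measurements.csv"),
        _write_csv(profiles_missing, out_dir / "profiles.csv"),
        _write_csv(trajectories, out_dir / "renal_trajectories.csv"),
        _write_csv(truth, out_dir / "truth.csv"),  # test-only artifact
    ]

    # assemble
    series = exposure_series(measurements, cfg.analysis.exposure_parameter)
    screened, exclusions = screen_cohort(
        profiles_missing, series.rename(columns={"value": "ldl"}),
        float(cfg.analysis.window_months))
    outcomes = ascertain_outcomes_table(screened, trajectories)
    artifacts += [
        _write_csv(exclusions, out_dir / "exclusions.csv"),
        _write_csv(outcomes, out_dir / "outcomes.csv"),
    ]

    # estimate
    series = series[series["subject_id"].isin(screened["subject_id"])]
    spec = dataclasses.replace(cfg.model, seed=cfg.stage_seed("estimate"))
    estimates, report = fit_hierarchical(series, spec, value_col="value")
    artifacts.append(_write_csv(estimates, out_dir / "variability_estimates.csv"))
    conv_path = out_dir / "convergence.json"
    conv_path.write_text(json.dumps(report.to_dict(), indent=2))
    artifacts.append(conv_path)

    # impute
    if _covariate_nan(screened).any().any():
        spec_imp = dataclasses.replace(cfg.imputation,
                                       seed=cfg.stage_seed("impute"))
        with_outcomes = screened.merge(outcomes, on="subject_id")
        completed = mice_impute(with_outcomes, spec_imp)
        datasets = [d[screened.columns] for d in completed]
        for i, d in enumerate(datasets):
            artifacts.append(_write_csv(d, out_dir / f"imputed_{i}.csv"))
    else:
        datasets = [screened]

    # analyse + report
    bundle = analyse_cohort(screened, estimates, outcomes, cfg,
                            imputed_profiles=datasets)
    artifacts += render_tables(bundle, datasets[0], estimates, outcomes,
                               out_dir)
    if cfg.analysis.run_sensitivity:
        sens = run_sensitivity(measurements, profiles_missing, trajectories,
                               cfg)
        artifacts.append(_write_csv(sens, out_dir / "sensitivity_hr.csv"))

    manifest = {
        "seed": cfg.seed,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
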