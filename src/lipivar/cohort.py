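"""Cohort assembly: lipid derivation, eligibility screening and renal
outcome ascertainment from longitudinal records.

Threshold semantics follow the study definitions literally: direct LDL-C is
used unless TG strictly exceeds 4.0 mmol/L (then the Friedewald value is
used); baseline kidney disease is eGFR < 60 mL/min/1.73 m^2 or ACR >= 3
mg/mmol; the decline outcome is a >= 30% reduction in eGFR since baseline,
ties counting as events (eGFR <= 0.7 x baseline); end-stage renal disease
is eGFR < 15.  Time is measured in months (days / 30.4375 when converting
from dates) from the subject's baseline, the date of the latest lipid panel
inside the inclusion window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "friedewald_ldl",
    "resolve_ldl",
    "resolve_ldl_series",
    "check_eligibility",
    "screen_cohort",
    "ascertain_outcomes",
    "ascertain_outcomes_table",
    "EligibilityDecision",
]

DAYS_PER_MONTH = 30.4375

AGE_RANGE = (45.0, 84.0)
MIN_MEASUREMENTS = 3
EGFR_KIDNEY_DISEASE = 60.0
EGFR_ESRD = 15.0
ACR_ALBUMINURIA = 3.0
TG_FRIEDEWALD_LIMIT = 4.0
DECLINE_FRACTION = 0.7  # >=30% reduction: event when eGFR <= 0.7 x baseline

OUTCOMES = ("kidney_disease", "renal_decline_30pct", "esrd")


def friedewald_ldl(tc: float, hdl: float, tg: float) -> float:
    """LDL-C estimated from total cholesterol, HDL-C and triglyceride,
    all in mmol/L: ``TC - HDL - TG/2.2``.

    Raises ``ValueError`` on non-positive inputs; a non-positive result is
    returned as-is and must be screened out by the caller (the reading is
    physiologically invalid).
    """
    if tc <= 0 or hdl <= 0 or tg <= 0:
        raise ValueError("lipid concentrations must be positive")
    return tc - hdl - tg / 2.2


def resolve_ldl(ldl_direct, tc, hdl, tg) -> tuple[float, bool] | None:
    """Resolve one panel to a single LDL-C value.

    Returns ``(value, derived)`` where ``derived`` is True when the
    Friedewald path was taken (TG > 4.0 mmol/L), or ``None`` when the panel
    yields no usable value (missing direct LDL with TG <= 4.0, incomplete
    panel on the Friedewald path, or a non-positive Friedewald result).
    """
    tg_known = tg is not None and not np.isnan(tg)
    direct_known = ldl_direct is not None and not np.isnan(ldl_direct)
    if tg_known and tg > TG_FRIEDEWALD_LIMIT:
        if tc is None or hdl is None or np.isnan(tc) or np.isnan(hdl):
            return None
        value = friedewald_ldl(tc, hdl, tg)
        if value <= 1e-9:  # tolerate float error at the exact-zero boundary
            return None
        return value, True
    if direct_known:
        return float(ldl_direct), False
    return None


def resolve_ldl_series(measurements: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`resolve_ldl` over a measurement table.

    Expects columns ``subject_id, month, ldl_direct, tc, hdl, tg``; returns
    the usable rows with columns ``subject_id, month, ldl, derived``.
    Unusable panels are dropped with a log entry counting them.
    """
    m = measurements
    tg = m["tg"].to_numpy(float)
    tc = m["tc"].to_numpy(float)
    hdl = m["hdl"].to_numpy(float)
    direct = m["ldl_direct"].to_numpy(float)

    use_friedewald = ~np.isnan(tg) & (tg > TG_FRIEDEWALD_LIMIT)
    friede = tc - hdl - tg / 2.2
    value = np.where(use_friedewald, friede, direct)
    valid = np.where(
        use_friedewald,
        ~np.isnan(tc) & ~np.isnan(hdl) & (friede > 1e-9),
        ~np.isnan(direct),
    )
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("resolve_ldl_series: dropped %d unusable panels", n_dropped)
    out = pd.DataFrame({
        "subject_id": m["subject_id"],
        "month": m["month"],
        "ldl": value,
        "derived": use_friedewald,
    })
    return out[valid].reset_index(drop=True)


@dataclass
class EligibilityDecision:
    subject_id: int
    eligible: bool
    reasons: list[str] = field(default_factory=list)


def check_eligibility(profile: pd.Series, n_readings: int,
                      window_months: float = 24.0) -> EligibilityDecision:
    """Apply the study inclusion criteria to one subject.

    Eligible iff aged 45-84 inclusive, >= 3 lipid readings inside the
    exposure window, baseline eGFR >= 60 and (missing or) baseline
    ACR < 3 mg/mmol.  All failed criteria are reported.
    """
    reasons = []
    age = profile["age"]
    if not (AGE_RANGE[0] <= age <= AGE_RANGE[1]):
        reasons.append("age")
    if n_readings < MIN_MEASUREMENTS:
        reasons.append("insufficient_measurements")
    if profile["egfr_baseline"] < EGFR_KIDNEY_DISEASE:
        reasons.append("baseline_kidney_disease")
    acr = profile.get("acr_baseline", np.nan)
    if not pd.isna(acr) and acr >= ACR_ALBUMINURIA:
        reasons.append("baseline_albuminuria")
    return EligibilityDecision(int(profile["subject_id"]),
                               eligible=not reasons, reasons=reasons)


def screen_cohort(profiles: pd.DataFrame, resolved: pd.DataFrame,
                  window_months: float = 24.0
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised eligibility screen over the whole cohort.

    ``resolved`` is the output of :func:`resolve_ldl_series`; only readings
    inside the ``window_months`` window ending at the subject's baseline
    count toward the >= 3-readings rule.  Returns ``(eligible_profiles,
    exclusions)`` where exclusions has columns ``subject_id, reasons``.
    """
    merged = resolved.merge(
        profiles[["subject_id", "baseline_month"]], on="subject_id"
    )
    in_window = (
        (merged["month"] <= merged["baseline_month"] + 1e-9)
        & (merged["month"] >= merged["baseline_month"] - window_months - 1e-9)
    )
    counts = (
        merged[in_window].groupby("subject_id").size()
        .reindex(profiles["subject_id"], fill_value=0).to_numpy()
    )
    age = profiles["age"].to_numpy()
    egfr = profiles["egfr_baseline"].to_numpy()
    acr = profiles["acr_baseline"].to_numpy(float)

    fail = {
        "age": (age < AGE_RANGE[0]) | (age > AGE_RANGE[1]),
        "insufficient_measurements": counts < MIN_MEASUREMENTS,
        "baseline_kidney_disease": egfr < EGFR_KIDNEY_DISEASE,
        "baseline_albuminuria": ~np.isnan(acr) & (acr >= ACR_ALBUMINURIA),
    }
    any_fail = np.zeros(len(profiles), bool)
    reason_lists: list[list[str]] = [[] for _ in range(len(profiles))]
    for name, mask in fail.items():
        any_fail |= mask
        for i in np.nonzero(mask)[0]:
            reason_lists[i].append(name)
    exclusions = pd.DataFrame({
        "subject_id": profiles["subject_id"].to_numpy()[any_fail],
        "reasons": [";".join(r) for r, f in zip(reason_lists, any_fail) if f],
    })
    return profiles[~any_fail].reset_index(drop=True), exclusions


def ascertain_outcomes(baseline_egfr: float, trajectory: pd.DataFrame,
                       death_month: float | None,
                       admin_end_month: float) -> dict:
    """Ascertain the three renal outcomes for one subject.

    ``trajectory`` has columns ``month`` (months after baseline), ``egfr``,
    ``acr``; the three outcomes are ascertained independently as the first
    record meeting each criterion, otherwise censored at
    min(last visit, death, administrative end).
    """
    death = np.inf if death_month is None or pd.isna(death_month) else death_month
    if len(trajectory) == 0:
        logger.warning("empty trajectory: censoring at baseline + epsilon")
        rec = {"subject_id": None}
        for o in OUTCOMES:
            rec[f"event_{o}"], rec[f"time_{o}"] = 0, 1e-6
            rec[f"censor_reason_{o}"] = "last_visit"
        return rec

    t = trajectory["month"].to_numpy(float)
    egfr = trajectory["egfr"].to_numpy(float)
    acr = trajectory["acr"].to_numpy(float)
    order = np.argsort(t, kind="stable")
    t, egfr, acr = t[order], egfr[order], acr[order]

    censor = min(t[-1], death, admin_end_month)
    crosses = {
        "kidney_disease": (egfr < EGFR_KIDNEY_DISEASE)
        | (~np.isnan(acr) & (acr >= ACR_ALBUMINURIA)),
        "renal_decline_30pct": egfr <= DECLINE_FRACTION * baseline_egfr,
        "esrd": egfr < EGFR_ESRD,
    }
    rec: dict = {}
    for o, mask in crosses.items():
        mask = mask & (t <= censor)
        if mask.any():
            rec[f"event_{o}"] = 1
            rec[f"time_{o}"] = float(t[mask][0])
            rec[f"censor_reason_{o}"] = "event"
        else:
            rec[f"event_{o}"] = 0
            rec[f"time_{o}"] = float(censor)
            if censor == death:
                rec[f"censor_reason_{o}"] = "death"
            elif censor == admin_end_month:
                rec[f"censor_reason_{o}"] = "admin_end"
            else:
                rec[f"censor_reason_{o}"] = "last_visit"
    return rec


def ascertain_outcomes_table(profiles: pd.DataFrame,
                             trajectories: pd.DataFrame,
                             admin_end_month: float = np.inf) -> pd.DataFrame:
    """Vectorised outcome ascertainment over the whole cohort.

    Returns one row per subject with ``event_* / time_* /
    censor_reason_*`` columns for the three outcomes.
    """
    traj = trajectories.sort_values(["subject_id", "month"], kind="stable")
    t = traj["month"].to_numpy(float)
    egfr = traj["egfr"].to_numpy(float)
    acr = traj["acr"].to_numpy(float)
    sid = traj["subject_id"].to_numpy()

    prof = profiles.set_index("subject_id")
    base = prof["egfr_baseline"].reindex(pd.Index(sid)).to_numpy(float)
    death_col = (
        prof["death_month"] if "death_month" in prof.columns
        else pd.Series(np.nan, index=prof.index)
    )

    df = pd.DataFrame({"subject_id": sid, "month": t})
    # per-subject censoring time: min(last visit, death, admin end)
    last_visit = df.groupby("subject_id")["month"].max()
    death = death_col.fillna(np.inf)
    censor = np.minimum(
        np.minimum(last_visit.reindex(prof.index).fillna(1e-6), death),
        admin_end_month,
    )
    reason = np.where(
        censor == last_visit.reindex(prof.index).fillna(1e-6), "last_visit",
        np.where(censor == death, "death", "admin_end"),
    )
    # death/admin may tie with last visit; last-visit label wins (the rule's
    # min is what matters, the reason is informational)

    crosses = {
        "kidney_disease": (egfr < EGFR_KIDNEY_DISEASE)
        | (~np.isnan(acr) & (acr >= ACR_ALBUMINURIA)),
        "renal_decline_30pct": egfr <= DECLINE_FRACTION * base,
        "esrd": egfr < EGFR_ESRD,
    }
    out = pd.DataFrame({"subject_id": prof.index.to_numpy()})
    censor_arr = censor.to_numpy(float)
    cmap = dict(zip(prof.index, censor_arr))
    climit = np.array([cmap[s] for s in sid])
    for o, mask in crosses.items():
        ok = mask & (t <= climit)
        first = (
            pd.Series(t[ok], index=sid[ok]).groupby(level=0).min()
            .reindex(prof.index)
        )
        event = first.notna().to_numpy()
        out[f"event_{o}"] = event.astype(int)
        out[f"time_{o}"] = np.where(event, first.to_numpy(float), censor_arr)
        out[f"censor_reason_{o}"] = np.where(event, "event", reason)
    return out
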