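"""Multiple imputation by chained equations and Rubin's-rule pooling.

Covariate missingness is filled with ``m`` (default 5) chained-equation
imputations via predictive mean matching, each downstream model is run on
every completed dataset, and the per-imputation estimates are pooled with
Rubin's rules on the log-HR scale (total variance
``T = W + (1 + 1/m) B``; t-based CI with Barnard-Rubin degrees of
freedom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.imputation.mice import MICEData

from .config import ImputationSpec

__all__ = ["mice_impute", "rubin_pool", "PooledEstimate"]


def mice_impute(
    profiles: pd.DataFrame,
    spec: ImputationSpec,
    exclude: tuple[str, ...] = ("subject_id", "death_month"),
) -> list[pd.DataFrame]:
    """Produce ``spec.m`` completed copies of ``profiles``.

    All numeric, non-constant columns outside ``exclude`` enter each
    chained-equation conditional model (predictive mean matching); callers
    should merge outcome indicators and event times into ``profiles``
    beforehand so the imputation model conditions on them.  Deterministic
    given ``spec.seed``.  A column that is entirely missing raises.

    ``exclude`` names columns that are neither imputed nor used as
    predictors; the default keeps identifiers and ``death_month`` (whose
    NaN encodes 'alive at end of follow-up', not a missing value) out of
    the chained equations.
    """
    spec.validate()
    miss_cols = [c for c in profiles.columns
                 if c not in exclude and profiles[c].isna().any()]
    for c in miss_cols:
        if profiles[c].isna().all():
            raise ValueError(f"column {c!r} is 100% missing; cannot impute")
    if not miss_cols:
        return [profiles.copy() for _ in range(spec.m)]

    numeric = profiles.select_dtypes(include=[np.number])
    work_cols = [
        c for c in numeric.columns
        if c not in exclude and numeric[c].nunique(dropna=True) > 1
    ]
    work = numeric[work_cols].astype(float)

    # statsmodels' MICE machinery draws from the global NumPy RNG
    np.random.seed(spec.seed % (2**31 - 1))
    completed = []
    for _ in range(spec.m):
        md = MICEData(work, k_pmm=spec.k_pmm)
        md.update_all(spec.sweeps)
        out = profiles.copy()
        for c in miss_cols:
            out[c] = md.data[c].to_numpy()
        completed.append(out)
    return completed


@dataclass
class PooledEstimate:
    """Rubin's-rule combination of ``m`` point estimates and variances."""

    point: float
    within: float          # W: mean within-imputation variance
    between: float         # B: between-imputation variance
    total: float           # T = W + (1 + 1/m) B
    df: float              # Barnard-Rubin (or classic Rubin) df
    ci_lower: float
    ci_upper: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total))


def rubin_pool(
    estimates,
    variances,
    level: float = 0.95,
    df_complete: float | None = None,
) -> PooledEstimate:
    """Pool per-imputation estimates with Rubin's rules.

    ``df_complete`` is the complete-data degrees of freedom; when given,
    the Barnard-Rubin small-sample adjustment is applied, otherwise the
    classic large-sample Rubin df ``(m-1)(1 + W / ((1+1/m)B))^2`` is used.
    With zero between-imputation variance the CI is normal-based.
    """
    est = np.asarray(estimates, float)
    var = np.asarray(variances, float)
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have equal length")
    m = est.size
    if m < 2:
        raise ValueError("pooling requires m >= 2 imputations")
    if np.any(var <= 0):
        raise ValueError("variances must be positive")

    point = float(est.mean())
    w = float(var.mean())
    b = float(est.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b

    if b == 0:
        df = np.inf
        crit = stats.norm.ppf(0.5 + level / 2)
    else:
        lam = (1.0 + 1.0 / m) * b / t
        df_m = (m - 1) / lam**2
        if df_complete is None:
            df = df_m
        else:
            df_obs = ((df_complete + 1.0) / (df_complete + 3.0)
                      * df_complete * (1.0 - lam))
            df = 1.0 / (1.0 / df_m + 1.0 / df_obs)
        crit = stats.t.ppf(0.5 + level / 2, df)
    half = crit * np.sqrt(t)
    return PooledEstimate(point, w, b, t, float(df),
                          point - half, point + half, m)
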