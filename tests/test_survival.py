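"""Survival stage: quintile mechanics, exact Poisson CIs, Cox oracle
checks, floated variances, spline basis, diagnostics and subgroups."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipivar.survival import (
    assign_quintiles,
    bonferroni,
    fit_cox,
    floated_ci,
    floated_hazard_table,
    incidence_table,
    ph_diagnostics,
    poisson_rate_ci,
    quintile_design,
    rcs_basis,
    subgroup_analysis,
)


class TestQuintiles:
    def test_study_size_group_counts(self):
        rng = np.random.default_rng(0)
        q, _ = assign_quintiles(rng.normal(size=105552))
        sizes = sorted(q["quintile"].value_counts().tolist())
        assert sizes == [21110, 21110, 21110, 21111, 21111]

    def test_small_distinct_values(self):
        values = np.array([5.0, 1.0, 9.0, 3.0, 7.0, 2.0, 8.0, 4.0, 6.0, 10.0])
        q, cuts = assign_quintiles(values)
        assert (q["quintile"].value_counts() == 2).all()
        # each quintile holds consecutive ranks
        for lvl in range(1, 6):
            vals = sorted(q.loc[q["quintile"] == lvl, "exposure"])
            assert vals == [2 * lvl - 1, 2 * lvl]
        assert list(cuts) == [3.0, 5.0, 7.0, 9.0]

    def test_all_equal_values_balanced_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            q, _ = assign_quintiles(np.full(23, 1.5))
        sizes = sorted(q["quintile"].value_counts().tolist())
        assert sizes == [4, 4, 5, 5, 5]
        assert "tied" in caplog.text

    def test_group_sizes_never_differ_by_more_than_one(self):
        rng = np.random.default_rng(1)
        for n in (5, 17, 101, 1003):
            q, _ = assign_quintiles(rng.normal(size=n))
            sizes = q["quintile"].value_counts()
            assert sizes.max() - sizes.min() <= 1

    def test_input_validation(self):
        with pytest.raises(ValueError):
            assign_quintiles([1.0, 2.0])
        with pytest.raises(ValueError):
            assign_quintiles([1.0, np.inf, 2.0, 3.0, 4.0])


class TestPoissonCI:
    def test_zero_events_closed_form(self):
        r = poisson_rate_ci(0, 100.0)
        assert r.ci_lower == 0.0
        # upper = chi2.ppf(0.975, 2)/2 = -ln(0.025)
        assert r.ci_upper == pytest.approx(-np.log(0.025) / 100.0 * 1000)

    @pytest.mark.parametrize("events", [1, 7, 100, 5000, 100000])
    def test_matches_gamma_quantile_oracle(self, events):
        """The exact Poisson interval equals gamma-distribution quantiles
        (independent parameterisation of the same exact interval)."""
        py = 1234.5
        r = poisson_rate_ci(events, py)
        lo = stats.gamma.ppf(0.025, events) / py * 1000
        hi = stats.gamma.ppf(0.975, events + 1) / py * 1000
        assert r.ci_lower == pytest.approx(lo, rel=1e-12)
        assert r.ci_upper == pytest.approx(hi, rel=1e-12)

    def test_invariants(self):
        r = poisson_rate_ci(50, 100.0)
        assert r.rate_per_1000py == pytest.approx(500.0)
        assert r.ci_lower <= r.rate_per_1000py <= r.ci_upper
        with pytest.raises(ValueError):
            poisson_rate_ci(-1, 100.0)
        with pytest.raises(ValueError):
            poisson_rate_ci(5, 0.0)


def _two_group_exponential(n=4000, rate0=0.02, ratio=2.0, seed=0):
    rng = np.random.default_rng(seed)
    group = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(1.0 / np.where(group == 1, rate0 * ratio, rate0))
    cens = np.minimum(rng.uniform(20, 120, n), 100.0)
    return pd.DataFrame({
        "time": np.minimum(t, cens),
        "event": (t <= cens).astype(int),
        "group": group,
    })


class TestCox:
    def test_two_group_matches_rate_ratio_oracle(self):
        """Cox HR on two-group exponential data agrees with the
        closed-form incidence-rate ratio (events / person-time)."""
        df = _two_group_exponential(seed=3)
        res = fit_cox(df, "time", "event", ["group"])
        g1 = df[df["group"] == 1]
        g0 = df[df["group"] == 0]
        rr = (g1["event"].sum() / g1["time"].sum()) / (
            g0["event"].sum() / g0["time"].sum())
        assert res.log_hr[0] == pytest.approx(np.log(rr), abs=0.02)
        assert np.exp(res.log_hr[0]) == pytest.approx(2.0, abs=0.2)

    def test_requires_events_and_variation(self):
        df = _two_group_exponential(n=50, seed=4)
        with pytest.raises(ValueError):
            fit_cox(df.assign(event=0), "time", "event", ["group"])
        with pytest.raises(ValueError):
            fit_cox(df.assign(flat=1.0), "time", "event", ["flat"])


class TestFloatedCI:
    def test_two_level_exact_split(self):
        lam, q = floated_ci(np.array([[0.08]]))
        assert lam == pytest.approx([0.04, 0.04])
        assert q == 0.0
        # pairwise identity holds exactly: Var(b1 - b0) = lam0 + lam1
        assert lam.sum() == pytest.approx(0.08)

    def test_compound_structure_recovered_exactly(self):
        """Reference-coded contrasts of independent groups have covariance
        v0 + diag(vi); the floated variances are the per-group variances."""
        v0 = 0.010
        vi = np.array([0.012, 0.020, 0.016, 0.030])
        cov = np.full((4, 4), v0) + np.diag(vi)
        lam, q = floated_ci(cov)
        assert lam[0] == pytest.approx(v0, rel=0.02)
        assert lam[1:] == pytest.approx(vi, rel=0.02)
        assert q < 0.01

    def test_quintile_fit_quality_bounded(self, small_cohort):
        """On a genuine quintile Cox covariance the pairwise identity
        holds within 10% (quality index reported)."""
        _, _, profiles, trajectories, truth = small_cohort
        from lipivar.cohort import ascertain_outcomes_table
        out = ascertain_outcomes_table(profiles, trajectories)
        df = profiles.merge(out, on="subject_id").merge(
            truth[["subject_id", "sigma_true"]], on="subject_id")
        q, _ = assign_quintiles(df["sigma_true"].to_numpy(),
                                df["subject_id"].to_numpy())
        df = df.merge(q[["subject_id", "quintile"]], on="subject_id")
        dfq, qcols = quintile_design(df)
        res = fit_cox(dfq, "time_kidney_disease", "event_kidney_disease",
                      qcols + ["age", "male"])
        idx = [res.term_index(c) for c in qcols]
        block = res.cov[np.ix_(idx, idx)]
        table = floated_hazard_table(res.log_hr[idx], block)
        assert table.attrs["floated_quality_index"] < 0.10
        assert len(table) == 5
        assert table["floated_se"].gt(0).all()  # reference level included

    def test_rejects_non_positive_definite(self):
        with pytest.raises(ValueError):
            floated_ci(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestRcsBasis:
    def test_three_knots_two_columns(self):
        x = np.linspace(0, 1, 200)
        basis = rcs_basis(x, n_knots=3)
        assert basis.shape == (200, 2)

    def test_left_tail_identically_zero(self):
        x = np.linspace(0, 1, 100)
        knots = np.array([0.3, 0.5, 0.8])
        basis = rcs_basis(x, knots=knots)
        assert np.all(basis[x <= 0.3, 1] == 0.0)

    def test_linear_tails_numerically(self):
        """Second differences vanish beyond the boundary knots."""
        knots = np.array([0.2, 0.5, 0.9])
        h = 1e-3
        for x0 in (-1.0, 2.5):
            pts = np.array([x0 - h, x0, x0 + h])
            col = rcs_basis(pts, knots=knots)[:, 1]
            second = (col[0] - 2 * col[1] + col[2]) / h**2
            assert abs(second) < 1e-6

    def test_coincident_knots_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.linspace(0, 1, 50), knots=np.array([0.2, 0.2, 0.8]))


class TestDiagnostics:
    def test_duplicated_covariate_flagged(self, caplog):
        df = _two_group_exponential(seed=5)
        rng = np.random.default_rng(6)
        df["x"] = rng.normal(size=len(df))
        df["x_copy"] = df["x"] + rng.normal(0, 1e-4, len(df))
        res = fit_cox(df, "time", "event", ["group", "x", "x_copy"])
        with caplog.at_level(logging.WARNING):
            rep = ph_diagnostics(res, df, "time", "event")
        assert rep.vif["x"] > 100
        assert "collinearity" in caplog.text

    def test_ph_violation_detected(self):
        """A hazard ratio that decays over follow-up should be caught by
        the scaled-Schoenfeld trend test."""
        rng = np.random.default_rng(7)
        n = 3000
        group = (rng.random(n) < 0.5).astype(float)
        # piecewise hazard: strong early effect that disappears later
        t = rng.exponential(np.where(group == 1, 20.0, 60.0))
        late = t > 15.0
        t = np.where(late & (group == 1),
                     15.0 + rng.exponential(60.0, n), t)
        df = pd.DataFrame({"time": np.minimum(t, 80.0),
                           "event": (t <= 80.0).astype(int),
                           "group": group})
        res = fit_cox(df, "time", "event", ["group"])
        rep = ph_diagnostics(res, df, "time", "event")
        assert rep.global_p < 0.05

    def test_vif_at_least_one(self):
        df = _two_group_exponential(seed=8)
        rng = np.random.default_rng(9)
        df["x"] = rng.normal(size=len(df))
        res = fit_cox(df, "time", "event", ["group", "x"])
        rep = ph_diagnostics(res, df, "time", "event")
        assert all(v >= 1.0 for v in rep.vif.values())
        assert all(0.0 <= p <= 1.0 for p in rep.schoenfeld_p.values())


class TestIncidenceTable:
    def test_rates_consistent_with_poisson_op(self, small_cohort):
        _, _, profiles, trajectories, truth = small_cohort
        from lipivar.cohort import ascertain_outcomes_table
        out = ascertain_outcomes_table(profiles, trajectories)
        q, _ = assign_quintiles(truth["sigma_true"].to_numpy(),
                                truth["subject_id"].to_numpy())
        table = incidence_table(out, q, "kidney_disease")
        assert len(table) == 6  # Q1..Q5 + overall
        row = table.iloc[2]
        ref = poisson_rate_ci(int(row["events"]), row["person_years"])
        assert row["rate_per_1000py"] == pytest.approx(ref.rate_per_1000py)
        assert row["ci_upper"] == pytest.approx(ref.ci_upper)
        assert table.iloc[-1]["events"] == table.iloc[:5]["events"].sum()


class TestSubgroups:
    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.01, 25) == pytest.approx(0.25)
        assert bonferroni(0.2, 10) == 1.0

    def test_stratum_specific_hr_recovered(self):
        """Two strata with genuinely different exposure effects: the
        per-stratum refits should recover the gradient."""
        rng = np.random.default_rng(10)
        n = 6000
        young = (rng.random(n) < 0.5)
        x = rng.normal(0, 1, n)
        beta = np.where(young, 0.6, 0.1)
        t = rng.exponential(1.0 / (0.02 * np.exp(beta * x)))
        df = pd.DataFrame({
            "time": np.minimum(t, 100.0),
            "event": (t <= 100.0).astype(int),
            "x": x,
            "young": young.astype(int),
        })
        strata = {"age_band": pd.Series(np.where(young, "young", "old"),
                                        index=df.index)}
        per_stratum, inter = subgroup_analysis(
            df, "time", "event", "x", ["x"], subgroups=strata)
        hrs = per_stratum.set_index("level")["hr"]
        assert hrs["young"] > hrs["old"]
        assert hrs["young"] == pytest.approx(np.exp(0.6), abs=0.15)
        assert inter.iloc[0]["p"] < 0.01
        assert inter.iloc[0]["p_bonferroni"] == pytest.approx(
            min(1.0, inter.iloc[0]["p"] * 1), rel=1e-9)
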