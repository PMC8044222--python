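"""Hierarchical model correctness: exact-posterior oracles on toy data,
the shared-variance (REML) limit, shrinkage and recovery properties, and
the naive SD/CV/VIM metrics."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lipivar import GeneratorConfig, HierarchicalModelSpec, generate_cohort
from lipivar.cohort import resolve_ldl_series
from lipivar.config import ConfigurationError
from lipivar.variability import (
    cv,
    effective_sample_size,
    fit_hierarchical,
    naive_sd,
    split_rhat,
    vim,
)


class TestNaiveMetrics:
    @pytest.mark.parametrize("values,expected", [
        ((3.0, 3.0, 3.0), 0.0),
        ((2.0, 3.0, 4.0), 1.0),
        ((1.8, 2.6, 3.4), 0.8),  # hand computation
    ])
    def test_naive_sd(self, values, expected):
        assert naive_sd(values) == pytest.approx(expected)

    def test_naive_sd_needs_two_values(self):
        with pytest.raises(ValueError):
            naive_sd([3.0])

    def test_cv(self):
        assert cv(0.5, 2.5) == pytest.approx(0.2)
        assert cv(0.0, 1.7) == 0.0
        with pytest.raises(ValueError):
            cv(0.5, 0.0)

    def test_cv_matches_ratio_on_random_draws(self):
        rng = np.random.default_rng(0)
        sds = rng.uniform(0.1, 1.0, 100)
        means = rng.uniform(1.0, 5.0, 100)
        assert np.allclose([cv(s, m) for s, m in zip(sds, means)],
                           sds / means)


class TestVim:
    def test_equal_means_falls_back_to_sd(self, caplog):
        sds = np.array([0.2, 0.5, 0.9])
        with caplog.at_level(logging.WARNING):
            out = vim(sds, np.full(3, 2.5))
        assert np.allclose(out, sds)
        assert "unidentifiable" in caplog.text

    def test_perfect_proportionality(self):
        rng = np.random.default_rng(1)
        means = rng.uniform(1.0, 5.0, 200)
        out = vim(0.15 * means, means)
        assert np.allclose(out, 0.15 * means.mean())

    def test_decorrelation_on_log_linear_data(self):
        rng = np.random.default_rng(2)
        means = rng.lognormal(1.0, 0.3, 5000)
        sds = 0.1 * means**0.7 * np.exp(rng.normal(0, 0.2, 5000))
        out = vim(sds, means)
        r = np.corrcoef(out, means)[0, 1]
        assert abs(r) < 0.02


def _exact_posterior_means(y, mu0, tau, eta, omega, n_grid=400):
    """Dense 2-D grid integration of the per-subject posterior over
    (mu_i, ln sigma_i) with hyperparameters pinned — the independent
    oracle for the sampler."""
    y = np.asarray(y, float)
    n = y.size
    mu_g = np.linspace(mu0 - 6 * tau, mu0 + 6 * tau, n_grid)
    ls_g = np.linspace(eta - 6 * omega, eta + 6 * omega, n_grid)
    mu_m, ls_m = np.meshgrid(mu_g, ls_g, indexing="ij")
    sig2 = np.exp(2 * ls_m)
    ss = ((y[:, None, None] - mu_m[None]) ** 2).sum(axis=0)
    logp = (
        -n * ls_m - ss / (2 * sig2)
        - (mu_m - mu0) ** 2 / (2 * tau**2)
        - (ls_m - eta) ** 2 / (2 * omega**2)
    )
    w = np.exp(logp - logp.max())
    w /= w.sum()
    e_mu = float((w * mu_m).sum())
    e_sig = float((w * np.exp(ls_m)).sum())
    return e_mu, e_sig


class TestSamplerOracles:
    HYPERS = {"mu0": 3.0, "tau": 0.5, "eta": math.log(0.5), "omega": 0.5}

    def test_two_subject_toy_matches_grid_integration(self):
        data = {0: [2.9, 3.0, 3.1], 1: [2.0, 3.0, 4.0]}
        series = pd.DataFrame({
            "subject_id": np.repeat([0, 1], 3),
            "ldl": np.concatenate([data[0], data[1]]),
        })
        spec = HierarchicalModelSpec(seed=7, burn_in=1000, draws=8000,
                                     fixed_hyperparams=dict(self.HYPERS))
        est, _ = fit_hierarchical(series, spec)
        for sid in (0, 1):
            e_mu, e_sig = _exact_posterior_means(data[sid], **self.HYPERS)
            row = est[est["subject_id"] == sid].iloc[0]
            assert row["usual_level"] == pytest.approx(e_mu, abs=0.02)
            assert row["variability"] == pytest.approx(e_sig, abs=0.03)

    def test_shared_variance_limit_matches_reml(self):
        """With omega pinned at 0 the model is a standard random-intercept
        model; the posterior mean of the common sigma should match the
        REML residual SD."""
        rng = np.random.default_rng(3)
        n_subj, n_rep = 50, 4
        mu_i = rng.normal(3.0, 0.5, n_subj)
        y = rng.normal(np.repeat(mu_i, n_rep), 0.4)
        series = pd.DataFrame({
            "subject_id": np.repeat(np.arange(n_subj), n_rep), "ldl": y})
        md = sm.MixedLM(y, np.ones_like(y), groups=series["subject_id"])
        reml_resid_sd = math.sqrt(md.fit(reml=True).scale)
        spec = HierarchicalModelSpec(seed=8, burn_in=1000, draws=4000,
                                     fixed_hyperparams={"omega": 0.0})
        est, _ = fit_hierarchical(series, spec)
        assert est["variability"].nunique() == 1
        assert est["variability"].iloc[0] == pytest.approx(
            reml_resid_sd, rel=0.04)


class TestFitProperties:
    def test_determinism(self, small_fit):
        resolved, spec, estimates, _ = small_fit
        again, _ = fit_hierarchical(resolved, spec)
        pd.testing.assert_frame_equal(estimates, again)

    def test_convergence_on_well_posed_problem(self, small_fit):
        *_, report = small_fit
        assert all(r < 1.05 for r in report.rhat.values())
        assert not report.flagged

    def test_shrinkage_toward_population_mean(self, small_fit):
        """Every posterior-mean usual level lies between the subject's
        sample mean and the population mean estimate."""
        resolved, _, estimates, _ = small_fit
        sample_means = resolved.groupby("subject_id")["ldl"].mean()
        mu0_hat = estimates.attrs["hyper_posterior_mean"]["mu0"]
        merged = estimates.set_index("subject_id").join(
            sample_means.rename("sample_mean"))
        # small slack: with mu0 itself sampled, subjects whose sample mean
        # sits on top of mu0 can land a hair outside the point interval
        lo = np.minimum(merged["sample_mean"], mu0_hat) - 0.02
        hi = np.maximum(merged["sample_mean"], mu0_hat) + 0.02
        assert ((merged["usual_level"] >= lo)
                & (merged["usual_level"] <= hi)).all()

    def test_posterior_sd_less_dispersed_than_naive(self, small_fit):
        resolved, _, estimates, _ = small_fit
        assert estimates["variability"].std() < estimates["naive_sd"].std()

    def test_prior_sensitivity(self, small_fit):
        """Doubling the hyperprior scales moves the subject estimates by
        far less than the posterior uncertainty."""
        resolved, spec, estimates, _ = small_fit
        import dataclasses
        wide = dataclasses.replace(spec, prior_mu0_sd=30.0,
                                   prior_tau_scale=10.0,
                                   prior_omega_scale=10.0, prior_eta_sd=4.0)
        est2, _ = fit_hierarchical(resolved, wide)
        assert np.abs(estimates["usual_level"]
                      - est2["usual_level"]).max() < 0.03
        assert np.abs(estimates["variability"]
                      - est2["variability"]).max() < 0.03

    def test_zero_spread_subject_flagged(self):
        series = pd.DataFrame({
            "subject_id": np.repeat([0, 1, 2, 3], 3),
            "ldl": [3.0, 3.0, 3.0,  # zero within-subject spread
                    2.0, 2.5, 3.0, 3.1, 3.4, 3.9, 2.2, 2.9, 3.6],
        })
        spec = HierarchicalModelSpec(seed=9, burn_in=300, draws=600)
        est, _ = fit_hierarchical(series, spec)
        assert est.loc[est["subject_id"] == 0, "flag"].iloc[0] == \
            "prior_dominated"
        assert (est["variability"] > 0).all()

    def test_spec_validation(self):
        with pytest.raises(ConfigurationError):
            HierarchicalModelSpec(n_chains=1).validate()
        with pytest.raises(ConfigurationError):
            HierarchicalModelSpec(draws=0).validate()


class TestDiagnosticsHelpers:
    def test_split_rhat_detects_disagreement(self):
        rng = np.random.default_rng(4)
        good = rng.normal(0, 1, (2, 2000))
        bad = np.vstack([rng.normal(0, 1, 2000), rng.normal(3, 1, 2000)])
        assert split_rhat(good) < 1.02
        assert split_rhat(bad) > 1.5

    def test_ess_penalises_autocorrelation(self):
        rng = np.random.default_rng(5)
        iid = rng.normal(0, 1, (2, 2000))
        ar = np.cumsum(rng.normal(0, 1, (2, 2000)), axis=1)
        assert effective_sample_size(iid) > 5 * effective_sample_size(ar)
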