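"""Usual lipid level and regression-dilution-corrected variability via a
hierarchical Bayesian model with subject-specific residual variance.

Model
-----
With ``y_ij`` the j-th lipid reading of subject i::

    y_ij      ~ Normal(mu_i, sigma_i^2)      (within-subject)
    mu_i      ~ Normal(mu0, tau^2)           (usual levels)
    ln sigma_i ~ Normal(eta, omega^2)        (log-variabilities)

with weakly-informative hyperpriors (normal on ``mu0`` and ``eta``,
half-normal on ``tau`` and ``omega``).  The posterior mean of ``mu_i`` is
the subject's *usual level* and the posterior mean of ``sigma_i`` their
*variability*: both are shrunken toward the population, which is what
corrects the severe sampling noise of a 3-reading sample SD (regression
dilution) when the estimate is later used as a Cox exposure.

Sampler
-------
Metropolis-within-Gibbs, fully vectorised across subjects:

* ``mu_i`` and ``mu0`` have conjugate normal full conditionals (Gibbs);
* ``eta`` is conjugate normal given the ``ln sigma_i``;
* ``ln sigma_i`` (jointly, independent across subjects), ``ln tau`` and
  ``ln omega`` use random-walk Metropolis steps whose scales adapt toward
  44% acceptance during burn-in only, so the kept draws form a valid chain.

Any subset of the hyperparameters can be pinned via
``HierarchicalModelSpec.fixed_hyperparams``; pinning ``omega = 0``
collapses the model to a shared residual SD (standard random-intercept
model), in which case ``eta`` is updated by Metropolis against the pooled
likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import HierarchicalModelSpec

logger = logging.getLogger(__name__)

__all__ = [
    "fit_hierarchical",
    "naive_sd",
    "cv",
    "vim",
    "ConvergenceReport",
    "split_rhat",
    "effective_sample_size",
]

RHAT_FLAG_THRESHOLD = 1.05
HYPER_NAMES = ("mu0", "tau", "eta", "omega")


# -- convergence diagnostics ---------------------------------------------------


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of Gelman et al. for an array of shape (n_chains, draws)."""
    n_chains, n = chains.shape
    half = n // 2
    splits = chains[:, : 2 * half].reshape(2 * n_chains, half)
    m, n_s = splits.shape
    means = splits.mean(axis=1)
    b = n_s * means.var(ddof=1)
    w = splits.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_plus = (n_s - 1) / n_s * w + b / n_s
    return float(np.sqrt(var_plus / w))


def effective_sample_size(chains: np.ndarray) -> float:
    """Bulk ESS from pooled autocorrelations (Geyer initial positive
    sequence, computed per chain and averaged)."""
    n_chains, n = chains.shape
    rho_sum = 0.0
    for c in range(n_chains):
        x = chains[c] - chains[c].mean()
        var = x @ x / n
        if var == 0:
            continue
        acf = np.correlate(x, x, mode="full")[n - 1 :] / (n * var)
        s, t = 0.0, 1
        while t + 1 < n:
            pair = acf[t] + acf[t + 1]
            if pair < 0:
                break
            s += pair
            t += 2
        rho_sum += 1.0 + 2.0 * s
    if rho_sum == 0:
        return float(n_chains * n)
    return float(n_chains * n / (rho_sum / n_chains))


@dataclass
class ConvergenceReport:
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    flagged: bool = False

    def to_dict(self) -> dict:
        return {"rhat": self.rhat, "ess": self.ess, "flagged": self.flagged}


# -- naive metrics -------------------------------------------------------------


def naive_sd(values) -> float:
    """Sample standard deviation (n-1 denominator) of one subject's readings."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("naive SD needs at least 2 readings")
    return float(v.std(ddof=1))


def cv(sd: float, mean: float) -> float:
    """Coefficient of variation, SD divided by the (positive) mean."""
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    return sd / mean


def vim(sds, means) -> np.ndarray:
    """Variability independent of the mean.

    Fits ``ln(sd_i) = a + beta * ln(mean_i)`` across subjects by least
    squares, then rescales ``VIM_i = sd_i * M**beta / mean_i**beta`` with
    ``M`` the cohort average of the means, which removes the Pearson
    correlation between variability and level on the fitting set.  When the
    means are (numerically) all equal, beta is unidentifiable and falls
    back to 0 with a warning, making VIM proportional to SD.
    """
    sds = np.asarray(sds, float)
    means = np.asarray(means, float)
    if np.any(means <= 0) or np.any(sds <= 0):
        raise ValueError("VIM requires positive sds and means")
    lm = np.log(means)
    if np.ptp(lm) < 1e-12:
        logger.warning("vim: all means equal, beta unidentifiable; using 0")
        beta = 0.0
    else:
        beta = float(np.polyfit(lm, np.log(sds), 1)[0])
    big_m = means.mean()
    return sds * (big_m / means) ** beta


# -- sampler -------------------------------------------------------------------


def _suffstats(series: pd.DataFrame, value_col: str):
    g = series.groupby("subject_id")[value_col]
    agg = g.agg(["count", "mean"])
    sumsq = series[value_col].pow(2).groupby(series["subject_id"]).sum()
    n_i = agg["count"].to_numpy(float)
    ybar = agg["mean"].to_numpy(float)
    ss = np.maximum(sumsq.to_numpy(float) - n_i * ybar**2, 0.0)
    return agg.index.to_numpy(), n_i, ybar, ss


class _Adapt:
    """Robbins-Monro step-size adaptation toward a target acceptance rate,
    active during burn-in only."""

    def __init__(self, scale: float, target: float = 0.44):
        self.scale = scale
        self.target = target
        self.count = 0

    def update(self, acc_rate: float) -> None:
        self.count += 1
        gamma = 1.0 / np.sqrt(self.count)
        self.scale *= float(np.exp(gamma * (acc_rate - self.target)))


def fit_hierarchical(
    series: pd.DataFrame,
    spec: HierarchicalModelSpec,
    value_col: str = "ldl",
) -> tuple[pd.DataFrame, ConvergenceReport]:
    """Fit the heteroscedastic hierarchy and return per-subject estimates.

    Parameters
    ----------
    series : long table with columns ``subject_id`` and ``value_col``;
        every subject should contribute >= 3 readings (>= 2 is accepted,
        with the posterior for that subject leaning more on the prior).
    spec : chain settings and hyperpriors.

    Returns
    -------
    estimates : one row per subject — ``usual_level`` / ``variability``
        (posterior means of ``mu_i`` / ``sigma_i``), their posterior SDs,
        ``naive_sd``, model-based ``cv`` and ``vim``, ``n_readings`` and a
        ``flag`` column (``prior_dominated`` for zero-spread subjects).
    report : split-R-hat / ESS per sampled hyperparameter; ``flagged``
        when any R-hat exceeds 1.05.
    """
    spec.validate()
    ids, n_i, ybar, ss = _suffstats(series, value_col)
    n_subj = len(ids)
    if np.any(n_i < 2):
        raise ValueError("every subject needs >= 2 readings")

    fixed = dict(spec.fixed_hyperparams or {})
    shared_sigma = "omega" in fixed and fixed["omega"] == 0.0

    pooled_sd = float(np.sqrt(np.maximum(ss.sum() / max(
        (n_i - 1).sum(), 1.0), 1e-8)))
    prior_mu0_mean = float(np.average(ybar, weights=n_i))
    prior_eta_mean = float(np.log(pooled_sd))

    keep = spec.draws // spec.thin
    hyper_chains = {h: np.empty((spec.n_chains, keep)) for h in HYPER_NAMES}
    sum_mu = np.zeros(n_subj)
    sum_mu2 = np.zeros(n_subj)
    sum_sig = np.zeros(n_subj)
    sum_sig2 = np.zeros(n_subj)
    total_kept = 0

    for chain in range(spec.n_chains):
        rng = np.random.default_rng([int(spec.seed), chain])
        mu = ybar + rng.normal(0, 0.01 * max(pooled_sd, 1e-3), n_subj)
        raw_sd = np.sqrt(ss / np.maximum(n_i - 1, 1.0))
        lnsig = np.log(np.clip(raw_sd, 0.3 * pooled_sd, None))
        lnsig += rng.normal(0, 0.05, n_subj)
        mu0 = fixed.get("mu0", float(np.mean(ybar)) + rng.normal(0, 0.05))
        tau = fixed.get("tau", max(float(np.std(ybar, ddof=1)), 1e-3)
                        * np.exp(rng.normal(0, 0.05)))
        eta = fixed.get("eta", float(np.mean(lnsig)))
        omega = fixed.get(
            "omega", max(float(np.std(lnsig, ddof=1)), 0.1)
        )
        if shared_sigma:
            lnsig = np.full(n_subj, eta)

        ad_sig = _Adapt(0.8 / np.sqrt(np.mean(n_i)))
        ad_tau = _Adapt(0.3)
        ad_omega = _Adapt(0.3)
        ad_eta = _Adapt(0.1)  # shared-sigma mode only

        kept_idx = 0
        for it in range(spec.burn_in + spec.draws):
            adapting = it < spec.burn_in
            sig2 = np.exp(2.0 * lnsig)

            # mu_i | rest  (conjugate)
            prec = n_i / sig2 + 1.0 / tau**2
            mean = (n_i * ybar / sig2 + mu0 / tau**2) / prec
            mu = mean + rng.normal(0, 1, n_subj) / np.sqrt(prec)

            # mu0 | mu  (conjugate, prior N(prior_mu0_mean, prior_mu0_sd^2))
            if "mu0" not in fixed:
                p0 = n_subj / tau**2 + 1.0 / spec.prior_mu0_sd**2
                m0 = (mu.sum() / tau**2
                      + prior_mu0_mean / spec.prior_mu0_sd**2) / p0
                mu0 = m0 + rng.normal(0, 1) / np.sqrt(p0)

            # tau  (random-walk Metropolis on log tau, half-normal prior)
            if "tau" not in fixed:
                dev = float(((mu - mu0) ** 2).sum())

                def lp_tau(lt):
                    t2 = np.exp(2.0 * lt)
                    return (-n_subj * lt - dev / (2.0 * t2)
                            - t2 / (2.0 * spec.prior_tau_scale**2) + lt)

                lt = np.log(tau)
                prop = lt + rng.normal(0, ad_tau.scale)
                acc = float(np.log(rng.random()) < lp_tau(prop) - lp_tau(lt))
                if acc:
                    tau = float(np.exp(prop))
                if adapting:
                    ad_tau.update(acc)

            # ln sigma_i  (vectorised Metropolis) or shared-sigma eta step
            ssq = ss + n_i * (ybar - mu) ** 2
            if shared_sigma:
                def lp_eta_shared(e):
                    s2 = np.exp(2.0 * e)
                    like = float(-(n_i * e).sum() - ssq.sum() / (2.0 * s2))
                    return like - (e - prior_eta_mean) ** 2 / (
                        2.0 * spec.prior_eta_sd**2)

                if "eta" not in fixed:
                    prop = eta + rng.normal(0, ad_eta.scale)
                    acc = float(np.log(rng.random())
                                < lp_eta_shared(prop) - lp_eta_shared(eta))
                    if acc:
                        eta = float(prop)
                    if adapting:
                        ad_eta.update(acc)
                lnsig = np.full(n_subj, eta)
            else:
                def lp_lnsig(ls):
                    return (-n_i * ls - ssq / (2.0 * np.exp(2.0 * ls))
                            - (ls - eta) ** 2 / (2.0 * omega**2))

                prop = lnsig + rng.normal(0, ad_sig.scale, n_subj)
                accept = np.log(rng.random(n_subj)) < lp_lnsig(prop) - lp_lnsig(lnsig)
                lnsig = np.where(accept, prop, lnsig)
                if adapting:
                    ad_sig.update(float(accept.mean()))

                # eta | ln sigma  (conjugate)
                if "eta" not in fixed:
                    pe = n_subj / omega**2 + 1.0 / spec.prior_eta_sd**2
                    me = (lnsig.sum() / omega**2
                          + prior_eta_mean / spec.prior_eta_sd**2) / pe
                    eta = me + rng.normal(0, 1) / np.sqrt(pe)

                # omega  (random-walk Metropolis on log omega)
                if "omega" not in fixed:
                    devw = float(((lnsig - eta) ** 2).sum())

                    def lp_omega(lw):
                        w2 = np.exp(2.0 * lw)
                        return (-n_subj * lw - devw / (2.0 * w2)
                                - w2 / (2.0 * spec.prior_omega_scale**2) + lw)

                    lw = np.log(omega)
                    prop = lw + rng.normal(0, ad_omega.scale)
                    acc = float(np.log(rng.random())
                                < lp_omega(prop) - lp_omega(lw))
                    if acc:
                        omega = float(np.exp(prop))
                    if adapting:
                        ad_omega.update(acc)

            if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
                if kept_idx < keep:
                    for h, val in zip(HYPER_NAMES, (mu0, tau, eta, omega)):
                        hyper_chains[h][chain, kept_idx] = val
                    kept_idx += 1
                sig = np.exp(lnsig)
                sum_mu += mu
                sum_mu2 += mu * mu
                sum_sig += sig
                sum_sig2 += sig * sig
                total_kept += 1

    report = ConvergenceReport()
    for h in HYPER_NAMES:
        if h in fixed:
            continue
        report.rhat[h] = split_rhat(hyper_chains[h])
        report.ess[h] = effective_sample_size(hyper_chains[h])
    report.flagged = any(r > RHAT_FLAG_THRESHOLD for r in report.rhat.values())
    if report.flagged:
        logger.warning("convergence flag: R-hat %s", report.rhat)

    post_mu = sum_mu / total_kept
    post_mu_sd = np.sqrt(np.maximum(sum_mu2 / total_kept - post_mu**2, 0.0))
    post_sig = sum_sig / total_kept
    post_sig_sd = np.sqrt(np.maximum(sum_sig2 / total_kept - post_sig**2, 0.0))

    naive = np.sqrt(ss / np.maximum(n_i - 1, 1.0))
    flags = np.where(ss <= 1e-12, "prior_dominated", "")
    model_cv = post_sig / post_mu
    estimates = pd.DataFrame({
        "subject_id": ids,
        "usual_level": post_mu,
        "usual_level_sd": post_mu_sd,
        "variability": post_sig,
        "variability_sd": post_sig_sd,
        "naive_sd": naive,
        "cv": model_cv,
        "vim": vim(post_sig, post_mu),
        "n_readings": n_i.astype(int),
        "flag": flags,
    })
    # attach posterior means of the hyperparameters as table metadata
    estimates.attrs["hyper_posterior_mean"] = {
        h: float(hyper_chains[h].mean()) for h in HYPER_NAMES
    }
    estimates.attrs["convergence"] = report.to_dict()
    return estimates, report
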