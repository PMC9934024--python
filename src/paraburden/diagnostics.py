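"""Simulation-based goodness-of-fit checks.

New responses are simulated from the fitted hierarchy (fresh random effects
by default, conditional on the estimated modes optionally), observed counts
are placed within their simulated reference distribution as randomized
quantile (PIT) residuals, and uniformity / dispersion are tested against
that simulated null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .nbglmm import FitResult, ModelData

__all__ = [
    "ResidualSet",
    "draw_random_effects",
    "simulate_responses",
    "quantile_residuals",
    "ks_uniformity",
    "dispersion_test",
]


@dataclass
class ResidualSet:
    """Randomized quantile residuals in (0, 1), reproducible given the seed."""

    residuals: np.ndarray
    nsim: int
    seed: int


def _hyper(fit: FitResult, name: str, default=0.0) -> float:
    return fit.params.get(name, default)


def simulate_responses(fit: FitResult, data: ModelData, nsim: int,
                       seed: int, conditional: bool = False) -> np.ndarray:
    """Simulate ``nsim`` response vectors from the fitted model.

    Unconditional simulation (the default) redraws every random effect from
    its fitted hyper-distribution, so the reference distribution reflects
    the full hierarchy; ``conditional=True`` keeps the conditional modes
    fixed and only redraws the NB counts.
    """
    if nsim < 2:
        raise ValueError("nsim must be >= 2")
    rng = np.random.default_rng(seed)
    spec = fit.spec
    n = data.n
    sims = np.empty((nsim, n), dtype=np.int64)

    nat = fit.params_natural
    for s in range(nsim):
        if conditional:
            eta = _eta_from_modes(fit, data)
            log_phi = (fit.re_modes["log_phi"][data.taxon_idx]
                       if "log_phi" in fit.re_modes
                       else np.full(n, fit.params["log_mu_phi"]))
        else:
            eta = np.zeros(n)
            if spec.random_intercept:
                mean_o = fit.params.get("mu_o", 0.0) \
                    if spec.intercept_grouping == "none" else 0.0
                b_o = rng.normal(mean_o, nat["sigma_o"], size=data.J)
                eta += b_o[data.pair_idx]
            else:
                eta += fit.params["mu_o"]
            if spec.intercept_grouping != "none":
                b_og = rng.normal(fit.params["mu_beta_o"], nat["sigma_beta_og"],
                                  size=len(data.intercept_group_labels))
                eta += b_og[data.intercept_group_idx[data.taxon_idx]]
            if spec.include_latitude:
                b_lat = rng.normal(fit.params["mu_lat"], nat["sigma_lat"],
                                   size=data.K)
                eta += data.X_lat * b_lat[data.taxon_idx]
            if spec.include_length:
                b_len = rng.normal(fit.params["mu_len"], nat["sigma_len"],
                                   size=data.J)
                eta += data.X_len * b_len[data.pair_idx]
            if spec.include_fish:
                zeta = rng.normal(0.0, nat["sigma_zeta"], size=data.F)
                eta += zeta[data.fish_idx]
            for c, p in enumerate(spec.predictors):
                if spec.slope_grouping == "none":
                    mg = np.full(data.K, fit.params[f"mu_gamma[{p}]"])
                else:
                    means = np.array([fit.params[f"mu_gamma[{p}][{g}]"]
                                      for g in data.slope_group_labels])
                    mg = means[data.slope_group_idx]
                gam = rng.normal(mg, nat[f"sigma_gamma[{p}]"])
                eta += data.U[:, c] * gam[data.taxon_idx]
            if spec.random_dispersion:
                log_phi = rng.normal(fit.params["log_mu_phi"],
                                     nat["sigma_logphi"], size=data.K)[data.taxon_idx]
            else:
                log_phi = np.full(n, fit.params["log_mu_phi"])
        mu = np.exp(np.clip(eta, -30, 30))
        phi = np.exp(np.clip(log_phi, -20, 20))
        sims[s] = rng.negative_binomial(phi, phi / (phi + mu))
    return sims


def draw_random_effects(fit: FitResult, data: ModelData, seed: int) -> dict:
    """Draw one latent random-effect state from the fitted hyper-distributions.

    Returns per-block arrays shaped like ``fit.re_modes``; placing them back
    into a parameter wrapper (``fit_result_from_parameters``) gives a fully
    specified latent state for conditional simulation or parametric
    bootstrap.
    """
    rng = np.random.default_rng(seed)
    spec = fit.spec
    nat = fit.params_natural
    out: dict = {}
    if spec.random_intercept:
        mean_o = fit.params.get("mu_o", 0.0) \
            if spec.intercept_grouping == "none" else 0.0
        out["beta_o"] = rng.normal(mean_o, nat["sigma_o"], size=data.J)
    if spec.intercept_grouping != "none":
        out["beta_og"] = rng.normal(fit.params["mu_beta_o"],
                                    nat["sigma_beta_og"],
                                    size=len(data.intercept_group_labels))
    if spec.include_latitude:
        out["beta_lat"] = rng.normal(fit.params["mu_lat"], nat["sigma_lat"],
                                     size=data.K)
    if spec.include_length:
        out["beta_len"] = rng.normal(fit.params["mu_len"], nat["sigma_len"],
                                     size=data.J)
    if spec.include_fish:
        out["zeta"] = rng.normal(0.0, nat["sigma_zeta"], size=data.F)
    for p in spec.predictors:
        if spec.slope_grouping == "none":
            mg = np.full(data.K, fit.params[f"mu_gamma[{p}]"])
        else:
            means = np.array([fit.params[f"mu_gamma[{p}][{g}]"]
                              for g in data.slope_group_labels])
            mg = means[data.slope_group_idx]
        out[f"gamma[{p}]"] = rng.normal(mg, nat[f"sigma_gamma[{p}]"])
    if spec.random_dispersion:
        out["log_phi"] = rng.normal(fit.params["log_mu_phi"],
                                    nat["sigma_logphi"], size=data.K)
    return out


def _eta_from_modes(fit: FitResult, data: ModelData) -> np.ndarray:
    spec = fit.spec
    eta = np.zeros(data.n)
    if "beta_o" in fit.re_modes:
        eta += fit.re_modes["beta_o"][data.pair_idx]
    else:
        eta += fit.params.get("mu_o", 0.0)
    if "beta_og" in fit.re_modes:
        eta += fit.re_modes["beta_og"][data.intercept_group_idx[data.taxon_idx]]
    if spec.include_latitude:
        eta += data.X_lat * fit.re_modes["beta_lat"][data.taxon_idx]
    if spec.include_length:
        eta += data.X_len * fit.re_modes["beta_len"][data.pair_idx]
    if spec.include_fish:
        eta += fit.re_modes["zeta"][data.fish_idx]
    for c, p in enumerate(spec.predictors):
        eta += data.U[:, c] * fit.re_modes[f"gamma[{p}]"][data.taxon_idx]
    return eta


def quantile_residuals(y: np.ndarray, sims: np.ndarray, seed: int) -> ResidualSet:
    """Randomized PIT residuals of observations within their simulations.

    ``r_i = (#{sims < y_i} + u * (1 + #{sims = y_i})) / (nsim + 1)`` with
    ``u ~ Uniform(0, 1)``: the observation counts itself among the ties, so
    residuals are strictly inside (0, 1) and are iid uniform when the
    observations come from the same distribution as the simulations.
    """
    y = np.asarray(y)
    sims = np.asarray(sims)
    if sims.shape[1] != len(y):
        raise ValueError("sims columns must align with y")
    nsim = sims.shape[0]
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=len(y))
    less = (sims < y[None, :]).sum(axis=0)
    equal = (sims == y[None, :]).sum(axis=0)
    res = (less + u * (1 + equal)) / (nsim + 1)
    return ResidualSet(residuals=res, nsim=nsim, seed=seed)


def ks_uniformity(residuals: ResidualSet | np.ndarray) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of residuals against Uniform(0,1)."""
    res = residuals.residuals if isinstance(residuals, ResidualSet) else np.asarray(residuals)
    if len(res) < 10:
        raise ValueError("need >= 10 residuals")
    if np.any((res <= 0) | (res >= 1)):
        raise ValueError("residuals must lie strictly inside (0, 1)")
    out = stats.kstest(res, "uniform")
    return float(out.statistic), float(out.pvalue)


def dispersion_test(y: np.ndarray, sims: np.ndarray) -> tuple[float, float]:
    """Simulation-based overdispersion test.

    The statistic is the variance of standardized (Pearson-type) residuals,
    with per-observation means and SDs estimated from the simulations; the
    observed statistic is compared with its simulated null distribution.
    Returns ``(ratio, two-sided p)`` where ratio > 1 indicates more
    dispersion in the data than the model generates.
    """
    y = np.asarray(y, dtype=float)
    sims = np.asarray(sims, dtype=float)
    nsim = sims.shape[0]
    mu = sims.mean(axis=0)
    sd = sims.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)

    def stat(v):
        return float(np.var((v - mu) / sd, ddof=1))

    obs = stat(y)
    null = np.array([stat(sims[s]) for s in range(nsim)])
    ratio = obs / null.mean() if null.mean() > 0 else np.inf
    n_ge = int(np.sum(null >= obs))
    n_le = int(np.sum(null <= obs))
    p = 2.0 * min((n_ge + 1) / (nsim + 1), (n_le + 1) / (nsim + 1))
    return ratio, float(min(p, 1.0))
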