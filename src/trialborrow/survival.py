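"""Bayesian Weibull proportional-hazards model for event-free survival.

The hazard for subject i is h_i(t) = nu * t**(nu-1) * exp(eta_i) with a
shared shape nu and linear predictor

    eta_i = mu_c + beta * 1[arm = experimental]   (current trial)
    eta_i = mu_h                                  (historical controls)

so HR = exp(beta) is the experimental-vs-control hazard ratio.  Borrowing
acts through a commensurate prior on the log-rate intercepts,
mu_c ~ Normal(mu_h, sigma_tau^2): a small commensurate SD pools the two
control strata while a large one recovers the concurrent-only analysis.
The shape is shared across strata; borrowing touches only the intercept.

Sampling is the package's adaptive Metropolis-within-Gibbs; the posterior
is summarised with HR threshold probabilities (defaults 0.76 / 0.87 / 1.0,
i.e. assumed benefit / moderate benefit / any benefit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .errors import ConfigError
from .binary import BorrowConfig
from .mcmc import MCMCConfig, PosteriorSummary, adaptive_mwg, gelman_rubin
from .synthetic import TrialDataset

__all__ = [
    "WeibullParams", "weibull_loglik", "fit_weibull_borrow",
    "gelman_rubin", "threshold_probs", "DEFAULT_HR_THRESHOLDS",
]

DEFAULT_HR_THRESHOLDS = (0.76, 0.87, 1.0)
TIME_FLOOR = 0.01  # months; events recorded at t=0 are floored here


@dataclass(frozen=True)
class WeibullParams:
    """Parameters of the commensurate Weibull model."""

    shape: float                  # nu > 0
    mu_hist: float                # historical-control log rate
    mu_ctrl: float                # concurrent-control log rate
    log_hr: float                 # beta; HR = exp(beta)
    sigma_tau: Optional[float] = None

    def __post_init__(self):
        if self.shape <= 0:
            raise ConfigError("shape must be > 0")

    @property
    def hr(self) -> float:
        return math.exp(self.log_hr)


def _group_arrays(data: TrialDataset, floor: float):
    """(time, event) arrays per analysis group, with the time floor
    applied to event times of zero."""
    out = {}
    for key, pred in (
        ("experimental", lambda r: r.source == "current" and r.arm == "experimental"),
        ("control", lambda r: r.source == "current" and r.arm == "control"),
        ("historical", lambda r: r.source == "historical"),
    ):
        recs = [r for r in data.records if pred(r)]
        t = np.array([r.efs_time for r in recs], dtype=float)
        d = np.array([r.efs_event for r in recs], dtype=bool)
        if np.any(t < 0):
            raise ValueError("negative survival times")
        t = np.where(t < floor, floor, t)
        out[key] = (t, d)
    return out


def weibull_loglik(params: WeibullParams, data: TrialDataset,
                   floor: float = TIME_FLOOR) -> float:
    """Right-censored Weibull log-likelihood.

    sum_i [ delta_i (log nu + (nu-1) log t_i + eta_i) - t_i^nu exp(eta_i) ]
    with times below ``floor`` floored before evaluation.
    """
    nu = params.shape
    groups = _group_arrays(data, floor)
    eta = {"experimental": params.mu_ctrl + params.log_hr,
           "control": params.mu_ctrl,
           "historical": params.mu_hist}
    total = 0.0
    for key, (t, d) in groups.items():
        if t.size == 0:
            continue
        tnu = t ** nu
        total += float(np.sum(d * (math.log(nu) + (nu - 1.0) * np.log(t) + eta[key]))
                       - np.exp(eta[key]) * np.sum(tnu))
    return total


def threshold_probs(hr_draws: np.ndarray,
                    thresholds: Sequence[float] = DEFAULT_HR_THRESHOLDS,
                    ) -> Dict[float, float]:
    """Fraction of posterior HR draws strictly below each threshold."""
    draws = np.asarray(hr_draws, dtype=float).reshape(-1)
    if draws.size == 0:
        raise ValueError("empty draws")
    return {float(th): float(np.mean(draws < th)) for th in thresholds}


def fit_weibull_borrow(data: TrialDataset, borrow: BorrowConfig,
                       mcmc: MCMCConfig,
                       thresholds: Sequence[float] = DEFAULT_HR_THRESHOLDS,
                       fix_shape: Optional[float] = None,
                       prior_sd: float = 10.0,
                       floor: float = TIME_FLOOR) -> PosteriorSummary:
    """Fit the commensurate Weibull model by MCMC.

    Priors: beta ~ N(0, prior_sd^2), mu_h ~ N(0, prior_sd^2),
    log nu ~ N(0, prior_sd^2), mu_c ~ N(mu_h, sigma_tau^2) (or
    N(0, prior_sd^2) without borrowing); sigma_tau fixed or half-normal per
    ``borrow``.  ``fix_shape`` pins nu instead of sampling it.

    Requires at least one event in each randomized arm.  Non-convergence
    (any R-hat > 1.05) is flagged on the returned summary, not fatal.
    """
    mcmc.validate()
    groups = _group_arrays(data, floor)
    te, de = groups["experimental"]
    tc, dc = groups["control"]
    th_, dh = groups["historical"]
    for name, d in (("experimental", de), ("control", dc)):
        if d.sum() == 0:
            raise ValueError(f"no events in required arm {name!r}")

    use_hist = th_.size > 0 and borrow.mode != "none"
    adaptive = use_hist and borrow.mode == "adaptive"
    sig_fixed = borrow.sigma_tau if (use_hist and borrow.mode == "fixed") else None

    # sufficient statistics; sum t^nu is cached per nu value
    stats_fixed = {}
    logt = {}
    for key, (t, d) in (("e", (te, de)), ("c", (tc, dc)), ("h", (th_, dh))):
        stats_fixed[key] = (float(d.sum()), float(np.sum(d * np.log(t))))
        logt[key] = t
    cache = {"nu": None, "A": None}

    def tnu_sums(nu):
        if cache["nu"] != nu:
            with np.errstate(over="ignore"):  # inf rejected by the -inf guard
                cache["A"] = {k: float(np.sum(logt[k] ** nu)) for k in logt}
            cache["nu"] = nu
        return cache["A"]

    sample_shape = fix_shape is None

    # when borrowing, mu_ctrl is parametrised non-centered:
    # mu_ctrl = mu_hist + sigma_tau * gap, gap ~ N(0, 1), so the sampler
    # mixes in both the pooling (sigma -> 0) and no-borrow limits
    def mu_ctrl_of(p):
        if not use_hist:
            return p["mu_ctrl"]
        sig = (math.exp(p["log_sigma_tau"]) if adaptive else sig_fixed)
        return p["mu_hist"] + sig * p["gap"]

    def log_post(p):
        if sample_shape and abs(p["log_nu"]) > 15.0:
            return -np.inf
        if adaptive and abs(p["log_sigma_tau"]) > 30.0:
            return -np.inf
        nu = math.exp(p["log_nu"]) if sample_shape else fix_shape
        A = tnu_sums(nu)
        if not all(np.isfinite(a) for a in A.values()):
            return -np.inf
        lp = 0.0
        mu_c = mu_ctrl_of(p)
        eta = {"e": mu_c + p["beta"], "c": mu_c}
        if use_hist:
            eta["h"] = p["mu_hist"]
        if any(abs(e) > 500.0 for e in eta.values()):
            return -np.inf
        for k, e in eta.items():
            D, L = stats_fixed[k]
            lp += D * (math.log(nu) + e) + (nu - 1.0) * L - math.exp(e) * A[k]
        lp += -0.5 * (p["beta"] / prior_sd) ** 2
        if sample_shape:
            lp += -0.5 * (p["log_nu"] / prior_sd) ** 2
        if use_hist:
            lp += -0.5 * (p["mu_hist"] / prior_sd) ** 2
            lp += -0.5 * p["gap"] ** 2
            if adaptive:
                sig = math.exp(p["log_sigma_tau"])
                # half-normal prior on sigma_tau, log-scale Jacobian
                lp += -0.5 * (sig / borrow.hyper_scale) ** 2 + p["log_sigma_tau"]
        else:
            lp += -0.5 * (p["mu_ctrl"] / prior_sd) ** 2
        return lp

    # crude moment initialisation at nu = 1
    def mu0(t, d):
        return math.log(max(d.sum(), 0.5) / max(t.sum(), floor))

    init = {"beta": mu0(te, de) - mu0(tc, dc)}
    if sample_shape:
        init["log_nu"] = 0.0
    if use_hist:
        sig0 = borrow.sigma_tau if borrow.mode == "fixed" \
            else 0.5 * borrow.hyper_scale
        init["mu_hist"] = mu0(th_, dh)
        init["gap"] = float(np.clip(
            (mu0(tc, dc) - mu0(th_, dh)) / max(sig0, 1e-3), -3, 3))
        if adaptive:
            init["log_sigma_tau"] = math.log(sig0)
    else:
        init["mu_ctrl"] = mu0(tc, dc)

    raw = adaptive_mwg(log_post, init, mcmc)
    if use_hist:
        sig_draws = (np.exp(raw["log_sigma_tau"]) if adaptive
                     else sig_fixed)
        mu_ctrl = raw["mu_hist"] + sig_draws * raw["gap"]
    else:
        mu_ctrl = raw["mu_ctrl"]
    draws = {"beta": raw["beta"], "hr": np.exp(raw["beta"]),
             "mu_ctrl": mu_ctrl}
    draws["shape"] = (np.exp(raw["log_nu"]) if sample_shape
                      else np.full_like(raw["beta"], fix_shape))
    if use_hist:
        draws["mu_hist"] = raw["mu_hist"]
        if adaptive:
            draws["sigma_tau"] = np.exp(raw["log_sigma_tau"])
    rhat_params = ["beta", "mu_ctrl"] + (["shape"] if sample_shape else [])
    rhat_params += (["mu_hist"] if use_hist else [])
    summary = PosteriorSummary.from_draws(
        {**draws, **({"log_nu": raw["log_nu"]} if sample_shape else {})},
        thresholds={"hr": list(thresholds)},
        rhat_params=rhat_params)
    return summary
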