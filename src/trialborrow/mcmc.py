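"""Self-contained MCMC machinery shared by the Bayesian endpoint models.

The sampler is an adaptive random-walk Metropolis-within-Gibbs: each scalar
parameter gets its own Gaussian proposal whose step size is tuned during
warmup toward a target acceptance rate and frozen afterwards.  Parameters
with an exact full conditional (e.g. a conjugate Beta) can be supplied as
Gibbs updates instead.

Convergence is diagnosed with the Gelman-Rubin potential scale reduction
factor computed across chains.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError

RHAT_THRESHOLD = 1.05  # convergence flag raised above this


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``n_iter`` is the total number of iterations per chain; the first
    ``warmup_frac`` fraction is used for step-size adaptation and discarded.
    """

    n_chains: int = 3
    n_iter: int = 50_000
    warmup_frac: float = 0.5
    seed: int = 0
    target_accept: float = 0.3

    def validate(self) -> None:
        if self.n_chains < 2:
            raise ConfigError("n_chains must be >= 2")
        if self.n_iter < 1000:
            raise ConfigError("n_iter must be >= 1000")
        if not 0.0 < self.warmup_frac < 1.0:
            raise ConfigError("warmup_frac must be in (0, 1)")

    @property
    def n_warmup(self) -> int:
        return int(self.n_iter * self.warmup_frac)


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Potential scale reduction factor R-hat over equal-length chains.

    With m chains of length n: B = n * var(chain means) (m-1 denominator),
    W = mean within-chain variance (n-1 denominator),
    var+ = ((n-1)/n) W + B/n, and R-hat = sqrt(var+ / W).
    """
    arr = [np.asarray(c, dtype=float) for c in chains]
    m = len(arr)
    if m < 2:
        raise ValueError("gelman_rubin needs at least 2 chains")
    n = len(arr[0])
    if n < 2 or any(len(c) != n for c in arr):
        raise ValueError("chains must have equal lengths >= 2")
    means = np.array([c.mean() for c in arr])
    b = n * means.var(ddof=1)
    w = float(np.mean([c.var(ddof=1) for c in arr]))
    if w == 0.0:
        return 1.0 if b == 0.0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


@dataclass
class PosteriorSummary:
    """Retained MCMC draws with medians, equal-tailed 95% credible
    intervals, threshold probabilities and per-parameter R-hat."""

    draws: Dict[str, np.ndarray]            # name -> (n_chains, n_kept)
    median: Dict[str, float] = field(default_factory=dict)
    ci95: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    threshold_probs: Dict[str, Dict[float, float]] = field(default_factory=dict)
    rhat: Dict[str, float] = field(default_factory=dict)
    converged: bool = True
    warnings: list = field(default_factory=list)

    @classmethod
    def from_draws(cls, draws: Dict[str, np.ndarray],
                   thresholds: Optional[Dict[str, Sequence[float]]] = None,
                   rhat_params: Optional[Sequence[str]] = None,
                   ) -> "PosteriorSummary":
        s = cls(draws={k: np.asarray(v) for k, v in draws.items()})
        for name, d in s.draws.items():
            flat = d.reshape(-1)
            s.median[name] = float(np.median(flat))
            lo, hi = np.percentile(flat, [2.5, 97.5])
            s.ci95[name] = (float(lo), float(hi))
        if thresholds:
            for name, ths in thresholds.items():
                flat = s.draws[name].reshape(-1)
                s.threshold_probs[name] = {
                    float(th): float(np.mean(flat < th)) for th in ths}
        check = rhat_params if rhat_params is not None else list(s.draws)
        for name in check:
            d = s.draws[name]
            if d.shape[0] >= 2 and d.shape[1] >= 2:
                s.rhat[name] = gelman_rubin(list(d))
        if any(r > RHAT_THRESHOLD for r in s.rhat.values()):
            s.converged = False
            worst = max(s.rhat, key=s.rhat.get)
            s.warnings.append(
                f"R-hat {s.rhat[worst]:.3f} for {worst!r} exceeds "
                f"{RHAT_THRESHOLD}; interpret with caution")
        return s

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def to_dict(self) -> dict:
        return {
            "median": self.median,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "threshold_probs": {
                k: {str(t): p for t, p in v.items()}
                for k, v in self.threshold_probs.items()},
            "rhat": self.rhat,
            "converged": self.converged,
            "warnings": list(self.warnings),
        }


def adaptive_mwg(
    log_post: Callable[[Dict[str, float]], float],
    init: Dict[str, float],
    config: MCMCConfig,
    gibbs: Optional[Dict[str, Callable]] = None,
    init_jitter: float = 0.1,
) -> Dict[str, np.ndarray]:
    """Adaptive random-walk Metropolis-within-Gibbs.

    Parameters in ``gibbs`` map a name to ``f(rng, params) -> value`` drawing
    from the exact full conditional; all other parameters get scalar Gaussian
    random-walk updates.  Step sizes adapt in batches of 50 during warmup
    (multiplied by exp(+-delta) toward ``target_accept``) and are frozen for
    the retained draws.  Returns per-parameter arrays of shape
    (n_chains, n_iter - n_warmup).

    Chains are over-dispersed by jittering the initial point per chain.
    """
    config.validate()
    gibbs = gibbs or {}
    names = list(init)
    mh_names = [n for n in names if n not in gibbs]
    n_keep = config.n_iter - config.n_warmup
    out = {n: np.empty((config.n_chains, n_keep)) for n in names}
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains)

    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        params = dict(init)
        for n in mh_names:
            params[n] = params[n] + init_jitter * rng.standard_normal()
        step = {n: 0.5 for n in mh_names}
        acc = {n: 0 for n in mh_names}
        lp = log_post(params)
        if not np.isfinite(lp):
            # fall back to the un-jittered init
            params = dict(init)
            lp = log_post(params)
        batch = 0
        for it in range(config.n_iter):
            for n in mh_names:
                prop = dict(params)
                prop[n] = params[n] + step[n] * rng.standard_normal()
                lp_prop = log_post(prop)
                if np.log(rng.uniform()) < lp_prop - lp:
                    params, lp = prop, lp_prop
                    acc[n] += 1
            for n, draw in gibbs.items():
                params[n] = draw(rng, params)
                lp = log_post(params)
            if it < config.n_warmup:
                if (it + 1) % 50 == 0:
                    batch += 1
                    delta = min(0.25, batch ** -0.5)
                    for n in mh_names:
                        rate = acc[n] / 50.0
                        step[n] *= np.exp(delta if rate > config.target_accept
                                          else -delta)
                        acc[n] = 0
            else:
                k = it - config.n_warmup
                for n in names:
                    out[n][c, k] = params[n]
    return out
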