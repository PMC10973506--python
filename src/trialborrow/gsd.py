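"""Conventional group-sequential design for a survival endpoint.

Implements the frequentist comparator to the Bayesian interim analyses:
Schoenfeld event counts, the Lan-DeMets O'Brien-Fleming (OBF) error-spending
function, efficacy boundaries solved by recursive numerical integration over
the correlated Gaussian increments of the score process, non-binding
futility boundaries from beta-spending of the same OBF form under the
design alternative, conversion of z bounds to the hazard-ratio scale, and
simulation-based operating characteristics of the log-rank test.

Conventions: one-sided efficacy testing in the benefit direction (HR < 1
maps to positive z), information fraction = event fraction, 1:1 allocation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats, optimize

from .errors import ConvergenceError

_PHI = stats.norm.cdf
_PHINV = stats.norm.ppf

N_GRID = 4001          # integration grid points per look
GRID_HALFWIDTH = 8.0   # half-width in marginal SDs


@dataclass
class GSDesign:
    """A solved K-look group-sequential design."""

    fractions: Tuple[float, ...]       # information fractions, last = 1
    alpha: float                       # one-sided type-I error
    beta_err: Optional[float]          # type-II error (futility designs)
    drift: float                       # E[Z_K] under the design alternative
    z_eff: Tuple[float, ...]
    z_fut: Optional[Tuple[float, ...]] = None
    events_planned: Optional[int] = None
    spending: str = "Lan-DeMets O'Brien-Fleming"

    @property
    def k(self) -> int:
        return len(self.fractions)

    def events_at_looks(self) -> Optional[Tuple[int, ...]]:
        if self.events_planned is None:
            return None
        return tuple(int(round(t * self.events_planned)) for t in self.fractions)

    def hr_bounds(self) -> Optional[dict]:
        """Efficacy/futility bounds on the HR scale (needs planned events)."""
        ev = self.events_at_looks()
        if ev is None:
            return None
        out = {"efficacy": tuple(z_to_hr(z, d) for z, d in zip(self.z_eff, ev))}
        if self.z_fut is not None:
            out["futility"] = tuple(z_to_hr(z, d) for z, d in zip(self.z_fut, ev))
        return out


def schoenfeld_events(hr: float, alpha_two_sided: float = 0.05,
                      power: float = 0.82) -> int:
    """Events required to detect ``hr`` at two-sided ``alpha`` with 1:1
    allocation: ceil(4 (z_{1-a/2} + z_power)^2 / log(hr)^2)."""
    if not 0.0 < hr < 1.0:
        raise ValueError("hr must be in (0, 1); hr=1 needs infinite events")
    if not 0.0 < power < 1.0:
        raise ValueError("power must be in (0, 1)")
    za = _PHINV(1.0 - alpha_two_sided / 2.0)
    zb = _PHINV(power)
    return int(math.ceil(4.0 * (za + zb) ** 2 / math.log(hr) ** 2))


def schoenfeld_power(hr: float, events: int,
                     alpha_two_sided: float = 0.05) -> float:
    """Closed-form log-rank power: Phi(sqrt(d) |log hr| / 2 - z_{1-a/2})."""
    za = _PHINV(1.0 - alpha_two_sided / 2.0)
    return float(_PHI(math.sqrt(events) * abs(math.log(hr)) / 2.0 - za))


def obf_spend(t: float, alpha_one_sided: float = 0.025) -> float:
    """Lan-DeMets O'Brien-Fleming cumulative error spend at information
    fraction ``t``: 2 (1 - Phi(z_{1-alpha/2} / sqrt(t)))."""
    if t <= 0:
        raise ValueError("information fraction must be > 0")
    t = min(t, 1.0)
    return float(2.0 * (1.0 - _PHI(_PHINV(1.0 - alpha_one_sided / 2.0)
                                   / math.sqrt(t))))


def z_to_hr(z: float, events: float) -> float:
    """Hazard-ratio scale of a z bound: exp(-2 z / sqrt(events)), 1:1
    allocation, benefit direction HR < 1."""
    if events <= 0:
        raise ValueError("events must be > 0")
    return float(math.exp(-2.0 * z / math.sqrt(events)))


def drift_for_hr(hr: float, events: float) -> float:
    """Expected final-look z under ``hr`` with ``events`` total events."""
    return float(-math.log(hr) * math.sqrt(events) / 2.0)


# -- boundary recursion -------------------------------------------------
#
# The score process S_k = Z_k sqrt(t_k) is (discrete-time) Brownian motion:
# independent increments N(drift * dt, dt).  A sub-density of still-running
# paths is propagated look to look on a trapezoid grid and each bound is
# solved so the crossing mass equals the spending increment.


def _propagate(x, g, dt, drift, y):
    """Convolve sub-density (x, g) with the N(drift*dt, dt) increment,
    evaluated at points y (trapezoid rule over x)."""
    w = np.gradient(x)
    s = math.sqrt(dt)
    z = (y[:, None] - x[None, :] - drift * dt) / s
    dens = np.exp(-0.5 * z * z) / (s * math.sqrt(2.0 * math.pi))
    return dens @ (g * w)


def _tail_above(y, h, c):
    """integral of h over [c, y_max] by trapezoid with linear cut at c."""
    if c <= y[0]:
        return float(np.trapezoid(h, y))
    if c >= y[-1]:
        return 0.0
    j = np.searchsorted(y, c)
    hc = np.interp(c, y, h)
    ys = np.concatenate([[c], y[j:]])
    hs = np.concatenate([[hc], h[j:]])
    return float(np.trapezoid(hs, ys))


def solve_boundaries(fractions: Sequence[float], alpha_one_sided: float = 0.025,
                     beta_err: float = 0.18, drift: Optional[float] = None,
                     futility: bool = False, events_planned: Optional[int] = None,
                     n_grid: int = N_GRID) -> GSDesign:
    """Solve OBF-spending efficacy (and optional futility) z boundaries.

    Efficacy bounds are solved under the null so each look's incremental
    crossing probability equals the alpha-spend increment; the cumulative
    spend at the final look is exactly ``alpha_one_sided``.  Futility bounds
    (non-binding: efficacy ignores them) come from beta-spending of the same
    OBF form under the ``drift`` alternative, accounting for the efficacy
    bounds.  ``drift`` defaults to the value calibrated so the final
    futility and efficacy bounds coincide (see `calibrate_drift`).
    """
    t = tuple(float(x) for x in fractions)
    if len(t) > 25 or any(b <= a for a, b in zip(t, t[1:])) or abs(t[-1] - 1) > 1e-9:
        raise ValueError("fractions must be <= 25 values strictly increasing to 1")
    z_eff = _solve_efficacy(t, alpha_one_sided, n_grid)
    z_fut = None
    if futility:
        if drift is None:
            drift = calibrate_drift(t, alpha_one_sided, beta_err, n_grid=n_grid)
        z_fut = _solve_futility(t, z_eff, beta_err, drift, n_grid)
    return GSDesign(fractions=t, alpha=alpha_one_sided,
                    beta_err=beta_err if futility else None,
                    drift=0.0 if drift is None else float(drift),
                    z_eff=tuple(z_eff), z_fut=z_fut,
                    events_planned=events_planned)


def _solve_efficacy(t, alpha, n_grid):
    spends = [obf_spend(tk, alpha) for tk in t]
    bounds = []
    x = g = None
    for k, tk in enumerate(t):
        inc = spends[k] - (spends[k - 1] if k else 0.0)
        sd_k = math.sqrt(tk)
        if k == 0:
            c = sd_k * _PHINV(1.0 - inc)  # exact single-normal tail
            y = None
        else:
            dt = tk - t[k - 1]
            y = np.linspace(min(x[0], -GRID_HALFWIDTH * sd_k),
                            GRID_HALFWIDTH * sd_k, n_grid)
            h = _propagate(x, g, dt, 0.0, y)

            def excess(c_):
                return _tail_above(y, h, c_) - inc

            lo, hi = 0.0, GRID_HALFWIDTH * sd_k
            if excess(lo) < 0 or excess(hi) > 0:
                raise ConvergenceError(
                    f"efficacy bound bracket failed at look {k + 1}: "
                    f"excess({lo})={excess(lo):.2e}, excess({hi})={excess(hi):.2e}")
            c = optimize.brentq(excess, lo, hi, xtol=1e-10)
        bounds.append(c / sd_k)
        # restrict to the continuation region below c
        xn = np.linspace(-GRID_HALFWIDTH * sd_k, c, n_grid)
        if k == 0:
            g = stats.norm.pdf(xn, scale=sd_k)
        else:
            g = np.interp(xn, y, h)
        x = xn
    return bounds


def _solve_futility(t, z_eff, beta_err, drift, n_grid, unclamped=False):
    """Beta-spending futility bounds under the drift alternative, with the
    efficacy bounds in place.

    With ``unclamped=True`` (drift calibration) the raw solved bounds may
    exceed the efficacy bounds and are returned as-is so the calibration
    gap keeps its sign; the continuation region is still truncated at the
    efficacy bound.
    """
    spends = [obf_spend(tk, beta_err) for tk in t]
    bounds = []
    x = g = None
    for k, tk in enumerate(t):
        inc = spends[k] - (spends[k - 1] if k else 0.0)
        sd_k = math.sqrt(tk)
        c_eff = z_eff[k] * sd_k
        m = drift * tk
        if k == 0:
            # exact normal lower tail
            a = m + sd_k * _PHINV(inc)
            y = None
        else:
            dt = tk - t[k - 1]
            y = np.linspace(m - GRID_HALFWIDTH * sd_k,
                            max(x[-1], c_eff) + GRID_HALFWIDTH * math.sqrt(dt),
                            n_grid)
            h = _propagate(x, g, dt, drift, y)

            def deficit(a_):
                below = np.trapezoid(h, y) - _tail_above(y, h, a_)
                return below - inc

            hi = y[-1]
            a = optimize.brentq(deficit, y[0], hi, xtol=1e-10) \
                if deficit(hi) > 0 else hi
        if not unclamped:
            a = min(a, c_eff)
        bounds.append(a / sd_k)
        xn = np.linspace(min(a, c_eff - 1e-9), c_eff, n_grid)
        if k == 0:
            g = stats.norm.pdf(xn, loc=m, scale=sd_k)
        else:
            g = np.interp(xn, y, h)
        x = xn
    return bounds


def calibrate_drift(fractions, alpha_one_sided=0.025, beta_err=0.18,
                    n_grid=N_GRID) -> float:
    """Drift at which the final futility bound meets the final efficacy
    bound — i.e. the design alternative a futility-augmented design can
    just reject with power 1 - beta_err.  This exceeds the fixed-design
    drift; the ratio squared is the event-inflation factor."""
    t = tuple(float(x) for x in fractions)
    grid = min(n_grid, 1001)  # calibration loop; final bounds use full grid
    z_eff = _solve_efficacy(t, alpha_one_sided, grid)

    def gap(delta):
        z_fut = _solve_futility(t, z_eff, beta_err, delta, grid,
                                unclamped=True)
        return max(zf - ze for zf, ze in zip(z_fut, z_eff))

    lo = _PHINV(1 - alpha_one_sided) + _PHINV(1 - beta_err)  # fixed design
    hi = lo + 1.5
    try:
        return float(optimize.brentq(gap, lo - 0.2, hi, xtol=1e-6))
    except ValueError as exc:
        raise ConvergenceError(f"drift calibration failed: {exc}") from None


def boundary_crossing_probs(design: GSDesign, drift: float) -> dict:
    """First-crossing probabilities at each look under ``drift`` by the
    same recursive integration used to solve the bounds."""
    t = design.fractions
    eff = np.zeros(design.k)
    fut = np.zeros(design.k)
    x = g = None
    for k, tk in enumerate(t):
        sd_k = math.sqrt(tk)
        c = design.z_eff[k] * sd_k
        a = design.z_fut[k] * sd_k if design.z_fut is not None else -np.inf
        m = drift * tk
        lo_grid = min(m - GRID_HALFWIDTH * sd_k, a if np.isfinite(a) else np.inf)
        if k == 0:
            eff[0] = 1.0 - _PHI((c - m) / sd_k)
            if np.isfinite(a):
                fut[0] = _PHI((a - m) / sd_k)
            y = None
        else:
            dt = tk - t[k - 1]
            y = np.linspace(min(x[0] - GRID_HALFWIDTH * math.sqrt(dt),
                                lo_grid if np.isfinite(lo_grid) else x[0] - GRID_HALFWIDTH),
                            max(x[-1] + GRID_HALFWIDTH * math.sqrt(dt), c + 1.0),
                            len(x))
            h = _propagate(x, g, dt, drift, y)
            total = float(np.trapezoid(h, y))
            eff[k] = _tail_above(y, h, c)
            if np.isfinite(a):
                # mass at or below the futility bound (tail above `a`
                # already excludes it, including the efficacy region)
                fut[k] = max(total - _tail_above(y, h, min(a, c)), 0.0)
        lo_cont = a if np.isfinite(a) else -GRID_HALFWIDTH * sd_k + m
        xn = np.linspace(min(lo_cont, c), c, N_GRID)
        if k == 0:
            g = stats.norm.pdf(xn, loc=m, scale=sd_k)
        else:
            g = np.interp(xn, y, h)
        x = xn
    out = {"efficacy": eff, "efficacy_cumulative": np.cumsum(eff)}
    if design.z_fut is not None:
        out["futility"] = fut
        out["futility_cumulative"] = np.cumsum(fut)
    return out


# -- Monte-Carlo oracle over Gaussian increment paths -------------------


def simulate_crossing(design: GSDesign, drift: float, n_paths: int,
                      seed: int = 0, block: int = 200_000) -> dict:
    """Independent Monte-Carlo estimate of boundary crossing: simulates
    standard correlated Gaussian increment paths of the score process and
    counts first crossings of the efficacy (and futility) bounds."""
    t = np.asarray(design.fractions)
    dts = np.diff(np.concatenate([[0.0], t]))
    c = np.asarray(design.z_eff) * np.sqrt(t)
    a = (np.asarray(design.z_fut) * np.sqrt(t)
         if design.z_fut is not None else None)
    rng = np.random.default_rng(seed)
    eff_first = np.zeros(design.k)
    fut_first = np.zeros(design.k)
    done = 0
    while done < n_paths:
        m = min(block, n_paths - done)
        inc = rng.standard_normal((m, design.k)) * np.sqrt(dts) + drift * dts
        s = np.cumsum(inc, axis=1)
        alive = np.ones(m, dtype=bool)
        for k in range(design.k):
            hit_eff = alive & (s[:, k] >= c[k])
            eff_first[k] += hit_eff.sum()
            alive &= ~hit_eff
            if a is not None:
                hit_fut = alive & (s[:, k] <= a[k])
                fut_first[k] += hit_fut.sum()
                alive &= ~hit_fut
        done += m
    out = {"efficacy": eff_first / n_paths,
           "efficacy_cumulative": np.cumsum(eff_first) / n_paths}
    if a is not None:
        out["futility"] = fut_first / n_paths
        out["futility_cumulative"] = np.cumsum(fut_first) / n_paths
    return out


# -- log-rank simulation ------------------------------------------------


def logrank_z(time: np.ndarray, event: np.ndarray,
              group: np.ndarray) -> float:
    """Two-group log-rank z statistic (O - E over sqrt V in group 1),
    hypergeometric variance, ties handled by unique-time aggregation."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.asarray(group, int)
    order = np.argsort(time, kind="stable")
    time, event, group = time[order], event[order], group[order]
    n = len(time)
    utimes, first = np.unique(time, return_index=True)
    # at-risk counts just before each unique time
    n_at = n - first
    n1_at = group.sum() - np.concatenate([[0], np.cumsum(group)[:-1]])[first]
    d = np.add.reduceat(event.astype(float), first)
    d1 = np.add.reduceat((event & (group == 1)).astype(float), first)
    mask = (d > 0) & (n_at > 1)
    n_at, n1_at, d, d1 = n_at[mask], n1_at[mask], d[mask], d1[mask]
    e1 = d * n1_at / n_at
    v1 = d * (n1_at / n_at) * (1 - n1_at / n_at) * (n_at - d) / (n_at - 1)
    v = v1.sum()
    if v <= 0:
        return 0.0
    return float((d1.sum() - e1.sum()) / math.sqrt(v))


def simulate_logrank_operating_chars(hr: float, total_events: int,
                                     alpha_two_sided: float = 0.05,
                                     nsim: int = 10_000, seed: int = 0,
                                     n_patients: int = 800) -> dict:
    """Empirical rejection fraction of the two-sided log-rank test.

    Simulates 1:1 two-arm exponential trials administratively censored at
    the common follow-up giving ``total_events`` expected events; returns
    the rejection fraction and its binomial Monte-Carlo standard error.
    """
    if nsim < 1000:
        raise ValueError("nsim must be >= 1000")
    if not 0 < total_events <= n_patients:
        raise ValueError("need 0 < total_events <= n_patients")
    lam_c = 1.0  # time unit arbitrary
    lam_e = hr * lam_c
    frac = total_events / n_patients

    def expected_frac(tau):
        return 0.5 * ((1 - math.exp(-lam_c * tau))
                      + (1 - math.exp(-lam_e * tau))) - frac

    tau = optimize.brentq(expected_frac, 1e-9, 50.0 / min(lam_c, lam_e))
    n1 = n_patients // 2
    rng = np.random.default_rng(seed)
    zcrit = _PHINV(1.0 - alpha_two_sided / 2.0)
    group = np.concatenate([np.ones(n1, int), np.zeros(n_patients - n1, int)])
    rej = 0
    for _ in range(nsim):
        lam = np.where(group == 1, lam_e, lam_c)
        tt = rng.exponential(1.0 / lam)
        event = tt <= tau
        tt = np.minimum(tt, tau)
        if abs(logrank_z(tt, event, group)) > zcrit:
            rej += 1
    p = rej / nsim
    return {"rejection_fraction": p,
            "mc_se": math.sqrt(p * (1 - p) / nsim),
            "nsim": nsim, "tau": tau}
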