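"""Interim benefit-risk monitoring across scheduled enrollment milestones.

For each milestone the data are locked (`cut_at_milestone`), the historical
cohort is restricted to the propensity-matched set, and five endpoint
models are fitted: the commensurate Weibull model for EFS (HR threshold
probabilities at 0.76 / 0.87 / 1.0) and beta-binomial models for CR,
MRD-negative CR, 60-day mortality and grade 4-5 adverse events (posterior
treatment difference Delta = experimental - control and P(Delta > 0); for
the two harm endpoints that probability reads as excess harm).

Matching is performed once on the full dataset and reused at every interim.
Per-interim seeds derive from the master seed via
``numpy.random.SeedSequence([master_seed, interim_index])`` (documented,
deterministic), so any single interim can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .binary import ArmCounts, BinaryCounts, BorrowConfig, fit_binary_borrow
from .errors import MilestoneError
from .matching import MatchResult
from .mcmc import MCMCConfig, PosteriorSummary
from .survival import DEFAULT_HR_THRESHOLDS, fit_weibull_borrow
from .synthetic import TrialDataset, cut_at_milestone

BINARY_ENDPOINTS = ("cr", "mrd", "death60", "ae45")
HARM_ENDPOINTS = frozenset({"death60", "ae45"})
FUTILITY_PROB_THRESHOLD = 0.05  # advisory: P(HR < 0.76) below this


@dataclass
class EndpointSummary:
    """One endpoint's posterior summary at one interim."""

    endpoint: str
    status: str = "ok"                  # ok | error
    median: Optional[float] = None      # HR (efs) or Delta (binary)
    ci95: Optional[tuple] = None
    probs: Dict[float, float] = field(default_factory=dict)
    is_harm: bool = False
    rhat_max: Optional[float] = None
    converged: Optional[bool] = None
    error: Optional[str] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["probs"] = {str(k): v for k, v in self.probs.items()}
        return d


@dataclass
class InterimReport:
    """Benefit-risk summary for one milestone."""

    milestone: int
    cutoff: float
    median_follow_up: float
    n_current: int
    n_events: int
    efs: EndpointSummary = None
    binary: Dict[str, EndpointSummary] = field(default_factory=dict)
    borrow_mode: str = "adaptive"
    seed: int = 0
    futility_signal: Optional[bool] = None

    def to_dict(self) -> dict:
        return {
            "milestone": self.milestone, "cutoff": self.cutoff,
            "median_follow_up": self.median_follow_up,
            "n_current": self.n_current, "n_events": self.n_events,
            "efs": self.efs.to_dict() if self.efs else None,
            "binary": {k: v.to_dict() for k, v in self.binary.items()},
            "borrow_mode": self.borrow_mode, "seed": self.seed,
            "futility_signal": self.futility_signal,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def derive_interim_seed(master_seed: int, interim_index: int) -> int:
    """Deterministic per-interim seed: first word of
    SeedSequence([master_seed, interim_index]), reduced mod 2^31."""
    ss = np.random.SeedSequence([master_seed, interim_index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _binary_counts(data: TrialDataset, endpoint: str,
                   use_historical: bool) -> BinaryCounts:
    """Success/denominator counts for one binary endpoint per group.

    MRD uses CR patients with a non-missing MRD assessment as denominator;
    the other endpoints use all patients in the group.
    """
    def count(records):
        if endpoint == "cr":
            return sum(r.cr for r in records), len(records)
        if endpoint == "mrd":
            known = [r for r in records if r.cr and r.mrd_negative is not None]
            return sum(r.mrd_negative for r in known), len(known)
        if endpoint == "death60":
            return sum(r.death60 for r in records), len(records)
        if endpoint == "ae45":
            return sum(r.ae_grade45 for r in records), len(records)
        raise ValueError(f"unknown endpoint {endpoint!r}")

    exp = [r for r in data.current if r.arm == "experimental"]
    ctrl = [r for r in data.current if r.arm == "control"]
    hist = list(data.historical)
    ye, ne = count(exp)
    yc, nc = count(ctrl)
    historical = None
    if use_historical and hist:
        yh, nh = count(hist)
        if nh > 0:
            historical = ArmCounts(int(yh), int(nh))
    return BinaryCounts(ArmCounts(int(ye), int(ne)),
                        ArmCounts(int(yc), int(nc)), historical)


def _summ_efs(summary: PosteriorSummary) -> EndpointSummary:
    return EndpointSummary(
        endpoint="efs", median=summary.median["hr"], ci95=summary.ci95["hr"],
        probs=dict(summary.threshold_probs["hr"]),
        rhat_max=max(summary.rhat.values()) if summary.rhat else None,
        converged=summary.converged)


def _summ_binary(endpoint: str, summary: PosteriorSummary) -> EndpointSummary:
    p_gt0 = 1.0 - summary.threshold_probs["delta"][0.0]
    return EndpointSummary(
        endpoint=endpoint, median=summary.median["delta"],
        ci95=summary.ci95["delta"], probs={0.0: p_gt0},
        is_harm=endpoint in HARM_ENDPOINTS,
        rhat_max=max(summary.rhat.values()) if summary.rhat else None,
        converged=summary.converged)


def run_interim_schedule(data: TrialDataset, pairs: Optional[MatchResult],
                         milestones: Sequence[int], borrow: BorrowConfig,
                         mcmc: MCMCConfig,
                         thresholds: Sequence[float] = DEFAULT_HR_THRESHOLDS,
                         futility_prob: float = FUTILITY_PROB_THRESHOLD,
                         ) -> List[InterimReport]:
    """Run the full interim schedule and return one report per milestone.

    ``pairs`` (matching computed once on the full data) restricts the
    historical cohort; pass None to use all historical subjects, which with
    ``borrow.mode='none'`` reduces to a concurrent-only analysis.  A model
    failure on one endpoint is recorded in that endpoint's status; the
    other endpoints are still reported.
    """
    ms = list(milestones)
    if ms != sorted(set(ms)):
        raise MilestoneError("milestones must be strictly increasing")
    n_current = len(data.current)
    for m in ms:
        if m > n_current:
            raise MilestoneError(
                f"milestone {m} infeasible: only {n_current} current patients")

    if pairs is not None and pairs.pairs:
        matched = {h for _, h in pairs.pairs}
        data = data.subset(
            lambda r: r.source == "current" or r.id in matched)

    reports = []
    for idx, m in enumerate(ms):
        seed = derive_interim_seed(mcmc.seed, idx)
        cut = cut_at_milestone(data, m)
        n_events = sum(r.efs_event for r in cut.current)
        report = InterimReport(
            milestone=m, cutoff=cut.calendar_now,
            median_follow_up=cut.median_follow_up,
            n_current=len(cut.current), n_events=int(n_events),
            borrow_mode=borrow.mode, seed=seed)
        try:
            efs_summary = fit_weibull_borrow(
                cut, borrow, replace(mcmc, seed=seed), thresholds=thresholds)
            report.efs = _summ_efs(efs_summary)
        except Exception as exc:
            report.efs = EndpointSummary(endpoint="efs", status="error",
                                         error=str(exc))
        for j, endpoint in enumerate(BINARY_ENDPOINTS):
            try:
                counts = _binary_counts(cut, endpoint,
                                        use_historical=borrow.mode != "none")
                summary = fit_binary_borrow(
                    counts, borrow, replace(mcmc, seed=seed + j + 1))
                report.binary[endpoint] = _summ_binary(endpoint, summary)
            except Exception as exc:
                report.binary[endpoint] = EndpointSummary(
                    endpoint=endpoint, status="error", error=str(exc))
        if report.efs.status == "ok" and thresholds:
            report.futility_signal = bool(
                report.efs.probs.get(0.76, 1.0) < futility_prob)
        reports.append(report)
    return reports


def run_without_borrowing(data: TrialDataset, milestones: Sequence[int],
                          mcmc: MCMCConfig,
                          thresholds: Sequence[float] = DEFAULT_HR_THRESHOLDS,
                          ) -> List[InterimReport]:
    """Concurrent-data-only schedule: historical subjects dropped,
    borrow mode 'none'."""
    current_only = data.subset(lambda r: r.source == "current")
    return run_interim_schedule(current_only, None, milestones,
                                BorrowConfig(mode="none"), mcmc,
                                thresholds=thresholds)


def reports_to_frame(reports: Sequence[InterimReport]) -> pd.DataFrame:
    """Combined summary table: one row per (interim, endpoint)."""
    rows = []
    for r in reports:
        entries = [("efs", r.efs)] + list(r.binary.items())
        for name, s in entries:
            if s is None or s.status != "ok":
                rows.append({"interim": r.milestone, "endpoint": name,
                             "median": np.nan, "lo95": np.nan,
                             "hi95": np.nan, "prob_benefit": np.nan})
                continue
            prob = (s.probs.get(0.76) if name == "efs"
                    else s.probs.get(0.0))
            rows.append({"interim": r.milestone, "endpoint": name,
                         "median": s.median, "lo95": s.ci95[0],
                         "hi95": s.ci95[1], "prob_benefit": prob})
    return pd.DataFrame(rows)
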