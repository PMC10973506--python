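"""Propensity-score matching of historical controls to concurrent controls.

The propensity model is a logistic regression of trial membership (current
vs historical) on standardized age and two ELN-risk indicator contrasts
(intermediate and adverse vs favorable).  Historical controls are then
matched 1:1 to concurrent controls by greedy nearest-neighbour on the
propensity score, without replacement, processing concurrent controls in
decreasing score order; ties on |score difference| break to the lowest
historical id.  Covariate balance is reported as standardized mean
differences before and after matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConvergenceError, SeparationError
from .synthetic import ELN_LEVELS, PatientRecord

GRADIENT_TOL = 1e-8


@dataclass(frozen=True)
class MatchResult:
    """Propensity scores, fitted coefficients, pairs and balance table."""

    scores: Dict[str, float]
    coefficients: Dict[str, float]
    pairs: Tuple[Tuple[str, str], ...] = ()     # (current_id, historical_id)
    balance: Optional[pd.DataFrame] = None
    _frame: Optional[pd.DataFrame] = field(default=None, repr=False)

    def pairs_frame(self) -> pd.DataFrame:
        rows = [{"current_id": c, "historical_id": h,
                 "score_current": self.scores[c],
                 "score_historical": self.scores[h]}
                for c, h in self.pairs]
        return pd.DataFrame(
            rows, columns=["current_id", "historical_id",
                           "score_current", "score_historical"])


def _design(records: Sequence[PatientRecord]):
    """Model frame: standardized age + ELN contrasts vs favorable."""
    df = pd.DataFrame({
        "id": [r.id for r in records],
        "source": [r.source for r in records],
        "age": [r.age for r in records],
        "eln": [r.eln_risk for r in records],
    })
    mu, sd = df["age"].mean(), df["age"].std(ddof=0)
    sd = sd if sd > 0 else 1.0
    X = np.column_stack([
        np.ones(len(df)),
        (df["age"] - mu) / sd,
        (df["eln"] == "intermediate").astype(float),
        (df["eln"] == "adverse").astype(float),
    ])
    y = (df["source"] == "current").astype(float).to_numpy()
    return df, X, y


def fit_propensity(records: Sequence[PatientRecord]) -> MatchResult:
    """Maximum-likelihood logistic fit of current-trial membership.

    Restricted to control-arm subjects of both sources.  Raises
    `SeparationError` on complete separation and `ConvergenceError` if the
    score (gradient) norm does not reach 1e-8.
    """
    records = [r for r in records if r.arm == "control"]
    sources = {r.source for r in records}
    if sources != {"current", "historical"}:
        raise ValueError(
            f"need control subjects from both sources, got {sorted(sources)}")
    df, X, y = _design(records)
    names = ["intercept", "age_std", "eln_intermediate", "eln_adverse"]
    # drop constant (information-free) covariate columns, keep the intercept
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    X = X[:, keep]
    names = [names[j] for j in keep]
    model = sm.Logit(y, X)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(method="newton", maxiter=200, tol=1e-12, disp=False)
        params = fit.params
    except Exception as exc:  # statsmodels raises on perfect separation
        raise SeparationError(
            f"complete separation in propensity model: {exc}") from None
    p = model.predict(params)
    if np.all((p > 1 - 1e-8) == (y == 1)) and np.all((p < 1e-8) == (y == 0)):
        raise SeparationError(
            "complete separation: fitted probabilities are degenerate "
            f"(age range current {df.loc[y == 1, 'age'].min():.1f}-"
            f"{df.loc[y == 1, 'age'].max():.1f}, historical "
            f"{df.loc[y == 0, 'age'].min():.1f}-"
            f"{df.loc[y == 0, 'age'].max():.1f})")
    grad = model.score(params)
    if np.linalg.norm(grad) > GRADIENT_TOL:
        raise ConvergenceError(
            f"propensity fit gradient norm {np.linalg.norm(grad):.2e} > "
            f"{GRADIENT_TOL}")
    frame = df.assign(score=p)
    return MatchResult(
        scores=dict(zip(df["id"], map(float, p))),
        coefficients=dict(zip(names, map(float, params))),
        balance=_balance_table(frame, frame),
        _frame=frame,
    )


def _smd(x1: np.ndarray, x2: np.ndarray) -> float:
    """Standardized mean difference with pooled (average-variance) scale."""
    if len(x1) < 2 or len(x2) < 2:
        return float("nan")
    v = 0.5 * (x1.var(ddof=1) + x2.var(ddof=1))
    if v == 0:
        return 0.0
    return float((x1.mean() - x2.mean()) / np.sqrt(v))


def _balance_table(before: pd.DataFrame, after: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for name, col in [("age", "age")] + [
            (f"eln_{lv}", lv) for lv in ELN_LEVELS]:
        def vals(frame, src):
            sub = frame[frame["source"] == src]
            if col == "age":
                return sub["age"].to_numpy(dtype=float)
            return (sub["eln"] == col).to_numpy(dtype=float)
        rows.append({
            "covariate": name,
            "smd_before": _smd(vals(before, "current"), vals(before, "historical")),
            "smd_after": _smd(vals(after, "current"), vals(after, "historical")),
        })
    return pd.DataFrame(rows)


def greedy_match(result: MatchResult, n_pairs: int, seed: int = 0,
                 caliper: Optional[float] = None) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Concurrent controls are processed in decreasing propensity-score order
    (ties: ascending id); each takes the unused historical control with the
    smallest |score difference| (ties: lowest historical id).  Stops after
    ``n_pairs`` pairs.  ``seed`` is accepted for interface symmetry — the
    tie-break rules make the algorithm fully deterministic.  An optional
    caliper (max |score difference|) is off by default.
    """
    if result._frame is None:
        raise ValueError("scores must be computed before matching")
    frame = result._frame
    cur = frame[frame["source"] == "current"]
    hist = frame[frame["source"] == "historical"]
    if n_pairs > min(len(cur), len(hist)):
        raise ValueError(
            f"n_pairs={n_pairs} exceeds available subjects "
            f"({len(cur)} current, {len(hist)} historical)")
    cur_order = sorted(zip(cur["id"], cur["score"]),
                       key=lambda t: (-t[1], t[0]))
    avail = sorted(zip(hist["id"], hist["score"]), key=lambda t: t[0])
    pairs: List[Tuple[str, str]] = []
    for cid, cscore in cur_order:
        if len(pairs) >= n_pairs:
            break
        if not avail:
            break
        best = min(avail, key=lambda t: (abs(t[1] - cscore), t[0]))
        if caliper is not None and abs(best[1] - cscore) > caliper:
            continue
        avail.remove(best)
        pairs.append((cid, best[0]))
    matched_ids = {i for pair in pairs for i in pair}
    after = frame[frame["id"].isin(matched_ids)]
    return replace(result, pairs=tuple(pairs),
                   balance=_balance_table(frame, after))
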