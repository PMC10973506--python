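"""Synthetic patient-level trial data for interim-analysis experiments.

Emulates a two-arm randomized AML induction trial (roughly 390 patients per
arm, 1:1) together with a historical control cohort (~426 patients) from a
preceding trial whose control treatment matched the current one.  Each
patient carries an enrollment time under uniform staggered accrual, a latent
Weibull event-free-survival (EFS) time, an ELN 2017 genetic-risk category,
and four binary endpoints: complete remission (CR) after induction,
MRD-negative CR, death within 60 days, and grade 4-5 adverse events.

The generator is deterministic given a seed, and `cut_at_milestone`
reproduces an interim-analysis database lock: patients enrolled after the
cutoff are dropped and EFS is administratively censored at the cutoff.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataValidationError, MilestoneError

ELN_LEVELS = ("favorable", "intermediate", "adverse")
SOURCES = ("current", "historical")
ARMS = ("experimental", "control")

#: exact column order of the dataset CSV interchange format
CSV_COLUMNS = (
    "id", "source", "arm", "age", "eln_risk", "enroll_time",
    "efs_time", "efs_event", "cr", "mrd_negative", "death60", "ae_grade45",
)

DEATH60_WINDOW = 2.0  # months; 60 days == 2 months throughout


@dataclass(frozen=True)
class PatientRecord:
    """One subject: provenance, covariates, EFS and binary endpoints.

    ``mrd_negative`` is defined (non-None) only for subjects in CR with an
    evaluable MRD assay; ``None`` encodes "undefined/missing".
    """

    id: str
    source: str              # current | historical
    arm: str                 # experimental | control
    age: float               # years, in [18, 65]
    eln_risk: str            # favorable | intermediate | adverse
    enroll_time: float       # months from study start
    efs_time: float          # months from enrollment
    efs_event: bool
    cr: bool
    mrd_negative: Optional[bool]
    death60: bool
    ae_grade45: bool

    def validate(self) -> None:
        if self.source not in SOURCES:
            raise DataValidationError(f"bad source {self.source!r}")
        if self.arm not in ARMS:
            raise DataValidationError(f"bad arm {self.arm!r}")
        if self.eln_risk not in ELN_LEVELS:
            raise DataValidationError(f"bad eln_risk {self.eln_risk!r}")
        if self.source == "historical" and self.arm != "control":
            raise DataValidationError("historical records must be control-arm")
        if not 18.0 <= self.age <= 65.0:
            raise DataValidationError(f"age {self.age} outside [18, 65]")
        if self.enroll_time < 0 or self.efs_time < 0:
            raise DataValidationError("negative time")
        if self.mrd_negative is not None and not self.cr:
            raise DataValidationError("mrd_negative defined without CR")
        if self.death60 and not (self.efs_event and self.efs_time <= DEATH60_WINDOW):
            raise DataValidationError(
                "death60 requires an observed event within 2 months")


@dataclass(frozen=True)
class EndpointRates:
    """Binary endpoint probabilities for one treatment group."""

    cr: float
    mrd_neg_given_cr: float
    death60: float
    ae_grade45: float

    def validate(self) -> None:
        for name, p in dataclasses.asdict(self).items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {name}={p} outside [0, 1]")


@dataclass(frozen=True)
class TrialConfig:
    """Study conditions for the synthetic trial.

    Defaults reproduce the structure of a 388/392 randomized induction trial
    with a 426-patient historical control cohort: Weibull EFS with ~44%
    (current arms) / ~36% (historical) survival at 48 months, uniform accrual
    at 22 patients/month, and Table-1-style binary endpoint rates.
    """

    n_experimental: int = 388
    n_control: int = 392
    n_historical: int = 426
    accrual_rate: float = 22.0          # patients / month, uniform accrual
    weibull_shape: float = 0.9          # nu > 0, shared across groups
    mu_experimental: float = -3.681     # log baseline rate, S(48) ~= 0.44
    mu_control: float = -3.681
    mu_historical: float = -3.463       # S(48) ~= 0.36
    rates: dict = field(default_factory=lambda: {
        "experimental": EndpointRates(0.822, 0.758, 0.067, 0.299),
        "control": EndpointRates(0.867, 0.799, 0.054, 0.286),
        "historical": EndpointRates(0.845, 0.704, 0.080, 0.277),
    })
    mrd_missing_current: float = 0.22   # fraction of CR patients lacking MRD
    mrd_missing_historical: float = 0.35
    eln_probs: tuple = (0.36, 0.30, 0.34)
    milestones: tuple = (150, 300, 450, 600)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_experimental", "n_control", "n_historical"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.accrual_rate <= 0:
            raise ConfigError("accrual_rate must be > 0")
        if self.weibull_shape <= 0:
            raise ConfigError("weibull_shape must be > 0")
        if len(self.eln_probs) != 3 or any(p < 0 for p in self.eln_probs):
            raise ConfigError("eln_probs must be 3 non-negative values")
        if abs(sum(self.eln_probs) - 1.0) > 1e-9:
            raise ConfigError("eln_probs must sum to 1")
        for p in (self.mrd_missing_current, self.mrd_missing_historical):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("MRD missingness outside [0, 1]")
        for group in ("experimental", "control", "historical"):
            if group not in self.rates:
                raise ConfigError(f"missing endpoint rates for {group!r}")
            self.rates[group].validate()
        n_current = self.n_experimental + self.n_control
        if any(m > n_current for m in self.milestones):
            raise ConfigError("milestone exceeds current-trial size")
        if list(self.milestones) != sorted(set(self.milestones)):
            raise ConfigError("milestones must be strictly increasing")

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d = {k: (float(v) if isinstance(v, float) else v) for k, v in d.items()}
        d["rates"] = {
            g: {k: float(v) for k, v in dataclasses.asdict(r).items()}
            for g, r in self.rates.items()}
        d["eln_probs"] = [float(p) for p in self.eln_probs]
        d["milestones"] = [int(m) for m in self.milestones]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialConfig":
        d = dict(d)
        if "rates" in d:
            d["rates"] = {g: EndpointRates(**r) for g, r in d["rates"].items()}
        for key in ("eln_probs", "milestones"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrialConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class TrialDataset:
    """A collection of patient records plus provenance.

    ``calendar_now`` is the administrative cutoff in months from study start
    (None for a fully mature, uncut dataset where every latent event is
    observed).
    """

    records: tuple
    config: Optional[TrialConfig] = None
    calendar_now: Optional[float] = None

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, pred) -> "TrialDataset":
        return replace(self, records=tuple(r for r in self.records if pred(r)))

    @property
    def current(self) -> tuple:
        return tuple(r for r in self.records if r.source == "current")

    @property
    def historical(self) -> tuple:
        return tuple(r for r in self.records if r.source == "historical")

    @property
    def median_follow_up(self) -> Optional[float]:
        """Median of (cutoff - enroll_time) over retained current patients."""
        if self.calendar_now is None:
            return None
        fu = [self.calendar_now - r.enroll_time for r in self.current]
        return float(np.median(fu)) if fu else None

    def validate(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise DataValidationError("duplicate patient ids")
        for r in self.records:
            r.validate()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "id": r.id, "source": r.source, "arm": r.arm,
                "age": r.age, "eln_risk": r.eln_risk,
                "enroll_time": r.enroll_time, "efs_time": r.efs_time,
                "efs_event": int(r.efs_event), "cr": int(r.cr),
                "mrd_negative": "" if r.mrd_negative is None else int(r.mrd_negative),
                "death60": int(r.death60), "ae_grade45": int(r.ae_grade45),
            })
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _sample_weibull(rng, shape: float, rate: float, size: int) -> np.ndarray:
    """Weibull times with survivor S(t) = exp(-rate * t**shape)."""
    e = rng.exponential(size=size)
    return (e / rate) ** (1.0 / shape)


def _sample_weibull_trunc(rng, shape: float, rate: float, upper: float,
                          size: int) -> np.ndarray:
    """Weibull truncated to [0, upper] by inverse-CDF."""
    f_up = 1.0 - np.exp(-rate * upper ** shape)
    u = rng.uniform(size=size) * f_up
    return (-np.log1p(-u) / rate) ** (1.0 / shape)


def generate_trial(config: TrialConfig, seed: int) -> TrialDataset:
    """Draw a full synthetic trial dataset; deterministic given ``seed``.

    Latent EFS times are fully observed (no censoring) — interim censoring
    is applied afterwards by `cut_at_milestone`.  The death60 constraint is
    enforced by resampling EFS from the Weibull truncated to [0, 2 months]
    for death60-positive subjects.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    records = []
    n_current = config.n_experimental + config.n_control
    current_window = max(n_current / config.accrual_rate, 1e-9)
    hist_window = max(config.n_historical / config.accrual_rate, 1e-9)

    groups = (
        ("E", "current", "experimental", config.n_experimental,
         config.mu_experimental, current_window),
        ("C", "current", "control", config.n_control,
         config.mu_control, current_window),
        ("H", "historical", "control", config.n_historical,
         config.mu_historical, hist_window),
    )
    for prefix, source, arm, n, mu, window in groups:
        if n == 0:
            continue
        rate = float(np.exp(mu))
        rates = config.rates[arm if source == "current" else "historical"]
        miss = (config.mrd_missing_current if source == "current"
                else config.mrd_missing_historical)
        age = rng.uniform(18.0, 65.0, size=n)
        eln = rng.choice(ELN_LEVELS, size=n, p=np.asarray(config.eln_probs))
        enroll = rng.uniform(0.0, window, size=n)
        efs = _sample_weibull(rng, config.weibull_shape, rate, n)
        cr = rng.uniform(size=n) < rates.cr
        mrd_missing = rng.uniform(size=n) < miss
        mrd_neg = rng.uniform(size=n) < rates.mrd_neg_given_cr
        death60 = rng.uniform(size=n) < rates.death60
        ae = rng.uniform(size=n) < rates.ae_grade45
        n_d60 = int(death60.sum())
        if n_d60:
            efs[death60] = _sample_weibull_trunc(
                rng, config.weibull_shape, rate, DEATH60_WINDOW, n_d60)
        for i in range(n):
            records.append(PatientRecord(
                id=f"{prefix}{i:04d}", source=source, arm=arm,
                age=float(age[i]), eln_risk=str(eln[i]),
                enroll_time=float(enroll[i]), efs_time=float(efs[i]),
                efs_event=True, cr=bool(cr[i]),
                mrd_negative=(None if (not cr[i] or mrd_missing[i])
                              else bool(mrd_neg[i])),
                death60=bool(death60[i]), ae_grade45=bool(ae[i]),
            ))
    ds = TrialDataset(records=tuple(records), config=config, calendar_now=None)
    ds.validate()
    return ds


def cut_at_milestone(data: TrialDataset, milestone: int) -> TrialDataset:
    """Interim database lock after the ``milestone``-th current enrollment.

    The calendar cutoff is the enrollment time of the milestone-th
    current-trial patient (in enrollment order).  Later current patients are
    dropped; retained patients have EFS administratively censored at
    (cutoff - enroll_time).  death60 is masked when the latent death has not
    yet been observed at the cutoff.  Historical records pass through
    unchanged.
    """
    current = sorted(data.current, key=lambda r: r.enroll_time)
    if milestone < 1 or milestone > len(current):
        raise MilestoneError(
            f"milestone {milestone} infeasible: {len(current)} current "
            f"patients enrolled")
    cutoff = current[milestone - 1].enroll_time
    kept = []
    for r in current:
        if r.enroll_time > cutoff:
            continue
        follow_up = cutoff - r.enroll_time
        if r.efs_time > follow_up:
            r = replace(r, efs_time=follow_up, efs_event=False,
                        death60=False,
                        mrd_negative=r.mrd_negative)
        kept.append(r)
    return replace(data, records=tuple(kept) + data.historical,
                   calendar_now=cutoff)


# -- CSV interchange ----------------------------------------------------


def _parse_bool(raw, line: int, col: str) -> bool:
    s = str(raw).strip()
    if s in ("0", "1"):
        return s == "1"
    raise DataValidationError(f"line {line}: column {col!r} must be 0/1, got {raw!r}")


def read_dataset_csv(path) -> TrialDataset:
    """Read a patient table, validating schema and record invariants.

    Errors carry 1-based file line numbers (header is line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != list(CSV_COLUMNS):
        raise DataValidationError(
            f"bad header: expected {list(CSV_COLUMNS)}, got {list(df.columns)}")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            mrd_raw = row["mrd_negative"].strip()
            rec = PatientRecord(
                id=row["id"], source=row["source"], arm=row["arm"],
                age=float(row["age"]), eln_risk=row["eln_risk"],
                enroll_time=float(row["enroll_time"]),
                efs_time=float(row["efs_time"]),
                efs_event=_parse_bool(row["efs_event"], line, "efs_event"),
                cr=_parse_bool(row["cr"], line, "cr"),
                mrd_negative=(None if mrd_raw == ""
                              else _parse_bool(mrd_raw, line, "mrd_negative")),
                death60=_parse_bool(row["death60"], line, "death60"),
                ae_grade45=_parse_bool(row["ae_grade45"], line, "ae_grade45"),
            )
            rec.validate()
        except DataValidationError as exc:
            raise DataValidationError(f"line {line}: {exc}") from None
        except ValueError as exc:
            raise DataValidationError(f"line {line}: {exc}") from None
        records.append(rec)
    ds = TrialDataset(records=tuple(records))
    ds.validate()
    return ds
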