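"""Shared fixtures: small synthetic datasets and record factories."""

import numpy as np
import pytest

from trialborrow import (EndpointRates, PatientRecord, TrialConfig,
                         generate_trial)


def make_record(id: str, *, source="current", arm="control", age=50.0,
                eln_risk="favorable", enroll_time=0.0, efs_time=1.0,
                efs_event=True, cr=True, mrd_negative=None, death60=False,
                ae_grade45=False) -> PatientRecord:
    return PatientRecord(
        id=id, source=source, arm=arm, age=age, eln_risk=eln_risk,
        enroll_time=enroll_time, efs_time=efs_time, efs_event=efs_event,
        cr=cr, mrd_negative=mrd_negative, death60=death60,
        ae_grade45=ae_grade45)


def null_config(**kw) -> TrialConfig:
    """Trial with no treatment effect and no death60 EFS distortion."""
    rates = {g: EndpointRates(0.85, 0.78, 0.0, 0.29)
             for g in ("experimental", "control", "historical")}
    defaults = dict(weibull_shape=1.0, mu_experimental=np.log(0.02),
                    mu_control=np.log(0.02), mu_historical=np.log(0.02),
                    rates=rates)
    defaults.update(kw)
    return TrialConfig(**defaults)


@pytest.fixture(scope="session")
def table1_dataset():
    """Full-scale synthetic trial with the default study conditions."""
    return generate_trial(TrialConfig(), seed=20240)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
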