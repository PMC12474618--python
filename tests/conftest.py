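"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from eitbp.core import N_CHANNELS
from eitbp.synthdata import (
    EventSchedule,
    SimulationConfig,
    SubjectProfile,
    generate_cohort,
)

SEED = 20240917


def make_profile(**overrides) -> SubjectProfile:
    """A clean single-subject profile: fixed template, no noise."""
    base = dict(
        subject_id="test01",
        baseline_hr=90.0,
        hr_jitter=0.0,
        resp_rate=0.3,
        baseline_sap=120.0,
        baseline_map=90.0,
        baseline_dap=70.0,
        channel_dc=np.zeros(N_CHANNELS),
        channel_cardiac_gain=np.zeros(N_CHANNELS),
        channel_resp_gain=np.zeros(N_CHANNELS),
        noise_sd=0.0,
        beat_var_sd=0.0,
    )
    base.update(overrides)
    return SubjectProfile(**base)


@pytest.fixture(scope="session")
def quiet_cohort():
    """Two noise-free, jitter-free, event-free subjects (exact labels)."""
    cfg = SimulationConfig(
        n_subjects=2, base_duration_s=40.0, unbalance_factor=1.0
    ).quiet()
    return generate_cohort(cfg, seed=SEED)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Two subjects under the default study conditions, short records."""
    cfg = SimulationConfig(n_subjects=2, base_duration_s=60.0)
    return generate_cohort(cfg, seed=SEED)


@pytest.fixture()
def empty_schedule():
    return EventSchedule()
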