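"""Shared fixtures and deterministic hypothesis profile."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ictsib as ic
from ictsib.types import Condition

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def generator_config():
    return ic.default_generator_config()


@pytest.fixture(scope="session")
def eo_firm_trial(generator_config):
    return ic.generate_cop_trial(generator_config, Condition.EO_FIRM, seed=424242)


@pytest.fixture(scope="session")
def small_cohort(generator_config):
    """A 20-subject cohort shared by model/pipeline tests."""
    return ic.generate_cohort(generator_config, 20, seed=777)


def make_trial(x, y, fs=23.0, condition=Condition.EO_FIRM, subject_id=""):
    from ictsib.types import CopTrial

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.arange(len(x)) / fs
    return CopTrial(time=t, x=x, y=y, fs=fs, condition=condition, subject_id=subject_id)
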