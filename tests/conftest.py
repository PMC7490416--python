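"""Shared fixtures.

The expensive session fixture is the n=1000 study dataset used by the
population-statistics and acceptance tests; smaller fixtures cover the unit
and pipeline tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from hemopred.config import StudyConfig
from hemopred.population import SamplingConfig
from hemopred.simulator import (
    ArterialParams,
    CardiacParams,
    VirtualSubject,
    simulate_beat,
)
from hemopred.study import generate_study_dataset

#: Population-mean subject (the study's Table-of-parameters means).
MEAN_CARDIAC = dict(e_es=2.29, e_ed=0.12, p_fill=15.12, hr=82.57)
MEAN_ARTERIAL = dict(d_ao=3.0, height=175.0, tac=1.86, tpr=0.80)


def mean_subject(sid: str = "mean", **overrides) -> VirtualSubject:
    card = {**MEAN_CARDIAC, **{k: v for k, v in overrides.items()
                               if k in MEAN_CARDIAC}}
    art = {**MEAN_ARTERIAL, **{k: v for k, v in overrides.items()
                               if k in MEAN_ARTERIAL}}
    return VirtualSubject(CardiacParams(**card), ArterialParams(**art), sid)


@pytest.fixture(scope="session")
def mean_result():
    return simulate_beat(mean_subject())


@pytest.fixture(scope="session")
def study_config_1000():
    return StudyConfig(sampling=SamplingConfig(n=1000, seed=42))


@pytest.fixture(scope="session")
def study_report_1000(study_config_1000):
    """The full-scale noise-corrupted study dataset (shared; slow to build)."""
    return generate_study_dataset(study_config_1000)


@pytest.fixture(scope="session")
def study_dataset(study_report_1000):
    return study_report_1000.dataset


@pytest.fixture(scope="session")
def small_report():
    """A quick 120-subject dataset for pipeline-level unit tests."""
    config = StudyConfig(sampling=SamplingConfig(n=120, seed=7))
    return generate_study_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
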