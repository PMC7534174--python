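import numpy as np
import pytest

from algometry import (
    AcquisitionConfig,
    AscendingProtocol,
    OperatorModel,
    SubjectModel,
    individualize_train,
)


@pytest.fixture
def acq20():
    """Default 20 Hz acquisition."""
    return AcquisitionConfig()


@pytest.fixture
def train_a():
    """Worked-example train: peak 100 N, 5-s ascent, 1-s hold, instant descent."""
    return individualize_train(100.0, "fixed_durations", dict(a=5.0, p=1.0, d=0.0))


@pytest.fixture
def ascending_20():
    """Ascending ramp at 20 N/s towards the default 150 N limit."""
    return AscendingProtocol(loading_rate=20.0)


@pytest.fixture
def ideal_operator():
    """Lag-free, noise-free operator (trace equals the guideline)."""
    return OperatorModel(tracking_time_constant=0.0, noise_sd=0.0, seed=0)


@pytest.fixture
def subject_80():
    """Subject with all thresholds at 80 N and zero reaction time."""
    return SubjectModel(
        detection_threshold=80.0,
        pain_threshold=80.0,
        tolerance_threshold=80.0,
        reaction_time=0.0,
        seed=0,
    )
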