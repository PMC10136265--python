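import numpy as np
import pytest

from aptanomaly.signal_model import InjectionSchedule
from aptanomaly.synth import SynthConfig


@pytest.fixture
def tiny_schedule():
    """A short protocol (150 samples, L=30) so unit tests stay fast."""
    return InjectionSchedule(
        initial_load_duration_s=60.0,
        injection_interval_s=30.0,
        time_step_s=1.0,
        ladder=("No Analyte", "1 nM", "10 nM", "100 nM"),
    )


@pytest.fixture
def tiny_config(tiny_schedule):
    return SynthConfig(schedule=tiny_schedule, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
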