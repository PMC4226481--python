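import numpy as np
import pytest

from erpspell.paradigm import (FlashEvent, StimulusSchedule, TimingConfig,
                               build_schedule, make_letter_matrix)
from erpspell.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def matrix():
    return make_letter_matrix()


@pytest.fixture
def short_timing():
    """Two sequences per trial: fast unit-test schedules."""
    return TimingConfig(sequences_per_trial=2)


@pytest.fixture
def small_config(short_timing):
    """Small simulated study for unit-level end-to-end checks."""
    return SimulationConfig(timing=short_timing,
                            train_sentence="BRAIN",
                            test_sentence="KU")


def make_single_flash_schedule(stimulus_class: str, is_target: bool = True,
                               onset: float = 1.0) -> StimulusSchedule:
    """A schedule with exactly one flash event (forward-model probes)."""
    matrix = make_letter_matrix()
    letters = frozenset(matrix.row(0))          # A-F
    target = "A" if is_target else "Z"
    event = FlashEvent(onset=onset, letters=letters,
                       stimulus_class=stimulus_class, trial_index=0,
                       sequence_index=0, flash_index=0,
                       is_target=target in letters)
    return StimulusSchedule(condition="RASP_F", matrix=matrix,
                            targets=(target,), events=(event,),
                            timing=TimingConfig(sequences_per_trial=1))


@pytest.fixture
def single_flash_schedule():
    return make_single_flash_schedule


@pytest.fixture
def rc_schedule(rng):
    return build_schedule("RC", "AB", rng=rng)
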