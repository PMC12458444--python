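import numpy as np
import pytest

from invbehave import AssayDesign, FlyMetadata, TrajectoryRecord
from invbehave.simulate import SimulationConfig


@pytest.fixture
def design() -> AssayDesign:
    return AssayDesign(
        tube_length_mm=65.0,
        dt_s=1.0,
        stimulus_times_s=(3600.0, 3900.0),
        recording_duration_s=4200.0,
    )


@pytest.fixture
def short_sim_config() -> SimulationConfig:
    """A cohort config small enough for unit tests: one stimulus soon after
    the baseline hour, short tail."""
    return SimulationConfig(
        seed=42,
        n_per_cell=2,
        stimulus_times_s=(3600.0, 3900.0),
        recording_duration_s=4200.0,
    )


@pytest.fixture
def std_female() -> FlyMetadata:
    return FlyMetadata("f0", "STD", "F", 25.0, "1")


def make_trajectory(positions, dt_s=1.0, fly_id="f") -> TrajectoryRecord:
    positions = np.asarray(positions, dtype=float)
    times = np.arange(len(positions)) * dt_s
    return TrajectoryRecord(fly_id=fly_id, times=times, positions=positions, dt_s=dt_s)


def brute_force_bouts(flags, min_bout):
    """Independent run-length scanner used as the sleep-bout oracle."""
    bouts = []
    i = 0
    n = len(flags)
    while i < n:
        if not flags[i]:
            j = i
            while j < n and not flags[j]:
                j += 1
            if j - i >= min_bout:
                bouts.append((i, j))
            i = j
        else:
            i += 1
    return bouts
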