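"""Core data model for single-fly tube-assay recordings.

A fly is tracked in one dimension along a food-capped tube: position 0 mm is
the food end, ``tube_length_mm`` the far end.  Positions are sampled on a
uniform grid; speed is the absolute displacement per step, aligned to the
later sample of each pair (the first sample's speed is 0 by convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Closed set of In(2L)t karyotypes: inverted homozygote, heterozygote,
#: standard homozygote.
GENOTYPES = ("INV", "HET", "STD")
SEXES = ("F", "M")
#: Assay chamber temperatures (deg C).
TEMPERATURES = (20.0, 25.0, 30.0)

#: The six per-fly behavioral traits, in canonical column order.
TRAITS = (
    "sleep_min_per_hour",
    "base_speed_mm_s",
    "startle_duration_s",
    "startle_magnitude_mm_s",
    "prop_near_food",
    "prop_far_food",
)

#: Human-readable trait labels used in report tables.
TRAIT_LABELS = {
    "sleep_min_per_hour": "Sleep",
    "base_speed_mm_s": "Base Speed",
    "startle_duration_s": "Startle Duration",
    "startle_magnitude_mm_s": "Startle Magnitude",
    "prop_near_food": "Prop_nearfood",
    "prop_far_food": "Prop_farfood",
}

#: Traits that are proportions and get variance-stabilized before modeling.
PROPORTION_TRAITS = ("prop_near_food", "prop_far_food")


class ValidationError(ValueError):
    """Raised when an input record violates a structural invariant."""


def derive_speeds(positions: np.ndarray, dt_s: float) -> np.ndarray:
    """Per-sample speed |Δx|/dt aligned to the later sample; speeds[0] = 0."""
    positions = np.asarray(positions, dtype=float)
    speeds = np.empty_like(positions)
    speeds[0] = 0.0
    np.abs(np.diff(positions), out=speeds[1:])
    speeds[1:] /= dt_s
    return speeds


@dataclass(frozen=True)
class AssayDesign:
    """Geometry and schedule of one tracking assay.

    Parameters
    ----------
    tube_length_mm
        Tube length L; positions live in [0, L], food at 0.
    dt_s
        Uniform sampling interval in seconds.
    stimulus_times_s
        Ordered onsets of the mechanical startle stimuli.  The first stimulus
        must come no earlier than 3600 s so a full pre-stimulus baseline hour
        exists.
    recording_duration_s
        Total recording length; must exceed the last stimulus.
    """

    tube_length_mm: float = 65.0
    dt_s: float = 1.0
    stimulus_times_s: tuple[float, ...] = (3600.0, 5400.0, 7200.0, 9000.0)
    recording_duration_s: float = 10800.0

    def __post_init__(self) -> None:
        if self.tube_length_mm <= 0:
            raise ValidationError("tube_length_mm must be positive")
        if self.dt_s <= 0:
            raise ValidationError("dt_s must be positive")
        stims = tuple(float(t) for t in self.stimulus_times_s)
        object.__setattr__(self, "stimulus_times_s", stims)
        if len(stims) == 0:
            raise ValidationError("at least one stimulus is required")
        if any(b <= a for a, b in zip(stims, stims[1:])):
            raise ValidationError("stimulus_times_s must be strictly increasing")
        if stims[0] < 3600.0:
            raise ValidationError(
                "first stimulus must be >= 3600 s (pre-stimulus baseline hour)"
            )
        if self.recording_duration_s <= stims[-1]:
            raise ValidationError("recording_duration_s must exceed the last stimulus")

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.recording_duration_s / self.dt_s)) + 1

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_s


@dataclass(frozen=True)
class FlyMetadata:
    """Experimental labels for a single fly."""

    fly_id: str
    genotype: str
    sex: str
    temperature_c: float
    experiment_block: str
    cross_id: str = ""

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(
                f"unknown genotype {self.genotype!r} for fly {self.fly_id!r}; "
                f"expected one of {GENOTYPES}"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"unknown sex {self.sex!r} for fly {self.fly_id!r}; "
                f"expected one of {SEXES}"
            )
        if float(self.temperature_c) not in TEMPERATURES:
            raise ValidationError(
                f"temperature {self.temperature_c!r} for fly {self.fly_id!r} "
                f"not in {TEMPERATURES}"
            )
        object.__setattr__(self, "temperature_c", float(self.temperature_c))


@dataclass
class TrajectoryRecord:
    """One fly's 1-D track: uniform times, bounded positions, derived speeds."""

    fly_id: str
    times: np.ndarray
    positions: np.ndarray
    speeds: np.ndarray = field(default=None)  # type: ignore[assignment]
    dt_s: float = field(default=None)  # type: ignore[assignment]

    #: Relative tolerance on timestamp uniformity, as a fraction of dt.
    TIME_RTOL = 1e-9

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.shape != self.times.shape:
            raise ValidationError(
                f"fly {self.fly_id!r}: times and positions must be equal-length 1-D"
            )
        if len(self.times) < 2:
            raise ValidationError(f"fly {self.fly_id!r}: need at least 2 samples")
        steps = np.diff(self.times)
        dt = float(steps[0]) if self.dt_s is None else float(self.dt_s)
        if dt <= 0 or np.any(np.abs(steps - dt) > self.TIME_RTOL * dt):
            raise ValidationError(
                f"fly {self.fly_id!r}: timestamps not uniform with step {dt}"
            )
        self.dt_s = dt
        if self.speeds is None:
            self.speeds = derive_speeds(self.positions, dt)
        else:
            self.speeds = np.asarray(self.speeds, dtype=float)
            if self.speeds.shape != self.positions.shape:
                raise ValidationError(
                    f"fly {self.fly_id!r}: speeds length mismatch"
                )
        if np.any(self.speeds < 0):
            raise ValidationError(f"fly {self.fly_id!r}: negative speed")

    def check_bounds(self, tube_length_mm: float) -> None:
        """Reject positions outside [0, L]."""
        if np.any(self.positions < 0) or np.any(self.positions > tube_length_mm):
            bad = self.positions[
                (self.positions < 0) | (self.positions > tube_length_mm)
            ][0]
            raise ValidationError(
                f"fly {self.fly_id!r}: position {bad:g} mm outside "
                f"[0, {tube_length_mm:g}]"
            )

    def window(self, start_s: float, end_s: float) -> "TrajectoryRecord":
        """Sub-record with samples t in [start_s, end_s); speeds re-derived
        within the window (the first in-window speed is 0)."""
        mask = (self.times >= start_s) & (self.times < end_s)
        if mask.sum() < 2:
            raise ValidationError(
                f"fly {self.fly_id!r}: window [{start_s}, {end_s}) has <2 samples"
            )
        return TrajectoryRecord(
            fly_id=self.fly_id,
            times=self.times[mask],
            positions=self.positions[mask],
            dt_s=self.dt_s,
        )

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    def path_length_mm(self) -> float:
        """Total distance travelled Σ|Δx|; equals Σ speeds·dt exactly."""
        return float(np.sum(np.abs(np.diff(self.positions))))


@dataclass(frozen=True)
class SleepBout:
    """A maximal run of inactive minutes meeting the sleep-bout threshold."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValidationError("sleep bout must have end > start")

    @property
    def duration_min(self) -> float:
        return (self.end_s - self.start_s) / 60.0


@dataclass
class PhenotypeRecord:
    """The six per-fly behavioral traits.

    ``startle_duration_s`` and ``startle_magnitude_mm_s`` are aggregated
    (mean) over all scored stimuli; ``n_censored`` counts stimuli whose
    duration never returned to baseline before the cap and was recorded at
    the cap value.
    """

    fly_id: str
    sleep_min_per_hour: float
    base_speed_mm_s: float
    startle_duration_s: float
    startle_magnitude_mm_s: float
    prop_near_food: float
    prop_far_food: float
    n_stimuli: int = 0
    n_censored: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sleep_min_per_hour <= 60.0 + 1e-9):
            raise ValidationError(
                f"fly {self.fly_id!r}: sleep_min_per_hour out of [0, 60]"
            )
        if self.base_speed_mm_s < 0 or self.startle_duration_s < 0:
            raise ValidationError(f"fly {self.fly_id!r}: negative trait value")
        for name in ("prop_near_food", "prop_far_food"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"fly {self.fly_id!r}: {name} out of [0, 1]")
        if self.prop_near_food + self.prop_far_food > 1.0 + 1e-12:
            raise ValidationError(
                f"fly {self.fly_id!r}: near + far food proportions exceed 1"
            )

    def as_dict(self) -> dict:
        return {
            "fly_id": self.fly_id,
            **{t: getattr(self, t) for t in TRAITS},
            "n_stimuli": self.n_stimuli,
            "n_censored": self.n_censored,
        }


def metadata_frame(metadata: Sequence[FlyMetadata]):
    """Metadata collection as a pandas DataFrame (one row per fly)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "fly_id": m.fly_id,
                "genotype": m.genotype,
                "sex": m.sex,
                "temperature_c": m.temperature_c,
                "experiment_block": m.experiment_block,
                "cross_id": m.cross_id,
            }
            for m in metadata
        ]
    )
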