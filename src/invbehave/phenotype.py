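"""Per-fly behavioral traits from a position track.

Six traits are scored per fly, following standard Drosophila activity-monitor
conventions:

* **sleep_min_per_hour** — minutes per hour spent in sleep bouts, a sleep
  bout being at least five consecutive inactive minutes.  "Inactive" is
  operationalized as per-minute displacement <= ``epsilon_mm`` (default
  1 mm), on minute bins.  Scored over the full pre-stimulus period.
* **base_speed_mm_s** — mean speed over the hour before the first stimulus.
* **startle_duration_s** — time from a stimulus until the 10-s rolling mean
  speed first returns to (<=) the fly's baseline speed; right-censored at
  the next stimulus (or recording end) and retained at the cap.  Averaged
  over stimuli.
* **startle_magnitude_mm_s** — mean speed in the minute after a stimulus
  minus baseline speed.  Averaged over stimuli.
* **prop_near_food / prop_far_food** — fraction of samples spent in the
  food-adjacent / food-distal region when the tube is divided into eight
  equal-length zones (half-open bins, x = L falls in the last zone).
  Scored over the pre-stimulus baseline hour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    AssayDesign,
    PhenotypeRecord,
    SleepBout,
    TrajectoryRecord,
    ValidationError,
)


@dataclass(frozen=True)
class PhenotypeOptions:
    """Tunable scoring conventions (defaults documented in the module
    docstring)."""

    epsilon_mm: float = 1.0
    min_bout_min: int = 5
    smooth_window_s: float = 10.0
    n_zones: int = 8
    #: "baseline_hour" scores occupancy over the hour before the first
    #: stimulus; "full" uses the whole recording.
    occupancy_window: str = "baseline_hour"


def binarize_activity(
    traj: TrajectoryRecord, epsilon_mm: float = 1.0
) -> np.ndarray:
    """Per-minute activity flags: minute m is active iff the total
    displacement of steps falling in minute m exceeds ``epsilon_mm``.

    Minutes are counted from the first sample; a step (the displacement
    between consecutive samples) belongs to the minute containing its later
    sample, matching the speed alignment convention.  A partial trailing
    minute is dropped.
    """
    if epsilon_mm < 0:
        raise ValidationError("epsilon_mm must be >= 0")
    rel = traj.times - traj.times[0]
    if rel[-1] < 60.0:
        raise ValidationError(f"fly {traj.fly_id!r}: recording shorter than 1 min")
    n_minutes = int(np.floor(rel[-1] / 60.0 + 1e-9))
    steps = np.abs(np.diff(traj.positions))
    # minute of the later sample; t exactly on a boundary closes the minute
    minute = np.ceil(rel[1:] / 60.0 - 1e-9).astype(int) - 1
    keep = (minute >= 0) & (minute < n_minutes)
    disp = np.zeros(n_minutes)
    np.add.at(disp, minute[keep], steps[keep])
    return disp > epsilon_mm


def detect_sleep_bouts(
    active_flags: np.ndarray, min_bout_min: int = 5, start_s: float = 0.0
) -> list[SleepBout]:
    """Maximal runs of >= ``min_bout_min`` consecutive inactive minutes.

    The threshold is inclusive: a run of exactly ``min_bout_min`` inactive
    minutes is a bout.  Bout times are seconds relative to the start of the
    flag vector (offset by ``start_s``).
    """
    if min_bout_min < 1:
        raise ValidationError("min_bout_min must be >= 1")
    flags = np.asarray(active_flags, dtype=bool)
    bouts: list[SleepBout] = []
    run_start = None
    for i, active in enumerate(list(flags) + [True]):  # sentinel closes a run
        if not active:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start >= min_bout_min:
                bouts.append(
                    SleepBout(start_s=start_s + 60.0 * run_start, end_s=start_s + 60.0 * i)
                )
            run_start = None
    return bouts


def sleep_minutes_per_hour(
    bouts: Sequence[SleepBout], window_duration_s: float
) -> float:
    """Total sleep-bout minutes per hour of scoring window."""
    if window_duration_s <= 0:
        raise ValidationError("window_duration_s must be positive")
    total_min = 0.0
    for b in bouts:
        if b.start_s < -1e-9 or b.end_s > window_duration_s + 1e-9:
            raise ValidationError(
                f"sleep bout [{b.start_s}, {b.end_s}] outside scoring window"
            )
        total_min += b.duration_min
    return total_min / (window_duration_s / 3600.0)


def baseline_speed(traj: TrajectoryRecord, first_stimulus_s: float) -> float:
    """Mean derived speed over the hour before the first stimulus."""
    if first_stimulus_s < 3600.0:
        raise ValidationError("first stimulus must be >= 3600 s")
    start = first_stimulus_s - 3600.0
    if traj.times[0] > start + 1e-9 or traj.times[-1] < first_stimulus_s - traj.dt_s - 1e-9:
        raise ValidationError(
            f"fly {traj.fly_id!r}: recording does not span the baseline hour"
        )
    mask = (traj.times >= start) & (traj.times < first_stimulus_s)
    if not mask.any():
        raise ValidationError(f"fly {traj.fly_id!r}: no samples in baseline hour")
    return float(np.mean(traj.speeds[mask]))


def _rolling_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Trailing rolling mean over ``window`` samples (shorter at the start)."""
    c = np.concatenate(([0.0], np.cumsum(values)))
    n = len(values)
    idx = np.arange(n) + 1
    lo = np.maximum(idx - window, 0)
    return (c[idx] - c[lo]) / (idx - lo)


def startle_duration(
    traj: TrajectoryRecord,
    stim_s: float,
    baseline: float,
    smooth_window_s: float = 10.0,
    cap_s: float | None = None,
) -> tuple[float, bool]:
    """Time for the smoothed speed to return to baseline after a stimulus.

    The speed trace is smoothed with a trailing rolling mean of width
    ``smooth_window_s`` and evaluated at samples strictly after ``stim_s``.
    Duration is the elapsed time to the first sample at or below
    ``baseline`` (0 if the first post-stimulus sample already is).  If no
    return occurs within ``cap_s`` the duration is the cap and the censored
    flag is set.
    """
    if baseline < 0:
        raise ValidationError("baseline speed must be >= 0")
    if not (traj.times[0] <= stim_s <= traj.times[-1]):
        raise ValidationError(f"stimulus at {stim_s} s outside recording")
    if cap_s is None:
        cap_s = float(traj.times[-1] - stim_s)
    if cap_s <= 0:
        raise ValidationError("cap_s must be positive")
    window = max(int(round(smooth_window_s / traj.dt_s)), 1)
    post = np.flatnonzero(traj.times > stim_s + 1e-9)
    if len(post) == 0:
        raise ValidationError("no samples after stimulus")
    # smooth over post-stimulus samples only, so the pre-stimulus trace
    # (e.g. a sleeping fly) cannot leak into the early windows
    smoothed = _rolling_mean(traj.speeds[post], window)
    if smoothed[0] <= baseline:
        return 0.0, False
    elapsed = traj.times[post] - stim_s
    for k in range(len(post)):
        if elapsed[k] > cap_s + 1e-9:
            break
        if smoothed[k] <= baseline:
            return float(elapsed[k]), False
    return float(cap_s), True


def startle_magnitude(
    traj: TrajectoryRecord, stim_s: float, baseline: float
) -> float:
    """Mean speed over [stim, stim + 60 s) minus the baseline speed."""
    if baseline < 0:
        raise ValidationError("baseline speed must be >= 0")
    if traj.times[-1] + traj.dt_s < stim_s + 60.0 - 1e-9:
        raise ValidationError(
            f"fly {traj.fly_id!r}: <60 s of recording after stimulus at {stim_s}"
        )
    mask = (traj.times >= stim_s) & (traj.times < stim_s + 60.0)
    return float(np.mean(traj.speeds[mask]) - baseline)


def aggregate_startle(values: Sequence[float]) -> float:
    """One value per fly: the mean across stimuli (censored durations enter
    at their cap value)."""
    if len(values) == 0:
        raise ValidationError("no per-stimulus values to aggregate")
    return float(np.mean(values))


def zone_occupancy(
    positions: np.ndarray, tube_length_mm: float, n_zones: int = 8
) -> np.ndarray:
    """Proportion of samples per zone; zone i is [i*L/n, (i+1)*L/n) and
    x = L falls in the last zone.  Count-based, so proportions sum to 1 up
    to a final floating-point division."""
    if tube_length_mm <= 0:
        raise ValidationError("tube_length_mm must be positive")
    if n_zones < 2:
        raise ValidationError("n_zones must be >= 2")
    x = np.asarray(positions, dtype=float)
    if np.any(x < 0) or np.any(x > tube_length_mm):
        raise ValidationError("positions outside [0, L]")
    zones = np.minimum(
        (n_zones * x / tube_length_mm).astype(int), n_zones - 1
    )
    counts = np.bincount(zones, minlength=n_zones)
    return counts / counts.sum()


def arcsin_sqrt(p):
    """Variance-stabilizing transform for proportions: asin(sqrt(p))."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def phenotype_fly(
    traj: TrajectoryRecord,
    design: AssayDesign,
    options: PhenotypeOptions = PhenotypeOptions(),
) -> PhenotypeRecord:
    """Score all six traits for one fly."""
    traj.check_bounds(design.tube_length_mm)
    first_stim = design.stimulus_times_s[0]
    base = baseline_speed(traj, first_stim)

    # sleep over the full pre-stimulus period, normalized by scored minutes
    pre = traj.window(traj.times[0], first_stim)
    flags = binarize_activity(pre, options.epsilon_mm)
    bouts = detect_sleep_bouts(flags, options.min_bout_min)
    sleep = sleep_minutes_per_hour(bouts, 60.0 * len(flags))

    # startle, aggregated over stimuli
    durations, magnitudes = [], []
    n_censored = 0
    stims = design.stimulus_times_s
    for k, ts in enumerate(stims):
        cap_end = stims[k + 1] if k + 1 < len(stims) else traj.times[-1]
        dur, censored = startle_duration(
            traj, ts, base, options.smooth_window_s, cap_s=cap_end - ts
        )
        durations.append(dur)
        n_censored += int(censored)
        if traj.times[-1] + traj.dt_s >= ts + 60.0 - 1e-9:
            magnitudes.append(startle_magnitude(traj, ts, base))

    # occupancy over the baseline hour (or the full recording)
    if options.occupancy_window == "baseline_hour":
        occ_traj = traj.window(first_stim - 3600.0, first_stim)
    elif options.occupancy_window == "full":
        occ_traj = traj
    else:
        raise ValidationError(
            f"unknown occupancy_window {options.occupancy_window!r}"
        )
    props = zone_occupancy(
        occ_traj.positions, design.tube_length_mm, options.n_zones
    )

    return PhenotypeRecord(
        fly_id=traj.fly_id,
        sleep_min_per_hour=min(sleep, 60.0),
        base_speed_mm_s=base,
        startle_duration_s=aggregate_startle(durations),
        startle_magnitude_mm_s=aggregate_startle(magnitudes),
        prop_near_food=float(props[0]),
        prop_far_food=float(props[-1]),
        n_stimuli=len(stims),
        n_censored=n_censored,
    )


def phenotype_cohort(
    trajectories: Sequence[TrajectoryRecord],
    design: AssayDesign,
    options: PhenotypeOptions = PhenotypeOptions(),
) -> list[PhenotypeRecord]:
    return [phenotype_fly(t, design, options) for t in trajectories]
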