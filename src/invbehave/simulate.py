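"""Synthetic tube-assay cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, not fly biomechanics:

* **Sleep/wake** is an alternating renewal process with exponential sojourn
  times (means ``mu_wake_s``, ``mu_sleep_s``); asleep flies do not move, so
  the long-run fraction of time asleep is mu_S / (mu_S + mu_W).
* **Movement while awake** is a bounded walk: an Ornstein-Uhlenbeck proposal
  ``kappa*(pstar - x)*dt + sigma_x*sqrt(dt)*N(0,1)`` supplies the *direction*
  of each step, and the step *magnitude* is the wake-speed draw times dt, so
  the derived speed trace reproduces the configured log-normal speed
  distribution exactly.  Steps that would leave the tube are flipped back
  inside, which preserves the step magnitude.  A zero proposal (kappa = 0 and
  sigma_x = 0) means no movement.
* **Startle**: each stimulus wakes the fly and adds a speed excursion
  ``A*exp(-(t - t_stim)/tau)`` until it decays below one step-noise unit
  (sigma_x).  Per step the excursion contributes its exact integral, so the
  mean speed excess over the first post-stimulus minute has the closed form
  ``A*tau*(1 - exp(-60/tau))/60``.
* **Design effects**: genotype, sex and temperature shift the generating
  parameters; each experimental block adds Gaussian random-intercept shifts.

Randomness uses numpy's PCG64 via ``default_rng``.  A master seed is split
into independent substreams with ``SeedSequence(entropy=(seed, stream,
index))`` where ``index`` is a deterministic counter over design cells
(block, temperature, sex, genotype, replicate), so enlarging a cohort never
reshuffles previously generated flies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    GENOTYPES,
    SEXES,
    TEMPERATURES,
    TRAITS,
    AssayDesign,
    FlyMetadata,
    TrajectoryRecord,
    ValidationError,
)

_BLOCK_STREAM = 1
_FLY_STREAM = 2
_TABLE_STREAM = 3
_MAX_PER_CELL = 100_000

#: Number of distinct F1 cross identities per genotype class, mirroring the
#: 8 inverted / 16 heterozygous / 6 standard crosses of the assayed panel.
_N_CROSSES = {"INV": 8, "HET": 16, "STD": 6}


@dataclass(frozen=True)
class CellParams:
    """Generating parameters for one fly after all design effects."""

    mu_wake_s: float
    mu_sleep_s: float
    log_speed_mu: float
    log_speed_sigma: float
    kappa_per_s: float
    sigma_x_mm: float
    pstar_mm: float
    startle_A_mm_s: float
    startle_tau_s: float

    def validate(self, tube_length_mm: float) -> None:
        if self.mu_wake_s <= 0 or self.mu_sleep_s <= 0:
            raise ValidationError("mean bout durations must be positive")
        if self.startle_A_mm_s > 0 and self.startle_tau_s <= 0:
            raise ValidationError("startle tau must be positive when A > 0")
        if not (0.0 <= self.pstar_mm <= tube_length_mm):
            raise ValidationError("preferred position outside the tube")
        if self.sigma_x_mm < 0 or self.kappa_per_s < 0 or self.log_speed_sigma < 0:
            raise ValidationError("rates and SDs must be non-negative")


@dataclass(frozen=True)
class BlockShifts:
    """Additive random-intercept shifts one block applies to the
    trait-generating parameters."""

    sleep_s: float = 0.0
    wake_s: float = 0.0
    logspeed: float = 0.0
    startle_A: float = 0.0
    pstar_mm: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative configuration for a trajectory cohort.

    Baseline parameters describe a standard-homozygous female at 25 deg C;
    genotype/sex effects and per-degree temperature slopes (centred at
    25 deg C) shift them.  Defaults give a cohort of the scale and effect
    directions of the assay being emulated: inverted homozygotes sleep less
    (shorter sleep bouts, longer wake bouts), prefer positions away from the
    food end, and all flies sleep less / move faster / startle harder when
    warm.
    """

    seed: int = 0
    n_per_cell: int = 34
    genotypes: tuple[str, ...] = GENOTYPES
    sexes: tuple[str, ...] = SEXES
    temperatures_c: tuple[float, ...] = TEMPERATURES
    blocks: tuple[str, ...] = ("1", "2", "3")

    # assay geometry and schedule
    tube_length_mm: float = 65.0
    dt_s: float = 1.0
    stimulus_times_s: tuple[float, ...] = (3600.0, 5400.0, 7200.0, 9000.0)
    recording_duration_s: float = 10800.0

    # baseline state/movement/startle parameters (STD female, 25 C)
    mu_wake_s: float = 1200.0
    mu_sleep_s: float = 1800.0
    min_sleep_bout_s: float = 0.0
    log_speed_mu: float = math.log(1.2)
    log_speed_sigma: float = 0.15
    kappa_per_s: float = 0.02
    sigma_x_mm: float = 1.0
    startle_A_mm_s: float = 3.0
    startle_tau_s: float = 15.0

    # genotype effects: inverted flies have a *smaller sleep fraction* but
    # *longer individual bouts* of both kinds — the longer wake bouts are
    # what keeps them moving after a startle (longer response durations)
    d_mu_sleep_s: dict = field(
        default_factory=lambda: {"STD": 0.0, "HET": 150.0, "INV": 300.0}
    )
    d_mu_wake_s: dict = field(
        default_factory=lambda: {"STD": 0.0, "HET": 450.0, "INV": 900.0}
    )
    #: Genotype offsets on log wake speed, chosen to cancel the genotype
    #: difference in wake fraction so mean (baseline) speed is genotype-null,
    #: as observed in the assay being emulated.
    d_log_speed: dict = field(
        default_factory=lambda: {"STD": 0.0, "HET": -0.136, "INV": -0.223}
    )
    pstar_mm: dict = field(
        default_factory=lambda: {"STD": 15.0, "HET": 30.0, "INV": 45.0}
    )

    # sex effects (applied to males); the log-speed offset again cancels the
    # wake-fraction difference so baseline speed is sex-null
    d_mu_sleep_male_s: float = 300.0
    d_log_speed_male: float = 0.095
    d_startle_A_male: float = 0.5

    # temperature slopes per deg C, centred at 25 C
    temp_slope_mu_sleep_s: float = -60.0
    temp_slope_mu_wake_s: float = 60.0
    temp_slope_log_speed: float = 0.03
    temp_slope_startle_A: float = 0.06
    temp_slope_startle_tau: float = -0.4

    # block random-intercept SDs
    sigma_b_sleep_s: float = 120.0
    sigma_b_logspeed: float = 0.05
    sigma_b_startle_A: float = 0.1
    sigma_b_pstar_mm: float = 1.0

    def design(self) -> AssayDesign:
        return AssayDesign(
            tube_length_mm=self.tube_length_mm,
            dt_s=self.dt_s,
            stimulus_times_s=self.stimulus_times_s,
            recording_duration_s=self.recording_duration_s,
        )

    def block_shifts(self, block: str) -> BlockShifts:
        """Deterministic random-intercept shifts for one block."""
        bi = self.blocks.index(block)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(self.seed, _BLOCK_STREAM, bi))
        )
        return BlockShifts(
            sleep_s=rng.normal(0.0, self.sigma_b_sleep_s),
            wake_s=0.0,
            logspeed=rng.normal(0.0, self.sigma_b_logspeed),
            startle_A=rng.normal(0.0, self.sigma_b_startle_A),
            pstar_mm=rng.normal(0.0, self.sigma_b_pstar_mm),
        )

    def cell_params(self, md: FlyMetadata) -> CellParams:
        """Generating parameters for one fly's design cell (block shifts
        included)."""
        shifts = (
            self.block_shifts(md.experiment_block)
            if md.experiment_block in self.blocks
            else BlockShifts()
        )
        dtemp = md.temperature_c - 25.0
        male = md.sex == "M"
        mu_sleep = (
            self.mu_sleep_s
            + self.d_mu_sleep_s[md.genotype]
            + (self.d_mu_sleep_male_s if male else 0.0)
            + self.temp_slope_mu_sleep_s * dtemp
            + shifts.sleep_s
        )
        mu_wake = (
            self.mu_wake_s
            + self.d_mu_wake_s[md.genotype]
            + self.temp_slope_mu_wake_s * dtemp
            + shifts.wake_s
        )
        pstar = float(
            np.clip(
                self.pstar_mm[md.genotype] + shifts.pstar_mm,
                0.0,
                self.tube_length_mm,
            )
        )
        params = CellParams(
            mu_wake_s=mu_wake,
            mu_sleep_s=mu_sleep,
            log_speed_mu=self.log_speed_mu
            + self.d_log_speed[md.genotype]
            + (self.d_log_speed_male if male else 0.0)
            + self.temp_slope_log_speed * dtemp
            + shifts.logspeed,
            log_speed_sigma=self.log_speed_sigma,
            kappa_per_s=self.kappa_per_s,
            sigma_x_mm=self.sigma_x_mm,
            pstar_mm=pstar,
            startle_A_mm_s=max(
                0.0,
                self.startle_A_mm_s
                + (self.d_startle_A_male if male else 0.0)
                + self.temp_slope_startle_A * dtemp
                + shifts.startle_A,
            ),
            startle_tau_s=self.startle_tau_s + self.temp_slope_startle_tau * dtemp,
        )
        params.validate(self.tube_length_mm)
        return params

    def fly_rng(self, stream_index: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=(self.seed, _FLY_STREAM, stream_index))
        )


def _position_kernel_impl(step_mm, drift_z, x0, kappa, pstar, sigma_x, dt, L):
    """Sequential position update; step_mm[i] is the magnitude of step i."""
    n = step_mm.shape[0]
    x = np.empty(n)
    x[0] = x0
    sdt = math.sqrt(dt)
    for i in range(1, n):
        xi = x[i - 1]
        m = step_mm[i]
        if m == 0.0:
            x[i] = xi
            continue
        drift = kappa * (pstar - xi) * dt + sigma_x * sdt * drift_z[i]
        if drift == 0.0:
            x[i] = xi
            continue
        step = m if drift > 0.0 else -m
        xn = xi + step
        if xn < 0.0 or xn > L:
            xn = xi - step
            if xn < 0.0:
                xn = 0.0
            elif xn > L:
                xn = L
        x[i] = xn
    return x


position_kernel_py = _position_kernel_impl

try:  # pragma: no cover - exercised via equality test
    from numba import njit

    position_kernel = njit(cache=False)(_position_kernel_impl)
except Exception:  # pragma: no cover
    position_kernel = _position_kernel_impl


def _renewal_states(
    rng: np.random.Generator,
    n_samples: int,
    dt: float,
    mu_wake: float,
    mu_sleep: float,
    min_sleep: float,
    reset_times: Sequence[float] = (),
) -> np.ndarray:
    """Boolean awake flag per sample from the alternating renewal process.

    The initial state is drawn from the stationary distribution (the fly
    acclimated overnight), so the asleep fraction is mu_S/(mu_S + mu_W) from
    t = 0 (exponential sojourns are memoryless, so no residual-life
    correction is needed).  Sample i is awake iff the process is in the wake
    state at time i*dt.  At each ``reset_time`` (a stimulus) the current
    bout is truncated and a fresh wake bout begins: mechanical arousal
    restarts wake maintenance.
    """
    awake = np.empty(n_samples, dtype=np.bool_)
    resets = sorted(float(t) for t in reset_times)
    ri = 0
    t = 0.0
    i = 0
    state_awake = bool(rng.random() < mu_wake / (mu_wake + mu_sleep))
    while i < n_samples:
        if state_awake:
            dur = rng.exponential(mu_wake)
        else:
            dur = min_sleep + rng.exponential(max(mu_sleep - min_sleep, 1e-12))
        end = t + dur
        if ri < len(resets) and end >= resets[ri] > t:
            # stimulus interrupts this bout; fresh wake bout from the stimulus
            end = resets[ri]
            j = min(n_samples, int(math.ceil(end / dt - 1e-12)))
            awake[i:j] = state_awake
            i, t = j, end
            state_awake = True
            ri += 1
            continue
        j = min(n_samples, int(math.ceil(end / dt - 1e-12)))
        awake[i:j] = state_awake
        i, t = j, end
        state_awake = not state_awake
    return awake


def _startle_excess(design: AssayDesign, params: CellParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample startle speed excess (exact step integrals of
    A*exp(-u/tau)) and a forced-awake mask covering each excursion."""
    n = design.n_samples
    dt = design.dt_s
    times = design.times_s
    excess = np.zeros(n)
    forced = np.zeros(n, dtype=bool)
    A, tau = params.startle_A_mm_s, params.startle_tau_s
    if A <= 0:
        return excess, forced
    floor = params.sigma_x_mm if params.sigma_x_mm > 0 else 0.01 * A
    t_exc = tau * math.log(A / floor) if A > floor else 0.0
    for ts in design.stimulus_times_s:
        if t_exc <= 0:
            continue
        # steps (i-1 -> i) whose interval intersects [ts, ts + t_exc)
        i0 = int(np.searchsorted(times, ts, side="left")) + 1
        i1 = int(np.searchsorted(times, ts + t_exc, side="left")) + 1
        i1 = min(i1, n)
        for i in range(i0, i1):
            a = times[i - 1] - ts
            b = times[i] - ts
            excess[i] += A * tau * (math.exp(-a / tau) - math.exp(-b / tau)) / dt
        forced[max(i0 - 1, 0) : i1] = True
    return excess, forced


def simulate_fly_trajectory(
    config: SimulationConfig,
    metadata: FlyMetadata,
    rng: np.random.Generator,
) -> TrajectoryRecord:
    """Simulate one fly's position track under its design-cell parameters."""
    params = config.cell_params(metadata)
    design = config.design()
    n = design.n_samples
    dt = design.dt_s
    awake = _renewal_states(
        rng, n, dt, params.mu_wake_s, params.mu_sleep_s,
        config.min_sleep_bout_s, design.stimulus_times_s,
    )
    excess, forced = _startle_excess(design, params)
    awake = awake | forced
    wake_speed = rng.lognormal(params.log_speed_mu, params.log_speed_sigma, n)
    speeds = np.where(awake, wake_speed, 0.0) + excess
    x0 = rng.uniform(0.0, config.tube_length_mm)
    z = rng.standard_normal(n)
    positions = position_kernel(
        speeds * dt,
        z,
        x0,
        params.kappa_per_s,
        params.pstar_mm,
        params.sigma_x_mm,
        dt,
        config.tube_length_mm,
    )
    return TrajectoryRecord(
        fly_id=metadata.fly_id,
        times=design.times_s,
        positions=positions,
        dt_s=dt,
    )


def expected_sleep_fraction(config: SimulationConfig, md: FlyMetadata) -> float:
    """Long-run asleep fraction mu_S / (mu_S + mu_W) for a fly's cell."""
    p = config.cell_params(md)
    return p.mu_sleep_s / (p.mu_sleep_s + p.mu_wake_s)


def expected_startle_magnitude(config: SimulationConfig, md: FlyMetadata) -> float:
    """Closed-form mean speed excess over the post-stimulus minute:
    A*tau*(1 - exp(-60/tau))/60."""
    p = config.cell_params(md)
    A, tau = p.startle_A_mm_s, p.startle_tau_s
    if A <= 0:
        return 0.0
    return A * tau * (1.0 - math.exp(-60.0 / tau)) / 60.0


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[TrajectoryRecord], list[FlyMetadata], dict]:
    """Full-factorial cohort of trajectories plus realized ground truth.

    Returns (trajectories, metadata, truth) where ``truth`` records the
    block shifts actually drawn and the analytic per-cell expectations used
    by recovery tests.
    """
    if config.n_per_cell <= 0:
        raise ValidationError("n_per_cell must be positive")
    if config.n_per_cell > _MAX_PER_CELL:
        raise ValidationError(f"n_per_cell exceeds stream limit {_MAX_PER_CELL}")
    if not (config.genotypes and config.sexes and config.temperatures_c and config.blocks):
        raise ValidationError("every design factor needs at least one level")
    trajectories: list[TrajectoryRecord] = []
    metadata: list[FlyMetadata] = []
    cell_truth = []
    fly_counter = 0
    nT, nS, nG = len(config.temperatures_c), len(config.sexes), len(config.genotypes)
    for bi, block in enumerate(config.blocks):
        for ti, temp in enumerate(config.temperatures_c):
            for si, sex in enumerate(config.sexes):
                for gi, geno in enumerate(config.genotypes):
                    cell_index = ((bi * nT + ti) * nS + si) * nG + gi
                    for j in range(config.n_per_cell):
                        md = FlyMetadata(
                            fly_id=f"fly{fly_counter:06d}",
                            genotype=geno,
                            sex=sex,
                            temperature_c=temp,
                            experiment_block=block,
                            cross_id=f"{geno}-cross{j % _N_CROSSES.get(geno, 4) + 1}",
                        )
                        rng = config.fly_rng(cell_index * _MAX_PER_CELL + j)
                        trajectories.append(
                            simulate_fly_trajectory(config, md, rng)
                        )
                        metadata.append(md)
                        fly_counter += 1
                    cell_truth.append(
                        {
                            "genotype": geno,
                            "sex": sex,
                            "temperature_c": temp,
                            "experiment_block": block,
                            "expected_sleep_min_per_hour": 60.0
                            * expected_sleep_fraction(config, md),
                            "expected_startle_magnitude_mm_s": expected_startle_magnitude(
                                config, md
                            ),
                            "pstar_mm": config.cell_params(md).pstar_mm,
                        }
                    )
    truth = {
        "seed": config.seed,
        "n_per_cell": config.n_per_cell,
        "block_shifts": {
            b: vars(config.block_shifts(b)) for b in config.blocks
        },
        "cells": cell_truth,
    }
    return trajectories, metadata, truth


# ---------------------------------------------------------------------------
# Trait-table shortcut: draw the six traits directly from the linear model
# the inference ladder assumes, bypassing trajectory simulation.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitEffects:
    """Linear-model generative parameters for one trait.

    ``beta_cov`` is the male effect when the covariate is sex, or the slope
    per deg C (centred at 25 C) when the covariate is temperature.
    """

    intercept: float
    beta_het: float = 0.0
    beta_inv: float = 0.0
    beta_cov: float = 0.0
    beta_het_cov: float = 0.0
    beta_inv_cov: float = 0.0
    sigma_block: float = 0.0
    sigma_resid: float = 1.0
    clamp01: bool = False

    def __post_init__(self) -> None:
        if self.sigma_resid < 0 or self.sigma_block < 0:
            raise ValidationError("sigma_resid and sigma_block must be >= 0")


def default_trait_effects(covariate: str = "sex") -> dict[str, TraitEffects]:
    """Study-condition effect sizes for the six traits.

    Directions follow the emulated assay: inverted flies sleep less and
    occupy the far-from-food end more; males sleep slightly more and startle
    harder; warmth reduces sleep, raises speed and startle magnitude and
    shortens startle duration.
    """
    if covariate == "sex":
        cov = {
            "sleep_min_per_hour": 3.0,
            "base_speed_mm_s": 0.0,
            "startle_duration_s": 0.0,
            "startle_magnitude_mm_s": 0.3,
            "prop_near_food": 0.0,
            "prop_far_food": -0.01,
        }
    elif covariate == "temperature":
        cov = {
            "sleep_min_per_hour": -1.2,
            "base_speed_mm_s": 0.04,
            "startle_duration_s": -10.0,
            "startle_magnitude_mm_s": 0.05,
            "prop_near_food": -0.004,
            "prop_far_food": 0.0,
        }
    else:
        raise ValidationError(f"unknown covariate {covariate!r}")
    return {
        "sleep_min_per_hour": TraitEffects(
            intercept=35.0, beta_het=-3.0, beta_inv=-6.0,
            beta_cov=cov["sleep_min_per_hour"], sigma_block=2.0, sigma_resid=12.0,
        ),
        "base_speed_mm_s": TraitEffects(
            intercept=1.2, beta_cov=cov["base_speed_mm_s"],
            sigma_block=0.08, sigma_resid=0.5,
        ),
        "startle_duration_s": TraitEffects(
            intercept=300.0, beta_het=30.0, beta_inv=60.0,
            beta_cov=cov["startle_duration_s"], sigma_block=20.0, sigma_resid=250.0,
        ),
        "startle_magnitude_mm_s": TraitEffects(
            intercept=2.0, beta_cov=cov["startle_magnitude_mm_s"],
            sigma_block=0.2, sigma_resid=1.2,
        ),
        "prop_near_food": TraitEffects(
            intercept=0.18, beta_het=-0.025, beta_inv=-0.05,
            beta_cov=cov["prop_near_food"], sigma_block=0.01, sigma_resid=0.10,
            clamp01=True,
        ),
        "prop_far_food": TraitEffects(
            intercept=0.05, beta_het=0.02, beta_inv=0.04,
            beta_cov=cov["prop_far_food"], sigma_block=0.01, sigma_resid=0.10,
            clamp01=True,
        ),
    }


@dataclass(frozen=True)
class TraitTableConfig:
    """Configuration for :func:`simulate_phenotype_table`."""

    seed: int = 0
    n_per_cell: int = 34
    covariate: str = "sex"  # "sex" -> both sexes at 25 C; "temperature" -> females
    genotypes: tuple[str, ...] = GENOTYPES
    blocks: tuple[str, ...] = ("1", "2", "3")
    traits: dict = field(default_factory=default_trait_effects)

    def covariate_levels(self) -> tuple:
        return SEXES if self.covariate == "sex" else TEMPERATURES


def simulate_phenotype_table(
    config: TraitTableConfig,
) -> tuple[pd.DataFrame, dict]:
    """Draw per-fly trait values directly from the mixed linear model.

    trait = intercept + genotype contrast + covariate effect + interaction
    + block intercept + N(0, sigma_resid^2); proportion-type traits are
    clamped to [0, 1].  Returns the table (traits joined to metadata
    columns) and the true parameters per trait.
    """
    if config.n_per_cell <= 0:
        raise ValidationError("n_per_cell must be positive")
    if config.covariate not in ("sex", "temperature"):
        raise ValidationError(f"unknown covariate {config.covariate!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(config.seed, _TABLE_STREAM))
    )
    traits = dict(config.traits)
    block_shift = {
        t: {b: rng.normal(0.0, eff.sigma_block) for b in config.blocks}
        for t, eff in traits.items()
    }
    levels = config.covariate_levels()
    rows = []
    counter = 0
    for block in config.blocks:
        for lev in levels:
            for geno in config.genotypes:
                gvec = {"STD": (0, 0), "HET": (1, 0), "INV": (0, 1)}[geno]
                if config.covariate == "sex":
                    x = 1.0 if lev == "M" else 0.0
                    sex, temp = lev, 25.0
                else:
                    x = float(lev) - 25.0
                    sex, temp = "F", float(lev)
                for _ in range(config.n_per_cell):
                    row = {
                        "fly_id": f"fly{counter:06d}",
                        "genotype": geno,
                        "sex": sex,
                        "temperature_c": temp,
                        "experiment_block": block,
                    }
                    for t, eff in traits.items():
                        mu = (
                            eff.intercept
                            + gvec[0] * eff.beta_het
                            + gvec[1] * eff.beta_inv
                            + x * eff.beta_cov
                            + x * gvec[0] * eff.beta_het_cov
                            + x * gvec[1] * eff.beta_inv_cov
                            + block_shift[t][block]
                        )
                        val = mu + rng.normal(0.0, eff.sigma_resid)
                        if eff.clamp01:
                            val = float(np.clip(val, 0.0, 1.0))
                        row[t] = val
                    rows.append(row)
                    counter += 1
    truth = {
        "traits": {t: vars(eff) for t, eff in traits.items()},
        "block_shifts": block_shift,
        "covariate": config.covariate,
    }
    return pd.DataFrame(rows), truth
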