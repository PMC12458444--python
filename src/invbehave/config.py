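"""YAML configuration loading for the CLI and pipeline.

A config file has up to four sections, each optional and each overriding
dataclass defaults field-by-field::

    simulate:
      seed: 7
      n_per_cell: 10
      stimulus_times_s: [3600, 5400]
      recording_duration_s: 6000
    phenotype:
      epsilon_mm: 1.0
      min_bout_min: 5
    analyze:
      analyses: [sex, temperature]
      alpha: 0.05
      welch: true
    pipeline:
      save_trajectories: false
      make_plots: true
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .core import ValidationError
from .phenotype import PhenotypeOptions
from .pipeline import PipelineConfig
from .simulate import SimulationConfig


def _build(cls, section: dict, name: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(section) - set(fields)
    if unknown:
        raise ValidationError(f"config section {name!r}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in section.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path}: expected a mapping at top level")
    known = {"simulate", "phenotype", "analyze", "pipeline"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"config {path}: unknown sections {sorted(unknown)}")
    sim = _build(SimulationConfig, raw.get("simulate", {}) or {}, "simulate")
    phen = _build(PhenotypeOptions, raw.get("phenotype", {}) or {}, "phenotype")
    analyze = dict(raw.get("analyze", {}) or {})
    pipe = dict(raw.get("pipeline", {}) or {})
    analyses = tuple(analyze.pop("analyses", ("sex", "temperature")))
    return PipelineConfig(
        simulation=sim,
        phenotype=phen,
        analyses=analyses,
        alpha=float(analyze.pop("alpha", 0.05)),
        welch=bool(analyze.pop("welch", True)),
        save_trajectories=bool(pipe.pop("save_trajectories", False)),
        make_plots=bool(pipe.pop("make_plots", True)),
    )
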