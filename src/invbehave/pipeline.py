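"""One-command orchestration: simulate (or ingest) -> phenotype -> analyze
-> report, with a manifest that makes runs reproducible and self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import TRAIT_LABELS, TRAITS, ValidationError
from .io import (
    join_phenotypes,
    read_metadata,
    read_trajectories,
    write_metadata,
    write_phenotypes,
    write_trajectories,
)
from .models import run_analysis
from .phenotype import PhenotypeOptions, phenotype_cohort
from .simulate import SimulationConfig, simulate_cohort


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; snapshotted into the manifest."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    phenotype: PhenotypeOptions = field(default_factory=PhenotypeOptions)
    analyses: tuple[str, ...] = ("sex", "temperature")
    alpha: float = 0.05
    welch: bool = True
    save_trajectories: bool = False
    make_plots: bool = True


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_snapshot(config: PipelineConfig) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(config), default=list))


def _plot_report(report, data: pd.DataFrame, out_path: Path) -> None:
    """Genotype means with 95% CI error bars (mean +/- 1.96 SE) per trait
    and stratum, one panel per trait."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stratum_col = "sex" if report.mode == "sex" else "temperature_c"
    fig, axes = plt.subplots(2, 3, figsize=(13, 7), constrained_layout=True)
    colors = {"INV": "#c0392b", "HET": "#8e44ad", "STD": "#2471a3"}
    for ax, trait in zip(axes.ravel(), TRAITS):
        strata = sorted(data[stratum_col].unique())
        for gi, geno in enumerate(("INV", "HET", "STD")):
            means, errs, xs = [], [], []
            for si, s in enumerate(strata):
                vals = data.loc[
                    (data["genotype"] == geno) & (data[stratum_col] == s), trait
                ]
                if len(vals) == 0:
                    continue
                means.append(vals.mean())
                errs.append(1.96 * vals.std(ddof=1) / np.sqrt(len(vals)))
                xs.append(si + (gi - 1) * 0.12)
            ax.errorbar(
                xs, means, yerr=errs, fmt="o", capsize=3,
                color=colors[geno], label=geno,
            )
        ax.set_xticks(range(len(strata)))
        ax.set_xticklabels([str(s) for s in strata])
        ax.set_title(TRAIT_LABELS[trait])
        ax.set_xlabel(stratum_col)
    axes[0, 0].legend(frameon=False)
    fig.suptitle(f"{report.mode} analysis: genotype means ± 1.96 SE")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def run_end_to_end(
    config: PipelineConfig,
    out_dir,
    trajectories_csv=None,
    metadata_csv=None,
) -> Path:
    """Execute the full pipeline and write all artifacts into ``out_dir``.

    With ``trajectories_csv``/``metadata_csv`` given, those files are
    ingested instead of simulating; otherwise a synthetic cohort is drawn
    from ``config.simulation`` (and its ground truth saved).
    Returns the run directory; a manifest.json lists every output with its
    SHA-256 digest, per-stage row counts and collected warnings.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    counts: dict[str, int] = {}
    warnings_log: list[str] = []
    design = config.simulation.design()

    # --- stage: acquire trajectories -------------------------------------
    try:
        if trajectories_csv is not None:
            if metadata_csv is None:
                raise ValidationError("metadata_csv required with trajectories_csv")
            trajectories = read_trajectories(trajectories_csv, design)
            metadata = read_metadata(metadata_csv)
            truth = None
        else:
            trajectories, metadata, truth = simulate_cohort(config.simulation)
            with open(out / "truth.json", "w") as fh:
                json.dump(truth, fh, indent=1)
            outputs["truth"] = out / "truth.json"
        write_metadata(metadata, out / "metadata.csv")
        outputs["metadata"] = out / "metadata.csv"
        if config.save_trajectories:
            write_trajectories(trajectories, out / "trajectories.csv")
            outputs["trajectories"] = out / "trajectories.csv"
        counts["flies"] = len(metadata)
    except Exception as e:
        raise StageError("simulate/ingest", e) from e

    # --- stage: phenotype --------------------------------------------------
    try:
        phenotypes = phenotype_cohort(trajectories, design, config.phenotype)
        write_phenotypes(phenotypes, out / "phenotypes.csv")
        outputs["phenotypes"] = out / "phenotypes.csv"
        counts["phenotypes"] = len(phenotypes)
        n_cens = sum(p.n_censored for p in phenotypes)
        if n_cens:
            warnings_log.append(f"{n_cens} censored startle durations (kept at cap)")
        data = join_phenotypes(phenotypes, metadata)
    except Exception as e:
        raise StageError("phenotype", e) from e

    # --- stage: analyze ----------------------------------------------------
    reports = {}
    for mode in config.analyses:
        try:
            rep = run_analysis(data, mode, alpha=config.alpha, welch=config.welch)
            reports[mode] = rep
            warnings_log.extend(f"{mode}: {w}" for w in rep.warnings)
            counts[f"analysis_{mode}_flies"] = rep.n_flies
            cmp_path = out / f"model_comparison_{mode}.csv"
            rep.comparison_frame().to_csv(cmp_path, index=False)
            outputs[f"model_comparison_{mode}"] = cmp_path
            ph_path = out / f"posthoc_{mode}.csv"
            rep.posthoc_frame().to_csv(ph_path, index=False)
            outputs[f"posthoc_{mode}"] = ph_path
            if config.make_plots:
                plot_path = out / f"means_{mode}.png"
                _plot_report(rep, prepare_plot_data(data, mode), plot_path)
                outputs[f"plot_{mode}"] = plot_path
        except StageError:
            raise
        except Exception as e:
            raise StageError(f"analyze/{mode}", e) from e

    # --- stage: recovery report (simulated runs only) -----------------------
    if truth is not None:
        try:
            rec = recovery_report(truth, data)
            rec.to_csv(out / "recovery_report.csv", index=False)
            outputs["recovery_report"] = out / "recovery_report.csv"
        except Exception as e:
            raise StageError("recovery_report", e) from e

    manifest = {
        "invbehave_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.simulation.seed,
        "config": _config_snapshot(config),
        "row_counts": counts,
        "warnings": warnings_log,
        "outputs": {
            k: {"path": p.name, "sha256": _sha256(p)} for k, p in outputs.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def prepare_plot_data(data: pd.DataFrame, mode: str) -> pd.DataFrame:
    from .models import prepare_analysis_data

    return prepare_analysis_data(data, mode)


def recovery_report(truth: dict, data: pd.DataFrame) -> pd.DataFrame:
    """Observed per-cell trait means next to the generator's analytic
    expectations, for the traits with closed forms (sleep and startle
    magnitude)."""
    rows = []
    for cell in truth["cells"]:
        sel = (
            (data["genotype"] == cell["genotype"])
            & (data["sex"] == cell["sex"])
            & (data["temperature_c"] == cell["temperature_c"])
            & (data["experiment_block"] == cell["experiment_block"])
        )
        obs = data[sel]
        if len(obs) == 0:
            continue
        rows.append(
            {
                **{
                    k: cell[k]
                    for k in ("genotype", "sex", "temperature_c", "experiment_block")
                },
                "n": len(obs),
                "expected_sleep_min_per_hour": cell["expected_sleep_min_per_hour"],
                "observed_sleep_min_per_hour": obs["sleep_min_per_hour"].mean(),
                "expected_startle_magnitude_mm_s": cell[
                    "expected_startle_magnitude_mm_s"
                ],
                "observed_startle_magnitude_mm_s": obs[
                    "startle_magnitude_mm_s"
                ].mean(),
            }
        )
    return pd.DataFrame(rows)
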