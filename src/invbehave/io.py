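"""Readers, writers and design validation for the CSV interchange formats.

All tables are RFC-4180 CSV with a header row, UTF-8:

* trajectories: ``fly_id,time_s,position_mm`` (long format, one row per sample)
* metadata: ``fly_id,genotype,sex,temperature_c,experiment_block,cross_id``
* phenotypes: ``fly_id`` + the six trait columns of :data:`invbehave.core.TRAITS`
  + ``n_stimuli,n_censored``, in that fixed order
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    TRAITS,
    AssayDesign,
    FlyMetadata,
    PhenotypeRecord,
    TrajectoryRecord,
    ValidationError,
    metadata_frame,
)

TRAJECTORY_COLUMNS = ("fly_id", "time_s", "position_mm")
METADATA_COLUMNS = (
    "fly_id",
    "genotype",
    "sex",
    "temperature_c",
    "experiment_block",
    "cross_id",
)
PHENOTYPE_COLUMNS = ("fly_id",) + TRAITS + ("n_stimuli", "n_censored")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing columns {missing}")


def read_trajectories(path, design: AssayDesign) -> list[TrajectoryRecord]:
    """Read a long-format trajectory table into per-fly records.

    Rows may arrive unsorted; they are ordered by time within fly.  A fly
    with non-uniform timestamps, duplicate times, or positions outside
    [0, L] is rejected with an error naming it.
    """
    df = pd.read_csv(path)
    _require_columns(df, TRAJECTORY_COLUMNS, f"trajectories {path}")
    records = []
    for fly_id, grp in df.groupby("fly_id", sort=True):
        grp = grp.sort_values("time_s")
        times = grp["time_s"].to_numpy(dtype=float)
        if len(times) > 1 and np.any(np.diff(times) == 0):
            raise ValidationError(f"fly {fly_id!r}: duplicate timestamps")
        rec = TrajectoryRecord(
            fly_id=str(fly_id),
            times=times,
            positions=grp["position_mm"].to_numpy(dtype=float),
        )
        rec.check_bounds(design.tube_length_mm)
        records.append(rec)
    return records


def write_trajectories(records: Iterable[TrajectoryRecord], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "fly_id": rec.fly_id,
                "time_s": rec.times,
                "position_mm": rec.positions,
            }
        )
        for rec in records
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(TRAJECTORY_COLUMNS))
    )
    out.to_csv(path, index=False)


def read_metadata(path) -> list[FlyMetadata]:
    df = pd.read_csv(path, dtype={"experiment_block": str, "fly_id": str})
    _require_columns(df, METADATA_COLUMNS[:-1], f"metadata {path}")
    if "cross_id" not in df.columns:
        df["cross_id"] = ""
    dup = df["fly_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"metadata {path}: duplicate fly_id {df['fly_id'][dup].iloc[0]!r}"
        )
    return [
        FlyMetadata(
            fly_id=str(r.fly_id),
            genotype=str(r.genotype),
            sex=str(r.sex),
            temperature_c=float(r.temperature_c),
            experiment_block=str(r.experiment_block),
            cross_id="" if pd.isna(r.cross_id) else str(r.cross_id),
        )
        for r in df.itertuples()
    ]


def write_metadata(metadata: Sequence[FlyMetadata], path) -> None:
    metadata_frame(metadata).to_csv(path, index=False)


def write_phenotypes(records: Sequence[PhenotypeRecord], path) -> None:
    """Write one row per fly in the documented fixed column order."""
    ids = [r.fly_id for r in records]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate fly_id {dup!r} in phenotype records")
    df = pd.DataFrame([r.as_dict() for r in records], columns=list(PHENOTYPE_COLUMNS))
    df.to_csv(path, index=False)


def read_phenotypes(path) -> list[PhenotypeRecord]:
    df = pd.read_csv(path, dtype={"fly_id": str})
    _require_columns(df, PHENOTYPE_COLUMNS[:7], f"phenotypes {path}")
    recs = []
    for r in df.itertuples():
        kwargs = {t: float(getattr(r, t)) for t in TRAITS}
        recs.append(
            PhenotypeRecord(
                fly_id=str(r.fly_id),
                n_stimuli=int(getattr(r, "n_stimuli", 0)),
                n_censored=int(getattr(r, "n_censored", 0)),
                **kwargs,
            )
        )
    return recs


def join_phenotypes(
    records: Sequence[PhenotypeRecord], metadata: Sequence[FlyMetadata]
) -> pd.DataFrame:
    """One row per fly: six traits joined to the experimental labels."""
    ph = pd.DataFrame([r.as_dict() for r in records])
    md = metadata_frame(metadata)
    merged = ph.merge(md, on="fly_id", how="inner", validate="one_to_one")
    if len(merged) != len(ph):
        missing = set(ph.fly_id) - set(md.fly_id)
        raise ValidationError(f"flies without metadata: {sorted(missing)[:5]}")
    return merged


def validate_design(metadata: Sequence[FlyMetadata]) -> pd.DataFrame:
    """Cross-tabulate fly counts per genotype x sex x temperature x block.

    Returns a table with one row per design cell (including empty ones) and
    columns ``genotype, sex, temperature_c, experiment_block, n, empty``.
    Unknown labels are rejected by :class:`FlyMetadata` at construction.
    """
    if not metadata:
        raise ValidationError("empty metadata collection")
    md = metadata_frame(metadata)
    if md["fly_id"].duplicated().any():
        raise ValidationError("duplicate fly_id in metadata")
    from .core import GENOTYPES, SEXES

    blocks = sorted(md["experiment_block"].unique())
    temps = sorted(md["temperature_c"].unique())
    grid = pd.MultiIndex.from_product(
        [GENOTYPES, SEXES, temps, blocks],
        names=["genotype", "sex", "temperature_c", "experiment_block"],
    )
    counts = (
        md.groupby(["genotype", "sex", "temperature_c", "experiment_block"])
        .size()
        .reindex(grid, fill_value=0)
        .rename("n")
        .reset_index()
    )
    counts["empty"] = counts["n"] == 0
    return counts
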