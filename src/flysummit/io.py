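"""Readers and writers for tracking tables, metadata and result records.

File dialect: comma-delimited text with a header row and '.' decimal
separator. Tracking columns: ``fly_id,frame,t_sec,x_mm,y_raw[,speed_mms]``.
Metadata columns:
``fly_id,genotype,sex,exposed,survival,outcome[,death_frame,death_source]``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    ARENA_LENGTH_MM,
    Cohort,
    DataError,
    FlyRecord,
    FormatError,
    Trajectory,
    derive_speed,
)

_TRACK_REQUIRED = ["fly_id", "frame", "t_sec", "x_mm", "y_raw"]
_META_REQUIRED = ["fly_id", "genotype", "sex", "exposed", "survival", "outcome"]


def read_tracking(
    path: str | Path,
    scale: float = 1.0,
    arena_len_mm: float = ARENA_LENGTH_MM,
    zt0: float = 19.0,
) -> Cohort:
    """Read a tracking CSV into a :class:`Cohort` with placeholder records.

    ``scale`` converts raw position units to mm (1.0 when the file is already
    metric). ``y_raw`` is normalized to ``y_rel`` by ``arena_len_mm``. Speed
    is taken from the optional ``speed_mms`` column or derived from positions.
    Metadata records default to exposed survivors; merge a metadata table with
    :func:`read_metadata` to fill them in.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRACK_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing tracking columns {missing}")
    has_speed = "speed_mms" in df.columns

    trajectories = []
    records: dict[str, FlyRecord] = {}
    for fly_id, grp in df.groupby("fly_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if len(np.unique(frames)) != len(frames):
            raise DataError(f"{fly_id}: duplicated frame index")
        t = grp["t_sec"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataError(f"{fly_id}: non-monotone t_sec")
        x = grp["x_mm"].to_numpy(dtype=float) * scale
        y_raw = grp["y_raw"].to_numpy(dtype=float) * scale
        valid = (
            grp["valid"].to_numpy(dtype=bool)
            if "valid" in grp.columns
            else ~(np.isnan(x) | np.isnan(y_raw))
        )
        traj = Trajectory(
            fly_id=str(fly_id),
            t=t,
            x=x,
            y_rel=y_raw / arena_len_mm,
            speed=(
                grp["speed_mms"].to_numpy(dtype=float)
                if has_speed
                else np.zeros(len(t))
            ),
            valid=valid,
            zt0=zt0,
            arena_len_mm=arena_len_mm,
        )
        if not has_speed:
            traj = derive_speed(traj)
        trajectories.append(traj)
        records[traj.fly_id] = FlyRecord(fly_id=traj.fly_id)
    return Cohort(trajectories, records, {"zt0": zt0, "arena_len_mm": arena_len_mm})


def read_metadata(path: str | Path, cohort: Optional[Cohort] = None) -> dict[str, FlyRecord]:
    """Read a metadata CSV; if *cohort* is given, install the records on it."""
    df = pd.read_csv(path)
    missing = [c for c in _META_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    records: dict[str, FlyRecord] = {}
    for row in df.itertuples(index=False):
        death_frame = getattr(row, "death_frame", None)
        if death_frame is not None and pd.isna(death_frame):
            death_frame = None
        records[str(row.fly_id)] = FlyRecord(
            fly_id=str(row.fly_id),
            genotype=str(row.genotype),
            sex=str(row.sex),  # type: ignore[arg-type]
            exposed=bool(row.exposed),
            survival=int(row.survival),
            outcome=int(row.outcome),
            death_frame=None if death_frame is None else int(death_frame),
            death_source=str(getattr(row, "death_source", "manual" if death_frame is not None else "none")),  # type: ignore[arg-type]
        )
    if cohort is not None:
        for fid, rec in records.items():
            if fid in cohort.records:
                cohort.records[fid] = rec
    return records


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort as ``tracking.csv`` + ``metadata.csv`` under *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for traj in cohort.trajectories:
        rows.append(
            pd.DataFrame(
                {
                    "fly_id": traj.fly_id,
                    "frame": np.arange(len(traj)),
                    "t_sec": traj.t,
                    "x_mm": traj.x,
                    "y_raw": traj.y_rel * traj.arena_len_mm,
                    "speed_mms": traj.speed,
                    "valid": traj.valid.astype(int),
                }
            )
        )
    track = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["fly_id", "frame", "t_sec", "x_mm", "y_raw", "speed_mms", "valid"]
        )
    )
    track.to_csv(out_dir / "tracking.csv", index=False)

    meta = pd.DataFrame(
        [
            {
                "fly_id": rec.fly_id,
                "genotype": rec.genotype,
                "sex": rec.sex,
                "exposed": int(rec.exposed),
                "survival": rec.survival,
                "outcome": rec.outcome,
                "death_frame": rec.death_frame,
                "death_source": rec.death_source,
            }
            for rec in cohort.records.values()
        ],
        columns=[
            "fly_id",
            "genotype",
            "sex",
            "exposed",
            "survival",
            "outcome",
            "death_frame",
            "death_source",
        ],
    ).sort_values("fly_id") if cohort.records else pd.DataFrame(
        columns=[
            "fly_id",
            "genotype",
            "sex",
            "exposed",
            "survival",
            "outcome",
            "death_frame",
            "death_source",
        ]
    )
    meta.to_csv(out_dir / "metadata.csv", index=False)
    zt0 = cohort.config.get("zt0", 19.0)
    arena = cohort.config.get("arena_len_mm", ARENA_LENGTH_MM)
    (out_dir / "config.json").write_text(
        json.dumps({"zt0": zt0, "arena_len_mm": arena}, indent=1)
    )


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    cfg = {}
    if (in_dir / "config.json").exists():
        cfg = json.loads((in_dir / "config.json").read_text())
    cohort = read_tracking(
        in_dir / "tracking.csv",
        arena_len_mm=cfg.get("arena_len_mm", ARENA_LENGTH_MM),
        zt0=cfg.get("zt0", 19.0),
    )
    read_metadata(in_dir / "metadata.csv", cohort)
    cohort.config.update(cfg)
    return cohort


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(obj, path: str | Path) -> None:
    """Write a result dataclass (or dict of scalars/arrays) as JSON."""
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1))


def read_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
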