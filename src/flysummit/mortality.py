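"""Time-of-death calling, fictive deaths, and death-aligned cohort traces.

Death is defined behaviorally as the last observed walking: the last frame
of the last bout in which speed stayed at or above a movement threshold for
a minimum cumulative duration. Slow positional drift and tracking jitter do
not count as walking. Manual annotations, when present in the metadata,
always take precedence over automated detection.

Survivor and unexposed flies never die during tracking; to compare their
behavior with zombies on a common clock they are assigned *fictive* death
times resampled from the observed zombie death times of the same genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Cohort, DataError, Trajectory

MOVE_THRESH_MMS = 0.5
MIN_BOUT_S = 2.0
END_GUARD_S = 600.0  # movement within the last 10 min => still alive


@dataclass
class DeathDetection:
    frame: Optional[int]
    reason: str  # "ok", "no_movement", "no_sustained_movement", "moving_at_end"


def detect_death(
    traj: Trajectory,
    move_thresh: float = MOVE_THRESH_MMS,
    min_bout: float = MIN_BOUT_S,
) -> DeathDetection:
    """Automated time-of-death surrogate for manual last-movement calling.

    Scans valid frames for bouts (maximal runs) of speed >= ``move_thresh``
    whose cumulative duration is at least ``min_bout`` seconds. The death
    frame is the last frame of the last such bout; if that bout reaches into
    the final 10 minutes of the recording the fly is considered still moving
    and no death is called.
    """
    v = traj.valid
    supra = (traj.speed >= move_thresh) & v
    if not np.any(supra):
        return DeathDetection(None, "no_movement")
    # maximal runs of supra-threshold frames
    padded = np.concatenate(([False], supra, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    dt = 1.0 / traj.frame_rate
    durations = (ends - starts + 1) * dt
    qualifying = durations >= min_bout
    if not np.any(qualifying):
        return DeathDetection(None, "no_sustained_movement")
    last_end = int(ends[qualifying][-1])
    if traj.t[last_end] > traj.t[-1] - END_GUARD_S:
        return DeathDetection(None, "moving_at_end")
    return DeathDetection(last_end, "ok")


def assign_fictive_death(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    """Give every survivor/unexposed fly a fictive death frame.

    Drawn with replacement from the zombie death-frame pool of the same
    genotype. Raises :class:`DataError` naming any genotype that needs an
    assignment but has no zombie deaths to resample from.
    """
    out = cohort.copy()
    pools: dict[str, list[int]] = {}
    for rec in out.records.values():
        if rec.fly_class == "zombie" and rec.death_frame is not None:
            pools.setdefault(rec.genotype, []).append(rec.death_frame)
    for rec in out.records.values():
        if rec.fly_class in ("survivor", "unexposed"):
            pool = pools.get(rec.genotype)
            if not pool:
                raise DataError(
                    f"genotype {rec.genotype!r} has no zombie death times to resample"
                )
            rec.death_frame = int(pool[rng.integers(len(pool))])
            rec.death_source = "fictive"
    return out


@dataclass
class AlignedCohort:
    """Per-class cohort means on a common death-relative time axis."""

    rel_time_h: np.ndarray
    mean_y: dict[str, np.ndarray] = field(default_factory=dict)
    mean_speed: dict[str, np.ndarray] = field(default_factory=dict)
    band_lo: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    band_hi: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    n_per_class: dict[str, int] = field(default_factory=dict)


def _aligned_matrix(
    cohort: Cohort, flies: list[Trajectory], offsets: np.ndarray, attr: str
) -> np.ndarray:
    mat = np.full((len(flies), len(offsets)), np.nan, dtype=np.float32)
    for i, traj in enumerate(flies):
        death = cohort.records[traj.fly_id].death_frame
        idx = death + offsets
        ok = (idx >= 0) & (idx < len(traj))
        vals = getattr(traj, attr)[idx[ok]].astype(np.float32)
        vals[~traj.valid[idx[ok]]] = np.nan
        mat[i, ok] = vals
    return mat


def _boot_bands(
    mat: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Mean +/- 1 SD of bootstrapped (over flies) means."""
    n = mat.shape[0]
    filled = np.nan_to_num(mat, nan=0.0)
    present = (~np.isnan(mat)).astype(np.float32)
    boot_means = np.empty((n_boot, mat.shape[1]), dtype=np.float32)
    for b in range(n_boot):
        w = np.bincount(rng.integers(0, n, n), minlength=n).astype(np.float32)
        denom = w @ present
        with np.errstate(invalid="ignore"):
            boot_means[b] = (w @ filled) / denom
    sd = np.nanstd(boot_means, axis=0)
    mean = np.nanmean(mat, axis=0)
    return mean - sd, mean + sd


def align_to_death(
    cohort: Cohort,
    window_h: float = 12.0,
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> AlignedCohort:
    """Death-aligned per-class mean y and speed traces with bootstrap bands.

    Every included fly must carry a death frame (true or fictive); flies
    whose death falls within 10 min of the end of their recording are
    excluded as right-censored. ``n_boot=0`` skips the bands.
    """
    rng = np.random.default_rng() if rng is None else rng
    frame_rate = cohort.trajectories[0].frame_rate if cohort.trajectories else 3.0
    w = int(round(window_h * 3600 * frame_rate))
    offsets = np.arange(-w, 1)
    rel_time_h = offsets / (3600 * frame_rate)
    out = AlignedCohort(rel_time_h=rel_time_h)

    by_class: dict[str, list[Trajectory]] = {}
    for traj, rec in cohort:
        if rec.fly_class == "excluded" or rec.death_frame is None:
            continue
        if traj.t[min(rec.death_frame, len(traj) - 1)] > traj.t[-1] - END_GUARD_S:
            continue
        by_class.setdefault(rec.fly_class, []).append(traj)

    for cls, flies in sorted(by_class.items()):
        out.n_per_class[cls] = len(flies)
        for attr, target in (("y_rel", out.mean_y), ("speed", out.mean_speed)):
            mat = _aligned_matrix(cohort, flies, offsets, attr)
            with np.errstate(invalid="ignore"):
                target[cls] = np.nanmean(mat, axis=0)
            if n_boot > 0:
                lo, hi = _boot_bands(mat, n_boot, rng)
                out.band_lo.setdefault(attr, {})[cls] = lo
                out.band_hi.setdefault(attr, {})[cls] = hi
    return out


def death_time_summary(cohort: Cohort) -> dict:
    """Mean ZT, central-90% interval and histogram of zombie death times.

    Fictive deaths are excluded; requires at least one zombie.
    """
    zts = []
    for traj, rec in cohort:
        if rec.fly_class == "zombie" and rec.death_frame is not None:
            zts.append(float(traj.zt(rec.death_frame)))
    if not zts:
        raise DataError("death_time_summary requires at least one zombie")
    zts_arr = np.asarray(zts)
    counts, edges = np.histogram(zts_arr, bins=np.arange(0.0, 24.5, 0.5))
    return {
        "mean_zt": float(np.mean(zts_arr)),
        "p5_zt": float(np.percentile(zts_arr, 5)),
        "p95_zt": float(np.percentile(zts_arr, 95)),
        "n": len(zts),
        "hist_counts": counts,
        "hist_edges": edges,
    }
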