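"""Automatic flagging and repair of wall-tracking artifacts.

Centroid trackers occasionally lock onto reflections along the long edges of
an arena, producing single-frame position excursions whose implied speeds are
physiologically impossible (> ~40 mm/s). A trajectory is flagged when such
violations occur at more than 20 instances per day of tracked time. Repair
narrows the accepted x-interval (the analogue of trimming the tracker's
region of interest), masks frames outside it, bridges the gaps when
re-deriving speed, and stops as soon as the flag clears; if the retained
width falls below a floor the trajectory is discarded instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import DataError, Trajectory, derive_speed

SPEED_THRESH_MMS = 40.0
MAX_VIOLATIONS_PER_DAY = 20.0
# ROI floor: nine pixels of a ~50 px arena width at the original optics,
# expressed here as a fraction of the observed x-range.
MIN_WIDTH_FRAC = 9.0 / 50.0
TRIM_STEP = 0.05  # fraction of current width removed per iteration


@dataclass
class DenoiseReport:
    fly_id: str
    violations_per_day: float
    action: Literal["clean", "flagged", "repaired", "discarded"]
    width_retained: float = 1.0


def _violation_rate(traj: Trajectory, speed_thresh: float) -> float:
    days = traj.duration_s / 86400.0
    if days <= 0:
        raise DataError(f"{traj.fly_id}: zero-duration trajectory")
    n_bad = int(np.sum(traj.speed[traj.valid] > speed_thresh))
    return n_bad / days


def flag_noisy(
    traj: Trajectory,
    speed_thresh: float = SPEED_THRESH_MMS,
    max_per_day: float = MAX_VIOLATIONS_PER_DAY,
) -> DenoiseReport:
    """Count supra-threshold frames per tracked day; flag on strict excess."""
    rate = _violation_rate(traj, speed_thresh)
    return DenoiseReport(
        fly_id=traj.fly_id,
        violations_per_day=rate,
        action="clean" if rate <= max_per_day else "flagged",
    )


def repair(
    traj: Trajectory,
    min_width_frac: float = MIN_WIDTH_FRAC,
    speed_thresh: float = SPEED_THRESH_MMS,
    max_per_day: float = MAX_VIOLATIONS_PER_DAY,
) -> tuple[Trajectory, DenoiseReport]:
    """Iteratively trim the accepted x-interval until the flag clears.

    Each iteration removes ``TRIM_STEP`` of the current width (half from each
    side), masks frames outside the interval, re-derives speed across the
    masked gaps (nearest valid frames, divided by elapsed time), and
    recounts violations. Returns the repaired (or discarded) trajectory and
    a report; a discarded trajectory keeps its data but should be excluded
    downstream.
    """
    report = flag_noisy(traj, speed_thresh, max_per_day)
    if report.action == "clean":
        raise ValueError(f"{traj.fly_id}: repair() requires a flagged trajectory")

    x = traj.x[traj.valid]
    lo, hi = float(np.min(x)), float(np.max(x))
    orig_width = hi - lo
    if orig_width <= 0:
        return traj.copy(), DenoiseReport(traj.fly_id, report.violations_per_day, "discarded", 0.0)

    base_valid = traj.valid.copy()
    current = traj
    while True:
        width = hi - lo
        trim = width * TRIM_STEP / 2.0
        lo, hi = lo + trim, hi - trim
        width = hi - lo
        retained = width / orig_width
        if retained < min_width_frac:
            return current.copy(), DenoiseReport(
                traj.fly_id, _violation_rate(current, speed_thresh), "discarded", retained
            )
        current = traj.copy()
        current.valid = base_valid & (traj.x >= lo) & (traj.x <= hi)
        if current.valid.sum() < 2:
            return current, DenoiseReport(traj.fly_id, np.inf, "discarded", retained)
        current = derive_speed(current)
        rate = _violation_rate(current, speed_thresh)
        if rate <= max_per_day:
            return current, DenoiseReport(traj.fly_id, rate, "repaired", retained)


def denoise_cohort(cohort, **kwargs):
    """Flag and repair every trajectory in a cohort.

    Returns a new cohort (discarded flies' records are marked excluded by
    setting ``survival=0, outcome=0``) and the list of reports.
    """
    out = cohort.copy()
    reports = []
    for i, traj in enumerate(out.trajectories):
        rep = flag_noisy(traj, **{k: v for k, v in kwargs.items() if k != "min_width_frac"})
        if rep.action == "flagged":
            fixed, rep = repair(traj, **kwargs)
            out.trajectories[i] = fixed
            if rep.action == "discarded":
                rec = out.records[traj.fly_id]
                rec.survival, rec.outcome = 0, 0
        reports.append(rep)
    return out, reports
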