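"""The summit metric (SM) and bootstrap effect-size estimation.

SM quantifies the terminal locomotor burst of one zombie fly. The summiting
window opens exactly 2.5 h before death. The speed trace smoothed with a 1-h
sliding average defines (a) the baseline — its value at the window start —
and (b) the window end: the earliest moment after the smoothed trace first
exceeds the baseline at which it drops back to the baseline level (falling
back to the end of the recording if it never returns, or an empty window if
it never exceeds it). SM is the time average of the *raw* baseline-corrected
speed over that window:

    SM = integral(speed - baseline) / (window duration)        [mm/s]

Group comparisons use the relative effect

    E = (mean(SM_exp) - mean(SM_ctrl)) / mean(SM_ctrl)

whose uncertainty is estimated by bootstrapping flies independently within
each group; E = -1 means complete loss of summiting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import DataError, Trajectory

SMOOTH_WINDOW_H = 1.0
ONSET_OFFSET_H = 2.5
BASELINE_EPS = 1e-9  # smoothed trace must exceed baseline + eps before the
# return crossing can terminate the window


@dataclass
class SummitResult:
    fly_id: str
    window_start: float  # hours relative to death (== -2.5 at start)
    window_end: float
    baseline: float  # mm/s
    sm: float  # mm/s
    start_frame: int = 0
    end_frame: int = 0


@dataclass
class EffectSizeResult:
    effect_mean: float
    boot_effects: np.ndarray
    p_value: float
    n_exp: int
    n_ctrl: int


def smooth_speed(traj: Trajectory, window_h: float = SMOOTH_WINDOW_H) -> np.ndarray:
    """Centered sliding-window average of speed over valid frames.

    The window is truncated at the edges of the series; invalid frames
    contribute nothing (the average is over valid frames in the window).
    A window of one frame or less is the identity.
    """
    n = len(traj)
    win = int(round(window_h * 3600 * traj.frame_rate))
    if win <= 1 or n == 0:
        return traj.speed.astype(float).copy()
    half_lo = (win - 1) // 2
    half_hi = win // 2
    vals = np.where(traj.valid, traj.speed, 0.0)
    cnt = traj.valid.astype(float)
    cs = np.concatenate(([0.0], np.cumsum(vals)))
    cc = np.concatenate(([0.0], np.cumsum(cnt)))
    i = np.arange(n)
    lo = np.maximum(i - half_lo, 0)
    hi = np.minimum(i + half_hi, n - 1)
    tot = cs[hi + 1] - cs[lo]
    num = cc[hi + 1] - cc[lo]
    with np.errstate(invalid="ignore"):
        return np.where(num > 0, tot / np.maximum(num, 1), np.nan)


def summit_window(
    traj: Trajectory,
    death_frame: int,
    smoothed: Optional[np.ndarray] = None,
    window_h: float = SMOOTH_WINDOW_H,
    onset_offset_h: float = ONSET_OFFSET_H,
) -> tuple[int, int]:
    """Frame bounds (start, end) of the summiting window.

    Start is exactly ``onset_offset_h`` (2.5 h) before death. End is the
    first frame, after the smoothed speed strictly exceeds the baseline, at
    which it returns to or below the baseline; the last frame if it never
    returns; equal to start (empty window) if it never exceeds the baseline.
    """
    frames_back = int(round(onset_offset_h * 3600 * traj.frame_rate))
    start = death_frame - frames_back
    if start < 0:
        raise DataError(
            f"{traj.fly_id}: fewer than {onset_offset_h} h of pre-death data"
        )
    if smoothed is None:
        smoothed = smooth_speed(traj, window_h)
    baseline = smoothed[start]
    after = smoothed[start + 1 :]
    above = np.flatnonzero(after > baseline + BASELINE_EPS)
    if len(above) == 0:
        return start, start
    first_above = above[0]
    below = np.flatnonzero(after[first_above:] <= baseline)
    if len(below) == 0:
        return start, len(traj) - 1
    return start, start + 1 + first_above + int(below[0])


def compute_sm(
    traj: Trajectory,
    death_frame: int,
    window_h: float = SMOOTH_WINDOW_H,
    onset_offset_h: float = ONSET_OFFSET_H,
) -> SummitResult:
    """Summit metric of one fly: time-averaged baseline-corrected raw speed.

    Smoothing is used only to set the baseline and the window end; the
    integrand is the raw speed minus baseline, integrated by trapezoid over
    valid frames. An empty window yields SM = 0.
    """
    smoothed = smooth_speed(traj, window_h)
    start, end = summit_window(traj, death_frame, smoothed, window_h, onset_offset_h)
    baseline = float(smoothed[start])
    rel = lambda f: float((traj.t[f] - traj.t[death_frame]) / 3600.0)
    if end <= start:
        return SummitResult(traj.fly_id, rel(start), rel(start), baseline, 0.0, start, start)
    sel = slice(start, end + 1)
    v = traj.valid[sel]
    tt = traj.t[sel][v]
    ss = traj.speed[sel][v] - baseline
    duration = traj.t[end] - traj.t[start]
    sm = float(np.trapezoid(ss, tt) / duration) if len(tt) >= 2 else 0.0
    return SummitResult(traj.fly_id, rel(start), rel(end), baseline, sm, start, end)


def bootstrap_effect(
    exp_sms: Sequence[float],
    ctrl_sms: Sequence[float],
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> EffectSizeResult:
    """Relative SM effect of an experimental group versus its control.

    ``boot_effects[k]`` uses independent with-replacement resamples of each
    group; ``effect_mean`` is computed on the original samples. Significance
    is a two-tailed unpaired t-test on the SM lists themselves.
    """
    exp = np.asarray(exp_sms, dtype=float)
    ctrl = np.asarray(ctrl_sms, dtype=float)
    if len(exp) == 0 or len(ctrl) == 0:
        raise DataError("bootstrap_effect requires nonempty groups")
    mc = ctrl.mean()
    if mc <= 0:
        raise DataError("mean control SM must be positive for a relative effect")
    rng = np.random.default_rng() if rng is None else rng
    be = rng.choice(exp, size=(n_boot, len(exp)), replace=True).mean(axis=1)
    bc = rng.choice(ctrl, size=(n_boot, len(ctrl)), replace=True).mean(axis=1)
    boot = (be - bc) / bc
    t = stats.ttest_ind(exp, ctrl, equal_var=False)
    return EffectSizeResult(
        effect_mean=float((exp.mean() - mc) / mc),
        boot_effects=boot,
        p_value=float(t.pvalue),
        n_exp=len(exp),
        n_ctrl=len(ctrl),
    )


def cohort_sms(cohort, **kwargs) -> dict[str, SummitResult]:
    """Summit metric per fly, for every fly with a death frame.

    Flies with fewer than 2.5 h of pre-death data are skipped.
    """
    out = {}
    for traj, rec in cohort:
        if rec.death_frame is None or rec.fly_class == "excluded":
            continue
        try:
            out[traj.fly_id] = compute_sm(traj, rec.death_frame, **kwargs)
        except DataError:
            continue
    return out
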