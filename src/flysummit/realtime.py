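"""Simulated real-time classification, flagging and control selection.

Every ``period_s`` seconds (240 s by default) each fly is classified from
features built only on data up to the classification time. A fly is flagged
as a zombie at the third consecutive prediction frame where
P(during summiting) strictly exceeds P(never summiting) — with a 240 s
period the three frames span exactly 8 minutes. Flies never flagged by the
end of the run are called survivors.

For experiments needing time-matched non-summiting controls, unflagged
flies are ranked by a four-factor product score (mean never-probability,
one minus the maximum during-probability, an at-least-10%-moving indicator,
and the current cohort speed percentile).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import Cohort, Trajectory
from .classify import CLASSES, RECENT_WINDOW_S, build_features_batch
from .mortality import MOVE_THRESH_MMS
from .summit_metric import ONSET_OFFSET_H

DEFAULT_PERIOD_S = 240.0
STREAK_LEN = 3


@dataclass
class PredictionFrame:
    fly_id: str
    t: float  # seconds
    probs: np.ndarray  # (4,), ordered as CLASSES, sums to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if abs(self.probs.sum() - 1.0) > 1e-9 or np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError(f"{self.fly_id}: class probabilities must be a distribution")


@dataclass
class FlagEvent:
    fly_id: str
    t_flag: float  # seconds, time of the third qualifying frame
    kind: str  # "zombie" | "survivor"
    streak_start: float  # seconds, time of the first qualifying frame

    def validate(self, period_s: float = DEFAULT_PERIOD_S) -> None:
        if self.kind == "zombie" and abs(
            (self.t_flag - self.streak_start) - (STREAK_LEN - 1) * period_s
        ) > 1e-6:
            raise ValueError(
                f"{self.fly_id}: zombie flag must span {STREAK_LEN - 1} periods"
            )


def flag_from_probs(
    times: Sequence[float],
    p_during: Sequence[float],
    p_never: Sequence[float],
    fly_id: str = "",
) -> Optional[FlagEvent]:
    """Apply the 3-consecutive-frame rule to one probability stream.

    A frame qualifies when P(during) > P(never) strictly; equality breaks
    the streak. Returns the flag at the third consecutive qualifying frame,
    or None.
    """
    t_arr = np.asarray(times, dtype=float)
    streak = 0
    for i, (pd_, pn) in enumerate(zip(p_during, p_never)):
        if pd_ > pn:
            streak += 1
            if streak == STREAK_LEN:
                return FlagEvent(
                    fly_id=fly_id,
                    t_flag=float(t_arr[i]),
                    kind="zombie",
                    streak_start=float(t_arr[i - STREAK_LEN + 1]),
                )
        else:
            streak = 0
    return None


def _prob_matrix(model, X: np.ndarray) -> np.ndarray:
    """Per-class probabilities in CLASSES order, zero-filled for absent classes."""
    raw = model.predict_proba(X)
    out = np.zeros((len(X), len(CLASSES)))
    for j, cls in enumerate(model.classes_):
        out[:, CLASSES.index(cls)] = raw[:, j]
    return out


def run_realtime(
    cohort: Cohort,
    model,
    period_s: float = DEFAULT_PERIOD_S,
) -> tuple[list[PredictionFrame], list[FlagEvent]]:
    """Classify every fly on a fixed period and apply the flag rule.

    Classification times are multiples of ``period_s`` from the start of
    each recording, beginning at the first one at least 10 min in (features
    need a full recent-history window). Only data up to each classification
    time are used, so rerunning on a truncated trajectory reproduces the
    prediction prefix exactly. Flies with no flag by the end are reported as
    survivor FlagEvents at the final classification time.
    """
    if cohort.trajectories and period_s < 1.0 / cohort.trajectories[0].frame_rate:
        raise ValueError("classification period shorter than the frame interval")
    predictions: list[PredictionFrame] = []
    events: list[FlagEvent] = []
    for traj, rec in cohort:
        if rec.fly_class == "excluded":
            continue
        t0, t_end = float(traj.t[0]), float(traj.t[-1])
        k0 = int(np.ceil(max(RECENT_WINDOW_S, period_s) / period_s))
        times = t0 + period_s * np.arange(k0, int((t_end - t0) // period_s) + 1)
        if len(times) == 0:
            continue
        probs = _prob_matrix(model, build_features_batch(traj, times))
        for t, p in zip(times, probs):
            predictions.append(PredictionFrame(traj.fly_id, float(t), p))
        flag = flag_from_probs(
            times, probs[:, CLASSES.index("during")], probs[:, CLASSES.index("never")],
            fly_id=traj.fly_id,
        )
        if flag is None:
            flag = FlagEvent(traj.fly_id, float(times[-1]), "survivor", float(times[-1]))
        events.append(flag)
    return predictions, events


def control_score(
    predictions: Sequence[PredictionFrame],
    traj_so_far: Trajectory,
    cohort_speeds_now: Sequence[float],
    move_thresh: float = MOVE_THRESH_MMS,
) -> float:
    """Non-summiting control score in [0, 1] for one fly.

    The product of: the mean never-summiting probability so far; one minus
    the maximum during-summiting probability so far; an indicator that the
    fly has been moving in at least 10% of frames so far; and the percentile
    rank of the fly's current speed among all flies' current speeds.
    """
    if not predictions:
        raise ValueError("control_score requires at least one prediction frame")
    p = np.stack([pf.probs for pf in predictions])
    mean_never = float(p[:, CLASSES.index("never")].mean())
    max_during = float(p[:, CLASSES.index("during")].max())
    v = traj_so_far.valid
    moving_frac = float(np.mean(traj_so_far.speed[v] >= move_thresh)) if v.any() else 0.0
    pool = np.asarray(cohort_speeds_now, dtype=float)
    current = float(traj_so_far.speed[v][-1]) if v.any() else 0.0
    percentile = float(np.mean(pool <= current)) if len(pool) else 0.0
    return mean_never * (1.0 - max_during) * float(moving_frac >= 0.10) * percentile


def select_controls(
    scores: dict[str, float],
    flagged: set[str],
    k_pool: int = 5,
) -> list[str]:
    """Top-``k_pool`` unflagged flies by control score, best first.

    Ties are broken by fly_id so the selection is deterministic.
    """
    candidates = [(fid, s) for fid, s in scores.items() if fid not in flagged]
    candidates.sort(key=lambda fs: (-fs[1], fs[0]))
    return [fid for fid, _ in candidates[:k_pool]]


def score_realtime(
    events: Sequence[FlagEvent],
    records: dict,
    onset_by_fly: Optional[dict[str, float]] = None,
) -> dict:
    """Precision/recall of zombie calls plus latency statistics.

    Latency is ``t_flag`` minus the true summiting onset (death - 2.5 h when
    not supplied) for each true positive. Precision is None when no fly was
    flagged as a zombie.
    """
    tp = fp = fn = tn = 0
    latencies = []
    for ev in events:
        rec = records[ev.fly_id]
        is_zombie = rec.fly_class == "zombie"
        called = ev.kind == "zombie"
        if called and is_zombie:
            tp += 1
            if onset_by_fly and ev.fly_id in onset_by_fly:
                onset = onset_by_fly[ev.fly_id]
            else:
                onset = rec.death_frame / 3.0 - ONSET_OFFSET_H * 3600.0
            latencies.append(ev.t_flag - onset)
        elif called:
            fp += 1
        elif is_zombie:
            fn += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    lat = np.asarray(latencies)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "precision": precision,
        "recall": recall,
        "latency_mean_s": float(lat.mean()) if len(lat) else None,
        "latency_median_s": float(np.median(lat)) if len(lat) else None,
    }
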