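"""Domain types for summiting-behavior analysis.

The unit conventions used throughout the package:

* time ``t`` is seconds since the first tracked frame (frame 0), nominally
  sampled at 3 Hz;
* Zeitgeber time of a frame is ``(zt0 + t / 3600) % 24`` where ``zt0`` is the
  ZT hour at which tracking started (ZT0 = lights on, ZT12 = lights off);
* positions are millimetres; ``y_rel`` is the position along the arena's main
  (gravitational) axis rescaled to [0, 1], with 0 at the food end and 1 at the
  far end (arena length 65 mm by default);
* speeds are mm/s per frame.

Frames lost to tracking drop-outs are carried as ``valid == False`` rather
than removed, so frame indices stay aligned with death annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Optional

import numpy as np

ARENA_LENGTH_MM = 65.0
ARENA_WIDTH_MM = 5.0
FRAME_RATE_HZ = 3.0

FlyClass = Literal["zombie", "survivor", "unexposed", "excluded"]
DeathSource = Literal["manual", "detected", "fictive", "none"]


class DataError(ValueError):
    """Raised when input data violate a structural precondition."""


class FormatError(ValueError):
    """Raised when an input file does not match the expected schema."""


@dataclass
class Trajectory:
    """One fly's tracked time series.

    Attributes
    ----------
    fly_id : str
        Unique identifier, shared with the matching :class:`FlyRecord`.
    t : ndarray
        Seconds since the first tracked frame; strictly increasing.
    x : ndarray
        Position across the arena width, mm.
    y_rel : ndarray
        Position along the arena length, dimensionless in [0, 1]
        (0 = food end).
    speed : ndarray
        Per-frame speed, mm/s; ``speed[0] == 0`` by convention.
    valid : ndarray of bool
        Per-frame tracking-quality mask.
    zt0 : float
        Zeitgeber hour at ``t == 0``.
    arena_len_mm : float
        Physical arena length used to normalize ``y_rel``.
    """

    fly_id: str
    t: np.ndarray
    x: np.ndarray
    y_rel: np.ndarray
    speed: np.ndarray
    valid: np.ndarray
    zt0: float = 19.0
    arena_len_mm: float = ARENA_LENGTH_MM

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y_rel = np.asarray(self.y_rel, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def frame_rate(self) -> float:
        """Median sampling rate, Hz."""
        if len(self.t) < 2:
            return FRAME_RATE_HZ
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0

    def zt(self, frame: int | np.ndarray) -> float | np.ndarray:
        """Zeitgeber hour(s) of the given frame index/indices."""
        return (self.zt0 + self.t[frame] / 3600.0) % 24.0

    def validate(self) -> None:
        """Raise :class:`DataError` if any structural invariant is violated."""
        n = len(self.t)
        for name in ("x", "y_rel", "speed", "valid"):
            if len(getattr(self, name)) != n:
                raise DataError(
                    f"{self.fly_id}: field {name!r} length mismatch"
                )
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise DataError(f"{self.fly_id}: t not strictly increasing")
            med = np.median(dt)
            if not (0.9 / FRAME_RATE_HZ <= med <= 1.1 / FRAME_RATE_HZ):
                raise DataError(
                    f"{self.fly_id}: median frame interval {med:.4f}s "
                    f"outside 10% of nominal {1.0 / FRAME_RATE_HZ:.4f}s"
                )
        v = self.valid
        if np.any((self.y_rel[v] < -1e-9) | (self.y_rel[v] > 1 + 1e-9)):
            raise DataError(f"{self.fly_id}: y_rel outside [0, 1]")
        if np.any(self.speed[v] < 0):
            raise DataError(f"{self.fly_id}: negative speed")

    def copy(self) -> "Trajectory":
        return Trajectory(
            fly_id=self.fly_id,
            t=self.t.copy(),
            x=self.x.copy(),
            y_rel=self.y_rel.copy(),
            speed=self.speed.copy(),
            valid=self.valid.copy(),
            zt0=self.zt0,
            arena_len_mm=self.arena_len_mm,
        )


def derive_speed(traj: Trajectory, frame_rate: Optional[float] = None) -> Trajectory:
    """Return a copy of *traj* with speed recomputed from positions.

    Speed at a valid frame is the Euclidean displacement from the nearest
    preceding valid frame divided by the elapsed time, so masked gaps are
    bridged rather than interpolated and cannot create artificial spikes.
    ``speed[first valid frame] == 0``. Invalid frames get speed 0.
    """
    out = traj.copy()
    n = len(out)
    speed = np.zeros(n)
    if n <= 1:
        out.speed = speed
        return out
    idx = np.flatnonzero(out.valid)
    if len(idx) >= 2:
        y_mm = out.y_rel * out.arena_len_mm
        dx = np.diff(out.x[idx])
        dy = np.diff(y_mm[idx])
        dt = np.diff(out.t[idx])
        speed[idx[1:]] = np.hypot(dx, dy) / dt
    out.speed = speed
    return out


@dataclass
class FlyRecord:
    """Per-fly experimental metadata.

    ``survival`` is 1 for flies alive at the end of tracking; ``outcome`` is 1
    for flies showing fungal sporulation after death. A zombie is an exposed
    fly with ``survival == 0 and outcome == 1``; an exposed dead fly without
    sporulation is excluded from analysis.
    """

    fly_id: str
    genotype: str = "CantonS"
    sex: Literal["M", "F", "unknown"] = "unknown"
    exposed: bool = True
    survival: int = 1
    outcome: int = 0
    death_frame: Optional[int] = None
    death_source: DeathSource = "none"

    @property
    def fly_class(self) -> FlyClass:
        if not self.exposed:
            return "unexposed"
        if self.survival == 1:
            return "survivor"
        if self.outcome == 1:
            return "zombie"
        return "excluded"

    def validate(self) -> None:
        if self.fly_class == "zombie" and self.death_frame is None:
            raise DataError(f"{self.fly_id}: zombie without death_frame")
        if self.fly_class == "zombie" and self.death_source == "fictive":
            raise DataError(f"{self.fly_id}: zombie with fictive death")

    def copy(self) -> "FlyRecord":
        return replace(self)


@dataclass
class Cohort:
    """A set of trajectories with one metadata record per fly."""

    trajectories: list[Trajectory]
    records: dict[str, FlyRecord]
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[tuple[Trajectory, FlyRecord]]:
        for traj in self.trajectories:
            yield traj, self.records[traj.fly_id]

    def record_for(self, fly_id: str) -> FlyRecord:
        return self.records[fly_id]

    def of_class(self, fly_class: FlyClass) -> "Cohort":
        """Sub-cohort restricted to one fly class."""
        trajs = [
            tr
            for tr in self.trajectories
            if self.records[tr.fly_id].fly_class == fly_class
        ]
        recs = {tr.fly_id: self.records[tr.fly_id] for tr in trajs}
        return Cohort(trajs, recs, dict(self.config))

    def validate(self) -> None:
        traj_ids = {tr.fly_id for tr in self.trajectories}
        if len(traj_ids) != len(self.trajectories):
            raise DataError("duplicate fly_id among trajectories")
        if traj_ids != set(self.records):
            raise DataError("trajectory and record fly_ids do not match")
        for traj in self.trajectories:
            traj.validate()
        for rec in self.records.values():
            rec.validate()

    def copy(self) -> "Cohort":
        return Cohort(
            [tr.copy() for tr in self.trajectories],
            {fid: rec.copy() for fid, rec in self.records.items()},
            dict(self.config),
        )
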