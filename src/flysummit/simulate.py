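"""Synthetic cohorts of survivor / zombie / unexposed fly trajectories.

The generator emulates the statistical structure that the downstream
analysis assumes:

* **Zombies** rest near the food with a low mean speed (0.18 mm/s default)
  until 2.5 h before death, then ramp up through a locomotor burst peaking at
  0.87 mm/s about one hour before death, walk for the last time exactly at
  the death frame, and afterwards show only sub-threshold tracking jitter.
  Death times follow a circadian-gated distribution (skew-normal on ZT hours,
  calibrated so the mean is ZT9:50 and the central 90% lies in [ZT7, ZT12]).
* **Survivors / unexposed controls** wander around mid-arena with activity
  modulated by a crepuscular envelope peaking at the light transitions
  (ZT0 and ZT12, peak mean speed ~0.8 mm/s).

Locomotion is a two-state (move/rest) Markov renewal process at frame
resolution: bout lengths are geometric (memoryless, so the process is
stationary from frame 0), and while moving the per-frame speed is log-normal
with mean tied to the epoch envelope. Positions integrate the drawn step
lengths with random headings, folded into slowly moving residence bands so
that flies occupy the intended part of the arena without piling up against
walls; stored speed is always re-derived from positions so that tracking
files, the denoiser and the analysis all see one consistent speed series.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import Cohort, FlyRecord, Trajectory, derive_speed

# Skew-normal death-time parameters on ZT hours, solved numerically so that
# mean = 9.8333 h (ZT9:50), 5th pct = 7 h, 95th pct = 12 h.
SKEWNORM_DEATH = {"a": -3.0012844, "loc": 11.6161294, "scale": 2.3552113}

PHYSIOLOGICAL_MAX_SPEED = 40.0  # mm/s; only tracking noise exceeds this


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions for synthetic cohorts.

    Speeds are mm/s, offsets are hours before death, ``zt0`` is the Zeitgeber
    hour at the start of tracking. The burst envelope rises from
    ``zombie_baseline_speed`` at ``burst_start_offset`` to
    ``zombie_peak_speed`` at ``burst_plateau_start``, holds the peak through
    ``burst_plateau_end`` (so it passes through the peak at
    ``burst_peak_offset``), then falls to zero at death.
    """

    n_zombie: int = 0
    n_survivor: int = 0
    n_unexposed: int = 0
    duration_h: float = 20.0
    frame_rate: float = 3.0
    zt0: float = 19.0
    death_dist: tuple[str, dict] = ("skewnorm", SKEWNORM_DEATH)
    zombie_baseline_speed: float = 0.18
    zombie_peak_speed: float = 0.87
    burst_start_offset: float = 2.5
    burst_peak_offset: float = 1.0
    burst_plateau_start: float = 1.4
    burst_plateau_end: float = 0.6
    survivor_peak_speed: float = 0.8
    survivor_base_speed: float = 0.25
    crepuscular_sigma_h: float = 1.2
    move_rest_rates: dict = field(
        default_factory=lambda: {
            "zombie_move_frac": 0.25,
            "burst_move_frac": 0.8,
            "survivor_move_frac": 0.5,
            "mean_move_bout_s": 5.0,
        }
    )
    lognorm_sigma: float = 0.6
    # per-fly multiplier on the speed envelope, uniform on this range; mean 1
    # so cohort-average calibrations are unchanged while individual survivors
    # and pre-burst zombies overlap behaviorally (as real flies do)
    activity_scale_range: tuple[float, float] = (0.7, 1.3)
    # positional jitter of a dead fly, mm; small enough that jitter speed
    # essentially never crosses the 0.5 mm/s walking threshold
    jitter_sd: float = 0.02
    arena_len_mm: float = 65.0
    arena_width_mm: float = 5.0
    speed_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        if not (
            self.burst_start_offset
            > self.burst_plateau_start
            >= self.burst_peak_offset
            >= self.burst_plateau_end
            > 0
        ):
            raise ConfigError("burst offsets must be ordered start > plateau >= peak >= end > 0")
        for name in ("zombie_baseline_speed", "zombie_peak_speed", "survivor_peak_speed"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h * 3600 * self.frame_rate)) + 1

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


def draw_death_time(cfg: GeneratorConfig, rng: np.random.Generator) -> float:
    """Draw one zombie death time, in ZT hours."""
    family, params = cfg.death_dist
    if family == "skewnorm":
        return float(
            stats.skewnorm.rvs(
                params["a"], loc=params["loc"], scale=params["scale"], random_state=rng
            )
        )
    if family == "point":
        return float(params["zt"])
    raise ConfigError(f"unknown death_dist family {family!r}")


def zombie_speed_envelope(rel_h: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Expected per-frame speed (mm/s) vs time relative to death (hours).

    Flat at the pre-burst baseline, rising to the peak, holding it through a
    plateau that spans the nominal peak offset, then falling to zero at
    death; zero afterwards. The flat top keeps the 1-h-smoothed aligned mean
    close to the nominal peak value.
    """
    r = np.asarray(rel_h, dtype=float)
    b, p = cfg.zombie_baseline_speed, cfg.zombie_peak_speed
    t0, t1, t2 = -cfg.burst_start_offset, -cfg.burst_plateau_start, -cfg.burst_plateau_end
    out = np.full(r.shape, b)
    m = (r > t0) & (r <= t1)
    out[m] = b + (p - b) * (r[m] - t0) / (t1 - t0)
    out[(r > t1) & (r <= t2)] = p
    m = (r > t2) & (r <= 0)
    out[m] = p * (-r[m]) / (-t2)
    out[r > 0] = 0.0
    return out


def survivor_speed_envelope(zt: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Expected per-frame speed vs ZT hour: crepuscular bumps at ZT0 and ZT12."""
    z = np.asarray(zt, dtype=float) % 24.0
    sig = cfg.crepuscular_sigma_h
    if sig <= 0:  # flat limit: time-homogeneous activity
        return np.full(z.shape, cfg.survivor_base_speed)
    bump = np.zeros(z.shape)
    for center in (0.0, 12.0, 24.0):
        d = np.abs(z - center)
        d = np.minimum(d, 24.0 - d)
        bump = np.maximum(bump, np.exp(-0.5 * (d / sig) ** 2))
    return cfg.survivor_base_speed + (cfg.survivor_peak_speed - cfg.survivor_base_speed) * bump


def _move_states(
    move_frac: np.ndarray, mean_move_bout_frames: float, rng: np.random.Generator
) -> np.ndarray:
    """Simulate the move/rest renewal chain; returns a boolean 'moving' array.

    Geometric bout lengths make the chain memoryless, so drawing the initial
    state from the instantaneous moving fraction starts it in equilibrium:
    P(moving at frame i) == move_frac[i] wherever move_frac is constant.
    """
    n = len(move_frac)
    moving = np.zeros(n, dtype=bool)
    b = 1.0 / mean_move_bout_frames  # move -> rest hazard
    state = bool(rng.random() < move_frac[0])
    i = 0
    while i < n:
        if state:
            length = int(rng.geometric(b))
        else:
            f = min(max(float(move_frac[i]), 1e-9), 1 - 1e-9)
            a = b * f / (1.0 - f)  # rest -> move hazard preserving fraction f
            length = int(rng.geometric(min(a, 1.0)))
        moving[i : i + length] = state
        i += length
        state = not state
    return moving


def _draw_speeds(
    mean_speed: np.ndarray, moving: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal speeds for moving frames with E[speed | moving] = mean/frac."""
    speeds = np.zeros(len(mean_speed))
    idx = np.flatnonzero(moving)
    if len(idx):
        mu = np.log(np.maximum(mean_speed[idx], 1e-12)) - 0.5 * sigma**2
        speeds[idx] = np.exp(rng.normal(mu, sigma))
    return speeds


def _fold(z: np.ndarray, lo: np.ndarray, width: float) -> np.ndarray:
    """Triangle-fold an unbounded coordinate into the band [lo, lo + width]."""
    return lo + (width - np.abs(np.mod(z, 2 * width) - width))


def _integrate_positions(
    step_len: np.ndarray,
    y_lo_mm: np.ndarray,
    y_band_mm: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    y_start_frac: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Turn per-frame step lengths into (x, y_mm) paths.

    Headings split each step into a lengthwise (y) and crosswise (x)
    component; signed steps are accumulated and folded into residence bands
    (a slowly-moving band for y, a fixed interior band for x). Folding only
    alters a displacement when a band edge is crossed within a single step,
    so derived speed stays within ~1% of the drawn speed.
    """
    n = len(step_len)
    # narrow-corridor headings: steps are mostly lengthwise, which also keeps
    # crosswise fold losses (derived speed < drawn speed) well under 1%
    c = rng.uniform(0.85, 1.0, n)
    sy = rng.choice((-1.0, 1.0), n)
    sx = rng.choice((-1.0, 1.0), n)
    dy = step_len * c * sy
    dx = step_len * np.sqrt(1.0 - c**2) * sx
    dy[0] = dx[0] = 0.0
    zy = np.cumsum(dy) + y_start_frac * y_band_mm
    zx = np.cumsum(dx) + 0.5 * cfg.arena_width_mm
    y = _fold(zy, y_lo_mm, y_band_mm)
    x_lo, x_width = 0.3, cfg.arena_width_mm - 0.6
    x = _fold(zx - x_lo, np.zeros(n), x_width) + x_lo
    return x, y


def _zombie_bands(rel_h: np.ndarray, cfg: GeneratorConfig) -> tuple[np.ndarray, float]:
    """Food-proximal band pre-burst, gliding up to a summit band by the peak."""
    width = 24.0
    lo = np.zeros(len(rel_h))
    hi_lo = cfg.arena_len_mm - width - 1.0
    t0, t1 = -cfg.burst_start_offset, -cfg.burst_plateau_start
    m = (rel_h > t0) & (rel_h <= t1)
    lo[m] = hi_lo * (rel_h[m] - t0) / (t1 - t0)
    lo[rel_h > t1] = hi_lo
    return lo, width


def gen_zombie(
    cfg: GeneratorConfig, rng: np.random.Generator, fly_id: str = "z0"
) -> tuple[Trajectory, FlyRecord]:
    """One zombie trajectory plus its record (true death frame included)."""
    n = cfg.n_frames
    t = np.arange(n) * cfg.dt
    rates = cfg.move_rest_rates
    death_zt = None
    for _ in range(100):
        zt = draw_death_time(cfg, rng)
        td = ((zt - cfg.zt0) % 24.0) * 3600.0
        if cfg.burst_start_offset * 3600 + 60 <= td <= cfg.duration_h * 3600 - 601:
            death_zt = zt
            break
    if death_zt is None:
        raise ConfigError(
            "could not draw a death time inside the tracked window; "
            "increase duration_h or adjust zt0/death_dist"
        )
    death_frame = int(round(td * cfg.frame_rate))
    rel_h = (t - t[death_frame]) / 3600.0

    env = zombie_speed_envelope(rel_h, cfg)
    f_pre = rates["zombie_move_frac"]
    f_burst = rates["burst_move_frac"]
    frac = np.full(n, f_pre)
    t0, t1 = -cfg.burst_start_offset, -cfg.burst_plateau_start
    m = (rel_h > t0) & (rel_h <= t1)
    frac[m] = f_pre + (f_burst - f_pre) * (rel_h[m] - t0) / (t1 - t0)
    frac[rel_h > t1] = f_burst

    alive = slice(0, death_frame + 1)
    moving = np.zeros(n, dtype=bool)
    moving[alive] = _move_states(
        frac[alive], rates["mean_move_bout_s"] * cfg.frame_rate, rng
    )
    scale = rng.uniform(*cfg.activity_scale_range)
    speeds = _draw_speeds(scale * env / frac, moving, cfg.lognorm_sigma, rng)
    speeds[death_frame + 1 :] = 0.0
    # the final walking bout: death is defined as the last observed movement
    final = slice(max(death_frame - 11, 1), death_frame + 1)
    speeds[final] = rng.uniform(0.70, 0.90, speeds[final].shape)

    y_lo, y_band = _zombie_bands(rel_h, cfg)
    x, y_mm = _integrate_positions(
        speeds * cfg.dt, y_lo, y_band, cfg, rng, rng.uniform(0.1, 0.9)
    )
    # lay the final bout down as a straight walk toward the band center so
    # band-edge folding cannot shave its speed below the walking threshold
    f0 = final.start
    center = y_lo[death_frame] + y_band / 2.0
    direction = 1.0 if y_mm[f0 - 1] < center else -1.0
    y_mm[f0 : death_frame + 1] = y_mm[f0 - 1] + direction * np.cumsum(
        speeds[f0 : death_frame + 1] * cfg.dt
    )
    x[f0 : death_frame + 1] = x[f0 - 1]
    # dead fly: frozen at the death position plus tracking jitter
    dead = np.arange(death_frame + 1, n)
    if len(dead):
        jit = cfg.jitter_sd
        x[dead] = x[death_frame] + rng.normal(0.0, jit, len(dead))
        y_mm[dead] = y_mm[death_frame] + rng.normal(0.0, jit, len(dead))
        np.clip(x[dead], 0.0, cfg.arena_width_mm, out=x[dead])
        np.clip(y_mm[dead], 0.0, cfg.arena_len_mm, out=y_mm[dead])

    traj = Trajectory(
        fly_id=fly_id,
        t=t,
        x=x,
        y_rel=y_mm / cfg.arena_len_mm,
        speed=np.zeros(n),
        valid=np.ones(n, dtype=bool),
        zt0=cfg.zt0,
        arena_len_mm=cfg.arena_len_mm,
    )
    traj = derive_speed(traj)
    # optional uniform speed scaling (e.g. sex differences in summiting
    # vigor); applied to the speed channel so SM scales exactly linearly
    traj.speed *= cfg.speed_multiplier
    record = FlyRecord(
        fly_id=fly_id,
        sex="M" if rng.random() < 0.5 else "F",
        exposed=True,
        survival=0,
        outcome=1,
        death_frame=death_frame,
        death_source="manual",
    )
    return traj, record


def gen_survivor(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    fly_id: str = "s0",
    exposed: bool = True,
) -> tuple[Trajectory, FlyRecord]:
    """One survivor (or unexposed control) trajectory plus its record."""
    n = cfg.n_frames
    t = np.arange(n) * cfg.dt
    rates = cfg.move_rest_rates
    zt = (cfg.zt0 + t / 3600.0) % 24.0
    env = survivor_speed_envelope(zt, cfg)
    f = rates["survivor_move_frac"]
    moving = _move_states(
        np.full(n, f), rates["mean_move_bout_s"] * cfg.frame_rate, rng
    )
    scale = rng.uniform(*cfg.activity_scale_range)
    speeds = _draw_speeds(scale * env / f, moving, cfg.lognorm_sigma, rng)
    # per-fly mid-arena residence band; centers average to mid-arena
    band = 30.0
    lo = np.full(n, rng.uniform(3.0, 27.0))
    x, y_mm = _integrate_positions(
        speeds * cfg.dt, lo, band, cfg, rng, rng.uniform(0.1, 0.9)
    )
    traj = Trajectory(
        fly_id=fly_id,
        t=t,
        x=x,
        y_rel=y_mm / cfg.arena_len_mm,
        speed=np.zeros(n),
        valid=np.ones(n, dtype=bool),
        zt0=cfg.zt0,
        arena_len_mm=cfg.arena_len_mm,
    )
    traj = derive_speed(traj)
    traj.speed *= cfg.speed_multiplier
    record = FlyRecord(
        fly_id=fly_id,
        sex="M" if rng.random() < 0.5 else "F",
        exposed=exposed,
        survival=1,
        outcome=0,
    )
    return traj, record


def inject_tracking_noise(
    traj: Trajectory,
    spikes_per_day: float,
    spike_speed: float = 50.0,
    rng: np.random.Generator | None = None,
    at_walls: bool = True,
) -> Trajectory:
    """Corrupt a trajectory with single-frame tracking spikes.

    Each spike teleports the centroid for one frame to an arena side wall
    (``at_walls=True``, emulating edge-tracking artifacts) or to a uniform x
    position, displaced far enough along the arena that the frame speed is at
    least ``spike_speed``. Speed is re-derived so position and speed stay
    consistent. ``spikes_per_day=0`` returns an unmodified copy.
    """
    out = traj.copy()
    days = out.duration_s / 86400.0
    n_spikes = int(round(spikes_per_day * days))
    if n_spikes == 0:
        return out
    n = len(out)
    if n_spikes * 3 >= n - 4:
        raise ValueError("spike rate too high: spikes would collide")
    rng = np.random.default_rng() if rng is None else rng
    frames = np.sort(rng.choice(np.arange(2, n - 2, 3), size=n_spikes, replace=False))
    rate = out.frame_rate
    width = np.max(out.x) if np.max(out.x) > 0 else 5.0
    y_mm = out.y_rel * out.arena_len_mm
    jump = 1.2 * spike_speed / rate
    for i in frames:
        out.x[i] = (0.0 if rng.random() < 0.5 else width) if at_walls else rng.uniform(0, width)
        y_prev = y_mm[i - 1]
        y_new = y_prev + jump if y_prev < out.arena_len_mm / 2 else y_prev - jump
        out.y_rel[i] = np.clip(y_new, 0.0, out.arena_len_mm) / out.arena_len_mm
    return derive_speed(out)


def gen_cohort(cfg: GeneratorConfig) -> Cohort:
    """Generate a full cohort; deterministic under ``cfg.seed``.

    One child random stream per fly is spawned from the master seed, so the
    cohort is reproducible regardless of generation order.
    """
    total = cfg.n_zombie + cfg.n_survivor + cfg.n_unexposed
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(total)]
    trajectories: list[Trajectory] = []
    records: dict[str, FlyRecord] = {}
    k = 0
    for i in range(cfg.n_zombie):
        traj, rec = gen_zombie(cfg, streams[k], fly_id=f"z{i:04d}")
        trajectories.append(traj)
        records[rec.fly_id] = rec
        k += 1
    for i in range(cfg.n_survivor):
        traj, rec = gen_survivor(cfg, streams[k], fly_id=f"s{i:04d}", exposed=True)
        trajectories.append(traj)
        records[rec.fly_id] = rec
        k += 1
    for i in range(cfg.n_unexposed):
        traj, rec = gen_survivor(cfg, streams[k], fly_id=f"u{i:04d}", exposed=False)
        trajectories.append(traj)
        records[rec.fly_id] = rec
        k += 1
    return Cohort(trajectories, records, config=dataclasses.asdict(cfg))


def noiseless_burst_trajectory(
    cfg: GeneratorConfig | None = None,
    death_h: float = 14.8333,
    duration_h: float = 17.0,
) -> tuple[Trajectory, int]:
    """Deterministic trajectory whose speed equals the burst envelope exactly.

    Positions are held fixed (this is an analytic fixture for the summit
    metric, not a physical walk). Returns the trajectory and its death frame.
    """
    cfg = cfg or GeneratorConfig()
    n = int(round(duration_h * 3600 * cfg.frame_rate)) + 1
    t = np.arange(n) * cfg.dt
    death_frame = int(round(death_h * 3600 * cfg.frame_rate))
    rel_h = (t - t[death_frame]) / 3600.0
    speed = zombie_speed_envelope(rel_h, cfg)
    traj = Trajectory(
        fly_id="burst",
        t=t,
        x=np.full(n, 2.5),
        y_rel=np.full(n, 0.1),
        speed=speed,
        valid=np.ones(n, dtype=bool),
        zt0=cfg.zt0,
        arena_len_mm=cfg.arena_len_mm,
    )
    return traj, death_frame
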