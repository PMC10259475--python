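"""Summiting-state classification from causal trajectory features.

Each training example summarizes one fly's behavior up to an observation
time ``t_obs`` as a 61-element vector:

* feature 1 — hours since the start of the experiment;
* features 2-11 — y position at 10 lookback times geometrically spaced
  (in time before observation) between the start of the experiment and
  10 min before ``t_obs``, oldest first, so feature 2 is the *initial* y;
* features 12-21 — speed at the same historical times;
* features 22-41 — y position at 20 times uniformly spaced over the last
  10 min, oldest first, so feature 41 is the *current* y;
* features 42-61 — speed at the same recent times (feature 61 = current
  speed).

Values are read at the nearest valid frame at or before the requested time,
which makes feature construction strictly causal. Labels are four summiting
states: survivors are ``never`` at every frame; zombie frames are ``pre``
before summiting onset, ``during`` from onset to death, and ``post`` after
death. The classifier is a random forest emitting per-class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .core import Cohort, DataError, FlyRecord, Trajectory
from .summit_metric import ONSET_OFFSET_H

CLASSES = ("never", "pre", "during", "post")
N_FEATURES = 61
N_HIST = 10
N_RECENT = 20
RECENT_WINDOW_S = 600.0
FEATURE_NAMES = (
    ["t_obs_h"]
    + [f"hist_y_{i}" for i in range(N_HIST)]
    + [f"hist_speed_{i}" for i in range(N_HIST)]
    + [f"recent_y_{i}" for i in range(N_RECENT)]
    + [f"recent_speed_{i}" for i in range(N_RECENT)]
)


@dataclass
class TrainingExample:
    features: np.ndarray  # (61,)
    label: str
    fly_id: str
    t_obs: float


@dataclass
class TrainingSet:
    """Columnar container for feature vectors with labels and provenance."""

    X: np.ndarray  # (n, 61)
    labels: np.ndarray  # (n,) str
    fly_ids: np.ndarray  # (n,) str
    t_obs: np.ndarray  # (n,) seconds

    def __len__(self) -> int:
        return len(self.X)

    def example(self, i: int) -> TrainingExample:
        return TrainingExample(self.X[i], str(self.labels[i]), str(self.fly_ids[i]), float(self.t_obs[i]))


@dataclass
class EvalReport:
    confusion: np.ndarray  # (4, 4) counts, rows = true class
    precision: dict[str, float]
    recall: dict[str, float]
    feature_importances: Optional[np.ndarray] = None
    classes: tuple[str, ...] = CLASSES


def default_summit_onset(record: FlyRecord) -> int:
    """Summiting onset frame: 2.5 h before death at the nominal 3 Hz.

    Used when no manual onset annotation exists, matching the definition of
    the summiting window.
    """
    if record.death_frame is None:
        raise DataError(f"{record.fly_id}: no death frame for onset")
    return max(record.death_frame - int(round(ONSET_OFFSET_H * 3600 * 3.0)), 0)


def label_frames(
    traj: Trajectory, record: FlyRecord, summit_onset: Optional[int] = None
) -> np.ndarray:
    """Per-frame summiting labels (array of str)."""
    n = len(traj)
    if record.fly_class in ("survivor", "unexposed"):
        return np.full(n, "never", dtype=object)
    if record.fly_class != "zombie":
        raise DataError(f"{record.fly_id}: cannot label class {record.fly_class}")
    onset = default_summit_onset(record) if summit_onset is None else summit_onset
    death = record.death_frame
    if onset >= death:
        raise DataError(f"{record.fly_id}: summit onset at/after death")
    labels = np.empty(n, dtype=object)
    labels[:onset] = "pre"
    labels[onset:death] = "during"
    labels[death:] = "post"
    return labels


def lookback_times(t_obs: float, t_start: float, n: int = N_HIST) -> np.ndarray:
    """Historical sample times: lags geometric from (t_obs - t_start) down to
    10 min, returned oldest-first (first element == t_start)."""
    total = t_obs - t_start
    if total < RECENT_WINDOW_S:
        raise DataError("t_obs must be at least 10 min after the start")
    lags = RECENT_WINDOW_S * (total / RECENT_WINDOW_S) ** (
        np.arange(n - 1, -1, -1) / (n - 1)
    )
    return t_obs - lags


def _causal_lookup(traj: Trajectory, times: np.ndarray) -> np.ndarray:
    """Indices of the nearest valid frame at or before each requested time."""
    idx = np.searchsorted(traj.t, times + 1e-9) - 1
    idx = np.clip(idx, 0, len(traj) - 1)
    valid_idx = np.flatnonzero(traj.valid)
    if len(valid_idx) == 0:
        raise DataError(f"{traj.fly_id}: no valid frames")
    pos = np.clip(np.searchsorted(valid_idx, idx, side="right") - 1, 0, len(valid_idx) - 1)
    return valid_idx[pos]


def build_features(traj: Trajectory, t_obs: float) -> np.ndarray:
    """61-element feature vector for one observation time."""
    return build_features_batch(traj, np.asarray([t_obs], dtype=float))[0]


def build_features_batch(traj: Trajectory, t_obs: np.ndarray) -> np.ndarray:
    """Feature matrix (n_obs, 61); strictly causal frame lookups."""
    t_obs = np.asarray(t_obs, dtype=float)
    t_start = float(traj.t[0])
    out = np.empty((len(t_obs), N_FEATURES))
    out[:, 0] = (t_obs - t_start) / 3600.0
    hist_times = np.stack([lookback_times(to, t_start) for to in t_obs])
    step = RECENT_WINDOW_S / (N_RECENT - 1)
    recent_times = t_obs[:, None] - (RECENT_WINDOW_S - step * np.arange(N_RECENT))[None, :]
    recent_times[:, -1] = t_obs  # exact, avoids rounding at the current frame
    hi = _causal_lookup(traj, hist_times.ravel()).reshape(hist_times.shape)
    ri = _causal_lookup(traj, recent_times.ravel()).reshape(recent_times.shape)
    out[:, 1 : 1 + N_HIST] = traj.y_rel[hi]
    out[:, 1 + N_HIST : 1 + 2 * N_HIST] = traj.speed[hi]
    out[:, 21 : 21 + N_RECENT] = traj.y_rel[ri]
    out[:, 21 + N_RECENT :] = traj.speed[ri]
    return out


def sample_training_set(
    cohort: Cohort,
    n_per_fly: int = 200,
    rng: Optional[np.random.Generator] = None,
    onsets: Optional[dict[str, int]] = None,
) -> TrainingSet:
    """Sample ``n_per_fly`` observation times per fly and build features.

    Times are uniform on [start + 10 min, end of recording]; the first ten
    minutes are excluded because the recent-history window is undefined
    there. Total examples = n_flies * n_per_fly.
    """
    rng = np.random.default_rng() if rng is None else rng
    xs, ys, fids, ts = [], [], [], []
    for traj, rec in cohort:
        if rec.fly_class == "excluded":
            continue
        onset = (onsets or {}).get(traj.fly_id)
        labels = label_frames(traj, rec, onset)
        if n_per_fly == 0:
            continue
        t_obs = np.sort(
            rng.uniform(traj.t[0] + RECENT_WINDOW_S, traj.t[-1], n_per_fly)
        )
        X = build_features_batch(traj, t_obs)
        frame = np.clip(np.searchsorted(traj.t, t_obs + 1e-9) - 1, 0, len(traj) - 1)
        xs.append(X)
        ys.append(labels[frame])
        fids.append(np.full(n_per_fly, traj.fly_id, dtype=object))
        ts.append(t_obs)
    if not xs:
        return TrainingSet(
            np.empty((0, N_FEATURES)), np.empty(0, object), np.empty(0, object), np.empty(0)
        )
    return TrainingSet(
        np.vstack(xs), np.concatenate(ys), np.concatenate(fids), np.concatenate(ts)
    )


def _report(model, X: np.ndarray, y: np.ndarray) -> EvalReport:
    pred = model.predict(X)
    k = len(CLASSES)
    index = {c: i for i, c in enumerate(CLASSES)}
    conf = np.zeros((k, k), dtype=int)
    for true, hat in zip(y, pred):
        conf[index[true], index[hat]] += 1
    precision, recall = {}, {}
    for c, i in index.items():
        if conf[i].sum() == 0:
            continue
        col = conf[:, i].sum()
        precision[c] = float(conf[i, i] / col) if col else float("nan")
        recall[c] = float(conf[i, i] / conf[i].sum())
    return EvalReport(
        confusion=conf,
        precision=precision,
        recall=recall,
        feature_importances=getattr(model, "feature_importances_", None),
    )


def train(
    training: TrainingSet,
    split: float = 0.75,
    rng: Optional[np.random.Generator] = None,
    n_trees: int = 300,
) -> tuple[RandomForestClassifier, EvalReport]:
    """Fit a random forest on a by-fly train/validation split.

    All of a fly's examples land on one side of the split (prevents
    within-fly leakage). Returns the model and the validation report.
    """
    if len(set(training.labels)) < 2:
        raise DataError("training requires at least two classes")
    rng = np.random.default_rng() if rng is None else rng
    flies = np.unique(training.fly_ids)
    perm = rng.permutation(len(flies))
    n_train = max(int(round(split * len(flies))), 1)
    train_flies = set(flies[perm[:n_train]])
    in_train = np.array([f in train_flies for f in training.fly_ids])
    if in_train.all():  # single fly: fall back to an example-level split
        in_train = rng.random(len(training)) < split
    model = RandomForestClassifier(
        n_estimators=n_trees,
        class_weight="balanced_subsample",
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    model.fit(training.X[in_train], training.labels[in_train].astype(str))
    report = _report(
        model, training.X[~in_train], training.labels[~in_train].astype(str)
    )
    return model, report


def evaluate(model, X: np.ndarray, labels: Sequence[str]) -> EvalReport:
    """Confusion matrix and per-class precision/recall of argmax predictions."""
    X = np.asarray(X)
    if len(X) == 0:
        raise DataError("evaluate requires at least one example")
    return _report(model, X, np.asarray(labels, dtype=object))
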