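import numpy as np
import pytest

from flysummit import GeneratorConfig, Trajectory, gen_cohort


def make_trajectory(
    speed=None,
    n=200,
    frame_rate=3.0,
    y_rel=0.5,
    x=2.5,
    zt0=19.0,
    fly_id="f0",
    valid=None,
):
    """Hand-built trajectory with a prescribed speed series (analytic fixture)."""
    if speed is None:
        speed = np.zeros(n)
    speed = np.asarray(speed, dtype=float)
    n = len(speed)
    t = np.arange(n) / frame_rate
    return Trajectory(
        fly_id=fly_id,
        t=t,
        x=np.full(n, float(x)) if np.isscalar(x) else np.asarray(x, float),
        y_rel=np.full(n, float(y_rel)) if np.isscalar(y_rel) else np.asarray(y_rel, float),
        speed=speed,
        valid=np.ones(n, dtype=bool) if valid is None else np.asarray(valid, bool),
        zt0=zt0,
    )


@pytest.fixture(scope="session")
def small_cfg():
    """Short recording with a point-mass death time: cheap functional fixture."""
    return GeneratorConfig(
        n_zombie=3,
        n_survivor=3,
        duration_h=8.0,
        zt0=5.0,
        death_dist=("point", {"zt": 10.0}),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return gen_cohort(small_cfg)


@pytest.fixture(scope="session")
def medium_cohort():
    """Enough flies for train/validation splits to contain every class."""
    return gen_cohort(
        GeneratorConfig(
            n_zombie=10,
            n_survivor=14,
            duration_h=8.0,
            zt0=5.0,
            death_dist=("point", {"zt": 10.0}),
            seed=77,
        )
    )


@pytest.fixture(scope="session")
def default_zombie_cohort():
    """Default-condition zombie cohort used for calibration checks (n=200)."""
    return gen_cohort(GeneratorConfig(n_zombie=200, seed=1))


class SpeedThresholdModel:
    """Stub classifier: 'during' iff the current-speed feature is >= 0.5 mm/s.

    Produces perfectly separable probability streams for flag-rule tests.
    """

    classes_ = np.array(["during", "never"])

    def predict_proba(self, X):
        d = (np.asarray(X)[:, 60] >= 0.5).astype(float)
        return np.stack([d, 1.0 - d], axis=1)


@pytest.fixture
def threshold_model():
    return SpeedThresholdModel()
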