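import numpy as np
import pytest

from flysummit import (
    align_to_death,
    assign_fictive_death,
    death_time_summary,
    detect_death,
)
from flysummit.core import Cohort, DataError, FlyRecord
from flysummit.mortality import END_GUARD_S

from conftest import make_trajectory


def _bout_speed(n, bouts):
    """Zero speed with [start, stop) bouts at the given mm/s level."""
    s = np.zeros(n)
    for start, stop, level in bouts:
        s[start:stop] = level
    return s


class TestDetectDeath:
    def test_last_sustained_bout_is_death(self):
        n = 3 * 7200  # 2 h
        speed = _bout_speed(n, [(100, 130, 1.0), (3000, 3030, 1.0)])
        det = detect_death(make_trajectory(speed=speed))
        assert det.frame == 3029
        assert det.reason == "ok"

    def test_short_bouts_ignored(self):
        # jitter-like 1-second blips do not count as walking
        n = 3 * 7200
        speed = _bout_speed(n, [(100, 130, 1.0), (5000, 5003, 1.0)])
        det = detect_death(make_trajectory(speed=speed))
        assert det.frame == 129

    def test_survivor_moving_to_end_is_none(self):
        n = 3 * 7200
        speed = _bout_speed(n, [(n - 200, n - 100, 1.0)])
        det = detect_death(make_trajectory(speed=speed))
        assert det.frame is None and det.reason == "moving_at_end"

    def test_all_zero_is_no_movement(self):
        det = detect_death(make_trajectory(speed=np.zeros(3 * 7200)))
        assert det.frame is None and det.reason == "no_movement"

    def test_invariant_to_appended_jitter(self):
        n = 3 * 7200
        speed = _bout_speed(n, [(3000, 3030, 1.0)])
        base = detect_death(make_trajectory(speed=speed))
        rng = np.random.default_rng(0)
        appended = np.concatenate([speed, rng.uniform(0, 0.3, 3 * 3600)])
        assert detect_death(make_trajectory(speed=appended)).frame == base.frame

    def test_recovers_generator_ground_truth(self, small_cohort):
        for traj, rec in small_cohort:
            if rec.fly_class != "zombie":
                continue
            det = detect_death(traj)
            assert det.frame is not None
            assert abs(det.frame - rec.death_frame) <= 2 * 60 * 3


class TestFictiveDeath:
    def test_single_zombie_pool_forces_draw(self, small_cohort):
        cohort = small_cohort.copy()
        # keep one zombie only
        keep = next(r.fly_id for r in cohort.records.values() if r.fly_class == "zombie")
        for rec in cohort.records.values():
            if rec.fly_class == "zombie" and rec.fly_id != keep:
                rec.outcome = 0  # exclude
        forced = cohort.records[keep].death_frame
        out = assign_fictive_death(cohort, np.random.default_rng(0))
        for rec in out.records.values():
            if rec.fly_class == "survivor":
                assert rec.death_frame == forced
                assert rec.death_source == "fictive"

    def test_deterministic_under_seed(self, small_cohort):
        a = assign_fictive_death(small_cohort, np.random.default_rng(7))
        b = assign_fictive_death(small_cohort, np.random.default_rng(7))
        for fid in a.records:
            assert a.records[fid].death_frame == b.records[fid].death_frame

    def test_resampled_mean_matches_pool(self):
        # resampling oracle: with many survivors the assigned-time mean
        # approaches the pool mean within 3 standard errors
        rng = np.random.default_rng(3)
        pool = rng.integers(100_000, 180_000, 345)
        n_frames = 10
        trajs, recs = [], {}
        for i, f in enumerate(pool):
            fid = f"z{i}"
            trajs.append(make_trajectory(n=n_frames, fly_id=fid))
            recs[fid] = FlyRecord(fid, survival=0, outcome=1, death_frame=int(f),
                                  death_source="manual")
        for i in range(1000):
            fid = f"s{i}"
            trajs.append(make_trajectory(n=n_frames, fly_id=fid))
            recs[fid] = FlyRecord(fid)
        cohort = Cohort(trajs, recs)
        out = assign_fictive_death(cohort, np.random.default_rng(11))
        assigned = [r.death_frame for r in out.records.values() if r.death_source == "fictive"]
        se = np.std(pool) / np.sqrt(len(assigned))
        assert abs(np.mean(assigned) - np.mean(pool)) < 3 * se

    def test_genotype_without_zombies_errors(self, small_cohort):
        cohort = small_cohort.copy()
        for rec in cohort.records.values():
            if rec.fly_class == "survivor":
                rec.genotype = "w1118"
        with pytest.raises(DataError, match="w1118"):
            assign_fictive_death(cohort, np.random.default_rng(0))


class TestAlignToDeath:
    def _identical_cohort(self, n_flies=4):
        n = 3 * 3600 * 3  # 3 h
        speed = _bout_speed(n, [(1000, 1100, 1.0)])
        trajs, recs = [], {}
        for i in range(n_flies):
            fid = f"z{i}"
            trajs.append(make_trajectory(speed=speed, fly_id=fid))
            recs[fid] = FlyRecord(fid, survival=0, outcome=1, death_frame=n // 2,
                                  death_source="manual")
        return Cohort(trajs, recs)

    def test_identical_flies_zero_width_bands(self):
        cohort = self._identical_cohort()
        al = align_to_death(cohort, window_h=0.25, n_boot=50,
                            rng=np.random.default_rng(0))
        lo = al.band_lo["speed"]["zombie"]
        hi = al.band_hi["speed"]["zombie"]
        np.testing.assert_allclose(hi - lo, 0.0, atol=1e-7)

    def test_mean_invariant_to_fly_order(self, small_cohort):
        al1 = align_to_death(small_cohort, window_h=1.0, n_boot=0)
        shuffled = small_cohort.copy()
        shuffled.trajectories = shuffled.trajectories[::-1]
        al2 = align_to_death(shuffled, window_h=1.0, n_boot=0)
        np.testing.assert_allclose(  # float32 accumulation order wiggle only
            al1.mean_speed["zombie"], al2.mean_speed["zombie"],
            rtol=1e-5, equal_nan=True,
        )

    def test_single_resample_band(self):
        cohort = self._identical_cohort()
        al = align_to_death(cohort, window_h=0.25, n_boot=1,
                            rng=np.random.default_rng(0))
        assert al.band_lo["speed"]["zombie"].shape == al.rel_time_h.shape

    def test_right_censored_fly_excluded(self):
        cohort = self._identical_cohort(n_flies=3)
        n = len(cohort.trajectories[0])
        cohort.records["z0"].death_frame = n - int(END_GUARD_S * 3) + 10
        al = align_to_death(cohort, window_h=0.25, n_boot=0)
        assert al.n_per_class["zombie"] == 2


class TestDeathSummary:
    def test_single_zombie(self):
        n = 3 * 3600 * 6
        traj = make_trajectory(n=n, zt0=5.0, fly_id="z0")
        death = 3 * 3600 * 5  # 5 h in -> ZT10
        cohort = Cohort(
            [traj],
            {"z0": FlyRecord("z0", survival=0, outcome=1, death_frame=death,
                             death_source="manual")},
        )
        s = death_time_summary(cohort)
        assert s["mean_zt"] == pytest.approx(10.0)
        assert s["p5_zt"] == pytest.approx(10.0)
        assert s["p95_zt"] == pytest.approx(10.0)

    def test_no_zombies_errors(self):
        traj = make_trajectory(n=10, fly_id="s0")
        cohort = Cohort([traj], {"s0": FlyRecord("s0")})
        with pytest.raises(DataError):
            death_time_summary(cohort)
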