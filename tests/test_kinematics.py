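import numpy as np
import pytest

from betareach import kinematics as kin, simulate as sim
from betareach.designs import TargetSpec


def _traj(x, y, fs=250.0, target_dir=0.0, distance=4.0, rotation=0.0):
    n = len(x)
    return sim.Trajectory(
        trial_id=0,
        set_index=0,
        t=np.arange(n) / fs,
        x=np.asarray(x, float),
        y=np.asarray(y, float),
        fs=fs,
        target=TargetSpec(target_dir, distance, 0.5, 0.0),
        rotation_deg=rotation,
        true_onset_s=np.nan,
        true_dir_error_deg=np.nan,
        true_mt_s=np.nan,
    )


class TestDerivatives:
    def test_linear_motion_constant_speed(self):
        t = np.arange(500) / 250.0
        tr = _traj(3.0 * t, np.zeros_like(t))
        *_, speed, accel, _ = kin.smooth_and_differentiate(tr)
        interior = slice(50, -50)
        assert np.allclose(speed[interior], 3.0, atol=0.02)
        assert np.max(np.abs(accel[interior])) < 0.5

    def test_minimum_jerk_peak_speed(self):
        # closed form: max speed of a minimum-jerk reach is 15/8 * D / T
        fs, D, T = 250.0, 4.0, 0.3
        t = np.arange(int(fs * 1.0)) / fs
        u = np.clip((t - 0.3) / T, 0.0, 1.0)
        s = D * (10 * u**3 - 15 * u**4 + 6 * u**5)
        tr = _traj(s, np.zeros_like(s))
        *_, speed, _, _ = kin.smooth_and_differentiate(tr)
        assert speed.max() == pytest.approx(1.875 * D / T, rel=0.02)

    def test_constant_position_zero_speed(self):
        tr = _traj(np.ones(300), np.ones(300))
        *_, speed, _, _ = kin.smooth_and_differentiate(tr)
        assert np.allclose(speed, 0.0, atol=1e-9)

    def test_too_short_rejected(self):
        tr = _traj(np.zeros(50), np.zeros(50))
        with pytest.raises(ValueError):
            kin.smooth_and_differentiate(tr)


class TestComputeKinematics:
    def test_straight_reach_zero_directional_error(self, mov_trajectories):
        # noise-free trajectory exactly along a known hand direction
        rec_errors = []
        for tr in mov_trajectories[:20]:
            r = kin.compute_kinematics(tr)
            assert r.valid
            rec_errors.append(r.directional_error_deg - tr.true_dir_error_deg)
        assert np.max(np.abs(rec_errors)) < 0.5

    def test_planted_rt_recovered_within_one_sample(self, mov_trajectories):
        errs = []
        for tr in mov_trajectories:
            r = kin.compute_kinematics(tr)
            errs.append(r.onset_s - tr.true_onset_s)
        assert np.max(np.abs(errs)) <= 1.0 / mov_trajectories[0].fs + 1e-9

    def test_no_movement_flagged_invalid(self):
        rng = np.random.default_rng(0)
        tr = _traj(rng.normal(0, 0.01, 400), rng.normal(0, 0.01, 400))
        r = kin.compute_kinematics(tr)
        assert not r.valid
        assert np.isnan(r.reaction_time_ms)

    def test_signed_error_follows_rotation_direction(self):
        # hand moves at +20 deg while a +30 deg rotation is imposed: the
        # cursor lands at +50, i.e. +50 deg error relative to a 0 deg target
        fs = 250.0
        t = np.arange(int(fs)) / fs
        u = np.clip((t - 0.3) / 0.3, 0, 1)
        s = 4 * (10 * u**3 - 15 * u**4 + 6 * u**5)
        ang = np.deg2rad(20.0)
        tr = _traj(s * np.cos(ang), s * np.sin(ang), rotation=30.0)
        r = kin.compute_kinematics(tr)
        assert r.directional_error_deg == pytest.approx(50.0, abs=0.5)


class TestHandPathArea:
    def test_out_and_back_line_zero(self):
        t = np.linspace(0, 1, 200)
        s = np.concatenate([np.linspace(0, 4, 100), np.linspace(4, 0, 100)])
        tr = _traj(s, np.zeros_like(s))
        assert kin.hand_path_area(tr) == pytest.approx(0.0, abs=1e-9)

    def test_circle_normalized_area_is_half_radius(self):
        th = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        tr = _traj(2 * np.cos(th), 2 * np.sin(th))
        assert kin.hand_path_area(tr) == pytest.approx(1.0, rel=1e-3)

    def test_scaling_path_scales_normalized_area(self):
        th = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        a1 = kin.hand_path_area(_traj(np.cos(th), np.sin(th)))
        a2 = kin.hand_path_area(_traj(2 * np.cos(th), 2 * np.sin(th)))
        assert a2 == pytest.approx(2 * a1, rel=1e-6)

    def test_degenerate_single_point(self):
        tr = _traj(np.zeros(300), np.zeros(300))
        assert kin.hand_path_area(tr) == 0.0


def _record(**kw):
    base = dict(
        trial_id=0,
        set_index=0,
        reaction_time_ms=300.0,
        movement_time_ms=280.0,
        out_and_back_time_ms=560.0,
        peak_velocity_cms=25.0,
        pv_time_s=0.4,
        directional_error_deg=2.0,
        abs_directional_error=2.0,
        hand_path_area_norm=0.1,
        onset_s=0.3,
        rotation_deg=0.0,
        valid=True,
    )
    base.update(kw)
    return kin.KinematicRecord(**base)


class TestAdaptationRate:
    def test_full_and_zero_adaptation(self):
        recs = [_record(directional_error_deg=0.0) for _ in range(10)]
        assert kin.adaptation_rate(recs, 30.0) == pytest.approx(100.0)
        recs = [_record(directional_error_deg=30.0) for _ in range(10)]
        assert kin.adaptation_rate(recs, 30.0) == pytest.approx(0.0)

    def test_printed_formula_value(self):
        recs = [_record(directional_error_deg=8.52) for _ in range(5)]
        assert kin.adaptation_rate(recs, 30.0) == pytest.approx(71.6)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(1)
        errs = rng.normal(8, 3, 20)
        a = kin.adaptation_rate(
            [_record(directional_error_deg=e) for e in errs], 30.0
        )
        b = kin.adaptation_rate(
            [_record(directional_error_deg=-e) for e in errs], -30.0
        )
        assert a == pytest.approx(b)

    def test_zero_rotation_rejected(self):
        with pytest.raises(ValueError):
            kin.adaptation_rate([_record()], 0.0)

    def test_block_rate_averages_rotated_sets_only(self):
        recs = []
        for s, rot, err in ((0, 0.0, 1.0), (1, 30.0, 15.0), (2, 20.0, 5.0)):
            recs += [
                _record(set_index=s, rotation_deg=rot, directional_error_deg=err)
                for _ in range(5)
            ]
        # set1: (1-15/30)*100 = 50, set2: (1-5/20)*100 = 75 -> mean 62.5
        assert kin.block_adaptation_rate(recs) == pytest.approx(62.5)


class TestClassifyCorrect:
    def _norms(self):
        return kin.BaselineNorms(
            mean={k: 10.0 for k in kin.CORRECTNESS_INDICES},
            sd={k: 2.0 for k in kin.CORRECTNESS_INDICES},
        )

    def test_at_baseline_mean_is_correct(self):
        r = _record(**{k: 10.0 for k in kin.CORRECTNESS_INDICES})
        flags, pct = kin.classify_correct([r], self._norms())
        assert flags[0] and pct == 100.0

    def test_two_sd_violation_is_incorrect(self):
        vals = {k: 10.0 for k in kin.CORRECTNESS_INDICES}
        vals["reaction_time_ms"] = 14.0  # mean + 2 SD
        flags, pct = kin.classify_correct([_record(**vals)], self._norms())
        assert not flags[0] and pct == 0.0

    def test_toy_set_with_three_violations(self):
        recs = []
        for i in range(10):
            vals = {k: 10.0 for k in kin.CORRECTNESS_INDICES}
            if i < 3:
                vals["hand_path_area_norm"] = 16.0
            recs.append(_record(**vals))
        flags, pct = kin.classify_correct(recs, self._norms())
        assert pct == pytest.approx(70.0)
        assert flags.sum() == 7

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        recs, recs_scaled = [], []
        for _ in range(30):
            vals = {k: float(rng.normal(10, 3)) for k in kin.CORRECTNESS_INDICES}
            recs.append(_record(**vals))
            recs_scaled.append(
                _record(**{k: 7.0 * v + 3.0 for k, v in vals.items()})
            )
        norms = self._norms()
        norms_scaled = kin.BaselineNorms(
            mean={k: 7.0 * v + 3.0 for k, v in norms.mean.items()},
            sd={k: 7.0 * v for k, v in norms.sd.items()},
        )
        f1, p1 = kin.classify_correct(recs, norms)
        f2, p2 = kin.classify_correct(recs_scaled, norms_scaled)
        assert np.array_equal(f1, f2) and p1 == p2


class TestOutlierExclusion:
    def test_identical_trials_none_excluded(self):
        recs = [_record() for _ in range(10)]
        assert kin.exclude_outliers(recs).all()

    def test_planted_outlier_excluded(self):
        rng = np.random.default_rng(3)
        recs = [
            _record(
                trial_id=i,
                **{k: float(rng.normal(10, 1)) for k in kin.CORRECTNESS_INDICES},
            )
            for i in range(50)
        ]
        recs[17] = _record(trial_id=17, reaction_time_ms=10 + 5 * 1.0)
        # rebuild record 17 with a 5-SD reaction time, others at the mean
        vals = {k: 10.0 for k in kin.CORRECTNESS_INDICES}
        vals["reaction_time_ms"] = 15.0
        recs[17] = _record(trial_id=17, **vals)
        keep = kin.exclude_outliers(recs, k=2.0)
        assert not keep[17]

    def test_infinite_k_excludes_nothing(self):
        rng = np.random.default_rng(4)
        recs = [
            _record(**{k: float(rng.normal(10, 2)) for k in kin.CORRECTNESS_INDICES})
            for _ in range(20)
        ]
        assert kin.exclude_outliers(recs, k=np.inf).all()

    def test_minimum_records_required(self):
        with pytest.raises(ValueError):
            kin.exclude_outliers([_record(), _record()])
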