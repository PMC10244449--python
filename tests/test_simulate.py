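import numpy as np
import pytest

from gstride.config import RunConfig
from gstride.ins import StanceMask, strapdown
from gstride.metrics import (compute_stride_params, segment_strides,
                             strides_from_trajectory, summarize)
from gstride.simulate import (CohortSimConfig, GaitProfile, NoiseModel,
                              random_profile, synth_cohort, synth_imu,
                              synth_trajectory)


def _truth_traj(truth):
    from gstride.ins import NavTrajectory
    return NavTrajectory(t=truth.t, pos=truth.pos, vel=truth.vel, quat=truth.quat)


def _true_mask(truth):
    return StanceMask.from_mask(truth.mask)


class TestTrajectory:
    def test_clearance_apex_is_exact(self):
        truth = synth_trajectory(GaitProfile(clearance_m=0.15))
        assert truth.pos[:, 2].max() == pytest.approx(0.15, abs=1e-9)

    def test_total_displacement_is_n_strides_times_sl(self):
        truth = synth_trajectory(GaitProfile(n_strides=10, stride_length_m=1.0,
                                             heading_deg=0.0))
        assert truth.pos[-1, 0] == pytest.approx(10.0, abs=1e-9)
        assert abs(truth.pos[-1, 1]) < 1e-9

    def test_velocity_zero_and_position_constant_during_stance(self):
        truth = synth_trajectory(GaitProfile(n_strides=3))
        assert np.abs(truth.vel[truth.mask]).max() < 1e-12
        for s, e in truth.stance_intervals:
            seg = truth.pos[s:e]
            assert np.ptp(seg[:, 0]) < 1e-12 and np.ptp(seg[:, 2]) < 1e-12

    def test_pitch_hits_event_angles(self):
        prof = GaitProfile(heel_strike_angle_deg=20.0, toe_off_angle_deg=-60.0)
        truth = synth_trajectory(prof)
        seg = truth.events[0]
        assert truth.pitch_deg[seg.hs] == pytest.approx(20.0, abs=1e-9)
        assert truth.pitch_deg[seg.to] == pytest.approx(-60.0, abs=1e-9)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            synth_trajectory(GaitProfile(swing_pct=30.0))  # phases sum != 100
        with pytest.raises(ValueError):
            synth_trajectory(GaitProfile(n_strides=0))

    def test_realized_phases_within_one_sample_of_request(self):
        prof = GaitProfile()
        truth = synth_trajectory(prof)
        dt_pct = 100.0 / (prof.gct_s * prof.sample_rate_hz)
        for name in ("loading_pct", "footflat_pct", "pushing_pct"):
            assert abs(truth.realized[name] - getattr(prof, name)) < 1.5 * dt_pct
        # swing rounds to an even sample count: allow two samples
        assert abs(truth.realized["swing_pct"] - prof.swing_pct) < 2.5 * dt_pct


class TestClosure:
    """Gait metrics applied to the exact trajectory recover the profile."""

    @pytest.mark.parametrize("seed", range(6))
    def test_metrics_recover_realized_profile(self, seed):
        rng = np.random.default_rng(seed)
        prof = random_profile(rng, n_strides=8)
        truth = synth_trajectory(prof)
        traj, mask = _truth_traj(truth), _true_mask(truth)
        gyro = truth.omega_body
        strides = strides_from_trajectory(traj, mask, gyro, RunConfig())
        assert len(strides) == len(truth.true_strides)
        summary = summarize(strides)
        rz = truth.realized
        for key in ("gct_s", "swing_pct", "stride_length_m", "clearance_m",
                    "heel_strike_angle_deg", "toe_off_angle_deg",
                    "step_speed_mps"):
            assert summary.means[key] == pytest.approx(rz[key], rel=5e-3), key
        # threshold-based foot-flat detection quantizes the stance
        # sub-phase boundaries to the sample grid
        dt_pct = 100.0 / (rz["gct_s"] * prof.sample_rate_hz)
        for key in ("loading_pct", "footflat_pct", "pushing_pct"):
            assert summary.means[key] == pytest.approx(rz[key],
                                                       abs=2.5 * dt_pct), key

    def test_true_stride_params_recompute_from_true_trajectory(self):
        truth = synth_trajectory(GaitProfile(n_strides=5))
        cfg = RunConfig()
        for seg, tr in zip(truth.events, truth.true_strides):
            est = compute_stride_params(_truth_traj(truth), seg, cfg)
            assert est.gct_s == pytest.approx(tr.gct_s, abs=1e-12)
            assert est.stride_length_m == pytest.approx(tr.stride_length_m, rel=1e-9)
            assert est.clearance_m == pytest.approx(tr.clearance_m, rel=5e-3)
            assert est.path3d_m == pytest.approx(tr.path3d_m, rel=5e-3)


class TestImuSynthesis:
    def test_stationary_noise_free_signal_is_pure_gravity(self):
        truth = synth_trajectory(GaitProfile(n_strides=1, lead_still_s=2.0))
        rec = synth_imu(truth, NoiseModel(0, 0, 0, 0))
        still = truth.mask & (np.abs(truth.pitch_deg) < 1e-12)
        np.testing.assert_allclose(
            np.linalg.norm(rec.accel[still], axis=1), 9.81, atol=1e-9)
        np.testing.assert_allclose(rec.gyro[still], 0.0, atol=1e-12)

    def test_same_seed_identical_recordings(self):
        truth = synth_trajectory(GaitProfile(n_strides=2))
        a = synth_imu(truth, NoiseModel(seed=42))
        b = synth_imu(truth, NoiseModel(seed=42))
        np.testing.assert_array_equal(a.accel, b.accel)
        np.testing.assert_array_equal(a.gyro, b.gyro)
        c = synth_imu(truth, NoiseModel(seed=43))
        assert not np.array_equal(a.accel, c.accel)

    def test_noise_free_strapdown_closes_at_high_rate(self):
        """Integrating the exact IMU signal reproduces the trajectory."""
        prof = GaitProfile(n_strides=10, stride_length_m=1.0,
                           sample_rate_hz=1000.0, lead_still_s=0.5,
                           trail_still_s=0.5)
        truth = synth_trajectory(prof)
        rec = synth_imu(truth, NoiseModel(0, 0, 0, 0))
        from scipy.spatial.transform import Rotation
        traj = strapdown(rec, Rotation.from_quat(truth.quat[0]), gravity=9.81)
        err = np.linalg.norm(traj.pos[-1] - truth.pos[-1])
        assert err < 0.01  # < 1 cm after 10 m walked

    def test_too_short_truth_rejected(self):
        truth = synth_trajectory(GaitProfile(n_strides=1))
        truth.t = truth.t[:2]
        with pytest.raises(ValueError):
            synth_imu(truth, NoiseModel())


class TestCohort:
    def test_group_counts_and_labels(self):
        df = synth_cohort(CohortSimConfig(n_fallers=86, n_nonfallers=77, seed=0))
        assert len(df) == 163
        assert int(df["FALLS"].sum()) == 86

    def test_same_seed_identical_table(self):
        a = synth_cohort(CohortSimConfig(seed=9))
        b = synth_cohort(CohortSimConfig(seed=9))
        assert a.equals(b)

    def test_large_sample_mean_matches_configured_mean(self):
        cfg = CohortSimConfig(n_fallers=10_000, n_nonfallers=1, seed=5)
        df = synth_cohort(cfg)
        v = df.loc[df.FALLS, "Velocity (m/s)"]
        se = cfg.variables["Velocity (m/s)"].sd_faller / np.sqrt(len(v))
        assert abs(v.mean() - 0.6) < 3 * se

    def test_scale_ranges_respected(self, cohort_df):
        assert cohort_df["FES1"].between(7, 28).all()
        assert cohort_df["SPPB_Total"].between(0, 12).all()
        assert cohort_df["GDS"].between(1, 7).all()
        assert (cohort_df["Age"] >= 70).all()

    def test_latent_factor_induces_expected_correlation_signs(self, cohort_df):
        sub = cohort_df[["Speed_4m_walk", "TUG", "SPPB_Total", "FES1",
                         "Velocity (m/s)"]].corr(method="spearman")
        assert sub.loc["Speed_4m_walk", "TUG"] < 0
        assert sub.loc["Speed_4m_walk", "SPPB_Total"] > 0
        assert sub.loc["Speed_4m_walk", "FES1"] < 0
        assert sub.loc["Speed_4m_walk", "Velocity (m/s)"] > 0

    def test_invalid_group_size_rejected(self):
        with pytest.raises(ValueError):
            CohortSimConfig(n_fallers=0).validate()


class TestSegmentProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_segments_ordered_and_phase_sum_exact(self, seed):
        rng = np.random.default_rng(100 + seed)
        prof = random_profile(rng, n_strides=6)
        truth = synth_trajectory(prof)
        segs = segment_strides(_truth_traj(truth), _true_mask(truth),
                               truth.omega_body, RunConfig())
        prev_end = -1
        for seg in segs:
            assert seg.hs > prev_end - 1
            assert seg.hs <= seg.ff_start <= seg.ff_end <= seg.to < seg.next_hs
            prev_end = seg.next_hs
            p = compute_stride_params(_truth_traj(truth), seg, RunConfig())
            total = p.swing_pct + p.loading_pct + p.footflat_pct + p.pushing_pct
            assert total == pytest.approx(100.0, abs=1e-6)
            assert p.path3d_m >= p.path2d_m >= p.stride_length_m >= 0
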