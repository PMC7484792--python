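"""Power equations, propulsion window, work integrals and feature extraction."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from footpower import power_features as pf
from footpower.errors import DegenerateDataError
from footpower.foot_mechanics import ContactKinetics, SegmentKinematics
from footpower.inverse_dynamics import JointLoads
from footpower.pipeline import process_trial
from footpower.synthetic_data import SyntheticTrialSpec, generate_trial


def _kin(T=10, fs=150.0, v=(0, 0, 0), w=(0, 0, 0), com=(0, 0, 0),
         joint=None):
    com = np.tile(np.asarray(com, float), (T, 1))
    joint = com.copy() if joint is None else np.tile(np.asarray(joint, float), (T, 1))
    return SegmentKinematics(
        segment="seg", sample_rate=fs, rotation=np.tile(np.eye(3), (T, 1, 1)),
        com_position=com, com_velocity=np.tile(np.asarray(v, float), (T, 1)),
        angular_velocity=np.tile(np.asarray(w, float), (T, 1)),
        joint_point=joint,
    )


def _loads(T=10, f=(0, 0, 0), m=(0, 0, 0)):
    return JointLoads(force=np.tile(np.asarray(f, float), (T, 1)),
                      moment=np.tile(np.asarray(m, float), (T, 1)))


def _contact(T=10, grf=(0, 0, 0), cop=(0, 0, 0), free_z=0.0, valid=True):
    free = np.zeros((T, 3))
    free[:, 2] = free_z
    return ContactKinetics(cop=np.tile(np.asarray(cop, float), (T, 1)),
                           free_moment=free,
                           grf=np.tile(np.asarray(grf, float), (T, 1)),
                           valid=np.full(T, valid), threshold=50.0)


class TestAnklePower:
    def test_zero_loads_zero_power(self):
        p = pf.ankle_power(_loads(), _kin(), _kin())
        np.testing.assert_allclose(p, 0.0)

    def test_dot_product_definition(self):
        # F=(10,0,0) with 0.2 m/s relative translation: 2 W; M=(0,5,0) with
        # 1 rad/s relative rotation: 5 W; total 7 W
        foot = _kin(v=(0.2, 0, 0), w=(0, 1, 0))
        shank = _kin()
        p = pf.ankle_power(_loads(f=(10, 0, 0), m=(0, 5, 0)), foot, shank)
        np.testing.assert_allclose(p, 7.0)

    def test_welded_segments_transfer_no_power(self):
        kin = _kin(v=(0.4, 0.2, 0.1), w=(1.0, -0.5, 2.0), com=(0.1, 0, 0.2),
                   joint=(0.15, 0, 0.1))
        p = pf.ankle_power(_loads(f=(30, 10, -40), m=(5, 2, 1)), kin,
                           dataclasses.replace(kin))
        np.testing.assert_allclose(p, 0.0, atol=1e-12)

    def test_linearity_in_loads(self, noiseless_trial):
        from footpower.evaluation import _recovered_mechanics

        trial, _ = noiseless_trial
        _, foot_kin, shank_kin, contact, _, loads = _recovered_mechanics(trial)
        p1 = pf.ankle_power(loads, foot_kin, shank_kin)
        double = JointLoads(force=2 * loads.force, moment=2 * loads.moment)
        np.testing.assert_allclose(pf.ankle_power(double, foot_kin, shank_kin),
                                   2 * p1, rtol=1e-12)


class TestFootPower:
    def test_no_loads_no_power(self):
        np.testing.assert_allclose(pf.foot_power(_contact(), _kin()), 0.0)

    def test_spinning_foot_worked_example(self):
        # stationary COM, w=(0,0,1), COP offset R=(0.1,0,0), GRF=(0,100,0):
        # GRF . (w x R) = 100 * 0.1 = 10 W; plus M_free . w = 3 W
        foot = _kin(w=(0, 0, 1))
        contact = _contact(grf=(0, 100, 0), cop=(0.1, 0, 0), free_z=3.0)
        np.testing.assert_allclose(pf.foot_power(contact, foot), 13.0)

    def test_foot_at_rest_absorbs_nothing(self):
        contact = _contact(grf=(120, -40, 800), cop=(0.1, 0.02, 0), free_z=7.0)
        np.testing.assert_allclose(pf.foot_power(contact, _kin()), 0.0)

    def test_invalid_contact_samples_forced_to_zero(self):
        foot = _kin(v=(0.3, 0, 0))
        contact = _contact(grf=(100, 0, 0), valid=False)
        np.testing.assert_allclose(pf.foot_power(contact, foot), 0.0)


class TestSumPower:
    def test_samplewise_sum_and_cancellation(self):
        a = np.array([1.0, -2.0, 3.0])
        np.testing.assert_allclose(pf.sum_power(a, np.array([2.0, 5.0, -1.0])),
                                   [3.0, 3.0, 2.0])
        np.testing.assert_allclose(pf.sum_power(a, -a), 0.0)

    def test_linearity(self, rng):
        a, b, c = rng.normal(size=(3, 50))
        np.testing.assert_allclose(pf.sum_power(a + b, c),
                                   pf.sum_power(a, c) + b)


class TestPropulsionWindow:
    def test_last_crossing_starts_window(self):
        t = np.linspace(0, 1, 101)
        p = np.where(t < 0.7, -np.sin(np.pi * t / 0.7), np.sin(np.pi * (t - 0.7) / 0.3))
        win = pf.propulsion_window(p)
        assert win.start == np.flatnonzero((p[:-1] < 0) & (p[1:] >= 0))[-1] + 1
        assert abs(t[win.start] - 0.7) < 0.02
        assert win.stop == p.size

    def test_strictly_positive_falls_back_to_second_half(self):
        p = np.full(100, 2.0)
        with pytest.warns(UserWarning, match="final 50%"):
            win = pf.propulsion_window(p)
        assert (win.start, win.stop) == (50, 100)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pf.propulsion_window(np.zeros(40))

    def test_peak_extraction_inside_window(self):
        t = np.linspace(0, 1, 201)
        p = -np.sin(2 * np.pi * t)        # negative first half, positive second
        win = pf.propulsion_window(p)
        assert np.max(p[win]) == pytest.approx(1.0, abs=1e-3)


class TestWork:
    def test_constant_power(self):
        t = np.linspace(0, 1, 101)
        p = np.ones_like(t)
        assert pf.work(p, t, sign="positive") == pytest.approx(1.0)
        assert pf.work(p, t, sign="negative") == 0.0

    def test_full_period_sine_symmetry(self):
        t = np.linspace(0, 1, 1001)
        p = np.sin(2 * np.pi * t)
        wp = pf.work(p, t, sign="positive")
        wn = pf.work(p, t, sign="negative")
        assert wp == pytest.approx(-wn, rel=1e-6)
        assert pf.work(p, t) == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp_closed_form(self):
        t = np.linspace(0, 1, 101)        # kink at t=0.5 falls on a node
        p = t - 0.5
        assert pf.work(p, t) == pytest.approx(0.0, abs=1e-12)
        assert pf.work(p, t, sign="positive") == pytest.approx(0.125)
        assert pf.work(p, t, sign="negative") == pytest.approx(-0.125)

    def test_empty_window_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert pf.work(np.arange(5.0), np.arange(5.0),
                           window=slice(3, 3)) == 0.0

    @given(arrays(np.float64, 64, elements=st.floats(-100, 100)))
    def test_decomposition_identity(self, p):
        t = np.linspace(0, 0.63, p.size)
        wp = pf.work(p, t, sign="positive")
        wn = pf.work(p, t, sign="negative")
        assert wp >= 0.0 and wn <= 0.0
        assert wp + wn == pytest.approx(pf.work(p, t), abs=1e-9)


class TestStanceFeatures:
    def test_analytic_profile_closed_forms(self):
        # p_ankle = -sin(2 pi t) on [0,1]: positive burst in the second half,
        # W+ = -W- = 1/pi; p_foot = 0 throughout
        t = np.linspace(0, 1, 2001)
        pa = -np.sin(2 * np.pi * t)
        ps = pf.PowerSeries(t, pa, np.zeros_like(t), pa)
        feats = pf.stance_features(ps)
        assert feats["P_ankle"] == pytest.approx(1.0, rel=1e-3)
        assert feats["P_sum"] == pytest.approx(1.0, rel=1e-3)
        assert feats["P_foot"] == pytest.approx(0.0, abs=1e-12)
        assert feats["Wpos_ankle"] == pytest.approx(1 / np.pi, rel=1e-3)
        assert feats["Wneg_ankle"] == pytest.approx(-1 / np.pi, rel=1e-3)
        assert feats["Wpos_foot"] == 0.0 and feats["Wneg_foot"] == 0.0

    def test_work_decomposition_identity_per_feature(self, noiseless_trial):
        trial, _ = noiseless_trial
        ps = process_trial(trial)
        for series in (ps.p_ankle, ps.p_foot, ps.p_sum):
            wp = pf.work(series, ps.time, sign="positive")
            wn = pf.work(series, ps.time, sign="negative")
            assert wp + wn == pytest.approx(pf.work(series, ps.time), abs=1e-9)

    def test_psum_identity_exact(self, noiseless_trial):
        trial, _ = noiseless_trial
        ps = process_trial(trial)
        np.testing.assert_array_equal(ps.p_sum, ps.p_ankle + ps.p_foot)

    def test_identical_trials_average_to_themselves(self, noiseless_trial):
        trial, _ = noiseless_trial
        ps = process_trial(trial)
        rec = pf.extract_features([ps, ps, ps], "s", "comfortable", 1.23)
        single = pf.stance_features(ps)
        for name in pf.FEATURE_NAMES:
            assert rec.features[name] == pytest.approx(single[name])

    def test_too_few_trials_excluded_with_reason(self, noiseless_trial):
        trial, _ = noiseless_trial
        ps = process_trial(trial)
        with pytest.raises(DegenerateDataError, match="minimum"):
            pf.extract_features([ps], "s", "comfortable", 1.23, min_trials=3)

    def test_features_against_dense_ground_truth(self, noiseless_trial):
        trial, gt = noiseless_trial
        feats = pf.stance_features(process_trial(trial))
        floor = 0.01 * max(abs(v) for v in gt.features.values())
        for name, ref in gt.features.items():
            assert abs(feats[name] - ref) <= 0.01 * max(abs(ref), floor), name

    def test_discretization_robustness(self):
        # the same motion sampled at 150 vs 600 Hz markers: features < 1% apart
        feats = {}
        for rate in (150.0, 600.0):
            spec = SyntheticTrialSpec(seed=5, marker_rate=rate,
                                      marker_noise_sd=0.0, force_noise_sd=0.0)
            trial, _ = generate_trial(spec)
            feats[rate] = pf.stance_features(process_trial(trial))
        scale = max(abs(v) for v in feats[600.0].values())
        for name in pf.FEATURE_NAMES:
            a, b = feats[150.0][name], feats[600.0][name]
            assert abs(a - b) <= 0.01 * max(abs(b), 0.01 * scale), name

    def test_mass_normalization_scales_series(self, noiseless_trial):
        trial, _ = noiseless_trial
        ps = process_trial(trial)
        per_kg = ps.per_kg(trial.subject.mass)
        np.testing.assert_allclose(per_kg.p_sum * trial.subject.mass, ps.p_sum)
        assert per_kg.normalized_by_mass
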