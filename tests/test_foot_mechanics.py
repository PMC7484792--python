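"""Rigid pose estimation, angular velocity, COP/free moment, inertia tables."""

import csv
from importlib import resources

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from footpower import foot_mechanics as fm
from footpower.errors import ConfigError, GeometryError, NoContactError
from footpower.gait_io import ForcePlateRecord, MarkerTrajectories


def _make_markers(positions, labels, fs=150.0):
    return MarkerTrajectories(sample_rate=fs, labels=list(labels),
                              positions=positions,
                              time=np.arange(positions.shape[0]) / fs)


LOCAL = {
    "a": np.array([0.1, 0.0, 0.0]),
    "b": np.array([0.0, 0.08, 0.0]),
    "c": np.array([-0.05, -0.03, 0.06]),
    "d": np.array([0.02, 0.01, -0.04]),
}


def _segdef(**kw):
    kw.setdefault("joint_local", np.array([0.0, 0.0, 0.05]))
    return fm.SegmentDefinition(name="seg", local_positions=dict(LOCAL), **kw)


def _rigid_series(R_list, t_list):
    pos = np.stack([
        np.stack([R @ LOCAL[lab] + t for lab in LOCAL]) for R, t in
        zip(R_list, t_list)
    ])
    return _make_markers(pos, LOCAL.keys())


class TestSegmentPose:
    def test_translation_equivariance(self, rng):
        T = 5
        Rs = [np.eye(3)] * T
        ts = [np.array([0.3, 0.1, 0.2])] * T
        base = fm.segment_pose(_rigid_series(Rs, ts), _segdef())
        shift = np.array([0.1, 0.0, 0.0])
        moved = fm.segment_pose(_rigid_series(Rs, [t + shift for t in ts]),
                                _segdef())
        np.testing.assert_allclose(moved.rotation, base.rotation, atol=1e-12)
        np.testing.assert_allclose(moved.com_position,
                                   base.com_position + shift, atol=1e-12)

    def test_rotation_equivariance(self, rng):
        T = 5
        Q = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Rs = [Rotation.random(random_state=7).as_matrix()] * T
        ts = [np.array([0.2, -0.1, 0.3])] * T
        base = fm.segment_pose(_rigid_series(Rs, ts), _segdef())
        rot = fm.segment_pose(
            _rigid_series([Q @ R for R in Rs], [Q @ t for t in ts]), _segdef())
        np.testing.assert_allclose(rot.rotation, Q @ base.rotation, atol=1e-10)
        np.testing.assert_allclose(
            rot.com_position, base.com_position @ Q.T, atol=1e-10)

    def test_random_rigid_transform_equivariance_property(self, rng):
        T = 4
        Rs = [Rotation.random(random_state=int(s)).as_matrix()
              for s in rng.integers(0, 1000, T)]
        ts = [rng.normal(0, 0.3, 3) for _ in range(T)]
        base = fm.segment_pose(_rigid_series(Rs, ts), _segdef())
        for k in range(10):
            Q = Rotation.random(random_state=100 + k).as_matrix()
            d = rng.normal(0, 0.5, 3)
            moved = fm.segment_pose(
                _rigid_series([Q @ R for R in Rs],
                              [Q @ t + d for t in ts]), _segdef())
            np.testing.assert_allclose(moved.rotation,
                                       np.einsum("ij,tjk->tik", Q, base.rotation),
                                       atol=1e-9)
            np.testing.assert_allclose(moved.com_position,
                                       base.com_position @ Q.T + d, atol=1e-9)

    def test_rotations_are_orthonormal(self, noiseless_trial):
        from footpower.preprocess import segment_stance
        from footpower.synthetic_data import foot_segment_def

        trial, _ = noiseless_trial
        stance = segment_stance(trial)
        kin = fm.segment_pose(stance.markers_filtered, foot_segment_def())
        RtR = np.einsum("tij,tik->tjk", kin.rotation, kin.rotation)
        assert np.max(np.abs(RtR - np.eye(3))) < 1e-6
        assert np.allclose(np.linalg.det(kin.rotation), 1.0, atol=1e-9)

    def test_noisy_markers_recover_pose_within_tolerance(self, rng):
        # 1 mm marker noise on a known rigid motion of a well-spread
        # six-marker cluster: mean orientation error < 0.5 deg, mean COM
        # error < 2 mm
        local = {
            "px": np.array([0.12, 0.0, 0.0]), "mx": np.array([-0.12, 0.0, 0.0]),
            "py": np.array([0.0, 0.10, 0.02]), "my": np.array([0.0, -0.10, -0.02]),
            "pz": np.array([0.02, 0.0, 0.11]), "mz": np.array([-0.02, 0.0, -0.11]),
        }
        seg = fm.SegmentDefinition(name="cluster", local_positions=local,
                                   joint_local=(0.0, 0.0, 0.05))
        T = 40
        angles = 0.3 * np.sin(np.linspace(0, 2, T))
        Rs = [Rotation.from_rotvec(a * np.array([0.0, 1.0, 0.0])).as_matrix()
              for a in angles]
        ts = [np.array([0.01 * k, 0.0, 0.1]) for k in range(T)]
        pos = np.stack([
            np.stack([R @ local[lab] + t for lab in local])
            for R, t in zip(Rs, ts)
        ])
        pos += rng.normal(0, 0.001, pos.shape)
        kin = fm.segment_pose(_make_markers(pos, local.keys()), seg)
        rot_err = [Rotation.from_matrix(Rs[k].T @ kin.rotation[k]).magnitude()
                   for k in range(T)]
        com_err = np.linalg.norm(kin.com_position - np.stack(ts), axis=1)
        assert np.degrees(np.mean(rot_err)) < 0.5
        assert np.mean(com_err) < 0.002

    def test_collinear_markers_rejected(self):
        local = {"a": (0.0, 0, 0), "b": (0.1, 0, 0), "c": (0.2, 0, 0)}
        seg = fm.SegmentDefinition(name="bad", local_positions=local,
                                   joint_local=(0, 0, 0))
        pos = np.tile(np.array([[0.0, 0, 0], [0.1, 0, 0], [0.2, 0, 0]]),
                      (4, 1, 1))
        with pytest.raises(GeometryError, match="collinear"):
            fm.segment_pose(_make_markers(pos, local.keys()), seg)


class TestAngularVelocity:
    def test_constant_rotation_gives_zero(self):
        R = np.tile(Rotation.from_euler("x", 0.4).as_matrix(), (10, 1, 1))
        np.testing.assert_allclose(fm.angular_velocity(R, 150.0), 0.0,
                                   atol=1e-12)

    def test_uniform_spin_about_z(self):
        # sampled densely enough that the central-difference bias (w dt)^2/6
        # sits below the 1e-6 assertion
        fs, w = 3000.0, 2.0
        t = np.arange(60) / fs
        R = Rotation.from_rotvec(np.outer(w * t, [0.0, 0.0, 1.0])).as_matrix()
        omega = fm.angular_velocity(R, fs)
        np.testing.assert_allclose(
            omega[1:-1], np.tile([0.0, 0.0, w], (len(t) - 2, 1)), atol=1e-6)

    def test_matches_quaternion_log_oracle(self, rng):
        # independent oracle: central difference of the relative quaternion log
        fs = 1000.0
        t = np.arange(50) / fs
        worst = 0.0
        for _ in range(100):
            a1, a2 = rng.uniform(0.05, 0.3, 2)
            f1, f2 = rng.uniform(0.5, 2.0, 2)
            p1, p2 = rng.uniform(0, 2 * np.pi, 2)
            th1 = a1 * np.sin(2 * np.pi * f1 * t + p1)
            th2 = a2 * np.sin(2 * np.pi * f2 * t + p2)
            rot = (Rotation.from_rotvec(np.outer(th1, [0.0, 1.0, 0.0]))
                   * Rotation.from_rotvec(np.outer(th2, [0.0, 0.0, 1.0])))
            R = rot.as_matrix()
            omega = fm.angular_velocity(R, fs)
            q_oracle = np.stack([
                (rot[k + 1] * rot[k - 1].inv()).as_rotvec() * fs / 2.0
                for k in range(1, len(t) - 1)
            ])
            worst = max(worst, float(np.max(np.abs(omega[1:-1] - q_oracle))))
        assert worst < 1e-4


class TestDifferentiate:
    def test_linear_ramp(self):
        y = 3.0 * np.arange(20) / 150.0
        np.testing.assert_allclose(fm.differentiate(y, 150.0), 3.0, atol=1e-9)

    def test_constant_is_zero(self):
        np.testing.assert_allclose(
            fm.differentiate(np.full(10, 4.2), 150.0), 0.0, atol=1e-12)

    def test_sine_derivative_accuracy(self):
        fs = 150.0
        t = np.arange(int(fs)) / fs
        d = fm.differentiate(np.sin(2 * np.pi * t), fs)
        err = np.abs(d[1:-1] - 2 * np.pi * np.cos(2 * np.pi * t[1:-1]))
        assert np.max(err) < 1e-2


class TestCopAndFreeMoment:
    def _record(self, force, moment):
        T = force.shape[0]
        return ForcePlateRecord(sample_rate=300.0, force=force, moment_about_origin=moment,
                                plate_origin=np.zeros(3))

    def test_centred_load_cop_at_origin(self):
        T = 5
        rec = self._record(np.tile([0.0, 0, 500], (T, 1)), np.zeros((T, 3)))
        c = fm.cop_and_free_moment(rec, 50.0)
        np.testing.assert_allclose(c.cop, 0.0, atol=1e-12)
        np.testing.assert_allclose(c.free_moment, 0.0, atol=1e-12)

    def test_cop_x_from_my(self):
        T = 4
        moment = np.tile([0.0, -50.0, 0.0], (T, 1))
        rec = self._record(np.tile([0.0, 0, 500], (T, 1)), moment)
        c = fm.cop_and_free_moment(rec, 50.0)
        np.testing.assert_allclose(c.cop[:, 0], 0.1, atol=1e-12)

    def test_pure_torsion_is_free_moment(self):
        T = 4
        moment = np.tile([0.0, 0.0, 10.0], (T, 1))
        rec = self._record(np.tile([0.0, 0, 500], (T, 1)), moment)
        c = fm.cop_and_free_moment(rec, 50.0)
        np.testing.assert_allclose(c.free_moment, [[0, 0, 10.0]] * T,
                                   atol=1e-12)
        assert np.allclose(c.free_moment[:, :2], 0.0)   # strictly vertical

    def test_no_contact_error(self):
        rec = self._record(np.zeros((5, 3)), np.zeros((5, 3)))
        with pytest.raises(NoContactError):
            fm.cop_and_free_moment(rec, 50.0)

    def test_cop_on_surface_and_held_below_threshold(self, noiseless_trial):
        trial, _ = noiseless_trial
        c = fm.cop_and_free_moment(trial.forceplate, 50.0)
        np.testing.assert_allclose(c.cop[:, 2], 0.0, atol=1e-12)
        first = np.flatnonzero(c.valid)[0]
        np.testing.assert_allclose(
            c.cop[:first], np.tile(c.cop[first], (first, 1)), atol=1e-12)


class TestInertialParams:
    def _table_value(self, segment, column):
        with resources.files("footpower.data").joinpath(
                "anthropometry.csv").open() as fh:
            for row in csv.DictReader(fh):
                if row["table"] == "de_leva_male" and row["segment"] == segment:
                    return float(row[column])
        raise AssertionError("table entry missing")

    def test_foot_mass_matches_bundled_table(self):
        frac = self._table_value("foot", "mass_fraction")
        params = fm.foot_inertial(68.4, 0.26)
        assert params.mass == pytest.approx(68.4 * frac, rel=1e-12)
        assert params.com_offset == pytest.approx(
            self._table_value("foot", "com_fraction"))

    def test_zero_length_rejected(self):
        with pytest.raises(GeometryError):
            fm.foot_inertial(68.4, 0.0)

    def test_mass_proportionality(self):
        a = fm.foot_inertial(60.0, 0.25)
        b = fm.foot_inertial(120.0, 0.25)
        assert b.mass == pytest.approx(2 * a.mass)
        np.testing.assert_allclose(b.moi, 2 * a.moi)

    def test_unknown_table_rejected(self):
        with pytest.raises(ConfigError, match="de_leva"):
            fm.segment_inertial("foot", 70.0, 0.25, table="nonexistent")
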