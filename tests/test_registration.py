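import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import cartbox as cb
from cartbox.errors import (DegenerateConfigurationError,
                            InsufficientDataError)
from cartbox.phantom import inject_outflow_outliers, random_rigid_transform
from cartbox.registration import weighted_rigid_fit

from conftest import planar_patch


def rotation_angle_deg(R):
    return np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1)))


def make_landmarks(scale=30.0):
    return {"apex": np.array([0.0, 0.0, -scale]),
            "left_ostium": np.array([0.0, scale, scale]),
            "right_ostium": np.array([scale, 0.0, scale])}


class TestLandmarkRegister:
    def test_identity_on_exact_match(self):
        lm = make_landmarks()
        T = cb.landmark_register(lm, lm)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(T.translation, 0.0, atol=1e-12)

    def test_recovers_random_rigid_transform(self):
        """Construct-and-invert: dst = R src + t must be recovered to
        machine precision."""
        rng = np.random.default_rng(5)
        src = make_landmarks()
        for _ in range(25):
            ang = rng.uniform(-30, 30, 3)
            R = Rotation.from_euler("xyz", ang, degrees=True).as_matrix()
            t = rng.uniform(-50, 50, 3)
            dst = {k: R @ v + t for k, v in src.items()}
            T = cb.landmark_register(src, dst)
            assert np.abs(T.rotation - R).max() < 1e-9
            assert np.abs(T.translation - t).max() < 1e-9

    def test_apex_weight_shrinks_apex_residual(self):
        """With one ostium perturbed by 4 mm, a 10x apex weight leaves a
        strictly smaller apex residual than equal weights."""
        src = make_landmarks()
        dst = {k: v.copy() for k, v in src.items()}
        dst["right_ostium"] += np.array([0.0, 4.0, 0.0])

        def apex_residual(apex_weight):
            T = cb.landmark_register(src, dst,
                                     {"apex": apex_weight,
                                      "left_ostium": 1.0,
                                      "right_ostium": 1.0})
            return np.linalg.norm(T.apply(src["apex"]) - dst["apex"])

        assert apex_residual(10.0) < apex_residual(1.0)

    def test_equivariance_under_prerotation(self):
        """Rotating both landmark sets by Q conjugates the result by Q."""
        rng = np.random.default_rng(8)
        src = make_landmarks()
        dst = {k: v + rng.normal(0, 2, 3) for k, v in src.items()}
        T = cb.landmark_register(src, dst)
        Q = Rotation.random(random_state=rng).as_matrix()
        Tq = cb.landmark_register({k: Q @ v for k, v in src.items()},
                                  {k: Q @ v for k, v in dst.items()})
        assert np.abs(Tq.rotation - Q @ T.rotation @ Q.T).max() < 1e-9
        assert np.abs(Tq.translation - Q @ T.translation).max() < 1e-9

    def test_collinear_landmarks_rejected(self):
        src = {"apex": np.zeros(3), "left_ostium": np.array([0, 0, 10.0]),
               "right_ostium": np.array([0, 0, 20.0])}
        with pytest.raises(DegenerateConfigurationError):
            cb.landmark_register(src, src)

    def test_too_few_landmarks_rejected(self):
        lm = make_landmarks()
        del lm["apex"]
        with pytest.raises(InsufficientDataError):
            cb.landmark_register(lm, lm)

    def test_weighted_fit_requires_positive_weights(self):
        src = np.eye(3) * 10
        with pytest.raises(Exception):
            weighted_rigid_fit(src, src, np.array([1.0, -1.0, 1.0]))


class TestRegistrationError:
    def test_points_on_surface_zero(self, default_phantom):
        spec, endo, _, _, truth = default_phantom
        clean = cb.PhantomSpec(noise_sigma=0.0, seed=1)
        e2, _, _, t2 = cb.make_lv(clean)
        ds = cb.sample_emm(e2, t2, clean)
        mean, sd, per = cb.registration_error(ds, e2, t2.transform)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)
        assert len(per) == len(ds)

    def test_uniform_offset_planar(self, patch):
        pts = [cb.EMMPoint(id=i, position=[20.0 + 10 * i, 50.0, 3.0])
               for i in range(5)]
        ds = cb.EMMDataset(pts)
        mean, sd, _ = cb.registration_error(ds, patch)
        assert mean == pytest.approx(3.0, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_all_excluded_raises(self, patch):
        ds = cb.EMMDataset([cb.EMMPoint(id=1, position=[0, 0, 5.0])], {1})
        with pytest.raises(InsufficientDataError):
            cb.registration_error(ds, patch)

    def test_sample_sd(self, patch):
        pts = [cb.EMMPoint(id=0, position=[30, 50, 1.0]),
               cb.EMMPoint(id=1, position=[60, 50, 3.0])]
        mean, sd, _ = cb.registration_error(cb.EMMDataset(pts), patch)
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(np.std([1.0, 3.0], ddof=1))


class TestICP:
    def test_exact_points_identity(self):
        spec = cb.PhantomSpec(noise_sigma=0.0, seed=3)
        endo, _, _, truth = cb.make_lv(spec)
        ds = cb.sample_emm(endo, truth, spec)
        rep = cb.icp_register(ds, endo)
        assert rep.iterations == 1
        assert rep.converged
        assert rep.mean_error < 1e-6
        assert np.abs(rep.transform.rotation - np.eye(3)).max() < 1e-6
        assert np.abs(rep.transform.translation).max() < 1e-6

    def test_recovers_inlimit_transform_without_noise(self):
        rng = np.random.default_rng(21)
        T = random_rigid_transform(rng, max_angle_deg=5,
                                   max_translation_mm=8)
        spec = cb.PhantomSpec(true_transform=T, noise_sigma=0.0, seed=21,
                              n_emm_points=80)
        endo, _, _, truth = cb.make_lv(spec)
        ds = cb.sample_emm(endo, truth, spec)
        coarse = cb.landmark_register(ds.landmarks(), truth.landmarks)
        rep = cb.icp_register(ds, endo, init=coarse)
        dR = rep.transform.rotation @ T.rotation.T
        assert rotation_angle_deg(dR) <= 0.5
        assert np.linalg.norm(rep.transform.translation
                              - T.translation) <= 0.5
        assert rep.mean_error < 0.1

    def test_mean_error_monotone_descent(self):
        rng = np.random.default_rng(33)
        T = random_rigid_transform(rng, 6, 9)
        spec = cb.PhantomSpec(true_transform=T, seed=33)
        endo, _, _, truth = cb.make_lv(spec)
        ds = cb.sample_emm(endo, truth, spec)
        coarse = cb.landmark_register(ds.landmarks(), truth.landmarks)
        rep = cb.icp_register(ds, endo, init=coarse)
        assert len(rep.error_history) >= 2
        assert np.all(np.diff(rep.error_history) <= 1e-12)

    def test_sagittal_clamp_saturates_at_limit(self):
        """A 25-degree sagittal displacement must come back with the
        sagittal rotation component saturated at the 10-degree limit."""
        spec0 = cb.PhantomSpec(seed=2, noise_sigma=0.0)
        endo0, _, _, truth0 = cb.make_lv(spec0)
        axes = cb.anatomical_axes(
            endo0, right_ostium=truth0.landmarks["right_ostium"])
        R = Rotation.from_rotvec(np.radians(25.0) * axes[0]).as_matrix()
        T = cb.RigidTransform(R, np.zeros(3))
        spec = cb.PhantomSpec(true_transform=T, seed=2, noise_sigma=0.0)
        endo, _, _, truth = cb.make_lv(spec)
        ds = cb.sample_emm(endo, truth, spec)
        constraint = cb.RotationConstraint(axes=axes)
        rep = cb.icp_register(ds, endo, constraint=constraint)
        sagittal = constraint.decompose_deg(rep.transform.rotation)[0]
        assert rep.converged
        assert abs(sagittal - 10.0) < 1e-9

    def test_too_few_points(self, patch):
        ds = cb.EMMDataset([cb.EMMPoint(id=i, position=[i, 0, 0])
                            for i in range(3)])
        with pytest.raises(InsufficientDataError):
            cb.icp_register(ds, patch)


class TestExclusion:
    def test_interior_points_kept(self):
        spec = cb.PhantomSpec(seed=4)
        endo, _, _, truth = cb.make_lv(spec)
        ds = cb.sample_emm(endo, truth, spec)
        out = cb.exclude_outside_points(ds, endo, margin_mm=5.0)
        assert out.excluded_ids == set()

    def test_constructed_lvot_outlier_excluded(self):
        spec = cb.PhantomSpec(seed=4)
        endo, _, _, truth = cb.make_lv(spec)
        ds = cb.sample_emm(endo, truth, spec)
        ds, ids = inject_outflow_outliers(ds, endo, truth, 1,
                                          offset_mm=20.0, seed=4)
        out = cb.exclude_outside_points(ds, endo, margin_mm=5.0)
        assert out.excluded_ids == set(ids)
        # original order preserved
        assert [p.id for p in out.points] == [p.id for p in ds.points]

    def test_infinite_margin_excludes_nothing(self):
        spec = cb.PhantomSpec(seed=4)
        endo, _, _, truth = cb.make_lv(spec)
        ds = cb.sample_emm(endo, truth, spec)
        ds, _ = inject_outflow_outliers(ds, endo, truth, 5, seed=4)
        out = cb.exclude_outside_points(ds, endo, margin_mm=np.inf)
        assert out.excluded_ids == set()

    def test_exclusion_lowers_mean_error(self):
        """Mirrors the in-vivo reporting: the error over all points is at
        least the error after discarding out-of-mesh points."""
        spec = cb.PhantomSpec(seed=9, n_emm_points=61)
        endo, _, _, truth = cb.make_lv(spec)
        ds = cb.sample_emm(endo, truth, spec)
        ds, _ = inject_outflow_outliers(ds, endo, truth, 3, seed=9)
        m_all, _, _ = cb.registration_error(ds, endo, truth.transform)
        reg = cb.exclude_outside_points(ds.transformed(truth.transform),
                                        endo, 5.0)
        m_in, _, _ = cb.registration_error(reg, endo)
        assert m_in <= m_all


class TestManualAdjust:
    def test_zero_delta_is_identity_operation(self):
        T = cb.RigidTransform(
            Rotation.from_euler("xyz", [3, 4, 5], degrees=True).as_matrix(),
            [1.0, 2.0, 3.0])
        T2 = cb.manual_adjust(T, [0, 0, 0], [0, 0, 0])
        assert np.allclose(T2.rotation, T.rotation)
        assert np.allclose(T2.translation, T.translation)

    def test_translation_round_trip(self):
        T = cb.RigidTransform.identity()
        T2 = cb.manual_adjust(T, [0, 0, 0], [5.0, 0, 0])
        T3 = cb.manual_adjust(T2, [0, 0, 0], [-5.0, 0, 0])
        assert np.allclose(T3.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(T3.translation, 0.0, atol=1e-12)

    def test_correcting_a_misregistration_reduces_error(self):
        spec = cb.PhantomSpec(seed=6, noise_sigma=0.0)
        endo, _, _, truth = cb.make_lv(spec)
        ds = cb.sample_emm(endo, truth, spec)
        bad = cb.RigidTransform(np.eye(3), np.array([6.0, 0.0, 0.0]))
        m_bad, _, _ = cb.registration_error(ds, endo, bad)
        better = cb.manual_adjust(bad, [0, 0, 0], [-6.0, 0.0, 0.0])
        m_fix, _, _ = cb.registration_error(ds, endo, better)
        assert m_fix < m_bad


class TestRigidTransform:
    def test_compose_inverse(self):
        rng = np.random.default_rng(2)
        T = random_rigid_transform(rng, 20, 30)
        I = T.compose(T.inverse())
        assert np.allclose(I.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(I.translation, 0.0, atol=1e-10)

    def test_json_roundtrip(self):
        rng = np.random.default_rng(2)
        T = random_rigid_transform(rng, 20, 30)
        back = cb.RigidTransform.from_dict(T.to_dict())
        assert np.allclose(back.rotation, T.rotation)
        assert np.allclose(back.translation, T.translation)

    def test_improper_rotation_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(Exception):
            cb.RigidTransform(R, np.zeros(3))
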