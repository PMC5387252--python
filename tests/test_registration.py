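"""Rigid transform recovery from landmarks and ICP refinement."""

import numpy as np
import pytest

from airwaymorph import generate_phantom, registration as reg
from airwaymorph.mesh_io import LandmarkSet
from airwaymorph.morphometry import mesh_surface_area, mesh_volume
from airwaymorph.synthetic import PhantomSpec

from conftest import cylinder_spec


def rot_z(deg):
    th = np.radians(deg)
    return np.array(
        [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
    )


@pytest.fixture()
def landmark_cloud():
    rng = np.random.default_rng(7)
    return LandmarkSet({f"L{i}": rng.uniform(-30, 30, 3) for i in range(10)})


def test_identity_alignment_on_identical_sets(landmark_cloud):
    fit = reg.landmark_align(landmark_cloud, landmark_cloud)
    np.testing.assert_allclose(fit.transform.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(fit.transform.translation, 0.0, atol=1e-12)
    assert fit.rms < 1e-12


def test_exact_recovery_of_known_transform(landmark_cloud):
    R = rot_z(30.0)
    t = np.array([5.0, -2.0, 1.0])
    target = LandmarkSet({k: R @ v + t for k, v in landmark_cloud.points.items()})
    fit = reg.landmark_align(landmark_cloud, target)
    np.testing.assert_allclose(fit.transform.rotation, R, atol=1e-9)
    np.testing.assert_allclose(fit.transform.translation, t, atol=1e-9)
    assert fit.rms < 1e-9


def test_noisy_landmark_recovery_within_stated_bounds(landmark_cloud):
    """sigma = 0.3 mm noise: rotation < 1 deg, translation < 0.5 mm, 100 trials."""
    R = rot_z(20.0)
    t = np.array([3.0, 4.0, -5.0])
    rng = np.random.default_rng(42)
    src = landmark_cloud.array()
    worst_rot, worst_tr = 0.0, 0.0
    for _ in range(100):
        noisy = {
            k: R @ v + t + rng.normal(0, 0.3, 3)
            for k, v in landmark_cloud.points.items()
        }
        fit = reg.landmark_align(landmark_cloud, LandmarkSet(noisy))
        err = reg.RigidTransform(
            fit.transform.rotation @ R.T,
            fit.transform.translation - fit.transform.rotation @ R.T @ t,
        )
        worst_rot = max(worst_rot, err.rotation_angle_deg())
        # translation error measured at the cloud centroid
        centroid = src.mean(axis=0)
        worst_tr = max(
            worst_tr,
            float(np.linalg.norm(fit.transform.apply(centroid) - (R @ centroid + t))),
        )
    assert worst_rot < 1.0
    assert worst_tr < 0.5


def test_degenerate_landmark_configurations_rejected():
    a = LandmarkSet({"A": [0, 0, 0], "B": [1, 0, 0]})
    with pytest.raises(reg.RegistrationError, match=">= 3"):
        reg.landmark_align(a, a)
    collinear = LandmarkSet({"A": [0, 0, 0], "B": [1, 0, 0], "C": [2, 0, 0]})
    with pytest.raises(reg.RegistrationError, match="collinear"):
        reg.landmark_align(collinear, collinear)


def test_apply_transform_preserves_volume_and_area(cylinder):
    mesh, _ = cylinder
    t = reg.RigidTransform(rot_z(37.0), [10.0, -4.0, 2.0])
    moved = reg.apply_transform(mesh, t)
    assert abs(mesh_volume(moved) - mesh_volume(mesh)) < 1e-9
    assert abs(mesh_surface_area(moved) - mesh_surface_area(mesh)) < 1e-9


def test_transform_composition_matches_sequential_application(cylinder):
    mesh, _ = cylinder
    t1 = reg.RigidTransform(rot_z(15.0), [1.0, 2.0, 3.0])
    t2 = reg.RigidTransform(rot_z(-40.0), [-2.0, 0.5, 4.0])
    seq = reg.apply_transform(reg.apply_transform(mesh, t1), t2)
    once = reg.apply_transform(mesh, t2.compose(t1))
    np.testing.assert_allclose(seq.vertices, once.vertices, atol=1e-9)


def test_transform_round_trips_through_json(tmp_path):
    t = reg.RigidTransform(rot_z(12.0), [0.1, 0.2, 0.3])
    path = tmp_path / "t.json"
    t.save(path)
    back = reg.RigidTransform.load(path)
    np.testing.assert_allclose(back.matrix(), t.matrix(), atol=1e-12)


class TestICP:
    def test_fixed_point_on_identical_meshes(self):
        mesh, _ = generate_phantom(PhantomSpec(n_theta=48, axial_step=2.5))
        res = reg.global_refine(mesh, mesh, init=reg.RigidTransform.identity())
        assert res.mean_distance < 1e-6
        assert res.transform.rotation_angle_deg() < 1e-4

    def test_recovers_small_perturbation(self):
        mesh, _ = generate_phantom(
            cylinder_spec(radius=6.0, length=50.0, n_theta=96, axial_step=0.75)
        )
        # bulged variant so the cylinder's rotational symmetry is broken
        from airwaymorph.synthetic import adenoid_bulge
        from dataclasses import replace

        spec = replace(
            cylinder_spec(radius=6.0, length=50.0, n_theta=96, axial_step=0.75),
            bulges=(adenoid_bulge(3.0, center_z=25.0, sigma_z=8.0),),
        )
        mesh, _ = generate_phantom(spec)
        pert = reg.RigidTransform(rot_z(2.0), [0.4, -0.2, 0.3])
        moved = reg.apply_transform(mesh, pert)
        res = reg.global_refine(moved, mesh, init=reg.RigidTransform.identity())
        assert res.mean_distance < 0.1

    def test_never_worse_than_initialization(self):
        mesh, _ = generate_phantom(PhantomSpec(n_theta=48, axial_step=2.5))
        init = reg.RigidTransform(rot_z(5.0), [1.0, 0.0, 0.0])
        moved = reg.apply_transform(mesh, reg.RigidTransform(rot_z(3.0), [0.5, 0, 0]))
        from airwaymorph._geometry import SurfaceDistanceQuery

        q = SurfaceDistanceQuery(mesh.vertices, mesh.faces)
        res = reg.global_refine(moved, mesh, init=init)
        d_init, _ = q.distance(init.apply(moved.vertices))
        assert res.mean_distance <= d_init.mean() + 1e-9

    def test_disjoint_meshes_flag_non_convergence(self):
        mesh, _ = generate_phantom(PhantomSpec(n_theta=32, axial_step=4.0))
        far = reg.apply_transform(
            mesh, reg.RigidTransform(np.eye(3), [500.0, 0.0, 0.0])
        )
        res = reg.global_refine(far, mesh, init=reg.RigidTransform.identity(),
                                max_iterations=5)
        assert not res.converged or res.mean_distance > 10.0
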