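"""Phantom generators: determinism, quadrature truth, surgical pairs, cohorts."""

import numpy as np
import pytest
from scipy import stats as sps

from airwaymorph import (
    PhantomSpec,
    generate_cohort,
    generate_phantom,
    generate_surgical_pair,
    mesh_io,
    morphometry,
    wall_thickness,
)
from airwaymorph.synthetic import (
    DEFAULT_PROFILE,
    adenoid_bulge,
    obstruction_pair,
    phantom_landmarks,
)

from conftest import cylinder_spec, hourglass_spec


def test_uniform_tube_truth_is_exact_and_mesh_converges():
    spec = cylinder_spec(radius=5.0, length=60.0, n_theta=128)
    mesh, truth = generate_phantom(spec)
    analytic = np.pi * 25 * spec.total_length / 1000.0
    assert truth.volume_cm3["WHOLE"] == pytest.approx(analytic, rel=1e-6)
    assert morphometry.mesh_volume(mesh) == pytest.approx(analytic, rel=5e-3)


def test_hourglass_truth_min_area_at_neck():
    spec = hourglass_spec(r_outer=8.0, r_neck=3.0, length=60.0)
    _, truth = generate_phantom(spec)
    assert truth.min_lumen_area_mm2 == pytest.approx(np.pi * 9.0, rel=0.01)
    assert truth.min_lumen_z_mm == pytest.approx(30.0, abs=0.5)


def test_fixed_seed_reproduces_identical_stl(tmp_path):
    spec = PhantomSpec(n_theta=32, axial_step=4.0, noise_sigma=0.1, seed=123)
    m1, _ = generate_phantom(spec)
    m2, _ = generate_phantom(spec)
    p1, p2 = tmp_path / "a.stl", tmp_path / "b.stl"
    mesh_io.write_stl(m1, p1, dialect="binary")
    mesh_io.write_stl(m2, p2, dialect="binary")
    assert p1.read_bytes() == p2.read_bytes()


def test_self_intersecting_bulge_rejected():
    spec = PhantomSpec(bulges=(adenoid_bulge(depth=30.0),))
    with pytest.raises(ValueError, match="self-intersect"):
        generate_phantom(spec)


def test_mesh_resolution_convergence_toward_truth():
    """Doubling resolution shrinks the mesh-vs-truth volume discrepancy."""
    errs = []
    for n_theta, step in ((24, 4.0), (48, 2.0), (96, 1.0)):
        spec = PhantomSpec(
            bulges=obstruction_pair("adenoid", 5.0, 42.5, 180.0, 8.0, 50.0),
            n_theta=n_theta,
            axial_step=step,
        )
        mesh, truth = generate_phantom(spec)
        vol = morphometry.mesh_volume(mesh)
        # mesh spans the inferior margin too; compare against the same range
        z0, z1 = spec.z_range
        th = np.linspace(0, 2 * np.pi, 512, endpoint=False)[:, None]
        from scipy import integrate

        zz = np.linspace(z0, z1, 801)
        r = spec.radius(th, zz[None, :])
        expected = integrate.simpson(0.5 * (r**2).mean(axis=0) * 2 * np.pi, x=zz) / 1000
        errs.append(abs(vol - expected) / expected)
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 0.005


class TestSurgicalPair:
    def test_zero_depth_removal_is_identity(self):
        spec = PhantomSpec(
            bulges=(adenoid_bulge(4.0),), n_theta=32, axial_step=3.0
        )
        t1, t2, _ = generate_surgical_pair(spec, {"adenoid": 0.0})
        np.testing.assert_array_equal(t1.vertices, t2.vertices)

    def test_overdeep_removal_clipped_with_warning(self):
        spec = PhantomSpec(
            bulges=(adenoid_bulge(4.0),), n_theta=32, axial_step=3.0
        )
        with pytest.warns(UserWarning, match="clipping"):
            _, t2, truth = generate_surgical_pair(spec, {"adenoid": 99.0})
        assert truth.t2.spec.bulges[0].depth == 0.0

    def test_unknown_removal_target_rejected(self):
        spec = PhantomSpec(bulges=(adenoid_bulge(4.0),))
        with pytest.raises(ValueError, match="not present"):
            generate_surgical_pair(spec, {"tonsil_left": 2.0})

    def test_removal_monotonically_improves_caliber_bands(self):
        """Deflating the obstruction lowers constriction and raises patency."""
        spec = PhantomSpec(
            bulges=obstruction_pair("adenoid", 6.5, 42.5, 180.0, 9.0, 50.0),
            n_theta=64,
            axial_step=1.5,
        )
        _, _, truth = generate_surgical_pair(
            spec, {"adenoid_a": 5.0, "adenoid_b": 5.0}
        )
        b1 = truth.t1.caliber_band_fractions("NP")
        b2 = truth.t2.caliber_band_fractions("NP")
        assert b2["constriction"] < b1["constriction"]
        assert b2["patency"] > b1["patency"]

    def test_mesh_measured_bands_track_removal_truth(self):
        spec = PhantomSpec(
            bulges=obstruction_pair("adenoid", 6.5, 42.5, 180.0, 9.0, 50.0),
            n_theta=64,
            axial_step=1.5,
        )
        t1m, t2m, truth = generate_surgical_pair(
            spec, {"adenoid_a": 5.0, "adenoid_b": 5.0}
        )
        from airwaymorph import CuttingPlane, cut_mesh

        for mesh, truth_one in ((t1m, truth.t1), (t2m, truth.t2)):
            seg = cut_mesh(
                cut_mesh(mesh, CuttingPlane([0, 0, 30.0], [0, 0, 1]), "positive"),
                CuttingPlane([0, 0, 55.0], [0, 0, 1]),
                "negative",
            )
            res = wall_thickness.analyze(seg, weighting="area")
            expected = truth_one.caliber_band_fractions("NP")
            assert res.bands.constriction == pytest.approx(
                expected["constriction"], abs=6.0
            )


def test_phantom_landmarks_deterministic_and_off_surface():
    spec = PhantomSpec()
    lms = phantom_landmarks(spec, n=10)
    assert lms.count == 10
    lms2 = phantom_landmarks(spec, n=10)
    np.testing.assert_array_equal(lms.array(), lms2.array())


class TestCohort:
    def test_basic_contract(self):
        c = generate_cohort(n=8, assoc=0.5, seed=0)
        assert len(c.records) == 8
        for rec in c.records:
            assert 18 <= rec.osa18_t1 <= 126
            assert 18 <= rec.osa18_t2 <= 126
            assert set(rec.measures) == {
                "volume_cm3", "surface_cm2", "min_x_area_mm2",
                "constriction_pct", "patency_pct",
            }
            assert abs(sum(rec.subdomains_t1.values()) - rec.osa18_t1) < 1.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_cohort(n=3)
        with pytest.raises(ValueError):
            generate_cohort(n=10, assoc=1.5)

    def test_reproducible_under_seed(self):
        a = generate_cohort(n=6, assoc=0.7, seed=9)
        b = generate_cohort(n=6, assoc=0.7, seed=9)
        for ra, rb in zip(a.records, b.records):
            assert ra.osa18_t1 == rb.osa18_t1
            assert ra.measures == rb.measures

    def test_target_association_realized_at_scale(self):
        """n = 100: realized Spearman within +-0.1 of target over seeds."""
        rhos = []
        for seed in range(5):
            c = generate_cohort(n=100, assoc=0.7, seed=seed)
            gains = [
                r.measures["patency_pct"][1] - r.measures["patency_pct"][0]
                for r in c.records
            ]
            imp = [r.osa18_improvement_pct for r in c.records]
            rhos.append(sps.spearmanr(gains, imp).statistic)
        assert abs(float(np.mean(rhos)) - 0.7) < 0.1

    def test_null_association_stays_null(self):
        rhos = []
        for seed in range(10):
            c = generate_cohort(n=100, assoc=0.0, seed=seed)
            gains = [
                r.measures["patency_pct"][1] - r.measures["patency_pct"][0]
                for r in c.records
            ]
            imp = [r.osa18_improvement_pct for r in c.records]
            rhos.append(abs(sps.spearmanr(gains, imp).statistic))
        assert np.mean(np.array(rhos) < 0.2) >= 0.8
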