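"""Normal-ray caliber measures: analytic phantoms, band arithmetic, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from airwaymorph import (
    PhantomSpec,
    band_fractions,
    compute_wall_thickness,
    generate_phantom,
    summarize_thickness,
    thickness_change,
    wall_thickness,
)
from airwaymorph.mesh_io import AirwayMesh, MeshIOError
from airwaymorph.registration import RigidTransform, apply_transform

from conftest import cylinder_spec


def test_cylinder_lateral_distances_equal_diameter(cylinder):
    """Inward rays across a tube of radius r travel the diameter 2r."""
    mesh, _ = cylinder
    d, hit, origins = compute_wall_thickness(mesh)
    lateral = origins & hit
    assert lateral.sum() > 0
    rel = np.abs(d[lateral] - 10.0) / 10.0
    assert rel.max() < 0.02


def test_sphere_distances_equal_diameter():
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=3, radius=6.0)
    mesh = AirwayMesh.from_trimesh(tm)
    d, hit, origins = compute_wall_thickness(mesh)
    assert hit[origins].all()
    rel = np.abs(d[origins] - 12.0) / 12.0
    assert rel.max() < 0.02


def test_nested_shells_measure_radial_gap():
    """Rays from an outer shell first hit the inner shell across the gap."""
    import trimesh

    outer = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    inner = trimesh.creation.icosphere(subdivisions=3, radius=4.0)
    inner.invert()  # outward normals of the cavity wall point into the gap
    verts = np.vstack([outer.vertices, inner.vertices])
    faces = np.vstack([outer.faces, inner.faces + len(outer.vertices)])
    mesh = AirwayMesh(verts, faces)
    mesh.closed = True
    d, hit, origins = compute_wall_thickness(mesh)
    n_outer = len(outer.faces)
    gap = d[:n_outer][hit[:n_outer]]
    rel = np.abs(gap - 6.0) / 6.0
    assert rel.max() < 0.02


def test_open_mesh_rejected(cylinder):
    mesh, _ = cylinder
    open_mesh = AirwayMesh(mesh.vertices, mesh.faces[:-1])
    with pytest.raises(MeshIOError):
        compute_wall_thickness(open_mesh)


def test_inverted_winding_recovers(cylinder):
    mesh, _ = cylinder
    flipped = AirwayMesh(
        mesh.vertices, mesh.faces[:, ::-1].copy(), cap_faces=mesh.cap_faces
    )
    flipped.closed = True
    d, hit, origins = compute_wall_thickness(flipped)
    lateral = origins & hit
    assert np.abs(d[lateral] - 10.0).max() / 10.0 < 0.02


def test_summary_statistics_hand_computable():
    s = summarize_thickness(np.array([2.0, 4.0, 6.0, 8.0, 10.0]))
    assert s.minimum == 2 and s.maximum == 10
    assert s.mean == 6 and s.median == 6
    assert s.iqr == pytest.approx(np.subtract(*np.percentile([2, 4, 6, 8, 10], [75, 25])))
    const = summarize_thickness(np.full(7, 3.3))
    assert const.std == pytest.approx(0.0, abs=1e-12) and const.iqr == 0.0
    with pytest.raises(ValueError):
        summarize_thickness(np.array([np.nan, np.nan]))


def test_summary_matches_sample_oracle():
    rng = np.random.default_rng(5)
    d = rng.lognormal(mean=1.5, sigma=0.4, size=10_000)
    s = summarize_thickness(d)
    assert s.mean == pytest.approx(d.mean())
    assert s.median == pytest.approx(np.median(d))
    assert s.std == pytest.approx(d.std(ddof=1))
    assert s.iqr == pytest.approx(np.subtract(*np.percentile(d, [75, 25])))


class TestBandFractions:
    def test_all_constricted(self):
        b = band_fractions(np.full(10, 3.0))
        assert b.constriction == 100.0 and b.patency == 0.0

    def test_hand_counted_mixture(self):
        d = np.array([2, 2, 5, 12, 12, 12, 12, 12, 12, 12], dtype=float)
        b = band_fractions(d)
        assert b.constriction == pytest.approx(20.0)
        assert b.patency == pytest.approx(70.0)
        assert b.middle == pytest.approx(10.0)

    def test_boundary_values_fall_in_middle_band(self):
        b = band_fractions(np.array([4.0, 10.0]))
        assert b.middle == 100.0

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            band_fractions(np.array([5.0]), constriction_mm=10, patency_mm=4)

    def test_misses_excluded_from_denominator(self):
        d = np.array([3.0, np.nan, 12.0, np.nan])
        b = band_fractions(d)
        assert b.constriction == 50.0 and b.patency == 50.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 49.0), min_size=1, max_size=200),
        st.floats(0.5, 6.0),
        st.floats(7.0, 20.0),
    )
    def test_bands_partition_hits_exactly(self, values, lo, hi):
        b = band_fractions(np.array(values), lo, hi)
        assert b.constriction + b.middle + b.patency == pytest.approx(100.0)
        assert 0 <= b.constriction <= 100 and 0 <= b.patency <= 100

    def test_invariant_to_order_and_rigid_motion(self, cylinder):
        mesh, _ = cylinder
        res = wall_thickness.analyze(mesh)
        th = np.radians(33.0)
        rot = np.array(
            [[np.cos(th), 0, np.sin(th)], [0, 1, 0], [-np.sin(th), 0, np.cos(th)]]
        )
        moved = apply_transform(mesh, RigidTransform(rot, [3.0, 1.0, -9.0]))
        res2 = wall_thickness.analyze(moved)
        assert res.bands.constriction == pytest.approx(res2.bands.constriction, abs=1e-6)
        assert res.bands.patency == pytest.approx(res2.bands.patency, abs=1e-6)
        # triangle order permutation
        rng = np.random.default_rng(0)
        perm = rng.permutation(mesh.n_faces)
        shuffled = AirwayMesh(
            mesh.vertices, mesh.faces[perm], cap_faces=mesh.cap_faces[perm]
        )
        shuffled.closed = True
        res3 = wall_thickness.analyze(shuffled)
        assert res3.bands.patency == pytest.approx(res.bands.patency, abs=1e-6)


def test_area_weighted_fraction_matches_ray_marched_truth():
    """Hourglass: area fraction with caliber < 4 mm matches the analytic rays."""
    from conftest import hourglass_spec

    spec = hourglass_spec(r_outer=8.0, r_neck=1.5, n_theta=96)
    mesh, truth = generate_phantom(spec)
    fr_truth, _ = truth.wall_ray_band_fractions("OP", n_theta=64, n_z=90)
    res = wall_thickness.analyze(mesh, weighting="area")
    assert res.bands.constriction == pytest.approx(
        fr_truth["constriction"], abs=3.0
    )


def test_thickness_change_conventions():
    def fake(c, p):
        return wall_thickness.WallThicknessResult(
            distances=np.array([1.0]), hit=np.array([True]),
            triangle_areas=np.array([1.0]),
            summary=summarize_thickness(np.array([1.0])),
            bands=wall_thickness.BandFractions(c, 100 - c - p, p),
        )

    ch = thickness_change(fake(49.0, 3.1), fake(32.3, 14.0))
    assert ch.constriction_relief_relative_pct == pytest.approx(
        (49 - 32.3) / 49 * 100, abs=0.01
    )
    assert ch.constriction_relief_points == pytest.approx(16.7)
    assert ch.patency_gain_relative_pct == pytest.approx(
        (14.0 - 3.1) / 3.1 * 100, abs=0.01
    )
    zero = thickness_change(fake(10.0, 0.0), fake(5.0, 8.0))
    assert zero.patency_nonpercentable
    assert zero.patency_gain_points == pytest.approx(8.0)


def test_mesh_refinement_stability_of_area_fractions():
    """Doubling resolution moves area-weighted fractions by < 1 point."""
    from conftest import hourglass_spec

    coarse, _ = generate_phantom(hourglass_spec(r_neck=3.0, n_theta=64))
    fine, _ = generate_phantom(hourglass_spec(r_neck=3.0, n_theta=128))
    rc = wall_thickness.analyze(coarse, weighting="area")
    rf = wall_thickness.analyze(fine, weighting="area")
    assert abs(rc.bands.constriction - rf.bands.constriction) < 1.0
    assert abs(rc.bands.patency - rf.bands.patency) < 1.0
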