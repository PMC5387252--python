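"""Conventional airway measures: volume, surface area, minimum cross-section.

Volume comes from the divergence theorem on the watertight surface; surface
area sums triangle areas with cut caps optionally excluded; the minimum
cross-sectional area (MinXarea) is found by an exhaustive plane sweep along
a configured axis with local bisection refinement — an automated stand-in
for the radiologist's slice-by-slice search.

Internal units are mm; :class:`ConventionalMeasures` reports volume in cm^3
and areas in cm^2 at the boundary, with MinXarea kept in mm^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _geometry
from .mesh_io import AirwayMesh, MeshIOError
from .partition import CuttingPlane

MM3_PER_CM3 = 1000.0
MM2_PER_CM2 = 100.0


@dataclass
class CrossSection:
    """Area of mesh ∩ plane (mm^2), over possibly several disjoint lumen polygons."""

    area_mm2: float
    polygon_count: int
    missed: bool  # plane missed (or merely grazed) the mesh


@dataclass
class MinXareaResult:
    area_mm2: float
    offset_mm: float  # position of the minimizing plane along the sweep axis
    axis: np.ndarray
    occluded: bool  # lumen pinched closed at the minimum
    sweep_offsets: np.ndarray | None = None
    sweep_areas: np.ndarray | None = None


@dataclass
class ConventionalMeasures:
    """Per-segment conventional measures on the reporting scale."""

    volume_cm3: float
    surface_area_cm2_wall: float  # cap faces excluded
    surface_area_cm2_total: float
    min_x_area_mm2: float | None = None
    min_x_offset_mm: float | None = None
    min_x_axis: str = ""


def mesh_volume(mesh: AirwayMesh) -> float:
    """Enclosed volume in cm^3 (divergence-theorem sum of signed tetrahedra).

    Requires a watertight mesh.  A negative signed volume means inward
    winding; the absolute value is returned with a warning.
    """
    if not mesh.closed:
        raise MeshIOError(
            "volume requires a watertight mesh; run mesh_io.close_surface first"
        )
    signed = _geometry.signed_volume(mesh.vertices, mesh.faces)
    if signed < 0:
        warnings.warn("mesh winding is inward; returning |volume|")
    return abs(signed) / MM3_PER_CM3


def mesh_surface_area(mesh: AirwayMesh, include_caps: bool = True) -> float:
    """Total triangle area in cm^2; cut-cap faces excluded when ``include_caps`` is False."""
    areas = _geometry.triangle_areas(mesh.vertices, mesh.faces)
    if not include_caps:
        areas = areas[~mesh.cap_faces]
    return float(areas.sum()) / MM2_PER_CM2


def cross_section_area(mesh: AirwayMesh, plane: CuttingPlane) -> CrossSection:
    """Area of the planar lumen polygon(s) cut by ``plane`` (mm^2).

    Disjoint lumen polygons (e.g. the paired nasal passages) are summed.
    A plane that misses or only grazes the mesh yields area 0 with the
    ``missed`` flag set.
    """
    from shapely.geometry import Polygon

    tm = mesh.to_trimesh()
    section = tm.section(plane_origin=plane.point, plane_normal=plane.normal)
    if section is None:
        return CrossSection(0.0, 0, True)
    planar, _ = section.to_2D()
    rings = []
    for line in planar.discrete:  # closed polylines in plane coordinates
        if len(line) >= 4 and np.allclose(line[0], line[-1]):
            poly = Polygon(line)
            if poly.is_valid and poly.area > 1e-12:
                rings.append(poly)
    if not rings:
        return CrossSection(0.0, 0, True)
    # even-odd nesting: outer boundaries add area, holes subtract
    area = 0.0
    outer = 0
    for i, poly in enumerate(rings):
        depth = sum(
            1
            for j, other in enumerate(rings)
            if j != i and other.contains(poly.representative_point())
        )
        if depth % 2 == 0:
            area += poly.area
            outer += 1
        else:
            area -= poly.area
    if area <= 1e-9:
        return CrossSection(0.0, outer, True)
    return CrossSection(float(area), outer, False)


def min_cross_section(
    mesh: AirwayMesh,
    axis: np.ndarray = (0.0, 0.0, 1.0),
    step: float = 0.5,
    refine_to: float = 0.05,
    boundary_margin: float = 0.51,
    occlusion_area_mm2: float = 1e-3,
) -> MinXareaResult:
    """Minimum cross-sectional area along a straight sweep axis.

    Planes normal to ``axis`` are swept across the mesh at ``step`` mm
    (default 0.5), skipping ``boundary_margin`` mm at either end so end caps
    are not reported as minima; the coarse minimum is then refined by
    interval bisection down to ``refine_to`` mm.  The sweep log is retained
    so callers can assert the reported minimum is a true lower envelope.
    """
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    proj = mesh.vertices @ axis
    lo, hi = proj.min() + boundary_margin, proj.max() - boundary_margin
    if hi <= lo:
        raise ValueError("sweep range is empty: mesh thinner than two boundary margins")
    offsets = np.arange(lo, hi + 1e-9, step)

    def area_at(offset: float) -> float:
        cs = cross_section_area(mesh, CuttingPlane(axis * offset, axis))
        return cs.area_mm2

    areas = np.array([area_at(o) for o in offsets])
    k = int(np.argmin(areas))
    best_off, best_area = offsets[k], areas[k]

    # bisection refinement on the bracketing interval
    left = offsets[max(k - 1, 0)]
    right = offsets[min(k + 1, len(offsets) - 1)]
    width = (right - left) / 2.0
    while width > refine_to:
        for cand in (best_off - width / 2.0, best_off + width / 2.0):
            if left <= cand <= right:
                a = area_at(cand)
                if a < best_area:
                    best_area, best_off = a, cand
        width /= 2.0

    return MinXareaResult(
        float(best_area),
        float(best_off),
        axis,
        occluded=bool(best_area <= occlusion_area_mm2),
        sweep_offsets=offsets,
        sweep_areas=areas,
    )


def conventional_measures(
    mesh: AirwayMesh,
    sweep_axis: np.ndarray | None = None,
    step: float = 0.5,
) -> ConventionalMeasures:
    """Bundle volume, both surface-area variants and (optionally) MinXarea."""
    out = ConventionalMeasures(
        volume_cm3=mesh_volume(mesh),
        surface_area_cm2_wall=mesh_surface_area(mesh, include_caps=False),
        surface_area_cm2_total=mesh_surface_area(mesh, include_caps=True),
    )
    if sweep_axis is not None:
        mx = min_cross_section(mesh, sweep_axis, step=step)
        out.min_x_area_mm2 = mx.area_mm2
        out.min_x_offset_mm = mx.offset_mm
        out.min_x_axis = np.array2string(mx.axis, precision=3)
    return out
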