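"""Part comparison: point-based T2-T1 distance maps between registered models.

Every vertex of the reference (T1) model gets its unsigned distance to the
nearest point of the compared (T2) surface (exact point-to-triangle, not
point-to-vertex).  Distances are banded with the same 4/10 mm thresholds
used for the caliber measures and rendered as the familiar three-colour map:
green (< 4 mm change), orange-yellow (4-10 mm), red (> 10 mm).

Both meshes must already be in a common frame (see :mod:`registration`);
whether they actually are is the caller's responsibility — misregistration
is indistinguishable from tissue change by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _geometry
from .mesh_io import AirwayMesh

BAND_NAMES = ("green", "orange_yellow", "red")
BAND_COLORS = {"green": (0, 170, 0), "orange_yellow": (255, 165, 0), "red": (220, 0, 0)}


@dataclass
class PartComparisonMap:
    """Per-vertex T1 -> T2 surface distances with three-band classification."""

    distances: np.ndarray     # (n,) mm, unsigned
    signed: np.ndarray        # (n,) mm, + where T2 lies outward of T1
    band: np.ndarray          # (n,) int: 0 green, 1 orange-yellow, 2 red
    low_mm: float
    high_mm: float
    vertex_areas: np.ndarray  # (n,) mm^2 barycentric vertex areas, for weighting

    def band_counts(self) -> dict[str, int]:
        return {name: int((self.band == i).sum()) for i, name in enumerate(BAND_NAMES)}


def _vertex_areas(mesh: AirwayMesh) -> np.ndarray:
    """One third of each incident triangle's area, accumulated per vertex."""
    tri_areas = _geometry.triangle_areas(mesh.vertices, mesh.faces)
    va = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(va, mesh.faces[:, k], tri_areas / 3.0)
    return va


def _vertex_normals(mesh: AirwayMesh) -> np.ndarray:
    fn = _geometry.triangle_normals(mesh.vertices, mesh.faces)
    areas = _geometry.triangle_areas(mesh.vertices, mesh.faces)
    vn = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], fn * areas[:, None])
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, vn / norm, 0.0)


def compare_meshes(
    reference: AirwayMesh,
    compared: AirwayMesh,
    low_mm: float = 4.0,
    high_mm: float = 10.0,
) -> PartComparisonMap:
    """Distance map from each reference (T1) vertex to the compared (T2) surface.

    Band convention matches the published colour maps exactly: green strictly
    below ``low_mm``, red strictly above ``high_mm``, orange-yellow the
    closed interval between.  The signed variant is positive where the T2
    surface lies outward of T1 along the reference vertex normal (space
    gained, e.g. tissue removed).
    """
    if reference.n_faces == 0 or compared.n_faces == 0:
        raise ValueError("part comparison requires two non-empty meshes")
    if not 0 < low_mm < high_mm:
        raise ValueError(f"need 0 < low < high thresholds, got {low_mm}/{high_mm}")
    query = _geometry.SurfaceDistanceQuery(compared.vertices, compared.faces)
    dist, faces = query.distance(reference.vertices)
    # sign: project the offset vector onto the *reference* outward normal
    tri = compared.vertices[compared.faces[faces]]
    _, closest = _geometry.point_triangle_closest(
        reference.vertices, tri[:, 0], tri[:, 1], tri[:, 2]
    )
    normals = _vertex_normals(reference)
    signed = np.einsum("ij,ij->i", closest - reference.vertices, normals)
    band = np.where(dist < low_mm, 0, np.where(dist > high_mm, 2, 1))
    return PartComparisonMap(
        distances=dist,
        signed=signed,
        band=band.astype(np.int64),
        low_mm=low_mm,
        high_mm=high_mm,
        vertex_areas=_vertex_areas(reference),
    )


def band_summary(cmap: PartComparisonMap, weighting: str = "count") -> dict[str, float]:
    """Green / orange-yellow / red percentages, count- or area-weighted."""
    if weighting not in ("count", "area"):
        raise ValueError(f"weighting must be 'count' or 'area', got {weighting!r}")
    w = cmap.vertex_areas if weighting == "area" else np.ones(len(cmap.band))
    total = w.sum()
    return {
        name: float(w[cmap.band == i].sum() / total * 100.0)
        for i, name in enumerate(BAND_NAMES)
    }


def export_colored_ply(mesh: AirwayMesh, cmap: PartComparisonMap, path) -> None:
    """ASCII PLY with per-vertex RGB from the green/orange-yellow/red bands."""
    colors = np.array([BAND_COLORS[n] for n in BAND_NAMES], dtype=int)[cmap.band]
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for v, c in zip(mesh.vertices, colors):
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {c[0]} {c[1]} {c[2]}\n")
        for tri in mesh.faces:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def export_distances_csv(cmap: PartComparisonMap, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "vertex": np.arange(len(cmap.distances)),
            "distance_mm": cmap.distances,
            "signed_mm": cmap.signed,
            "band": [BAND_NAMES[b] for b in cmap.band],
        }
    ).to_csv(path, index=False)
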