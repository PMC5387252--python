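"""Point-based airway caliber measures ("wall thickness analysis").

For every triangle of a watertight lumen surface, a ray is cast from the
triangle (centroid by default) along its inward normal; the recorded
distance is the first intersection with the opposing wall.  The distribution
of these distances describes the local caliber of the airway everywhere at
once, unlike single-slice measures.  Two thresholded fractions summarize it:

* **constriction fraction** — percentage of triangles whose opposing-wall
  distance is below a low threshold (default 4 mm): potential collapse sites;
* **patency fraction** — percentage above a high threshold (default 10 mm):
  comfortably open lumen.

Both thresholds are operator-configurable, not constants.  Rays that exit
without hitting anything within ``max_ray`` are flagged as misses and
excluded from fraction denominators (end caps would otherwise distort them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _geometry
from .mesh_io import AirwayMesh, MeshIOError

DEFAULT_CONSTRICTION_MM = 4.0
DEFAULT_PATENCY_MM = 10.0


@dataclass
class ThicknessSummary:
    """Six-number summary of hit distances (mm)."""

    minimum: float
    maximum: float
    mean: float
    median: float
    std: float
    iqr: float


@dataclass
class BandFractions:
    """Three-band split of distances at the constriction/patency thresholds (%)."""

    constriction: float  # d <  low threshold
    middle: float        # low <= d <= high
    patency: float       # d >  high threshold
    weighting: str = "count"


@dataclass
class WallThicknessResult:
    distances: np.ndarray        # per-triangle ray distance, NaN on miss
    hit: np.ndarray              # per-triangle hit flag
    triangle_areas: np.ndarray   # mm^2, for area weighting
    summary: ThicknessSummary
    bands: BandFractions
    constriction_mm: float = DEFAULT_CONSTRICTION_MM
    patency_mm: float = DEFAULT_PATENCY_MM
    miss_percent: float = 0.0
    origin_mask: np.ndarray | None = None  # triangles rays were cast from

    @property
    def constriction_fraction(self) -> float:
        return self.bands.constriction

    @property
    def patency_fraction(self) -> float:
        return self.bands.patency


def _edge_neighbors(faces: np.ndarray) -> list[np.ndarray]:
    """For each face, the indices of faces sharing an edge with it."""
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    owner = np.tile(np.arange(len(faces)), 3)
    und = np.sort(edges, axis=1)
    order = np.lexsort((und[:, 1], und[:, 0]))
    und, owner = und[order], owner[order]
    same = (und[1:] == und[:-1]).all(axis=1)
    neigh: list[list[int]] = [[] for _ in range(len(faces))]
    for i in np.nonzero(same)[0]:
        a, b = int(owner[i]), int(owner[i + 1])
        neigh[a].append(b)
        neigh[b].append(a)
    return [np.asarray(sorted(set(n)), dtype=np.int64) for n in neigh]


def compute_wall_thickness(
    mesh: AirwayMesh,
    max_ray: float = 50.0,
    origin: str = "centroid",
    include_caps: bool = False,
    self_exclusion_mm: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-triangle inward normal-ray distances to the opposing wall.

    Parameters
    ----------
    mesh : watertight mesh with consistent outward winding.
    max_ray : rays longer than this (mm, default 50) count as misses.
    origin : ``centroid`` (default) casts one ray per triangle from its
        centroid; ``vertex`` casts from each triangle's vertices along the
        triangle normal and records the shortest hit.
    include_caps : cast rays from cap-tagged faces too (off by default —
        caps are synthetic cut surfaces, not airway wall).
    self_exclusion_mm : hits closer than this are treated as
        self-intersections and ignored; the originating triangle and its
        edge neighbours are excluded outright.

    Returns
    -------
    distances : (m,) mm, NaN where the ray missed or the face was skipped
    hit : (m,) bool
    origin_mask : (m,) bool, True where a ray was cast
    """
    if origin not in ("centroid", "vertex"):
        raise ValueError(f"origin must be 'centroid' or 'vertex', got {origin!r}")
    if not mesh.closed:
        raise MeshIOError("wall thickness requires a watertight mesh")
    normals = _geometry.triangle_normals(mesh.vertices, mesh.faces)
    if _geometry.signed_volume(mesh.vertices, mesh.faces) < 0:
        normals = -normals  # inward winding: flip so rays point into the lumen
    origin_mask = np.ones(mesh.n_faces, dtype=bool)
    if not include_caps:
        origin_mask &= ~mesh.cap_faces

    neighbors = _edge_neighbors(mesh.faces)
    idx = np.nonzero(origin_mask)[0]
    if origin == "centroid":
        starts = _geometry.triangle_centroids(mesh.vertices, mesh.faces)[idx]
        dirs = -normals[idx]  # inward
        exclude = [np.append(neighbors[i], i) for i in idx]
        t, _ = _geometry.ray_first_hits(
            starts, dirs, mesh.vertices, mesh.faces,
            exclude=exclude, t_min=self_exclusion_mm, t_max=max_ray,
        )
    else:
        corners = mesh.vertices[mesh.faces[idx]]          # (k,3,3)
        starts = corners.reshape(-1, 3)
        dirs = np.repeat(-normals[idx], 3, axis=0)
        exclude = []
        vert_faces = _vertex_faces(mesh.faces)
        for i in idx:
            for v in mesh.faces[i]:
                exclude.append(vert_faces[v])
        t, _ = _geometry.ray_first_hits(
            starts, dirs, mesh.vertices, mesh.faces,
            exclude=exclude, t_min=self_exclusion_mm, t_max=max_ray,
        )
        t = t.reshape(-1, 3).min(axis=1)

    distances = np.full(mesh.n_faces, np.nan)
    distances[idx] = np.where(np.isfinite(t), t, np.nan)
    hit = np.isfinite(distances)
    # inverted-normal guard: if most rays immediately exit (miss), retry flipped
    if origin_mask.sum() and hit[idx].mean() < 0.5:
        t2, _ = _geometry.ray_first_hits(
            starts[: len(idx)] if origin == "centroid" else starts,
            -dirs, mesh.vertices, mesh.faces,
            exclude=exclude, t_min=self_exclusion_mm, t_max=max_ray,
        )
        if origin == "vertex":
            t2 = t2.reshape(-1, 3).min(axis=1)
        if np.isfinite(t2).mean() > hit[idx].mean():
            distances[idx] = np.where(np.isfinite(t2), t2, np.nan)
            hit = np.isfinite(distances)
    return distances, hit, origin_mask


def _vertex_faces(faces: np.ndarray) -> list[np.ndarray]:
    nv = int(faces.max()) + 1
    out: list[list[int]] = [[] for _ in range(nv)]
    for fi, tri in enumerate(faces):
        for v in tri:
            out[int(v)].append(fi)
    return [np.asarray(o, dtype=np.int64) for o in out]


def summarize_thickness(distances: np.ndarray) -> ThicknessSummary:
    """Minimum, maximum, mean, median, standard deviation and IQR of hit distances."""
    d = np.asarray(distances, dtype=np.float64)
    d = d[np.isfinite(d)]
    if len(d) == 0:
        raise ValueError("no hit distances to summarize (all rays missed)")
    q1, q3 = np.percentile(d, [25, 75])
    return ThicknessSummary(
        minimum=float(d.min()),
        maximum=float(d.max()),
        mean=float(d.mean()),
        median=float(np.median(d)),
        std=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        iqr=float(q3 - q1),
    )


def band_fractions(
    distances: np.ndarray,
    constriction_mm: float = DEFAULT_CONSTRICTION_MM,
    patency_mm: float = DEFAULT_PATENCY_MM,
    weighting: str = "count",
    areas: np.ndarray | None = None,
) -> BandFractions:
    """Constriction / middle / patency percentages over hit distances.

    Bands are strict at both ends — d < ``constriction_mm`` is constriction,
    d > ``patency_mm`` is patency, equality falls in the middle band.  The
    default ``count`` weighting is a percentage of triangles; ``area``
    weighting uses triangle areas (``areas``, mm^2) instead.
    """
    if not 0 < constriction_mm < patency_mm:
        raise ValueError(
            f"thresholds must satisfy 0 < constriction < patency, got "
            f"{constriction_mm} / {patency_mm}"
        )
    if weighting not in ("count", "area"):
        raise ValueError(f"weighting must be 'count' or 'area', got {weighting!r}")
    d = np.asarray(distances, dtype=np.float64)
    mask = np.isfinite(d)
    if weighting == "area":
        if areas is None:
            raise ValueError("area weighting requires per-triangle areas")
        w = np.asarray(areas, dtype=np.float64)[mask]
    else:
        w = np.ones(mask.sum())
    d = d[mask]
    total = w.sum()
    if total == 0:
        raise ValueError("no hit distances; band fractions undefined")
    lo = float(w[d < constriction_mm].sum() / total * 100.0)
    hi = float(w[d > patency_mm].sum() / total * 100.0)
    return BandFractions(lo, 100.0 - lo - hi, hi, weighting)


def analyze(
    mesh: AirwayMesh,
    constriction_mm: float = DEFAULT_CONSTRICTION_MM,
    patency_mm: float = DEFAULT_PATENCY_MM,
    max_ray: float = 50.0,
    weighting: str = "count",
    origin: str = "centroid",
) -> WallThicknessResult:
    """Full wall-thickness analysis of one airway segment."""
    distances, hit, origin_mask = compute_wall_thickness(
        mesh, max_ray=max_ray, origin=origin
    )
    areas = _geometry.triangle_areas(mesh.vertices, mesh.faces)
    n_cast = int(origin_mask.sum())
    miss_pct = float((n_cast - hit.sum()) / n_cast * 100.0) if n_cast else 100.0
    return WallThicknessResult(
        distances=distances,
        hit=hit,
        triangle_areas=areas,
        summary=summarize_thickness(distances),
        bands=band_fractions(
            distances, constriction_mm, patency_mm, weighting, areas
        ),
        constriction_mm=constriction_mm,
        patency_mm=patency_mm,
        miss_percent=miss_pct,
        origin_mask=origin_mask,
    )


@dataclass
class ThicknessChange:
    """Pre/post change in the thresholded fractions, both conventions.

    The relief of constriction can be quoted two ways and published tables
    are ambiguous between them, so both are always reported:

    * ``*_relative_pct`` — 100 * (T1 - T2) / T1 for constriction and
      100 * (T2 - T1) / T1 for patency;
    * ``*_points`` — plain percentage-point differences.

    When the T1 patency fraction is 0, a relative gain is undefined; the
    absolute gain is reported and ``patency_nonpercentable`` is set.
    """

    constriction_relief_relative_pct: float | None
    constriction_relief_points: float
    patency_gain_relative_pct: float | None
    patency_gain_points: float
    patency_nonpercentable: bool = False


def thickness_change(t1: WallThicknessResult, t2: WallThicknessResult) -> ThicknessChange:
    """T1 -> T2 change in constriction and patency fractions (both conventions)."""
    if (t1.constriction_mm, t1.patency_mm) != (t2.constriction_mm, t2.patency_mm):
        raise ValueError("timepoints were analyzed with different thresholds")
    if t1.bands.weighting != t2.bands.weighting:
        raise ValueError("timepoints were analyzed with different weightings")
    c1, c2 = t1.bands.constriction, t2.bands.constriction
    p1, p2 = t1.bands.patency, t2.bands.patency
    relief_rel = (c1 - c2) / c1 * 100.0 if c1 != 0 else None
    if p1 != 0:
        gain_rel: float | None = (p2 - p1) / p1 * 100.0
        nonpct = False
    else:
        gain_rel = None
        nonpct = True
    return ThicknessChange(
        constriction_relief_relative_pct=relief_rel,
        constriction_relief_points=c1 - c2,
        patency_gain_relative_pct=gain_rel,
        patency_gain_points=p2 - p1,
        patency_nonpercentable=nonpct,
    )


def export_distances_csv(result: WallThicknessResult, path) -> None:
    """CSV of (triangle index, distance_mm, hit)."""
    import pandas as pd

    pd.DataFrame(
        {
            "triangle": np.arange(len(result.distances)),
            "distance_mm": result.distances,
            "hit": result.hit,
        }
    ).to_csv(path, index=False)


def export_colored_ply(mesh: AirwayMesh, result: WallThicknessResult, path) -> None:
    """ASCII PLY with a per-face scalar (quality) holding the ray distance."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("property float quality\n")
        fh.write("end_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for tri, d in zip(mesh.faces, result.distances):
            q = d if np.isfinite(d) else -1.0
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]} {q:.4f}\n")
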