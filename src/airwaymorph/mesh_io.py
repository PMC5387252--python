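"""Reading, writing, validation and conditioning of airway surface meshes.

Airway lumen segments arrive as triangulated STL surfaces (ASCII or binary),
one per subject per timepoint.  This module turns them into validated
:class:`AirwayMesh` objects — deduplicated vertices, consistent winding, a
watertight flag — and provides the conditioning steps applied before any
measurement: volume-preserving smoothing and hole capping ("wrapping").

All coordinates are millimetres.  Reporting layers convert to cm^3 / cm^2.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import _geometry

SEGMENT_LABELS = ("NS", "NP", "OP", "WHOLE")


class MeshIOError(ValueError):
    """Malformed mesh input (bad STL, empty mesh, non-cappable boundary)."""


@dataclass
class AirwayMesh:
    """A triangulated airway lumen surface segment.

    Attributes
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    segment_label : one of ``NS`` (nasal cavity), ``NP`` (nasopharynx),
        ``OP`` (oropharynx) or ``WHOLE``
    closed : watertight flag (every edge shared by exactly two faces)
    cap_faces : (m,) bool mask marking synthetic cap faces (cut planes /
        hole fills) so surface-area reports can exclude them
    """

    vertices: np.ndarray
    faces: np.ndarray
    segment_label: str = "WHOLE"
    closed: bool = False
    cap_faces: np.ndarray | None = None
    units: str = field(default="mm", repr=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.segment_label not in SEGMENT_LABELS:
            raise ValueError(
                f"segment_label must be one of {SEGMENT_LABELS}, got {self.segment_label!r}"
            )
        if self.cap_faces is None:
            self.cap_faces = np.zeros(len(self.faces), dtype=bool)
        else:
            self.cap_faces = np.asarray(self.cap_faces, dtype=bool).reshape(-1)
            if len(self.cap_faces) != len(self.faces):
                raise ValueError("cap_faces length must match number of faces")

    # -- basic accessors ----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "AirwayMesh":
        return AirwayMesh(
            self.vertices.copy(),
            self.faces.copy(),
            self.segment_label,
            self.closed,
            self.cap_faces.copy(),
        )

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(
        cls, mesh: trimesh.Trimesh, segment_label: str = "WHOLE"
    ) -> "AirwayMesh":
        out = cls(
            np.asarray(mesh.vertices, dtype=np.float64),
            np.asarray(mesh.faces, dtype=np.int64),
            segment_label,
        )
        out.closed = _is_closed(out.faces)
        return out


@dataclass
class LandmarkSet:
    """Named anatomical landmark coordinates (mm)."""

    points: dict[str, np.ndarray]

    def __post_init__(self):
        cleaned = {}
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=np.float64).reshape(3)
            if not np.isfinite(arr).all():
                raise ValueError(f"landmark {name!r} has non-finite coordinates")
            cleaned[str(name)] = arr
        self.points = cleaned

    @property
    def count(self) -> int:
        return len(self.points)

    @property
    def names(self) -> list[str]:
        return list(self.points)

    def array(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else self.names
        return np.stack([self.points[n] for n in names])


# ---------------------------------------------------------------------------
# Validation helpers
# ---------------------------------------------------------------------------

def _is_closed(faces: np.ndarray) -> bool:
    """Edge-manifold watertightness: every undirected edge used exactly twice."""
    if len(faces) == 0:
        return False
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    return bool((counts == 2).all())


def validate_mesh(mesh: AirwayMesh, area_tol: float = 1e-12) -> AirwayMesh:
    """Drop degenerate (zero-area / repeated-index) triangles and recompute flags."""
    f = mesh.faces
    distinct = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    in_range = (f >= 0).all(axis=1) & (f < mesh.n_vertices).all(axis=1)
    if not in_range.all():
        raise MeshIOError("triangle references out-of-range vertex index")
    areas = _geometry.triangle_areas(mesh.vertices, f)
    keep = distinct & (areas > area_tol)
    out = AirwayMesh(
        mesh.vertices, f[keep], mesh.segment_label, cap_faces=mesh.cap_faces[keep]
    )
    out.closed = _is_closed(out.faces)
    return out


def weld_vertices(mesh: AirwayMesh, tol: float = 1e-6) -> AirwayMesh:
    """Merge vertices closer than ``tol`` mm (STL repeats vertices per facet)."""
    if mesh.n_vertices == 0:
        return mesh.copy()
    keys = np.round(mesh.vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    out = AirwayMesh(
        mesh.vertices[first],
        inverse[mesh.faces],
        mesh.segment_label,
        cap_faces=mesh.cap_faces,
    )
    return validate_mesh(out)


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------

def read_stl(
    path: str | Path, segment_label: str = "WHOLE", weld_tol: float = 1e-6
) -> AirwayMesh:
    """Read an ASCII or binary STL file into a validated :class:`AirwayMesh`.

    Vertices are welded at ``weld_tol`` (mm) and the watertight flag is
    computed from an edge-manifold check.

    Raises
    ------
    MeshIOError
        If the file is malformed (with the failing byte offset where it can
        be determined) or describes an empty mesh.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = path.read_bytes()
    if len(raw) == 0:
        raise MeshIOError(f"{path}: empty file (byte offset 0)")
    # binary STL: cross-check the declared facet count at byte offset 80
    if not raw.lstrip()[:5].lower().startswith(b"solid") and len(raw) >= 84:
        declared = struct.unpack("<I", raw[80:84])[0]
        expected = 84 + declared * 50
        if len(raw) < expected:
            raise MeshIOError(
                f"{path}: binary STL declares {declared} facets at byte offset 80 "
                f"but file holds {(len(raw) - 84) // 50}"
            )
    try:
        mesh = trimesh.load_mesh(io.BytesIO(raw), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted types on malformed input
        raise MeshIOError(f"{path}: malformed STL ({exc}); header is bytes 0-79") from exc
    if isinstance(mesh, trimesh.Scene) or len(mesh.faces) == 0:
        raise MeshIOError(f"{path}: STL contains no facets")
    out = AirwayMesh(
        np.asarray(mesh.vertices, dtype=np.float64),
        np.asarray(mesh.faces, dtype=np.int64),
        segment_label,
    )
    return weld_vertices(out, tol=weld_tol)


def write_stl(mesh: AirwayMesh, path: str | Path, dialect: str = "binary") -> None:
    """Write the mesh as STL; ``dialect`` is ``ascii`` or ``binary``.

    ASCII facets are written at full ``repr`` precision, so an ASCII
    round-trip reproduces coordinates (and hence volume) exactly.  Binary
    STL stores float32 by definition of its 50-byte facet record, so binary
    round-trips are exact only to single precision.
    """
    if dialect not in ("ascii", "binary"):
        raise ValueError(f"dialect must be 'ascii' or 'binary', got {dialect!r}")
    if mesh.n_faces == 0:
        raise MeshIOError("refusing to write an empty mesh")
    if dialect == "binary":
        with open(path, "wb") as fh:
            fh.write(trimesh.exchange.stl.export_stl(mesh.to_trimesh()))
        return
    normals = _geometry.triangle_normals(mesh.vertices, mesh.faces)
    with open(path, "w") as fh:
        fh.write("solid airwaymorph\n")
        for tri, n in zip(mesh.faces, normals):
            nx, ny, nz = (float(x) for x in n)
            fh.write(f"facet normal {nx!r} {ny!r} {nz!r}\n outer loop\n")
            for v in mesh.vertices[tri]:
                vx, vy, vz = (float(x) for x in v)
                fh.write(f"  vertex {vx!r} {vy!r} {vz!r}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write("endsolid airwaymorph\n")


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------

def smooth_mesh(mesh: AirwayMesh, factor: float = 0.7, iterations: int = 10) -> AirwayMesh:
    """Volume-preserving two-step (shrink/inflate) Laplacian smoothing.

    ``factor`` in [0, 1] scales the per-step Laplacian weights of a Taubin
    shrink/inflate pair; 0 is the identity.  Topology and vertex count are
    unchanged.  Plain Laplacian smoothing shrinks tubes and would bias
    airway volume, hence the paired steps.
    """
    if not 0.0 <= factor <= 1.0:
        raise ValueError(f"smoothing factor must lie in [0, 1], got {factor}")
    if factor == 0.0 or iterations == 0:
        return mesh.copy()
    tm = mesh.to_trimesh()
    # inflate weight just below the shrink weight: net contractive on convex
    # shapes, near volume-preserving on tubes
    lam = 0.5 * factor
    nu = 0.48 * factor
    trimesh.smoothing.filter_taubin(tm, lamb=lam, nu=nu, iterations=iterations)
    out = AirwayMesh(
        np.asarray(tm.vertices, dtype=np.float64),
        mesh.faces.copy(),
        mesh.segment_label,
        mesh.closed,
        mesh.cap_faces.copy(),
    )
    return out


def close_surface(mesh: AirwayMesh) -> AirwayMesh:
    """Cap every boundary loop with a centroid fan, returning a watertight mesh.

    Already-closed meshes are returned unchanged.  New faces are tagged in
    ``cap_faces``.  Raises :class:`MeshIOError` when the boundary is not a
    set of simple loops (non-manifold edges), listing the offending vertices.
    """
    if mesh.closed and _is_closed(mesh.faces):
        return mesh
    loops = _geometry.boundary_loops(mesh.faces)
    bad = [lp for lp in loops if len(lp) < 3]
    if bad:
        raise MeshIOError(f"boundary chains too short to cap at vertices {bad}")
    cap_v, cap_f = _geometry._cap_loops(mesh.vertices, loops)
    verts = np.concatenate([mesh.vertices, cap_v]) if len(cap_v) else mesh.vertices
    faces = np.concatenate([mesh.faces, cap_f]) if len(cap_f) else mesh.faces
    caps = np.concatenate([mesh.cap_faces, np.ones(len(cap_f), dtype=bool)])
    out = AirwayMesh(verts, faces, mesh.segment_label, cap_faces=caps)
    out.closed = _is_closed(out.faces)
    if not out.closed:
        raise MeshIOError(
            "surface could not be made watertight: non-manifold edges remain"
        )
    return out


# ---------------------------------------------------------------------------
# Landmark files
# ---------------------------------------------------------------------------

def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a ``name,x,y,z`` CSV (mm) into a :class:`LandmarkSet`.

    Duplicate names and non-numeric coordinates are rejected.
    """
    df = pd.read_csv(path)
    expected = ["name", "x", "y", "z"]
    if list(df.columns[:4]) != expected:
        raise ValueError(f"{path}: expected header {expected}, got {list(df.columns)}")
    if df["name"].duplicated().any():
        dupes = df["name"][df["name"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate landmark names {dupes}")
    coords = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce")
    if coords.isna().any().any():
        bad = df.loc[coords.isna().any(axis=1), "name"].tolist()
        raise ValueError(f"{path}: non-numeric coordinates for {bad}")
    return LandmarkSet({n: c for n, c in zip(df["name"], coords.to_numpy())})


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    rows = [
        {"name": n, "x": p[0], "y": p[1], "z": p[2]}
        for n, p in landmarks.points.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
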