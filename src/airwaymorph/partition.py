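"""Anatomical partitioning of a whole upper-airway mesh.

The whole airway (anterior nares down to the anterior-inferior body of C3)
is split into nasal cavity (NS), nasopharynx (NP) and oropharynx (OP) by
three cutting planes supplied as explicit configuration — a point and a unit
normal, or three landmark names defining the plane.  Cut faces are re-capped
watertight and tagged so wall-only surface areas can exclude them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _geometry
from .mesh_io import AirwayMesh, LandmarkSet, MeshIOError


class PartitionError(ValueError):
    pass


@dataclass
class CuttingPlane:
    """Oriented plane: points with (x - point)·normal > 0 are on the positive side."""

    point: np.ndarray
    normal: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=np.float64).reshape(3)
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be non-zero")
        self.normal = n / norm

    @classmethod
    def from_landmarks(
        cls, landmarks: LandmarkSet, names: tuple[str, str, str], name: str = ""
    ) -> "CuttingPlane":
        a, b, c = (landmarks.points[n] for n in names)
        normal = np.cross(b - a, c - a)
        if np.linalg.norm(normal) < 1e-12:
            raise ValueError(f"landmarks {names} are collinear; plane undefined")
        return cls(a, normal, name or "+".join(names))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.point) @ self.normal


@dataclass
class SegmentSet:
    """The three analyzed airway segments."""

    NS: AirwayMesh
    NP: AirwayMesh
    OP: AirwayMesh

    def __iter__(self):
        yield from (("NS", self.NS), ("NP", self.NP), ("OP", self.OP))


def cut_mesh(mesh: AirwayMesh, plane: CuttingPlane, keep: str = "positive") -> AirwayMesh:
    """Keep one side of a plane cut, re-capped watertight.

    Triangles straddling the plane are split exactly at the plane.  If the
    plane misses the mesh, the whole (or an empty) mesh is returned with a
    warning rather than an error.
    """
    if not mesh.closed:
        raise MeshIOError("cut_mesh requires a watertight mesh; run close_surface first")
    s = plane.signed_distance(mesh.vertices)
    sign = 1.0 if keep == "positive" else -1.0
    if (sign * s >= 0).all():
        warnings.warn(f"plane {plane.name!r} misses the mesh; returning it whole")
        return mesh.copy()
    if (sign * s <= 0).all():
        warnings.warn(f"plane {plane.name!r} leaves nothing on the {keep} side")
        return AirwayMesh(
            np.empty((0, 3)), np.empty((0, 3), dtype=np.int64), mesh.segment_label
        )
    v, f, caps = _geometry.cut_mesh_arrays(
        mesh.vertices, mesh.faces, mesh.cap_faces, plane.point, plane.normal, keep
    )
    out = AirwayMesh(v, f, mesh.segment_label, cap_faces=caps)
    out.closed = True
    return out


def partition_airway(
    mesh: AirwayMesh,
    ns_np_plane: CuttingPlane,
    np_op_plane: CuttingPlane,
    inferior_plane: CuttingPlane,
    axis: np.ndarray | None = None,
    volume_tolerance: float = 0.005,
) -> SegmentSet:
    """Split a whole airway into NS / NP / OP with three configured planes.

    ``ns_np_plane`` separates nasal cavity from nasopharynx, ``np_op_plane``
    separates nasopharynx from oropharynx, and ``inferior_plane`` enforces
    the region-of-interest's inferior limit (level of the anterior-inferior
    body of C3).  All plane normals must point toward the nasal (superior)
    end so the planes are ordered along the airway; ``axis`` (default: the
    mean plane normal) is used only to check that ordering.  Raises
    :class:`PartitionError` on an empty segment, degenerate plane ordering,
    or broken volume conservation.
    """
    planes = [ns_np_plane, np_op_plane, inferior_plane]
    axis = (
        np.asarray(axis, dtype=np.float64)
        if axis is not None
        else np.mean([p.normal for p in planes], axis=0)
    )
    offsets = [float(p.point @ axis) for p in planes]
    if not offsets[0] > offsets[1] > offsets[2]:
        raise PartitionError(
            "degenerate plane ordering along the airway axis: expected "
            f"NS/NP > NP/OP > inferior boundary offsets, got {offsets}"
        )

    ns = cut_mesh(mesh, ns_np_plane, keep="positive")
    npx = cut_mesh(
        cut_mesh(mesh, ns_np_plane, keep="negative"), np_op_plane, keep="positive"
    )
    op = cut_mesh(
        cut_mesh(mesh, np_op_plane, keep="negative"), inferior_plane, keep="positive"
    )
    ns.segment_label, npx.segment_label, op.segment_label = "NS", "NP", "OP"

    vols = {}
    for label, seg in (("NS", ns), ("NP", npx), ("OP", op)):
        if seg.n_faces == 0:
            raise PartitionError(f"segment {label} is empty with the given planes")
        vols[label] = abs(_geometry.signed_volume(seg.vertices, seg.faces))
    # conservation is checked against the whole airway trimmed at the
    # inferior ROI limit
    trimmed = cut_mesh(mesh, inferior_plane, keep="positive")
    ref_vol = abs(_geometry.signed_volume(trimmed.vertices, trimmed.faces))
    total = sum(vols.values())
    if ref_vol > 0 and abs(total - ref_vol) / ref_vol > volume_tolerance:
        raise PartitionError(
            f"segment volumes {total:.3f} mm^3 fail to conserve the whole-airway "
            f"volume {ref_vol:.3f} mm^3 within {volume_tolerance:.1%}"
        )
    return SegmentSet(NS=ns, NP=npx, OP=op)
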