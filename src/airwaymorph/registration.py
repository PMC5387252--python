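"""Rigid alignment of post-surgical (T2) data into the pre-surgical (T1) frame.

Two stages mirror the clinical workflow: a closed-form landmark (Procrustes/
Kabsch) solve over corresponding named points, then an iterative-closest-point
refinement against the T1 surface.  T1 is always the fixed frame; transforms
never include scaling or reflection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geometry import SurfaceDistanceQuery, point_triangle_closest as _point_triangle_closest
from .mesh_io import AirwayMesh, LandmarkSet


class RegistrationError(ValueError):
    pass


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"matrix": self.matrix().tolist()}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        m = np.asarray(json.loads(Path(path).read_text())["matrix"])
        return cls(m[:3, :3], m[:3, 3])


@dataclass
class LandmarkFit:
    transform: RigidTransform
    residuals: dict[str, float]
    rms: float


@dataclass
class ICPResult:
    transform: RigidTransform
    mean_distance: float
    iterations: int
    converged: bool
    distance_log: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------

def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping src onto dst (SVD)."""
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])  # reflection guard
    rot = vt.T @ s @ u.T
    return RigidTransform(rot, cd - rot @ cs)


def landmark_align(source: LandmarkSet, target: LandmarkSet) -> LandmarkFit:
    """Closed-form rigid fit of corresponding named landmarks (source -> target).

    Requires at least three non-collinear landmarks with matching names.
    Returns the transform plus per-landmark residuals and their RMS (mm).
    """
    names = [n for n in source.names if n in target.points]
    if len(names) < 3:
        raise RegistrationError(
            f"need >= 3 corresponding landmarks, found {len(names)}: {names}"
        )
    src = source.array(names)
    dst = target.array(names)
    centered = src - src.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise RegistrationError(
            "landmarks are collinear (rank-deficient configuration); "
            f"singular values {svals}"
        )
    t = _kabsch(src, dst)
    resid = np.linalg.norm(t.apply(src) - dst, axis=1)
    rms = float(np.sqrt((resid**2).mean()))
    return LandmarkFit(t, dict(zip(names, resid.tolist())), rms)


def apply_transform(mesh: AirwayMesh, t: RigidTransform) -> AirwayMesh:
    """Transform a mesh's vertices; topology, areas and volume are unchanged."""
    return AirwayMesh(
        t.apply(mesh.vertices),
        mesh.faces.copy(),
        mesh.segment_label,
        mesh.closed,
        mesh.cap_faces.copy(),
    )


def global_refine(
    source_mesh: AirwayMesh,
    target_mesh: AirwayMesh,
    init: RigidTransform | None = None,
    max_iterations: int = 50,
    tolerance: float = 1e-4,
    trim_quantile: float = 0.9,
    sample: int = 2000,
    seed: int = 0,
) -> ICPResult:
    """Trimmed point-to-surface ICP refining ``init`` (source -> target).

    Correspondences are exact closest points on the target surface;
    per-iteration matches beyond the ``trim_quantile`` distance quantile are
    rejected for robustness to partial overlap at segment boundaries.
    Convergence when the mean distance improves by less than ``tolerance``
    mm; the best transform seen is always returned, so refinement never ends
    worse than its initialization.
    """
    init = init or RigidTransform.identity()
    rng = np.random.default_rng(seed)
    pts = source_mesh.vertices
    if len(pts) > sample:
        pts = pts[rng.choice(len(pts), size=sample, replace=False)]
    query = SurfaceDistanceQuery(target_mesh.vertices, target_mesh.faces)

    def mean_dist(transform: RigidTransform) -> float:
        d, _ = query.distance(transform.apply(pts))
        return float(d.mean())

    current = init
    best = init
    best_d = mean_dist(init)
    log = [best_d]
    converged = False
    for it in range(1, max_iterations + 1):
        moved = current.apply(pts)
        d, faces = query.distance(moved)
        # closest points on target for trimmed correspondences
        cutoff = np.quantile(d, trim_quantile)
        keep = d <= cutoff
        if keep.sum() < 3:
            break
        tri = query.vertices[query.faces[faces[keep]]]
        _, closest = _point_triangle_closest(
            moved[keep], tri[:, 0], tri[:, 1], tri[:, 2]
        )
        step = _kabsch(moved[keep], closest)
        current = step.compose(current)
        cur_d = mean_dist(current)
        log.append(cur_d)
        if cur_d < best_d:
            improvement = best_d - cur_d
            best, best_d = current, cur_d
            if improvement < tolerance:
                converged = True
                break
        else:
            # no further improvement; stop at the best transform so far
            converged = abs(log[-2] - cur_d) < tolerance
            break
    return ICPResult(best, best_d, len(log) - 1, converged, log)
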