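"""Low-level triangle-mesh geometry kernels.

Vectorized numpy implementations of the primitives the airway measures are
built on: first-hit ray casting (Moller-Trumbore), exact point-to-triangle
distance queries accelerated with a centroid k-d tree, boundary-loop
extraction, and plane cutting with cap tagging.  All coordinates are in
millimetres; all arrays are float64.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco

__all__ = [
    "triangle_areas",
    "triangle_normals",
    "triangle_centroids",
    "signed_volume",
    "ray_first_hits",
    "point_triangle_closest",
    "closest_surface_distance",
    "boundary_loops",
    "cut_mesh_arrays",
]


def triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area of each triangle (mm^2)."""
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def triangle_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Unit normals following the winding order; zero-area faces get a zero normal."""
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norm > 0, n / norm, 0.0)
    return unit


def triangle_centroids(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    return vertices[faces].mean(axis=1)


def signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Signed enclosed volume via the divergence theorem (mm^3).

    Positive for consistent outward winding; the caller decides how to treat
    a negative sign.
    """
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


# ---------------------------------------------------------------------------
# Ray casting
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mt_first_hits_kernel(
    origins, dirs, v0, e1, e2, excl_flat, excl_ptr, t_min, t_max
):  # pragma: no cover - exercised through ray_first_hits
    n_rays = origins.shape[0]
    n_tris = v0.shape[0]
    out_t = np.full(n_rays, np.inf)
    out_f = np.full(n_rays, -1, dtype=np.int64)
    for i in range(n_rays):
        ox, oy, oz = origins[i, 0], origins[i, 1], origins[i, 2]
        dx, dy, dz = dirs[i, 0], dirs[i, 1], dirs[i, 2]
        best = t_max
        best_f = -1
        for j in range(n_tris):
            e2x, e2y, e2z = e2[j, 0], e2[j, 1], e2[j, 2]
            px = dy * e2z - dz * e2y
            py = dz * e2x - dx * e2z
            pz = dx * e2y - dy * e2x
            e1x, e1y, e1z = e1[j, 0], e1[j, 1], e1[j, 2]
            det = e1x * px + e1y * py + e1z * pz
            if -1e-12 < det < 1e-12:
                continue
            inv = 1.0 / det
            tx = ox - v0[j, 0]
            ty = oy - v0[j, 1]
            tz = oz - v0[j, 2]
            u = (tx * px + ty * py + tz * pz) * inv
            if u < -1e-9 or u > 1.0 + 1e-9:
                continue
            qx = ty * e1z - tz * e1y
            qy = tz * e1x - tx * e1z
            qz = tx * e1y - ty * e1x
            v = (dx * qx + dy * qy + dz * qz) * inv
            if v < -1e-9 or u + v > 1.0 + 1e-9:
                continue
            t = (e2x * qx + e2y * qy + e2z * qz) * inv
            if t <= t_min or t >= best:
                continue
            skip = False
            for k in range(excl_ptr[i], excl_ptr[i + 1]):
                if excl_flat[k] == j:
                    skip = True
                    break
            if skip:
                continue
            best = t
            best_f = j
        if best_f >= 0:
            out_t[i] = best
            out_f[i] = best_f
    return out_t, out_f


def ray_first_hits(
    origins: np.ndarray,
    directions: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    exclude: list[np.ndarray] | None = None,
    t_min: float = 1e-4,
    t_max: float = np.inf,
) -> tuple[np.ndarray, np.ndarray]:
    """First intersection of each ray with the mesh.

    Parameters
    ----------
    origins, directions : (R, 3)
        Ray origins and (not necessarily unit) directions.  Reported
        distances are in units of the direction norm, so pass unit vectors
        for metric distances.
    exclude : optional list of R int arrays
        Face indices to ignore per ray (e.g. the originating triangle and
        its edge neighbours).
    t_min, t_max : float
        Accept hits with parameter in (t_min, t_max]; ``t_min`` doubles as
        the self-intersection exclusion radius.

    Returns
    -------
    t : (R,) distances, ``inf`` where the ray misses.
    face : (R,) hit face index, -1 where the ray misses.
    """
    origins = np.asarray(origins, dtype=np.float64)
    directions = np.asarray(directions, dtype=np.float64)
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0

    n_rays = len(origins)
    n_tris = len(faces)
    t_out = np.full(n_rays, np.inf)
    f_out = np.full(n_rays, -1, dtype=np.int64)
    if n_rays == 0 or n_tris == 0:
        return t_out, f_out

    if _HAVE_NUMBA:
        if exclude is None:
            excl_flat = np.empty(0, dtype=np.int64)
            excl_ptr = np.zeros(n_rays + 1, dtype=np.int64)
        else:
            lens = np.fromiter((len(e) for e in exclude), dtype=np.int64, count=n_rays)
            excl_ptr = np.concatenate([[0], np.cumsum(lens)])
            excl_flat = (
                np.concatenate([np.asarray(e, dtype=np.int64) for e in exclude])
                if excl_ptr[-1]
                else np.empty(0, dtype=np.int64)
            )
        t_cap = t_max if np.isfinite(t_max) else 1e300
        return _mt_first_hits_kernel(
            np.ascontiguousarray(origins),
            np.ascontiguousarray(directions),
            np.ascontiguousarray(v0),
            np.ascontiguousarray(e1),
            np.ascontiguousarray(e2),
            excl_flat,
            excl_ptr,
            float(t_min),
            float(t_cap),
        )

    # numpy fallback: chunk so the (chunk, T, 3) intermediates stay ~100 MB
    chunk = max(1, int(4_000_000 / max(n_tris, 1)))
    eps = 1e-12
    for lo in range(0, n_rays, chunk):
        hi = min(lo + chunk, n_rays)
        d = directions[lo:hi, None, :]            # (C,1,3)
        o = origins[lo:hi, None, :]
        pvec = np.cross(d, e2[None, :, :])        # (C,T,3)
        det = np.einsum("tk,ctk->ct", e1, pvec)
        with np.errstate(invalid="ignore", divide="ignore"):
            inv_det = np.where(np.abs(det) > eps, 1.0 / det, np.nan)
        tvec = o - v0[None, :, :]
        u = np.einsum("ctk,ctk->ct", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("ctk,ctk->ct", d, qvec) * inv_det
        t = np.einsum("tk,ctk->ct", e2, qvec) * inv_det
        bary_tol = 1e-9
        valid = (
            (u >= -bary_tol)
            & (v >= -bary_tol)
            & (u + v <= 1.0 + bary_tol)
            & (t > t_min)
            & (t <= t_max)
        )
        t = np.where(valid, t, np.inf)
        if exclude is not None:
            for i in range(lo, hi):
                ids = exclude[i]
                if len(ids):
                    t[i - lo, ids] = np.inf
        best = np.argmin(t, axis=1)
        rows = np.arange(hi - lo)
        t_best = t[rows, best]
        t_out[lo:hi] = t_best
        f_out[lo:hi] = np.where(np.isfinite(t_best), best, -1)
    return t_out, f_out


# ---------------------------------------------------------------------------
# Point-to-surface distance
# ---------------------------------------------------------------------------

def point_triangle_closest(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on each triangle (a,b,c) to each query point p.

    Vectorized Voronoi-region classification (Ericson, Real-Time Collision
    Detection).  All inputs (N, 3); returns (distance (N,), closest point
    (N, 3)).
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, pts):
        m = mask & ~done
        closest[m] = pts[m] if pts.shape == p.shape else pts
        done[m] = True

    # vertex regions
    assign((d1 <= 0) & (d2 <= 0), a)
    assign((d3 >= 0) & (d4 <= d3), b)
    assign((d6 >= 0) & (d5 <= d6), c)

    # edge AB
    vc = d1 * d4 - d3 * d2
    with np.errstate(invalid="ignore", divide="ignore"):
        v_ab = d1 / (d1 - d3)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)

    # edge AC
    vb = d5 * d2 - d1 * d6
    with np.errstate(invalid="ignore", divide="ignore"):
        w_ac = d2 / (d2 - d6)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)

    # edge BC
    va = d3 * d6 - d5 * d4
    with np.errstate(invalid="ignore", divide="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))

    # interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    assign(~done, a + v[:, None] * ab + w[:, None] * ac)

    dist = np.linalg.norm(p - closest, axis=1)
    return dist, closest


class SurfaceDistanceQuery:
    """Exact nearest-surface distance queries against a fixed triangle mesh.

    Candidate triangles come from a k-d tree over triangle centroids; the
    candidate set is then widened by each triangle's circumscribing radius so
    the reported minimum is exact, not approximate.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=np.float64)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.centroids = triangle_centroids(self.vertices, self.faces)
        corners = self.vertices[self.faces]  # (T,3,3)
        self.radii = np.linalg.norm(corners - self.centroids[:, None, :], axis=2).max(axis=1)
        self.max_radius = float(self.radii.max()) if len(self.radii) else 0.0
        self.tree = cKDTree(self.centroids)

    def _update_best(self, points, best, best_face, owner, cand):
        """Exact-evaluate candidate triangles and fold them into the running best."""
        tri = self.vertices[self.faces[cand]]
        d2, _ = point_triangle_closest(points[owner], tri[:, 0], tri[:, 1], tri[:, 2])
        order = np.lexsort((d2, owner))
        uniq, start = np.unique(owner[order], return_index=True)
        cand_idx = order[start]
        improve = d2[cand_idx] < best[uniq]
        best[uniq[improve]] = d2[cand_idx[improve]]
        best_face[uniq[improve]] = cand[cand_idx[improve]]

    def distance(self, points: np.ndarray, k: int = 8) -> tuple[np.ndarray, np.ndarray]:
        """Return (distance, closest face index) for each query point.

        Exactness argument: a triangle whose centroid is farther than
        ``best + circumradius`` cannot contain a closer point, so after the
        k-nearest stage only triangles inside that bound are re-examined.
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        n_tris = len(self.faces)
        npts = len(points)
        k1 = min(k, n_tris)
        k2 = min(max(8 * k1, 64), n_tris)
        d_c, idx = self.tree.query(points, k=k2)
        if k2 == 1:
            d_c = d_c[:, None]
            idx = idx[:, None]

        # stage 1: exact over the k1 nearest-centroid triangles
        flat_idx = idx[:, :k1].ravel()
        flat_pts = np.repeat(points, k1, axis=0)
        tri = self.vertices[self.faces[flat_idx]]
        d, _ = point_triangle_closest(flat_pts, tri[:, 0], tri[:, 1], tri[:, 2])
        d = d.reshape(npts, k1)
        best_col = np.argmin(d, axis=1)
        best = d[np.arange(npts), best_col]
        best_face = idx[np.arange(npts), best_col].astype(np.int64)

        # stage 2: of the remaining k-NN candidates, exact-evaluate only
        # those close enough to possibly beat the current best
        if k2 > k1:
            rest = idx[:, k1:]
            mask = d_c[:, k1:] < (best[:, None] + self.radii[rest])
            if mask.any():
                owner = np.nonzero(mask)[0]
                self._update_best(points, best, best_face, owner, rest[mask])

        # stage 3: points whose k2-th centroid is still inside the exactness
        # bound may have unexamined winners; resolve them with a ball query
        unresolved = np.nonzero(d_c[:, -1] < best + self.max_radius)[0]
        if len(unresolved) and k2 < n_tris:
            sub = points[unresolved]
            extra = self.tree.query_ball_point(sub, best[unresolved] + self.max_radius)
            counts = np.fromiter((len(e) for e in extra), dtype=np.int64,
                                 count=len(unresolved))
            if counts.sum():
                cand = np.concatenate(
                    [np.asarray(e, dtype=np.int64) for e in extra if e]
                )
                owner = np.repeat(unresolved, counts)
                # cheap prefilter with per-triangle radii: the global
                # max_radius bound is dominated by a few large cap fans
                d_pc = np.linalg.norm(
                    points[owner] - self.centroids[cand], axis=1
                )
                keep = d_pc - self.radii[cand] < best[owner]
                if keep.any():
                    self._update_best(
                        points, best, best_face, owner[keep], cand[keep]
                    )
        return best, best_face


def closest_surface_distance(
    points: np.ndarray, vertices: np.ndarray, faces: np.ndarray
) -> np.ndarray:
    """One-shot exact point-to-surface distances (mm)."""
    return SurfaceDistanceQuery(vertices, faces).distance(points)[0]


# ---------------------------------------------------------------------------
# Boundary loops
# ---------------------------------------------------------------------------

def boundary_loops(faces: np.ndarray) -> list[np.ndarray]:
    """Ordered vertex loops of boundary edges (edges used by one face).

    Loops follow the direction the boundary edges appear in their faces, so
    a cap fan built as (centroid, loop[i+1], loop[i]) has winding consistent
    with the surrounding surface.
    """
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary = edges[counts[inv] == 1]
    nxt = {}
    for a, b in boundary:
        nxt[int(a)] = int(b)
    loops = []
    visited: set[int] = set()
    for start in list(nxt):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        cur = nxt[start]
        while cur != start:
            loop.append(cur)
            visited.add(cur)
            if cur not in nxt:  # open chain: non-manifold boundary
                break
            cur = nxt[cur]
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def _cap_loops(
    vertices: np.ndarray, loops: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Fan-triangulate each loop about its centroid.

    Returns (new vertices appended, cap faces).  Assumes loops are
    star-shaped about their centroid (true for airway cross-sections).
    """
    new_verts = []
    new_faces = []
    nv = len(vertices)
    for loop in loops:
        if len(loop) < 3:
            continue
        centroid = vertices[loop].mean(axis=0)
        ci = nv + len(new_verts)
        new_verts.append(centroid)
        nxt = np.roll(loop, -1)
        # (centroid, b, a) so the cap winding matches the adjacent surface
        new_faces.append(np.column_stack([np.full(len(loop), ci), nxt, loop]))
    if not new_faces:
        return np.empty((0, 3)), np.empty((0, 3), dtype=np.int64)
    return np.asarray(new_verts, dtype=np.float64), np.concatenate(new_faces)


# ---------------------------------------------------------------------------
# Plane cutting
# ---------------------------------------------------------------------------

def cut_mesh_arrays(
    vertices: np.ndarray,
    faces: np.ndarray,
    cap_mask: np.ndarray,
    plane_point: np.ndarray,
    plane_normal: np.ndarray,
    keep: str = "positive",
    tol: float = 1e-9,
    cap: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut a closed mesh with a plane, keeping one side, re-capped watertight.

    Triangles straddling the plane are split exactly at the plane.  Returns
    (vertices, faces, cap_mask) of the kept half; ``cap_mask`` marks faces
    lying in the cut plane (and any caps inherited from the input).
    """
    if keep not in ("positive", "negative"):
        raise ValueError(f"keep must be 'positive' or 'negative', got {keep!r}")
    normal = np.asarray(plane_normal, dtype=np.float64)
    normal = normal / np.linalg.norm(normal)
    sign = 1.0 if keep == "positive" else -1.0
    s = sign * ((vertices - np.asarray(plane_point, dtype=np.float64)) @ normal)
    s[np.abs(s) < tol] = 0.0

    fs = s[faces]  # (F, 3)
    keep_all = (fs >= 0).all(axis=1) & ~(fs == 0).all(axis=1)
    drop_all = (fs <= 0).all(axis=1)
    straddle = ~(keep_all | drop_all)

    out_faces = [faces[keep_all]]
    out_caps = [cap_mask[keep_all]]
    verts = [vertices]
    n_base = len(vertices)
    edge_cache: dict[tuple[int, int], int] = {}
    extra_verts: list[np.ndarray] = []

    def edge_point(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        if key in edge_cache:
            return edge_cache[key]
        t = s[i] / (s[i] - s[j])
        p = vertices[i] + t * (vertices[j] - vertices[i])
        idx = n_base + len(extra_verts)
        extra_verts.append(p)
        edge_cache[key] = idx
        return idx

    split_faces = []
    split_caps = []
    for fi in np.nonzero(straddle)[0]:
        tri = faces[fi]
        sv = s[tri]
        pos = [int(tri[k]) for k in range(3) if sv[k] > 0]
        neg = [int(tri[k]) for k in range(3) if sv[k] < 0]
        zer = [int(tri[k]) for k in range(3) if sv[k] == 0]
        # rotate so winding is preserved: find original cyclic order
        order = [int(v) for v in tri]

        def after(v):
            return order[(order.index(v) + 1) % 3]

        if len(zer) == 1 and len(pos) == 1 and len(neg) == 1:
            z, p, n = zer[0], pos[0], neg[0]
            m = edge_point(p, n)
            # kept triangle is (z, p, m) in an order consistent with original
            if after(z) == p:
                split_faces.append([z, p, m])
            else:
                split_faces.append([z, m, p])
            split_caps.append(cap_mask[fi])
        elif len(pos) == 1 and len(neg) == 2:
            p = pos[0]
            n1, n2 = neg
            m1 = edge_point(p, n1)
            m2 = edge_point(p, n2)
            if after(p) == n1:
                split_faces.append([p, m1, m2])
            else:
                split_faces.append([p, m2, m1])
            split_caps.append(cap_mask[fi])
        elif len(pos) == 2 and len(neg) == 1:
            n = neg[0]
            p1, p2 = pos
            m1 = edge_point(p1, n)
            m2 = edge_point(p2, n)
            if after(n) == p1:  # order n, p1, p2
                split_faces.append([m1, p1, p2])
                split_faces.append([m1, p2, m2])
            else:  # order n, p2, p1
                split_faces.append([m2, p2, p1])
                split_faces.append([m2, p1, m1])
            split_caps.extend([cap_mask[fi]] * 2)
        # pos with zeros only (len(neg)==0) is covered by keep_all test;
        # zeros+neg only falls to drop.

    if extra_verts:
        verts.append(np.asarray(extra_verts))
    if split_faces:
        out_faces.append(np.asarray(split_faces, dtype=np.int64))
        out_caps.append(np.asarray(split_caps, dtype=bool))

    all_verts = np.concatenate(verts)
    all_faces = np.concatenate(out_faces) if out_faces else np.empty((0, 3), dtype=np.int64)
    all_caps = np.concatenate(out_caps) if out_caps else np.empty(0, dtype=bool)

    # drop unreferenced vertices
    used = np.unique(all_faces)
    remap = np.full(len(all_verts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    all_faces = remap[all_faces]
    all_verts = all_verts[used]

    if cap and len(all_faces):
        loops = boundary_loops(all_faces)
        cap_v, cap_f = _cap_loops(all_verts, loops)
        if len(cap_f):
            all_verts = np.concatenate([all_verts, cap_v])
            all_faces = np.concatenate([all_faces, cap_f])
            all_caps = np.concatenate([all_caps, np.ones(len(cap_f), dtype=bool)])
    return all_verts, all_faces, all_caps
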