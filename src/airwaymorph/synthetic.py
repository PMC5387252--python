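"""Synthetic airway phantoms and cohorts with closed-form ground truth.

The generator emulates the geometry the airway measures assume: a tubular
lumen running inferior (z = 0, level of C3) to superior (z = total length,
nares), with a radius profile r(theta, z) built from a smooth axial base
profile minus localized inward Gaussian "obstruction" bulges — an adenoid
pad on the posterior nasopharyngeal wall, tonsillar bulges on the
oropharyngeal walls.  Pre/post-surgical (T1/T2) pairs differ by a known
bulge deflation, and synthetic cohorts couple OSA-18 quality-of-life change
to airway patency change through a Gaussian copula with a controllable
Spearman association.

Ground truth (volumes, wall areas, minimum lumen area, caliber-band
fractions, removal fields) is computed by quadrature and ray marching on
the *parametric* surface, independent of any meshing, so mesh-based
measurements can be validated against it at any resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, interpolate, optimize, stats as sps
from scipy.spatial import cKDTree

from .mesh_io import AirwayMesh
from .stats import SubjectRecord, OSA18_SUBDOMAINS

TWO_PI = 2.0 * np.pi

# default anatomy (mm): oropharynx 0-30, nasopharynx 30-55, nasal cavity 55-100
DEFAULT_SEGMENTS = {"OP": 30.0, "NP": 25.0, "NS": 45.0}
# axial base-radius knots (z, r): widest in the pharynx, narrow nasal meatus
DEFAULT_PROFILE = ((-10.0, 7.0), (0.0, 7.0), (15.0, 7.2), (30.0, 7.8),
                   (42.5, 8.0), (55.0, 7.0), (70.0, 5.8), (100.0, 5.2))


@dataclass
class Bulge:
    """Inward Gaussian obstruction on the tube wall.

    ``center_z`` mm along the airway, ``theta_deg`` azimuth of the bulge
    center (180 = posterior wall), ``sigma_z`` / ``sigma_theta_deg`` extents,
    ``depth`` mm of maximal inward displacement.
    """

    center_z: float
    theta_deg: float
    sigma_z: float
    sigma_theta_deg: float
    depth: float
    name: str = ""

    def indent(self, theta: np.ndarray, z: np.ndarray) -> np.ndarray:
        dth = np.angle(np.exp(1j * (theta - np.radians(self.theta_deg))))
        return self.depth * np.exp(
            -0.5 * (z - self.center_z) ** 2 / self.sigma_z**2
            - 0.5 * dth**2 / np.radians(self.sigma_theta_deg) ** 2
        )

    def indent_partials(self, theta, z):
        """(d/dtheta, d/dz) of the indentation."""
        dth = np.angle(np.exp(1j * (theta - np.radians(self.theta_deg))))
        val = self.indent(theta, z)
        return (
            -val * dth / np.radians(self.sigma_theta_deg) ** 2,
            -val * (z - self.center_z) / self.sigma_z**2,
        )


def adenoid_bulge(depth: float, center_z: float = 42.5, sigma_z: float = 8.0,
                  sigma_theta_deg: float = 75.0) -> Bulge:
    """Adenoid pad: posterior nasopharyngeal wall."""
    return Bulge(center_z, 180.0, sigma_z, sigma_theta_deg, depth, "adenoid")


def tonsil_bulge(depth: float, side: str = "left", center_z: float = 15.0,
                 sigma_z: float = 7.0, sigma_theta_deg: float = 55.0) -> Bulge:
    """Palatine tonsil: lateral/posterolateral oropharyngeal wall."""
    theta = 120.0 if side == "left" else 240.0
    return Bulge(center_z, theta, sigma_z, sigma_theta_deg, depth, f"tonsil_{side}")


def obstruction_pair(
    name: str, depth_per_wall: float, center_z: float, theta_deg: float,
    sigma_z: float, sigma_theta_deg: float,
) -> tuple[Bulge, Bulge]:
    """Opposed bulge pair narrowing the lumen from both walls.

    A single-wall bulge cannot narrow the through-axis caliber below the
    opposite wall's base radius; severe obstructions (adenoid pad plus
    opposing-wall contact, kissing tonsils) indent both walls, which this
    helper models as two mirrored Gaussians sharing a name prefix.
    """
    a = Bulge(center_z, theta_deg, sigma_z, sigma_theta_deg, depth_per_wall,
              f"{name}_a")
    b = Bulge(center_z, (theta_deg + 180.0) % 360.0, sigma_z, sigma_theta_deg,
              depth_per_wall, f"{name}_b")
    return a, b


@dataclass
class PhantomSpec:
    """Full parametric description of one airway phantom."""

    segment_lengths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENTS)
    )
    profile_knots: tuple[tuple[float, float], ...] = DEFAULT_PROFILE
    bulges: tuple[Bulge, ...] = ()
    n_theta: int = 96
    axial_step: float = 1.0
    inferior_margin: float = 4.0  # tube extends below z=0 so the C3 plane cuts
    noise_sigma: float = 0.0     # radial vertex jitter, mm
    seed: int = 0
    radial_scale: float = 1.0    # uniform scaling of the whole radius field
    min_radius: float = 0.2      # positivity floor unless occlusion intended
    allow_occlusion: bool = False

    # -- derived geometry ---------------------------------------------------
    @property
    def total_length(self) -> float:
        return float(sum(self.segment_lengths.values()))

    @property
    def z_range(self) -> tuple[float, float]:
        return (-self.inferior_margin, self.total_length)

    def segment_bounds(self, label: str) -> tuple[float, float]:
        z0 = 0.0
        for name in ("OP", "NP", "NS"):
            z1 = z0 + self.segment_lengths[name]
            if name == label:
                return (z0, z1)
            z0 = z1
        raise KeyError(label)

    def _base(self):
        knots = np.asarray(self.profile_knots, dtype=np.float64)
        return interpolate.PchipInterpolator(knots[:, 0], knots[:, 1])

    def radius(self, theta, z):
        theta = np.asarray(theta, dtype=np.float64)
        z = np.asarray(z, dtype=np.float64)
        r = self._base()(z) * np.ones_like(theta)
        for b in self.bulges:
            r = r - b.indent(theta, z)
        return self.radial_scale * r

    def radius_partials(self, theta, z):
        """(r, dr/dtheta, dr/dz) on broadcast grids."""
        theta = np.asarray(theta, dtype=np.float64)
        z = np.asarray(z, dtype=np.float64)
        base = self._base()
        r = base(z) * np.ones_like(theta)
        r_t = np.zeros(np.broadcast_shapes(theta.shape, z.shape))
        r_z = base.derivative()(z) * np.ones_like(theta)
        for b in self.bulges:
            r = r - b.indent(theta, z)
            pt, pz = b.indent_partials(theta, z)
            r_t = r_t - pt
            r_z = r_z - pz
        s = self.radial_scale
        return s * r, s * r_t, s * r_z

    def validate(self) -> None:
        th = np.linspace(0, TWO_PI, 181)
        zz = np.linspace(*self.z_range, 301)
        r = self.radius(th[:, None], zz[None, :])
        if not self.allow_occlusion and r.min() <= self.min_radius:
            raise ValueError(
                f"bulges self-intersect the lumen: min radius {r.min():.3f} mm "
                f"<= floor {self.min_radius} mm"
            )


@dataclass
class PhantomTruth:
    """Meshing-independent ground truth for one phantom (quadrature-based)."""

    spec: PhantomSpec
    volume_cm3: dict[str, float]        # per segment + 'WHOLE'
    wall_area_cm2: dict[str, float]     # lateral wall only (no caps)
    min_lumen_area_mm2: float
    min_lumen_z_mm: float

    def section_area(self, z: float, n_theta: int = 512) -> float:
        th = np.linspace(0, TWO_PI, n_theta, endpoint=False)
        r = self.spec.radius(th, np.full_like(th, z))
        return float(0.5 * np.mean(r**2) * TWO_PI)

    def caliber_band_fractions(
        self, segment: str, low: float = 4.0, high: float = 10.0,
        n_theta: int = 256, n_z: int = 200,
    ) -> dict[str, float]:
        """Area-weighted band fractions of the through-axis lumen caliber.

        The caliber at a wall point is r(theta, z) + r(theta + pi, z): the
        chord through the axis, a fast surrogate for the normal-ray distance
        on smooth tubes.
        """
        z0, z1 = self.spec.segment_bounds(segment)
        th = np.linspace(0, TWO_PI, n_theta, endpoint=False)[:, None]
        zz = np.linspace(z0, z1, n_z)[None, :]
        r, r_t, r_z = self.spec.radius_partials(th, zz)
        opp = self.spec.radius(th + np.pi, zz)
        caliber = r + opp
        w = np.sqrt(r_t**2 + r**2 * (1.0 + r_z**2))  # area element
        total = w.sum()
        return {
            "constriction": float(w[caliber < low].sum() / total * 100.0),
            "middle": float(
                w[(caliber >= low) & (caliber <= high)].sum() / total * 100.0
            ),
            "patency": float(w[caliber > high].sum() / total * 100.0),
        }

    def wall_ray_band_fractions(
        self, segment: str, low: float = 4.0, high: float = 10.0,
        n_theta: int = 96, n_z: int = 120, max_ray: float = 50.0,
    ) -> tuple[dict[str, float], np.ndarray]:
        """Area-weighted band fractions of the true inward normal-ray distance.

        Rays are marched against the analytic surface (step 0.1 mm, then
        bisection to 1e-3 mm), so this matches the mesh measurement's
        definition without any mesh.  Returns (fractions, distances grid).
        """
        z0, z1 = self.spec.segment_bounds(segment)
        th = np.linspace(0, TWO_PI, n_theta, endpoint=False)
        zz = np.linspace(z0 + 1e-3, z1 - 1e-3, n_z)
        TH, ZZ = np.meshgrid(th, zz, indexing="ij")
        d = _ray_march_distances(self.spec, TH.ravel(), ZZ.ravel(), max_ray)
        r, r_t, r_z = self.spec.radius_partials(TH, ZZ)
        w = np.sqrt(r_t**2 + r**2 * (1.0 + r_z**2)).ravel()
        hit = np.isfinite(d)
        total = w[hit].sum()
        fr = {
            "constriction": float(w[hit & (d < low)].sum() / total * 100.0),
            "middle": float(
                w[hit & (d >= low) & (d <= high)].sum() / total * 100.0
            ),
            "patency": float(w[hit & (d > high)].sum() / total * 100.0),
        }
        return fr, d.reshape(n_theta, n_z)


def _surface_points_normals(spec: PhantomSpec, theta: np.ndarray, z: np.ndarray):
    """Surface points and outward unit normals at parametric samples."""
    r, r_t, r_z = spec.radius_partials(theta, z)
    ct, st = np.cos(theta), np.sin(theta)
    pts = np.stack([r * ct, r * st, z], axis=-1)
    # x_theta × x_z for x = (r ct, r st, z); outward has positive radial part
    nx = r * ct + r_t * st
    ny = r * st - r_t * ct
    nz = -r * r_z
    n = np.stack([nx, ny, nz], axis=-1)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    return pts, n


def _ray_march_distances(
    spec: PhantomSpec, theta: np.ndarray, z: np.ndarray,
    max_ray: float = 50.0, step: float = 0.1,
) -> np.ndarray:
    """First re-intersection distance of inward normal rays with the surface.

    The implicit surface is F(x) = |x_xy| - r(atan2(y, x), z) = 0; F < 0
    inside the lumen.  March from each wall sample along the inward normal
    until F crosses back to >= 0, then bisect.  Rays leaving the tube's z
    extent are misses (NaN).
    """
    pts, normals = _surface_points_normals(spec, theta, z)
    dirs = -normals
    zlo, zhi = spec.z_range

    def fval(t):
        p = pts + t[:, None] * dirs
        rad = np.hypot(p[:, 0], p[:, 1])
        th = np.arctan2(p[:, 1], p[:, 0])
        inside_z = (p[:, 2] >= zlo) & (p[:, 2] <= zhi)
        f = rad - spec.radius(th, np.clip(p[:, 2], zlo, zhi))
        return f, inside_z

    n = len(pts)
    t_lo = np.full(n, np.nan)
    t_hi = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)
    entered = np.zeros(n, dtype=bool)  # has gone properly inside (F < -tol)
    prev_t = np.full(n, 1e-4)
    f_prev, _ = fval(prev_t)
    tol = 1e-6
    t = 1e-4 + step
    while t <= max_ray + step and active.any():
        tt = np.full(n, t)
        f, inz = fval(tt)
        # leaving the z extent while still active => miss
        leave = active & ~inz
        active[leave] = False
        entered |= active & (f < -tol)
        cross = active & entered & (f >= 0) & (f_prev < 0)
        t_lo[cross] = prev_t[cross]
        t_hi[cross] = t
        active[cross] = False
        prev_t = tt
        f_prev = f
        t += step
    # bisection
    mask = np.isfinite(t_lo)
    lo = t_lo[mask]
    hi = t_hi[mask]
    sub_pts, sub_dirs = pts[mask], dirs[mask]

    def fsub(tv):
        p = sub_pts + tv[:, None] * sub_dirs
        th = np.arctan2(p[:, 1], p[:, 0])
        return np.hypot(p[:, 0], p[:, 1]) - spec.radius(
            th, np.clip(p[:, 2], zlo, zhi)
        )

    for _ in range(20):
        mid = 0.5 * (lo + hi)
        fm = fsub(mid)
        neg = fm < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    out = np.full(n, np.nan)
    out[mask] = 0.5 * (lo + hi)
    return out


# ---------------------------------------------------------------------------
# Truth quadrature
# ---------------------------------------------------------------------------

def _truth_for(spec: PhantomSpec, n_theta: int = 512, n_z_per_mm: float = 4.0) -> PhantomTruth:
    th = np.linspace(0, TWO_PI, n_theta, endpoint=False)[:, None]

    def section_area(zz):
        r = spec.radius(th, zz[None, :])
        return 0.5 * (r**2).mean(axis=0) * TWO_PI

    def seg_integrals(z0, z1):
        nz = max(9, int((z1 - z0) * n_z_per_mm) | 1)
        zz = np.linspace(z0, z1, nz)
        vol = integrate.simpson(section_area(zz), x=zz)
        r, r_t, r_z = spec.radius_partials(th, zz[None, :])
        ds = np.sqrt(r_t**2 + r**2 * (1.0 + r_z**2))
        area = integrate.simpson(ds.mean(axis=0) * TWO_PI, x=zz)
        return float(vol), float(area)

    volumes, areas = {}, {}
    for label in ("OP", "NP", "NS"):
        v, a = seg_integrals(*spec.segment_bounds(label))
        volumes[label] = v / 1000.0
        areas[label] = a / 100.0
    v, a = seg_integrals(0.0, spec.total_length)
    volumes["WHOLE"] = v / 1000.0
    areas["WHOLE"] = a / 100.0

    # minimum lumen area over the ROI
    zz = np.linspace(0.0, spec.total_length, int(spec.total_length * 4) + 1)
    aa = section_area(zz)
    k = int(np.argmin(aa))
    lo = zz[max(k - 1, 0)]
    hi = zz[min(k + 1, len(zz) - 1)]
    res = optimize.minimize_scalar(
        lambda z: float(section_area(np.array([z]))[0]),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-4},
    )
    return PhantomTruth(
        spec=spec,
        volume_cm3=volumes,
        wall_area_cm2=areas,
        min_lumen_area_mm2=float(res.fun),
        min_lumen_z_mm=float(res.x),
    )


# ---------------------------------------------------------------------------
# Meshing
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[AirwayMesh, PhantomTruth]:
    """Watertight mesh of the phantom plus its quadrature ground truth.

    Deterministic: the same spec (including seed) yields an identical mesh.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    z0, z1 = spec.z_range
    n_rows = max(2, int(round((z1 - z0) / spec.axial_step)) + 1)
    zz = np.linspace(z0, z1, n_rows)
    th = np.linspace(0, TWO_PI, spec.n_theta, endpoint=False)
    TH, ZZ = np.meshgrid(th, zz, indexing="xy")  # (n_rows, n_theta)
    r = spec.radius(TH, ZZ)
    if spec.noise_sigma > 0:
        r = np.maximum(
            r + rng.normal(0.0, spec.noise_sigma, size=r.shape), spec.min_radius
        )
    verts = np.stack(
        [r * np.cos(TH), r * np.sin(TH), ZZ], axis=-1
    ).reshape(-1, 3)

    nt = spec.n_theta
    faces = []
    for j in range(n_rows - 1):
        base = j * nt
        nxt = (j + 1) * nt
        k = np.arange(nt)
        kp = (k + 1) % nt
        # outward winding for CCW theta, z increasing
        faces.append(np.column_stack([base + k, base + kp, nxt + kp]))
        faces.append(np.column_stack([base + k, nxt + kp, nxt + k]))
    faces = np.concatenate(faces)
    caps = np.zeros(len(faces), dtype=bool)

    # end caps: fans about the axis points
    centers = np.array([[0.0, 0.0, z0], [0.0, 0.0, z1]])
    c0 = len(verts)
    c1 = c0 + 1
    verts = np.concatenate([verts, centers])
    k = np.arange(nt)
    kp = (k + 1) % nt
    bottom = np.column_stack([np.full(nt, c0), kp, k])            # normal -z
    top_base = (n_rows - 1) * nt
    top = np.column_stack([np.full(nt, c1), top_base + k, top_base + kp])  # +z
    faces = np.concatenate([faces, bottom, top])
    caps = np.concatenate([caps, np.ones(2 * nt, dtype=bool)])

    mesh = AirwayMesh(verts, faces, "WHOLE", cap_faces=caps)
    from ._geometry import signed_volume

    if signed_volume(mesh.vertices, mesh.faces) < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    mesh.closed = True
    return mesh, _truth_for(spec)


@dataclass
class SurgicalPairTruth:
    """Truth for a T1/T2 phantom pair differing by a known tissue removal."""

    t1: PhantomTruth
    t2: PhantomTruth
    removed_bulges: tuple[str, ...]

    def removal_depth_field(self, theta, z) -> np.ndarray:
        """Radial depth of removed tissue (mm) at parametric samples."""
        return self.t2.spec.radius(theta, z) - self.t1.spec.radius(theta, z)

    def displacement_band_fractions(
        self, low: float = 4.0, high: float = 10.0,
        n_theta: int = 256, n_z_per_mm: float = 3.0,
    ) -> dict[str, float]:
        """Area-weighted truth for the T1->T2 nearest-surface distance bands.

        Distances are measured from a fine parametric sampling of the T1
        surface to a finer point sampling of the T2 surface, independent of
        any measurement mesh.
        """
        spec1, spec2 = self.t1.spec, self.t2.spec
        z0, z1 = spec1.z_range
        nz = int((z1 - z0) * n_z_per_mm)
        th = np.linspace(0, TWO_PI, n_theta, endpoint=False)
        zz = np.linspace(z0, z1, nz)
        TH, ZZ = np.meshgrid(th, zz, indexing="ij")
        p1, _ = _surface_points_normals(spec1, TH, ZZ)
        r, r_t, r_z = spec1.radius_partials(TH, ZZ)
        w = np.sqrt(r_t**2 + r**2 * (1.0 + r_z**2)).ravel()
        # dense T2 cloud at twice the sampling rate
        th2 = np.linspace(0, TWO_PI, 2 * n_theta, endpoint=False)
        zz2 = np.linspace(z0, z1, 2 * nz)
        TH2, ZZ2 = np.meshgrid(th2, zz2, indexing="ij")
        p2, _ = _surface_points_normals(spec2, TH2, ZZ2)
        d, _ = cKDTree(p2.reshape(-1, 3)).query(p1.reshape(-1, 3))
        total = w.sum()
        return {
            "green": float(w[d < low].sum() / total * 100.0),
            "orange_yellow": float(
                w[(d >= low) & (d <= high)].sum() / total * 100.0
            ),
            "red": float(w[d > high].sum() / total * 100.0),
        }


def generate_surgical_pair(
    spec: PhantomSpec, removal: dict[str, float]
) -> tuple[AirwayMesh, AirwayMesh, SurgicalPairTruth]:
    """T1 mesh plus a T2 mesh with named bulges deflated by given depths (mm).

    ``removal`` maps bulge names to removal depths; depths exceeding the
    bulge are clipped with a warning.  The T1 and T2 meshes share the same
    parametric grid and seed, so they correspond point-for-point.
    """
    names = {b.name for b in spec.bulges}
    missing = set(removal) - names
    if missing:
        raise ValueError(f"removal targets not present in spec: {sorted(missing)}")
    new_bulges = []
    removed = []
    for b in spec.bulges:
        if b.name in removal:
            depth = removal[b.name]
            if depth > b.depth:
                warnings.warn(
                    f"removal {depth} mm deeper than bulge {b.name!r} "
                    f"({b.depth} mm); clipping"
                )
                depth = b.depth
            new_bulges.append(replace(b, depth=b.depth - depth))
            removed.append(b.name)
        else:
            new_bulges.append(b)
    spec_t2 = replace(spec, bulges=tuple(new_bulges))
    t1_mesh, t1_truth = generate_phantom(spec)
    t2_mesh, t2_truth = generate_phantom(spec_t2)
    return t1_mesh, t2_mesh, SurgicalPairTruth(t1_truth, t2_truth, tuple(removed))


def phantom_landmarks(spec: PhantomSpec, n: int = 10):
    """Deterministic named landmarks on the phantom surface (bony, fixed T1/T2).

    Points are placed on the *base* profile (bulges ignored), emulating
    skeletal landmarks unaffected by soft-tissue surgery.
    """
    from .mesh_io import LandmarkSet

    base = spec._base()
    zs = np.linspace(2.0, spec.total_length - 2.0, n)
    thetas = (np.arange(n) * 2.399963) % TWO_PI  # golden-angle spread
    pts = {}
    for i, (z, th) in enumerate(zip(zs, thetas)):
        r = float(base(z)) * spec.radial_scale + 2.0  # just outside the lumen
        pts[f"L{i:02d}"] = np.array([r * np.cos(th), r * np.sin(th), z])
    return LandmarkSet(pts)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSubject:
    record: SubjectRecord
    spec_t1: PhantomSpec
    spec_t2: PhantomSpec
    removal: dict[str, float]

    def meshes(self) -> tuple[AirwayMesh, AirwayMesh]:
        m1, _ = generate_phantom(self.spec_t1)
        m2, _ = generate_phantom(self.spec_t2)
        return m1, m2


@dataclass
class SyntheticCohort:
    subjects: list[CohortSubject]
    target_assoc: float
    seed: int

    @property
    def records(self) -> list[SubjectRecord]:
        return [s.record for s in self.subjects]


def _scale_profile(knots, scale):
    return tuple((z, r * scale) for z, r in knots)


def generate_cohort(
    n: int = 12,
    assoc: float = 0.7,
    seed: int = 0,
    tonsillectomy_fraction: float = 0.25,
    n_theta: int = 64,
    axial_step: float = 1.5,
) -> SyntheticCohort:
    """Synthetic pre/post surgical cohort with a controllable association.

    Each subject gets an individual airway size, an obstructing bulge
    (adenoid in NP for adenoidectomy subjects, palatine tonsil in OP for the
    tonsillectomy fraction) and a partial-to-complete removal.  OSA-18
    improvement is coupled to the truth patency gain (percentage points of
    the surgical segment's caliber-band fraction) through a Gaussian copula
    targeting Spearman ``assoc``.  A small uniform T2 radial re-scale
    emulates non-surgical state differences (mucosal congestion, breathing
    phase), which moves volume and surface area without much affecting
    caliber bands — the reason conventional measures track symptoms poorly.

    Records carry truth-derived measures; per-subject meshes are generated
    lazily via :meth:`CohortSubject.meshes`.
    """
    if n < 5:
        raise ValueError("cohort needs n >= 5")
    if not -1.0 <= assoc <= 1.0:
        raise ValueError("assoc must lie in [-1, 1]")
    if n < 8 and abs(assoc) > 0.8:
        warnings.warn("strong associations are poorly realizable at n < 8")
    rng = np.random.default_rng(seed)

    subjects: list[CohortSubject] = []
    patency_gain_points = np.empty(n)
    for i in range(n):
        scale = rng.uniform(0.9, 1.15)  # overall airway size
        is_tonsil = rng.random() < tonsillectomy_fraction
        seg = "OP" if is_tonsil else "NP"
        # base radius of the profile at the obstruction site
        base_r = (8.0 if seg == "NP" else 7.2) * scale
        # obstruction leaves a residual caliber of 2-6 mm at its deepest:
        # caliber = 2 * (base_r - depth_per_wall)
        residual = rng.uniform(2.0, 6.0)
        depth_per_wall = base_r - residual / 2.0
        sigma_z = rng.uniform(6.0, 11.0)
        # paired opposed Gaussians overlap in their azimuthal tails; keeping
        # sigma_theta <= 55 deg bounds the summed indentation below base_r
        sigma_th = rng.uniform(40.0, 55.0)
        if is_tonsil:
            bulges = obstruction_pair(
                "tonsil", depth_per_wall, center_z=15.0, theta_deg=120.0,
                sigma_z=sigma_z, sigma_theta_deg=sigma_th,
            )
            surgery = "tonsillectomy"
        else:
            bulges = obstruction_pair(
                "adenoid", depth_per_wall, center_z=42.5, theta_deg=180.0,
                sigma_z=sigma_z, sigma_theta_deg=sigma_th,
            )
            surgery = "adenoidectomy"
        removal_frac = rng.uniform(0.4, 1.0)
        removal = {b.name: removal_frac * depth_per_wall for b in bulges}
        # surgical-technique variability: the residual pad's extent differs
        # from the pre-surgical pad (suction diathermy vs microdebrider leave
        # different footprints), moving removed volume independently of the
        # residual caliber
        g_z = rng.uniform(0.7, 1.2)
        g_th = rng.uniform(0.7, 1.2)
        # non-surgical T2 state change (mucosal congestion state, breathing
        # phase, posture): uniform radial re-scale, ~5% sd — large enough to
        # move volume and surface area, too small to move caliber bands much
        t2_scale = rng.normal(1.0, 0.08)

        spec_t1 = PhantomSpec(
            profile_knots=_scale_profile(DEFAULT_PROFILE, scale),
            bulges=tuple(bulges),
            n_theta=n_theta,
            axial_step=axial_step,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        residual_bulges = tuple(
            replace(
                b,
                depth=b.depth - removal[b.name],
                sigma_z=b.sigma_z * g_z,
                sigma_theta_deg=min(b.sigma_theta_deg * g_th, 55.0),
            )
            for b in bulges
        )
        spec_t2 = replace(
            spec_t1, bulges=residual_bulges, radial_scale=t2_scale
        )
        truth1 = _truth_for(spec_t1, n_theta=256, n_z_per_mm=2.0)
        truth2 = _truth_for(spec_t2, n_theta=256, n_z_per_mm=2.0)
        b1 = truth1.caliber_band_fractions(seg)
        b2 = truth2.caliber_band_fractions(seg)
        patency_gain_points[i] = b2["patency"] - b1["patency"]

        record = SubjectRecord(
            subject_id=f"S{i + 1:03d}",
            osa18_t1=60.0,  # overwritten by the copula step below
            osa18_t2=60.0,
            measures={
                "volume_cm3": (truth1.volume_cm3[seg], truth2.volume_cm3[seg]),
                "surface_cm2": (truth1.wall_area_cm2[seg], truth2.wall_area_cm2[seg]),
                "min_x_area_mm2": (
                    truth1.min_lumen_area_mm2, truth2.min_lumen_area_mm2
                ),
                "constriction_pct": (b1["constriction"], b2["constriction"]),
                "patency_pct": (b1["patency"], b2["patency"]),
            },
            surgery="tonsillectomy" if is_tonsil else "adenoidectomy",
            recall_months=float(np.round(rng.normal(7.0, 1.5), 1)),
        )
        subjects.append(CohortSubject(record, spec_t1, spec_t2, removal))

    # Gaussian copula: OSA-18 improvement rank-coupled to patency gain
    rho_pearson = 2.0 * np.sin(np.pi * assoc / 6.0)
    ranks = sps.rankdata(patency_gain_points)
    scores = sps.norm.ppf((ranks - 0.5) / n)
    latent = rho_pearson * scores + np.sqrt(max(0.0, 1 - rho_pearson**2)) * rng.normal(
        size=n
    )
    # clip only at physiologic extremes; a tight clip would tie the ranks of
    # the best responders and distort the targeted association
    improvement_pct = np.clip(38.0 + 18.0 * latent, -40.0, 88.0)
    t1_totals = rng.uniform(55.0, 95.0, size=n)
    t2_totals = np.clip(t1_totals * (1.0 - improvement_pct / 100.0), 18.0, 126.0)

    # subdomain split: 4+4+3+3+4 items of the 18
    weights = np.array([4, 4, 3, 3, 4], dtype=float) / 18.0
    for i, subj in enumerate(subjects):
        rec = subj.record
        rec.osa18_t1 = float(np.round(t1_totals[i], 1))
        rec.osa18_t2 = float(np.round(t2_totals[i], 1))
        for t_attr, total in (("subdomains_t1", rec.osa18_t1),
                              ("subdomains_t2", rec.osa18_t2)):
            jitter = rng.dirichlet(weights * 40.0)
            setattr(
                subj.record, t_attr,
                {k: float(np.round(total * w, 1))
                 for k, w in zip(OSA18_SUBDOMAINS, jitter)},
            )
    return SyntheticCohort(subjects, assoc, seed)
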