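# Methods

This note documents the models, conventions and numerical choices behind
`airwaymorph`, in the order the pipeline applies them.

## Scope and units

The analyzed region of interest is the upper airway lumen from the anterior
nares to the level of the anterior-inferior body of C3, split into nasal
cavity (NS), nasopharynx (NP) and oropharynx (OP). All geometry is internal
millimetres; the reporting layer prints volume in cm³ and areas in cm²,
with MinXarea kept in mm² (published tables are inconsistent between mm²
and cm² for this quantity, so the unit is explicit everywhere and never
silently rescaled).

## Mesh conditioning

STL input (ASCII or binary) is welded at 1e-6 mm (STL repeats vertices per
facet), degenerate triangles are dropped, and watertightness is an
edge-manifold check (every undirected edge used exactly twice). ASCII
output is written at full `repr` precision so ASCII round-trips are exact;
binary STL stores float32 by definition of its 50-byte facet record, so
binary round-trips are exact only to single precision.

**Smoothing.** Commercial airway tools describe smoothing only by a
"factor"; the numeric semantics are not published. Here the factor f ∈
[0, 1] maps to a Taubin shrink/inflate pair with shrink weight λ = 0.5 f
and inflate weight ν = 0.48 f, 10 iterations by default. The inflate
weight sits just below the shrink weight so the smoother is contractive on
convex surfaces while remaining near volume-preserving on tubes (plain
Laplacian smoothing shrinks tubes and would bias airway volume low). f = 0
is the identity. On phantom tubes the default changes volume by well under
5%.

**"Wrapping"** is interpreted as hole-capping plus manifold repair, not
shrink-wrap remeshing: inputs are already segmented lumens and wrapping
serves only to produce watertight models for measurement. Boundary loops
are capped by centroid fans whose winding is inherited from the directed
boundary edges, so orientation stays globally consistent. Fans assume
loops star-shaped about their centroid — true for airway cross-sections,
not for arbitrary meshes.

## Partitioning

Cutting planes are explicit configuration (point + normal, or three
landmark names), never guessed anatomy. A plane cut splits straddling
triangles exactly at the plane, re-caps the kept half, and tags cap faces
so surface-area reports can exclude them; both cap-inclusive and
cap-exclusive areas are always available because published "surface area"
plausibly means airway wall only. Volume conservation across any partition
is enforced at 0.5% (cap tolerance); violation raises rather than warns.

## Conventional measures

Volume is the divergence-theorem sum of signed tetrahedra; negative signed
volume (inward winding) is auto-corrected with a warning. Cross-sectional
area sums the areas of all disjoint lumen polygons in the section plane —
the nasal airway is genuinely paired, so multi-polygon sections are summed,
not max-picked. MinXarea automates what is done manually on orthogonal
views: an exhaustive plane sweep along a configured axis (default step
0.5 mm, end caps skipped by a margin) followed by interval bisection to
0.05 mm. The sweep log is retained so the reported minimum can be checked
as a lower envelope. A minimum below 1e-3 mm² is flagged occluded.

## Wall-thickness (caliber) analysis

For each non-cap triangle, a ray starts at the centroid and travels along
the inward normal; the recorded distance is the first intersection with the
mesh, excluding the originating triangle and its edge neighbours and any
hit closer than 1e-4 mm (self-intersection guard). Rays that exit without a
hit within `max_ray` (default 50 mm) are misses: they are excluded from
band-fraction denominators and reported as a separate percentage, because
caps and open ends would otherwise distort the fractions. If the majority
of rays miss, normals are assumed inverted and the analysis retries with
flipped directions before failing.

Band conventions are strict at both ends — `d < 4` constriction, `d > 10`
patency, equality in the middle band — matching the literal threshold
wording. Thresholds are operator-configurable, not constants. Count
weighting ("percentage of triangles") is the default; area weighting is
offered because triangle sizes vary after smoothing. Whether the original
commercial implementation casts from vertices or centroids is not
documented; centroid is the default here and a vertex mode is available
(`origin="vertex"`, shortest hit over the triangle's three vertices).

Pre/post change is reported in **both** published conventions — relative
percent (T1−T2)/T1·100 for constriction, (T2−T1)/T1·100 for patency, and
plain percentage-point differences — because published change tables are
internally ambiguous between them. A zero T1 patency makes relative gain
undefined; the absolute gain is returned with a `nonpercentable` flag.

Ray casting is a numba-compiled Möller–Trumbore kernel with early exit
(a chunked-numpy fallback exists); a 10k-triangle mesh takes ~0.5 s.

## Registration

Landmark alignment is closed-form orthogonal Procrustes (SVD) with a
reflection guard; fewer than three correspondences or a collinear
configuration raises with the singular values reported. ICP refinement
uses exact point-to-triangle correspondences (k-d tree over triangle
centroids, candidate sets widened by circumradii so distances are exact,
not approximate), trims matches beyond the 90th distance percentile for
robustness at segment boundaries, samples at most 2000 source vertices,
caps at 50 iterations, converges at 1e-4 mm mean-distance improvement, and
always returns the best transform seen — refinement can never end worse
than its initialization. T1 is always fixed; T2 moves.

## Part comparison

Each T1 vertex gets its unsigned exact distance to the nearest point of the
T2 surface (point-to-triangle, same exact query as ICP). Bands follow the
color-map convention: green < 4 mm, orange-yellow [4, 10] mm, red > 10 mm.
A signed variant (projection of the offset onto the T1 vertex normal)
distinguishes space gained from space lost. Count- and area-weighted band
fractions are both reported; vertex areas are barycentric thirds of
incident triangle areas. Misregistration is indistinguishable from tissue
change by construction, so registration quality is the caller's
responsibility and is logged upstream.

## Cohort statistics

Quartiles default to Tukey inclusive hinges (each half includes the median
element at odd n), with NumPy's linear interpolation as an option — the two
differ at clinical-pilot sample sizes, which is why the rule is explicit.
The Wilcoxon signed-rank test drops zero differences by default (Pratt
handling optional) and computes the exact two-sided p for n ≤ 25 by
subset-sum counting over all 2ⁿ sign assignments — equivalent to full
enumeration but polynomial, and valid under ties (ranks are doubled so tied
average ranks become integers); larger n uses the tie-corrected normal
approximation with continuity correction. Spearman ρ uses average ranks;
p-values are exact full-permutation for n ≤ 10 and t-approximate above.
No multiple-testing correction is applied by default, matching how such
pilot tables are reported; `stats.holm_correction` provides step-down
adjusted p-values for callers who want family-wise control. OSA-18 totals are validated to [18, 126]
and banded < 60 low, 60–80 moderate (closed interval), > 80 severe.

Percent-change columns report **two labelled estimands** — the median of
per-subject changes and the change of medians — because published tables
mix them without stating which.

## Synthetic phantoms

A phantom is a tube along z (z = 0 at the C3 level, increasing toward the
nares) with radius r(θ, z) = base(z) − Σ bulges, where base(z) is a
monotone-safe PCHIP through configured knots (defaults: oropharynx ≈ 7 mm,
nasopharynx ≈ 8 mm, narrowing to ≈ 5 mm in the nasal meatus; segment
lengths OP 30, NP 25, NS 45 mm — a realistic pediatric scale) and each
bulge is an inward Gaussian in (z, θ). Adenoid bulges sit on the posterior
nasopharyngeal wall (θ = 180°), tonsillar bulges posterolaterally in the
oropharynx. Severe obstructions are modelled as *opposed bulge pairs*
(`obstruction_pair`): a single-wall bulge can never narrow the
through-axis caliber below the opposite wall's radius, whereas real
obstruction (adenoid pad plus opposing-wall contact, kissing tonsils)
narrows from both sides. Azimuthal extents are kept ≤ 55° so the two
Gaussians' overlapping tails cannot drive the radius negative. The tube
extends a few mm below z = 0 so the inferior ROI plane genuinely cuts.

Ground truth is meshing-independent: volumes and wall areas by
trapezoid/Simpson quadrature of the parametric surface (periodic θ rule,
spectrally accurate on these smooth profiles), minimum lumen area by a
dense sweep plus bounded scalar minimization, normal-ray caliber by
marching rays against the implicit surface (0.1 mm steps, 20 bisection
rounds), and T1→T2 removal distances by nearest-neighbour queries against
a doubly-fine parametric point cloud of the T2 surface. A cheaper caliber
surrogate — the through-axis chord r(θ) + r(θ + π) — is used for cohort
truth, where only monotone ordering matters.

## Synthetic cohorts

Each subject draws an airway size scale U(0.9, 1.15), an obstruction
leaving a residual caliber U(2, 6) mm, axial/azimuthal extents, and a
removal fraction U(0.4, 1.0). Two further mechanisms give the cohort the
correlation structure observed in real outcome studies, where conventional
measures track symptoms poorly:

- a **non-surgical T2 state change** — a uniform radial re-scale, sd 8% —
  standing in for mucosal congestion state, breathing phase and posture,
  which move volume and surface area substantially (nasal mucosal cycling
  alone changes airway caliber by tens of percent) while barely moving the
  4/10 mm caliber bands;
- **surgical-technique variability** — the residual pad's extent is
  re-scaled by independent U(0.7, 1.2) factors, so the volume of tissue
  removed varies independently of the residual caliber the patient ends up
  with.

OSA-18 improvement is coupled to the truth patency gain (percentage points)
through a Gaussian copula: the patency gains' normal scores are mixed with
independent noise at Pearson weight ρₚ = 2 sin(π ρₛ/6), the inverse of the
bivariate-normal grade-correlation formula, so the realized Spearman
correlation targets the requested `assoc`. Improvement percent is an affine
map of the latent (38 + 18·latent), clipped only at physiologic extremes
(−40%, +88%) because a tight clip would tie the best responders' ranks and
distort the association. Baseline totals are U(55, 95) — moderate-to-severe
impact — and subdomain scores split the total by the 4/4/3/3/4 item counts
with Dirichlet jitter.

What passing cohort tests show — and what they do not: the generator
reproduces the *rank structure* of a surgical cohort (patency gain
correlates with symptom change; volume and area do not), not the absolute
values of any real cohort. Real airways are non-tubular, branched, and
segmented from noisy CBCT; none of that is emulated, so phantom-validated
accuracy bounds do not transfer to patient data.

## Problem sizes and determinism

Default validation sizes: 128 circumferential segments for analytic-oracle
phantoms (mesh-vs-analytic errors ≲ 0.1–0.5%), 64 for pipeline-scale
phantoms, 48 with 2 mm axial steps for repeated cohort simulation; cohort
checks use 20 seeds at n = 100 (association recovery) and n = 12
(study-scale ranking, where sampling noise is intentionally visible — at
n = 12 a true ρ of 0.7 yields sample values roughly ±0.2, which is exactly
the uncertainty a pilot of that size carries). Every generator is
deterministic under its seed; the pipeline writes byte-identical outputs
for a fixed config + seed, and the config hash is recorded next to every
measure table.

## Known limitations

- Sweeps for MinXarea are straight-axis only; no centerline extraction or
  curved-planar reformatting.
- Cap fans require boundary loops star-shaped about their centroid.
- The wall-thickness definition is the normal-ray first hit, deliberately;
  medial-axis / maximal-inscribed-sphere thickness is out of scope.
- Registration operates on landmarks and surfaces, not image volumes.
- The ICP trims a fixed 90th percentile; pathological partial overlaps
  below 10% shared surface will mislead it (flagged by non-convergence).
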