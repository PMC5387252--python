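# airwaymorph

Surface-mesh morphometry of the upper airway for pre/post-surgical studies.

Pediatric sleep-disordered breathing is most often caused by anatomic
obstruction — adenoid and tonsillar hypertrophy narrowing the nasal and
pharyngeal airway — and is treated surgically. Imaging studies of surgical
outcome usually report *global* measures of the segmented airway lumen
(volume, surface area, a single minimum cross-sectional area), which blur
out exactly the local narrowing that matters clinically. `airwaymorph`
implements both the conventional measures and the *point-based* measures
that resolve local caliber everywhere on the airway wall, along with the
registration, partitioning, comparison, and cohort statistics needed to run
a full pre (T1) / post (T2) analysis — plus synthetic airway phantoms with
closed-form ground truth so every stage is testable without patient data.

## What it computes

For a watertight triangulated airway surface (STL, mm units):

- **Conventional measures** — volume (cm³, divergence theorem), wall
  surface area (cm², cut caps excluded or included), and minimum
  cross-sectional area MinXarea (mm², plane sweep with bisection
  refinement along a configured axis).
- **Wall-thickness (caliber) analysis** — for each triangle, a ray is cast
  from its centroid along the inward normal; the distance `d` to the first
  opposing-wall intersection measures the local lumen caliber. With
  operator thresholds (defaults 4 and 10 mm):
  - *constriction fraction* = % of triangles with `d < 4 mm` (potential
    collapse sites),
  - *patency fraction* = % of triangles with `d > 10 mm` (open lumen),
  plus min/max/mean/median/SD/IQR of all distances. Count- and
  area-weighted variants are available.
- **Part comparison (T2−T1)** — per-vertex unsigned distance from the T1
  surface to the registered T2 surface, classified green (< 4 mm),
  orange-yellow (4–10 mm), red (> 10 mm), exportable as a colored PLY.
- **Registration** — closed-form landmark (Kabsch/Procrustes) alignment
  with residuals, refined by trimmed point-to-surface ICP; T1 is always the
  fixed frame.
- **Partitioning** — three configured cutting planes split the whole
  airway into nasal cavity (NS), nasopharynx (NP) and oropharynx (OP),
  re-capped watertight with cap faces tagged.
- **Cohort statistics** — median (Q1–Q3) summaries (Tukey hinges or linear
  interpolation), exact Wilcoxon signed-rank tests (subset-sum enumeration,
  tie-aware), Spearman ρ with exact small-n permutation p-values, OSA-18
  severity banding (< 60 low, 60–80 moderate, > 80 severe), and
  correlations of each airway-change measure with OSA-18 change.
- **Synthetic data** — tubular airway phantoms with Gaussian obstruction
  bulges (adenoid, tonsillar), surgical T1/T2 pairs with a known removal
  field, and rank-coupled cohorts targeting a chosen Spearman association
  between patency gain and quality-of-life improvement. All ground truth is
  computed by quadrature/ray marching on the parametric surface,
  independent of meshing.

## Worked example

```python
from airwaymorph import PhantomSpec, generate_surgical_pair, wall_thickness, \
    cut_mesh, CuttingPlane, thickness_change
from airwaymorph.synthetic import obstruction_pair

spec = PhantomSpec(bulges=obstruction_pair(
    "adenoid", depth_per_wall=6.0, center_z=42.5, theta_deg=180.0,
    sigma_z=9.0, sigma_theta_deg=50.0))
t1, t2, truth = generate_surgical_pair(spec, {"adenoid_a": 5.0, "adenoid_b": 5.0})

def np_segment(m):
    m = cut_mesh(m, CuttingPlane([0, 0, 30], [0, 0, 1]), keep="positive")
    return cut_mesh(m, CuttingPlane([0, 0, 55], [0, 0, 1]), keep="negative")

r1 = wall_thickness.analyze(np_segment(t1))
r2 = wall_thickness.analyze(np_segment(t2))
print(r1.bands.constriction, r1.bands.patency)
print(r2.bands.constriction, r2.bands.patency)
```

prints (for this phantom)

```
5.3 19.5
0.0 99.5
```

meaning 5.3% of the obstructed nasopharyngeal wall faced a lumen narrower
than 4 mm before surgery and 19.5% faced more than 10 mm; after deflating
the adenoid pad by 5 mm per wall, no constricted wall remains and 99.5% of
the wall is patent. `thickness_change(r1, r2)` reports the change in both
published conventions (percentage points and relative percent).

The `examples/` directory holds one narrative script per capability
(conventional measures, wall thickness, registration + part comparison,
cohort statistics); each prints its numbers next to the generator truth.

A thin CLI covers the file-based pipeline:

```sh
airwaymorph simulate --out cohort/ --n 12 --seed 1
airwaymorph measure  --manifest cohort/manifest.csv --out measured/
airwaymorph report   --measures measured/measures.csv --osa18 cohort/osa18.csv --out report/
```

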