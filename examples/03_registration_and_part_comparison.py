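"""Two-stage registration and the T2-T1 color-map comparison.

A post-surgical (T2) model is displaced by a known rigid motion, brought
back with landmark alignment plus ICP refinement, and then compared
point-to-surface against T1.  Green < 4 mm, orange-yellow 4-10 mm,
red > 10 mm of local tissue change.
"""

import numpy as np

from airwaymorph import (
    PhantomSpec,
    band_summary,
    compare_meshes,
    generate_surgical_pair,
    registration as reg,
)
from airwaymorph.mesh_io import LandmarkSet
from airwaymorph.synthetic import DEFAULT_PROFILE, adenoid_bulge, phantom_landmarks

prof = tuple((z, r * 1.8) for z, r in DEFAULT_PROFILE)
spec = PhantomSpec(
    profile_knots=prof,
    bulges=(adenoid_bulge(12.0, sigma_z=8.0, sigma_theta_deg=70.0),),
    n_theta=96,
    axial_step=1.0,
)
t1_mesh, t2_mesh, truth = generate_surgical_pair(spec, {"adenoid": 12.0})

# displace T2 by a known rigid motion (scanner repositioning between visits)
angle = np.radians(4.0)
R = np.array([[np.cos(angle), -np.sin(angle), 0],
              [np.sin(angle), np.cos(angle), 0], [0, 0, 1]])
displacement = reg.RigidTransform(R, [3.0, -2.0, 1.5])
t2_moved = reg.apply_transform(t2_mesh, displacement)

lms = phantom_landmarks(spec, n=10)  # skeletal landmarks: identical at T1/T2
lms_moved = LandmarkSet(
    {k: displacement.apply(v) for k, v in lms.points.items()}
)
fit = reg.landmark_align(lms_moved, lms)
icp = reg.global_refine(t2_moved, t1_mesh, init=fit.transform)
t2_back = reg.apply_transform(t2_moved, icp.transform)

print(f"landmark fit RMS: {fit.rms:.2e} mm; ICP mean surface distance "
      f"{icp.mean_distance:.3f} mm after {icp.iterations} iterations")

cmap = compare_meshes(t1_mesh, t2_back)
bands = band_summary(cmap, weighting="area")
truth_bands = truth.displacement_band_fractions()
print("band fractions (% of T1 surface area):")
for k in ("green", "orange_yellow", "red"):
    print(f"  {k:<14} measured {bands[k]:6.2f}   truth {truth_bands[k]:6.2f}")
print()
print("The red band marks the adenoid bed where >10 mm of tissue was removed;")
print("its measured extent matches the generator's removal field.")
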