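"""Config-driven end-to-end pipeline: register -> partition -> measure ->
compare -> summarize, plus synthetic-cohort simulation.

The pipeline is deliberately manifest-based: a CSV lists, per subject, the
T1/T2 whole-airway STL paths and landmark files, and a YAML/JSON config
holds every tunable (cutting planes, thresholds, smoothing, weighting,
quartile rule, seed).  Per-subject failures are isolated and logged —
clinical cohorts routinely exclude subjects for positioning errors — and a
fixed config plus seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    mesh_io,
    morphometry,
    part_comparison,
    partition,
    registration,
    stats,
    synthetic,
    wall_thickness,
)

log = logging.getLogger("airwaymorph")


@dataclass
class PlaneConfig:
    name: str
    point: list[float] | None = None
    normal: list[float] | None = None
    landmarks: list[str] | None = None  # three landmark names instead

    def resolve(self, lms: mesh_io.LandmarkSet | None) -> partition.CuttingPlane:
        if self.landmarks is not None:
            if lms is None:
                raise ValueError(f"plane {self.name!r} needs landmarks")
            return partition.CuttingPlane.from_landmarks(
                lms, tuple(self.landmarks), self.name
            )
        return partition.CuttingPlane(self.point, self.normal, self.name)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, round-trippable through YAML/JSON."""

    planes: list[PlaneConfig] = field(default_factory=list)
    constriction_mm: float = 4.0
    patency_mm: float = 10.0
    smoothing_factor: float = 0.7
    smoothing_iterations: int = 10
    weighting: str = "count"
    quartile_rule: str = "tukey"
    max_ray_mm: float = 50.0
    minx_step_mm: float = 0.5
    sweep_axis: list[float] = field(default_factory=lambda: [0.0, 0.0, 1.0])
    surgical_segment: str = "NP"
    seed: int = 0
    output_dir: str = "airwaymorph_out"
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.constriction_mm < self.patency_mm:
            raise ValueError(
                "thresholds must satisfy 0 < constriction < patency, got "
                f"{self.constriction_mm} / {self.patency_mm}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        planes = [PlaneConfig(**p) for p in data.pop("planes", [])]
        return cls(planes=planes, **data)

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def default_phantom_planes() -> list[PlaneConfig]:
    """Planes matching the synthetic phantom's segment boundaries."""
    spec = synthetic.PhantomSpec()
    z_np = spec.segment_bounds("NS")[0]
    z_op = spec.segment_bounds("NP")[0]
    return [
        PlaneConfig("ns_np", point=[0, 0, z_np], normal=[0, 0, 1]),
        PlaneConfig("np_op", point=[0, 0, z_op], normal=[0, 0, 1]),
        PlaneConfig("inferior", point=[0, 0, 0.0], normal=[0, 0, 1]),
    ]


# ---------------------------------------------------------------------------
# Per-subject measurement
# ---------------------------------------------------------------------------

@dataclass
class SubjectPaths:
    subject: str
    t1_mesh: str
    t2_mesh: str
    t1_landmarks: str | None = None
    t2_landmarks: str | None = None


def read_manifest(path: str | Path) -> list[SubjectPaths]:
    df = pd.read_csv(path)
    required = {"subject", "t1_mesh", "t2_mesh"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SubjectPaths(
                str(row["subject"]), str(row["t1_mesh"]), str(row["t2_mesh"]),
                row.get("t1_landmarks") if isinstance(row.get("t1_landmarks"), str) else None,
                row.get("t2_landmarks") if isinstance(row.get("t2_landmarks"), str) else None,
            )
        )
    return out


def measure_mesh(
    mesh: mesh_io.AirwayMesh, config: PipelineConfig, minx: bool = True
) -> dict[str, float]:
    """All measures for one conditioned segment mesh."""
    wt = wall_thickness.analyze(
        mesh,
        constriction_mm=config.constriction_mm,
        patency_mm=config.patency_mm,
        max_ray=config.max_ray_mm,
        weighting=config.weighting,
    )
    row = {
        "volume_cm3": morphometry.mesh_volume(mesh),
        "surface_cm2_wall": morphometry.mesh_surface_area(mesh, include_caps=False),
        "surface_cm2_total": morphometry.mesh_surface_area(mesh, include_caps=True),
        "constriction_pct": wt.bands.constriction,
        "patency_pct": wt.bands.patency,
        "thickness_median_mm": wt.summary.median,
        "miss_pct": wt.miss_percent,
    }
    if minx:
        mx = morphometry.min_cross_section(
            mesh, np.asarray(config.sweep_axis), step=config.minx_step_mm
        )
        row["min_x_area_mm2"] = mx.area_mm2
        row["min_x_offset_mm"] = mx.offset_mm
    return row


def process_subject(
    paths: SubjectPaths, config: PipelineConfig
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Register T2 to T1, partition both, measure every segment at both
    timepoints, and part-compare the surgical segment.

    Returns (measure rows, comparison band fractions).
    """
    t1 = mesh_io.read_stl(paths.t1_mesh)
    t2 = mesh_io.read_stl(paths.t2_mesh)
    t1 = mesh_io.close_surface(t1)
    t2 = mesh_io.close_surface(t2)
    if config.smoothing_factor > 0:
        t1 = mesh_io.smooth_mesh(t1, config.smoothing_factor, config.smoothing_iterations)
        t2 = mesh_io.smooth_mesh(t2, config.smoothing_factor, config.smoothing_iterations)

    landmarks = None
    if paths.t1_landmarks and paths.t2_landmarks:
        lm1 = mesh_io.read_landmarks(paths.t1_landmarks)
        lm2 = mesh_io.read_landmarks(paths.t2_landmarks)
        fit = registration.landmark_align(lm2, lm1)  # T2 moves into T1 frame
        icp = registration.global_refine(t2, t1, fit.transform, seed=config.seed)
        t2 = registration.apply_transform(t2, icp.transform)
        landmarks = lm1
        log.info(
            "subject %s: landmark RMS %.3f mm, ICP mean distance %.3f mm",
            paths.subject, fit.rms, icp.mean_distance,
        )

    planes = {p.name: p.resolve(landmarks) for p in config.planes}
    rows = []
    compare: dict[str, float] = {}
    seg_meshes = {}
    for tp, mesh in (("T1", t1), ("T2", t2)):
        segs = partition.partition_airway(
            mesh, planes["ns_np"], planes["np_op"], planes["inferior"]
        )
        for label, seg in segs:
            # MinXarea for both pharyngeal segments (a subject's surgical
            # site may be NP or OP); the nasal sweep is skipped
            row = measure_mesh(seg, config, minx=(label in ("NP", "OP")))
            row.update(subject=paths.subject, timepoint=tp, segment=label)
            rows.append(row)
            seg_meshes[(tp, label)] = seg
    cmap = part_comparison.compare_meshes(
        seg_meshes[("T1", config.surgical_segment)],
        seg_meshes[("T2", config.surgical_segment)],
        low_mm=config.constriction_mm,
        high_mm=config.patency_mm,
    )
    compare = part_comparison.band_summary(cmap, weighting=config.weighting)
    return pd.DataFrame(rows), compare


def run_measure(
    config: PipelineConfig, manifest: list[SubjectPaths]
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Measure every subject in the manifest, isolating per-subject failures.

    Returns (measure table, part-comparison table, excluded subject ids).
    """
    all_rows = []
    cmp_rows = []
    excluded = []
    for paths in manifest:
        try:
            rows, compare = process_subject(paths, config)
            all_rows.append(rows)
            cmp_rows.append({"subject": paths.subject, **compare})
        except Exception as exc:  # noqa: BLE001 - deliberate isolation
            excluded.append(paths.subject)
            log.error("subject %s excluded: %s", paths.subject, exc)
            log.debug("%s", traceback.format_exc())
    measures = (
        pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
    )
    comparisons = pd.DataFrame(cmp_rows)
    if len(measures):
        measures = measures.sort_values(
            ["subject", "timepoint", "segment"]
        ).reset_index(drop=True)
    return measures, comparisons, excluded


def measure_cohort(
    cohort: synthetic.SyntheticCohort,
    config: PipelineConfig | None = None,
    minx: bool = False,
) -> pd.DataFrame:
    """Partition and measure every subject of an in-memory synthetic cohort.

    Measures the surgical segment of each subject's T1/T2 mesh pair through
    the same partition + measurement path the file pipeline uses (meshes are
    generated in a common frame, so no registration step is needed).
    Returns one tidy row per subject x timepoint.
    """
    config = config or PipelineConfig(planes=default_phantom_planes())
    planes = {p.name: p.resolve(None) for p in config.planes}
    rows = []
    for subj in cohort.subjects:
        seg_label = "OP" if subj.record.surgery == "tonsillectomy" else "NP"
        for tp, mesh in zip(("T1", "T2"), subj.meshes()):
            segs = partition.partition_airway(
                mesh, planes["ns_np"], planes["np_op"], planes["inferior"]
            )
            seg = dict(iter(segs))[seg_label]
            row = measure_mesh(seg, config, minx=minx)
            row.update(
                subject=subj.record.subject_id, timepoint=tp, segment=seg_label
            )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------

MEASURE_COLUMNS = (
    "volume_cm3", "surface_cm2_wall", "min_x_area_mm2",
    "constriction_pct", "patency_pct",
)


def run_cohort_report(
    config: PipelineConfig,
    measures: pd.DataFrame,
    osa18: pd.DataFrame,
    segment: str | None = None,
) -> stats.CohortSummary:
    """Cohort summary tables from per-subject measures and OSA-18 scores.

    ``osa18`` needs columns subject, osa18_t1, osa18_t2 (optionally
    ``surgery``, in which case each subject contributes the segment specific
    to their surgery: OP for tonsillectomy, NP otherwise).  Unpaired
    subjects are excluded with a warning.  Constriction improvement is a
    decrease; every other measure improves by increasing.
    """
    records = []
    for _, row in osa18.iterrows():
        sid = str(row["subject"])
        if segment is not None:
            subj_segment = segment
        elif "surgery" in osa18.columns:
            subj_segment = "OP" if str(row["surgery"]) == "tonsillectomy" else "NP"
        else:
            subj_segment = config.surgical_segment
        seg = measures[measures["segment"] == subj_segment]
        m1 = seg[(seg["subject"] == sid) & (seg["timepoint"] == "T1")]
        m2 = seg[(seg["subject"] == sid) & (seg["timepoint"] == "T2")]
        if len(m1) != 1 or len(m2) != 1:
            log.warning("subject %s unpaired in measures; excluded", sid)
            continue
        mdict = {}
        for col in MEASURE_COLUMNS:
            if col in m1.columns and np.isfinite(m1.iloc[0].get(col, np.nan)):
                mdict[col] = (float(m1.iloc[0][col]), float(m2.iloc[0][col]))
        records.append(
            stats.SubjectRecord(
                subject_id=sid,
                osa18_t1=float(row["osa18_t1"]),
                osa18_t2=float(row["osa18_t2"]),
                measures=mdict,
            )
        )
    return stats.correlate_airway_with_osa18(
        records, improvement_direction={"constriction_pct": "decrease"}
    )


def write_report(summary: stats.CohortSummary, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary.descriptives.to_csv(outdir / "descriptives.csv", index=False)
    summary.correlations.to_csv(outdir / "correlations.csv", index=False)
    summary.severity_transitions.to_csv(
        outdir / "severity_transitions.csv", index=False
    )
    lines = ["Cohort summary", "=" * 60, ""]
    for _, r in summary.descriptives.iterrows():
        lines.append(
            f"{r['variable']:<22} T1 {r['t1_median']:8.2f} "
            f"({r['t1_q1']:.2f}-{r['t1_q3']:.2f})  T2 {r['t2_median']:8.2f} "
            f"({r['t2_q1']:.2f}-{r['t2_q3']:.2f})  p={r['p_value']:.4g}"
        )
    lines += ["", "Spearman correlation with OSA-18 improvement:"]
    for _, r in summary.correlations.iterrows():
        lines.append(
            f"  {r['measure']:<20} rho={r['rho']:+.3f}  p={r['p_value']:.4g}  n={r['n']}"
        )
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Simulation entry (cohort -> files)
# ---------------------------------------------------------------------------

def simulate_cohort_files(
    outdir: str | Path,
    n: int = 12,
    assoc: float = 0.7,
    seed: int = 0,
    write_meshes: bool = True,
    n_theta: int = 64,
    axial_step: float = 1.5,
) -> tuple[Path, Path]:
    """Generate a synthetic cohort on disk: STLs, manifest CSV, OSA-18 CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = synthetic.generate_cohort(
        n=n, assoc=assoc, seed=seed, n_theta=n_theta, axial_step=axial_step
    )
    manifest_rows = []
    osa_rows = []
    for subj in cohort.subjects:
        rec = subj.record
        row = {"subject": rec.subject_id}
        if write_meshes:
            m1, m2 = subj.meshes()
            p1 = outdir / f"{rec.subject_id}_T1.stl"
            p2 = outdir / f"{rec.subject_id}_T2.stl"
            mesh_io.write_stl(m1, p1, dialect="binary")
            mesh_io.write_stl(m2, p2, dialect="binary")
            lmpath = outdir / f"{rec.subject_id}_landmarks.csv"
            mesh_io.write_landmarks(
                synthetic.phantom_landmarks(subj.spec_t1), lmpath
            )
            row.update(
                t1_mesh=str(p1), t2_mesh=str(p2),
                t1_landmarks=str(lmpath), t2_landmarks=str(lmpath),
            )
        manifest_rows.append(row)
        osa_rows.append(
            {
                "subject": rec.subject_id,
                "osa18_t1": rec.osa18_t1,
                "osa18_t2": rec.osa18_t2,
                "surgery": rec.surgery,
                "recall_months": rec.recall_months,
            }
        )
    manifest_path = outdir / "manifest.csv"
    osa_path = outdir / "osa18.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    pd.DataFrame(osa_rows).to_csv(osa_path, index=False)
    return manifest_path, osa_path
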