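"""End-to-end orchestration: volume -> mask -> mesh -> crop -> fill -> report.

A run is configured by a single :class:`RunConfig` document (YAML or JSON on
disk).  All stage parameters — the 140 HU bone cut-off, the display-window
presets, patch degrees and grids — are configuration defaults, never
hard-coded inside the stages, and the resolved configuration is logged so a
run can be reproduced exactly.  Identical configuration and inputs give
byte-identical outputs (no timestamps inside result files).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import trimesh
import yaml

from . import __version__
from .cleft_fill import (
    BoundaryLoop,
    RegionOfInterest,
    crop_mesh,
    detect_defect_boundary,
    fill_defect,
    mesh_boundary_loops,
    oral_surface_sheet,
)
from .ct_volume import read_volume
from .errors import FormatError, PalatometryError
from .morphometry import (
    CleftMeasurement,
    build_report,
    cleft_percentage,
    measure_cleft_extent,
    mesh_surface_area,
    total_palate_area,
    write_measurement_json,
)
from .segmentation import extract_bone_surface, write_stl

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run (versioned schema)."""

    input_path: str = ""
    output_dir: str = "palatometry_out"
    animal_id: str = "specimen"
    breed: str = ""
    diagnostic_code: str = ""
    threshold_hu: float = 140.0
    smooth_sigma_vox: float = 1.0
    connectivity: int = 26
    roi_box: tuple | None = None  # ((x0,y0,z0),(x1,y1,z1)) mm; None = whole mesh
    min_gap_mm: float = 1.5
    long_axis: tuple = (0.0, 1.0, 0.0)
    dorsal_axis: tuple = (0.0, 0.0, 1.0)
    support_band_mm: float = 3.0
    patch_degree: int = 3
    control_grid: tuple = (8, 8)
    rms_tol_mm: float = 0.2
    max_iter: int = 50
    tessellation_samples: int = 64
    seed: int = 0
    log_level: str = "INFO"
    schema_version: int = 1
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            doc = yaml.safe_load(path.read_text())
        except Exception as exc:
            raise FormatError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(doc, dict):
            raise FormatError(f"config {path} is not a mapping")
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in doc.items() if k in known}
        extra = {k: v for k, v in doc.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra = extra
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("roi_box", "long_axis", "dorsal_axis", "control_grid"):
            if d[key] is not None:
                d[key] = json.loads(json.dumps(d[key], default=list))
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Human-readable findings; an empty list means the config looks sane."""
    findings: list[str] = []
    if config.input_path and not Path(config.input_path).exists():
        findings.append(f"input_path does not exist: {config.input_path}")
    if not -1000.0 <= config.threshold_hu <= 3000.0:
        findings.append(
            f"threshold_hu {config.threshold_hu} outside plausible CT range [-1000, 3000]"
        )
    if config.min_gap_mm <= 0:
        findings.append("min_gap_mm must be > 0")
    elif config.min_gap_mm > 20:
        findings.append(
            f"min_gap_mm {config.min_gap_mm} mm is implausibly wide for a neonatal palate"
        )
    if config.smooth_sigma_vox < 0:
        findings.append("smooth_sigma_vox must be >= 0")
    if config.connectivity not in (6, 26):
        findings.append(f"connectivity must be 6 or 26, got {config.connectivity}")
    if config.rms_tol_mm <= 0:
        findings.append("rms_tol_mm must be > 0")
    if config.max_iter < 1:
        findings.append("max_iter must be >= 1")
    if config.tessellation_samples < 2:
        findings.append("tessellation_samples must be >= 2")
    nu, nv = config.control_grid
    if nu <= config.patch_degree or nv <= config.patch_degree:
        findings.append("control_grid must exceed patch_degree in both directions")
    if np.linalg.norm(config.long_axis) == 0 or np.linalg.norm(config.dorsal_axis) == 0:
        findings.append("long_axis and dorsal_axis must be non-zero")
    if config.roi_box is not None:
        lo, hi = np.asarray(config.roi_box[0], float), np.asarray(config.roi_box[1], float)
        if np.any(hi <= lo):
            findings.append("roi_box must have positive extent in all axes")
    return findings


def _match_hole_loop(
    defect: BoundaryLoop, hole_loops: list[BoundaryLoop]
) -> BoundaryLoop | None:
    """Residual-sheet hole belonging to a defect outline (nearest centroid)."""
    if not hole_loops:
        return None
    c = defect.points.mean(axis=0)[:2]
    dists = [np.linalg.norm(lp.points.mean(axis=0)[:2] - c) for lp in hole_loops]
    best = int(np.argmin(dists))
    if dists[best] > 10.0:
        return None
    return hole_loops[best]


def run_pipeline(config: RunConfig, volume=None) -> CleftMeasurement:
    """Execute all stages and persist artifacts under ``config.output_dir``.

    ``volume`` may be passed directly (a :class:`~palatometry.ct_volume.CTVolume`)
    to skip reading ``input_path``.  Writes bone/palate/fill STLs, a JSON
    measurement record, a one-row CSV report, and a structured log of every
    resolved parameter.  Raises the failing stage's error; a palate without
    defects is a valid outcome (cleft area 0), not an error.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = {"palatometry_version": __version__, "config": config.to_dict()}
    log.info("run configuration: %s", json.dumps(resolved, sort_keys=True))
    (out / "run_config.json").write_text(json.dumps(resolved, indent=2, sort_keys=True) + "\n")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PalatometryError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    if volume is None:
        volume = stage("read_volume", read_volume, config.input_path)
    fingerprint = f"shape={volume.shape} spacing={volume.spacing}"
    log.info("input volume: %s", fingerprint)

    bone = stage(
        "extract_bone_surface",
        extract_bone_surface,
        volume,
        threshold=config.threshold_hu,
        connectivity=config.connectivity,
        smooth_sigma_vox=config.smooth_sigma_vox,
    )
    write_stl(bone, out / "bone.stl")

    if config.roi_box is not None:
        roi = RegionOfInterest(box=tuple(config.roi_box))
        palate = stage("crop_mesh", crop_mesh, bone, roi)
    else:
        palate = bone
    write_stl(palate, out / "palate_cropped.stl")

    dorsal = np.asarray(config.dorsal_axis, float)
    sheet = stage("oral_surface_sheet", oral_surface_sheet, palate, dorsal)
    write_stl(sheet, out / "oral_sheet.stl")
    defects = stage(
        "detect_defect_boundary", detect_defect_boundary, palate, config.min_gap_mm, dorsal
    )
    log.info("detected %d defect outline(s)", len(defects))

    hole_loops = mesh_boundary_loops(sheet)
    if hole_loops:
        areas = [lp.projected_area for lp in hole_loops]
        hole_loops = [lp for i, lp in enumerate(hole_loops) if i != int(np.argmax(areas))]

    fills = []
    for i, defect in enumerate(defects):
        hole = _match_hole_loop(defect, hole_loops)
        result = stage(
            f"fill_defect[{i}]",
            fill_defect,
            sheet,
            defect,
            hole_loop=hole,
            support_band_mm=config.support_band_mm,
            degree=config.patch_degree,
            control_grid=tuple(config.control_grid),
            rms_tol=config.rms_tol_mm,
            max_iter=config.max_iter,
            samples_per_direction=config.tessellation_samples,
        )
        fills.append(result)
        write_stl(result.fill_mesh, out / f"fill_{i}.stl")
        (out / f"patch_{i}.json").write_text(
            json.dumps(result.patch.to_dict(), sort_keys=True) + "\n"
        )
        log.info(
            "defect %d: rms_fit=%.4f mm, iterations=%d, area=%.3f mm^2",
            i, result.rms_fit, result.iterations, mesh_surface_area(result.fill_mesh),
        )

    per_loop = [mesh_surface_area(r.fill_mesh) for r in fills]
    cleft_area = float(sum(per_loop))
    repair_meshes = [r.repair_mesh if r.repair_mesh is not None else r.fill_mesh for r in fills]
    total = stage("total_palate_area", total_palate_area, sheet, repair_meshes)
    if fills:
        length, wmin, wmax = stage(
            "measure_cleft_extent",
            measure_cleft_extent,
            fills[0].fill_mesh,
            np.asarray(config.long_axis, float),
        )
        pct = cleft_percentage(min(cleft_area, total), total)
    else:
        length = wmin = wmax = 0.0
        pct = 0

    measurement = CleftMeasurement(
        animal_id=config.animal_id,
        breed=config.breed,
        cleft_area=cleft_area,
        total_palate_area=total,
        percentage=pct,
        length=length,
        width_min=wmin,
        width_max=wmax,
        n_loops=len(fills),
        diagnostic_code=config.diagnostic_code if fills else "",
        per_loop_areas=per_loop,
    )
    write_measurement_json(measurement, out / "measurement.json")
    build_report([measurement], out / "report.csv")
    log.info(
        "result: cleft %.2f mm^2 of %.2f mm^2 total (%d%%), %d loop(s)",
        cleft_area, total, pct, len(fills),
    )
    return measurement
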