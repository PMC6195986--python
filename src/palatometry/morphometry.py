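"""Curved-surface morphometry of the hard palate and its defects.

Areas are true (curved) surface areas in mm^2, computed on triangle meshes;
the cleft percentage is reported as an integer, matching how such results
are tabulated clinically.  "Total palate area" is defined on the virtually
repaired palate: the residual oral-surface sheet plus the trimmed fill
patches, which keeps the percentage well defined even for wide clefts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import trimesh

from .errors import ConsistencyError, GeometryError, ParameterError


@dataclass
class CleftMeasurement:
    """Per-animal morphometry record (Table-style row)."""

    animal_id: str
    breed: str = ""
    cleft_area: float = 0.0  # mm^2
    total_palate_area: float = 0.0  # mm^2
    percentage: int = 0  # integer %
    length: float = 0.0  # mm
    width_min: float = 0.0  # mm
    width_max: float = 0.0  # mm
    n_loops: int = 0
    diagnostic_code: str = ""
    per_loop_areas: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cleft_area < 0 or self.total_palate_area < 0:
            raise ConsistencyError("areas must be non-negative")
        if self.total_palate_area and self.cleft_area > self.total_palate_area * (1 + 1e-9):
            raise ConsistencyError("cleft area exceeds total palate area")
        if self.width_min > self.width_max:
            raise ConsistencyError("width_min must be <= width_max")

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "breed": self.breed,
            "cleft_area_mm2": self.cleft_area,
            "total_area_mm2": self.total_palate_area,
            "percentage": self.percentage,
            "length_mm": self.length,
            "width_min_mm": self.width_min,
            "width_max_mm": self.width_max,
            "n_loops": self.n_loops,
            "diagnostic_code": self.diagnostic_code,
            "per_loop_areas_mm2": list(self.per_loop_areas),
        }


def mesh_surface_area(mesh: trimesh.Trimesh | None) -> float:
    """Total triangle area in mm^2: sum of 0.5 * |(v1-v0) x (v2-v0)|.

    Degenerate (collinear) faces contribute zero; an empty mesh has area 0.
    """
    if mesh is None or len(mesh.faces) == 0:
        return 0.0
    tri = mesh.triangles
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def cleft_percentage(cleft_area: float, total_area: float) -> int:
    """Integer percentage of the cleft, rounded half away from zero.

    Raises
    ------
    ParameterError
        If ``total_area <= 0``.
    ConsistencyError
        If ``cleft_area`` is negative or exceeds ``total_area``.
    """
    if total_area <= 0:
        raise ParameterError(f"total area must be > 0, got {total_area}")
    if cleft_area < 0 or cleft_area > total_area:
        raise ConsistencyError(
            f"cleft area {cleft_area} outside [0, total={total_area}]"
        )
    ratio = 100.0 * cleft_area / total_area
    return int(math.floor(ratio + 0.5))  # half away from zero (ratio >= 0)


def total_palate_area(
    residual_palate_mesh: trimesh.Trimesh,
    fill_meshes: Iterable[trimesh.Trimesh] = (),
) -> float:
    """Area of the virtually repaired palate: residual oral sheet + fills."""
    return mesh_surface_area(residual_palate_mesh) + sum(
        mesh_surface_area(m) for m in fill_meshes
    )


def measure_cleft_extent(
    fill_mesh: trimesh.Trimesh,
    long_axis: Sequence[float] = (0.0, 1.0, 0.0),
    n_stations: int = 64,
    end_margin_frac: float = 0.05,
) -> tuple[float, float, float]:
    """Length and min/max transverse width of a defect (fill) surface.

    Length is the extent of the mesh along ``long_axis`` (the rostro-caudal
    direction); widths are the diameters of cross-sections in transverse
    planes sampled along that axis.  Stations within ``end_margin_frac`` of
    the length from either extreme are excluded from the width statistics:
    a closed defect outline necessarily tapers to zero width at its
    rostro-caudal extremes, so widths there reflect the corner geometry,
    not the fissure.

    Raises
    ------
    GeometryError
        If the mesh is empty or has zero extent along the axis.
    """
    if fill_mesh is None or len(fill_mesh.faces) == 0:
        raise GeometryError("cannot measure an empty fill mesh")
    axis = np.asarray(long_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ParameterError("long_axis must be non-zero")
    axis = axis / norm
    t = fill_mesh.vertices @ axis
    t0, t1 = float(t.min()), float(t.max())
    length = t1 - t0
    if length <= 0:
        raise GeometryError("fill mesh has zero extent along the long axis")
    margin = end_margin_frac * length
    step = (length - 2 * margin) / n_stations
    widths = []
    for k in range(n_stations):
        station = t0 + margin + (k + 0.5) * step
        section = fill_mesh.section(plane_origin=axis * station, plane_normal=axis)
        if section is None or len(section.vertices) < 2:
            continue
        pts = np.asarray(section.vertices)
        perp = pts - np.outer(pts @ axis, axis)
        # diameter of the cross-section point set
        d = 0.0
        for p in perp:
            d = max(d, float(np.linalg.norm(perp - p, axis=1).max()))
        widths.append(d)
    if not widths:
        raise GeometryError("no usable cross-sections along the long axis")
    return length, float(min(widths)), float(max(widths))


REPORT_COLUMNS = [
    "dog_no",
    "breed",
    "total_area_mm2",
    "cleft_area_mm2",
    "percentage",
    "length_mm",
    "width_min_mm",
    "width_max_mm",
    "n_loops",
    "diagnostic_code",
]


def build_report(measurements: Sequence[CleftMeasurement], path: str | Path) -> None:
    """Write a CSV report (one row per animal, ordered by animal id)."""
    import pandas as pd

    rows = []
    for m in sorted(measurements, key=lambda m: str(m.animal_id)):
        rows.append(
            {
                "dog_no": m.animal_id,
                "breed": m.breed,
                "total_area_mm2": m.total_palate_area,
                "cleft_area_mm2": m.cleft_area,
                "percentage": m.percentage,
                "length_mm": m.length,
                "width_min_mm": m.width_min,
                "width_max_mm": m.width_max,
                "n_loops": m.n_loops,
                "diagnostic_code": m.diagnostic_code,
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, index=False)


def write_measurement_json(measurement: CleftMeasurement, path: str | Path) -> None:
    """Persist one measurement record as deterministic JSON."""
    Path(path).write_text(
        json.dumps(measurement.to_dict(), indent=2, sort_keys=True) + "\n"
    )
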