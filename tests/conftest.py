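"""Shared fixtures: analytic sheets, suite phantoms, cached pipeline runs."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
import trimesh

import palatometry as pm
from palatometry.cleft_fill import BoundaryLoop


def gridded_sheet(fz, hole_radius: float = 4.0, extent: float = 10.0, n: int = 81):
    """Triangulated graph surface z = fz(x, y) with a circular hole.

    Returns (sheet mesh, dense boundary loop on the exact surface).
    """
    xs = np.linspace(-extent, extent, n)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), fz(xx, yy).ravel()])
    idx = np.arange(n * n).reshape(n, n)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
    mesh = trimesh.Trimesh(verts, faces, process=False)
    r = np.hypot(verts[:, 0], verts[:, 1])
    keep = (r[faces] > hole_radius).all(axis=1)
    sheet = mesh.submesh([np.flatnonzero(keep)], append=True)
    theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    bx, by = hole_radius * np.cos(theta), hole_radius * np.sin(theta)
    loop = BoundaryLoop(points=np.column_stack([bx, by, fz(bx, by)]))
    return sheet, loop


def suite_by_name():
    return {spec.name: spec for spec in pm.standard_suite()}


@pytest.fixture(scope="session")
def suite_specs():
    return suite_by_name()


@pytest.fixture(scope="session")
def suite_results(tmp_path_factory):
    """Full pipeline measurements + ground truths for every suite phantom."""
    base = tmp_path_factory.mktemp("suite_runs")
    out = {}
    for spec in pm.standard_suite():
        volume, truth = pm.generate_phantom(spec)
        cfg = pm.RunConfig(
            output_dir=str(base / spec.name),
            animal_id=spec.name,
            roi_box=truth.roi_box,
            log_level="ERROR",
        )
        out[spec.name] = (spec, truth, pm.run_pipeline(cfg, volume=volume))
    return out


@pytest.fixture(scope="session")
def intact_twin_totals(tmp_path_factory):
    """Pipeline-measured total palate area for the intact twin of each
    cleft-bearing suite phantom (same shell, clefts removed)."""
    base = tmp_path_factory.mktemp("twin_runs")
    out = {}
    for spec in pm.standard_suite():
        if not spec.cleft_outlines:
            continue
        twin = replace(spec, name=spec.name + "-intact", cleft_outlines=[])
        volume, truth = pm.generate_phantom(twin)
        cfg = pm.RunConfig(
            output_dir=str(base / twin.name),
            animal_id=twin.name,
            roi_box=truth.roi_box,
            log_level="ERROR",
        )
        out[spec.name] = pm.run_pipeline(cfg, volume=volume).total_palate_area
    return out
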