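"""Cropping, defect detection, spline patch fitting, tessellation, trimming."""

import numpy as np
import pytest
import trimesh
from scipy import integrate

import palatometry as pm
from palatometry.cleft_fill import (
    BoundaryLoop,
    _clamped_knots,
    _greville,
    fit_fill_patch,
    mesh_boundary_loops,
    tessellate_patch,
    trim_to_outline,
)
from palatometry.errors import (
    EmptyResultError,
    GeometryError,
    InsufficientSupportError,
    ParameterError,
)

from conftest import gridded_sheet


def unit_square_mesh():
    return trimesh.Trimesh(
        vertices=[[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
        faces=[[0, 1, 2], [0, 2, 3]],
        process=False,
    )


def planar_patch(extent=10.0, n_ctrl=8):
    """An exactly planar spline patch over [-extent, extent]^2 at z = 0."""
    knots = _clamped_knots(n_ctrl, 3)
    g = _greville(knots, 3) * 2 * extent - extent
    control = np.zeros((n_ctrl, n_ctrl, 3))
    control[..., 0] = g[:, None]
    control[..., 1] = g[None, :]
    return pm.SurfacePatch(
        degree_u=3, degree_v=3, knots_u=knots, knots_v=knots, control=control
    )


class TestCrop:
    def test_identity_box(self):
        mesh = unit_square_mesh()
        roi = pm.RegionOfInterest(box=((-1, -1, -1), (2, 2, 1)))
        out = pm.crop_mesh(mesh, roi)
        assert abs(out.area - mesh.area) < 1e-9

    def test_midplane_split_halves(self):
        mesh = unit_square_mesh()
        left = pm.crop_mesh(
            mesh, pm.RegionOfInterest(planes=[((0.5, 0, 0), (-1, 0, 0))])
        )
        right = pm.crop_mesh(
            mesh, pm.RegionOfInterest(planes=[((0.5, 0, 0), (1, 0, 0))])
        )
        assert abs(left.area - 0.5) < 1e-6
        assert abs(right.area - 0.5) < 1e-6

    def test_empty_crop_raises(self):
        with pytest.raises(EmptyResultError):
            pm.crop_mesh(
                unit_square_mesh(), pm.RegionOfInterest(box=((5, 5, 5), (6, 6, 6)))
            )

    def test_phantom_palate_area_matches_quadrature(self, suite_specs):
        """Cropping the intact control to its ROI recovers the quadrature
        oracle area of the oral sheet within 3%."""
        spec = suite_specs["intact-sutures"]
        spec = type(spec)(**{**spec.__dict__, "suture_slits": [], "name": "plain"})
        volume, truth = pm.generate_phantom(spec)
        bone = pm.extract_bone_surface(volume)
        palate = pm.crop_mesh(bone, pm.RegionOfInterest(box=truth.roi_box))
        sheet = pm.oral_surface_sheet(palate)
        assert abs(sheet.area - truth.palate_area_true) / truth.palate_area_true < 0.03

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"box": ((0, 0, 0), (0, 1, 1))},  # zero extent
            {"planes": [((0, 0, 0), (0, 0, 0))]},  # zero normal
            {},  # nothing given
        ],
    )
    def test_roi_validation(self, kwargs):
        with pytest.raises(ParameterError):
            pm.RegionOfInterest(**kwargs)


class TestBoundaryLoop:
    def test_requires_three_distinct_points(self):
        with pytest.raises(GeometryError):
            BoundaryLoop(points=np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0]]))

    def test_drops_duplicates_and_closure(self):
        loop = BoundaryLoop(
            points=np.array(
                [[0, 0, 0], [1, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0]]
            )
        )
        assert len(loop.points) == 4
        assert loop.projected_area == pytest.approx(1.0)

    def test_mesh_boundary_loops_of_square(self):
        loops = mesh_boundary_loops(unit_square_mesh())
        assert len(loops) == 1
        assert loops[0].projected_area == pytest.approx(1.0)


class TestDetect:
    def test_intact_control_has_no_defects(self, suite_results):
        _, _, m = suite_results["intact-sutures"]
        assert m.n_loops == 0 and m.cleft_area == 0.0

    def test_single_cleft_with_sutures_gives_one_loop(self, suite_specs):
        """A real cleft is detected while sub-millimetre suture slits are
        bridged or filtered out."""
        base = suite_specs["cleft-5mm-midline"]
        spec = type(base)(
            **{
                **base.__dict__,
                "name": "cleft+sutures",
                "suture_slits": [((-9.0, 6.0), (-3.0, 6.0), 0.5)],
            }
        )
        volume, truth = pm.generate_phantom(spec)
        bone = pm.extract_bone_surface(volume)
        palate = pm.crop_mesh(bone, pm.RegionOfInterest(box=truth.roi_box))
        loops = pm.detect_defect_boundary(palate)
        assert len(loops) == 1

    def test_bilateral_gives_two_loops_largest_first(self, suite_specs):
        spec = suite_specs["bilateral-4mm-3mm"]
        volume, truth = pm.generate_phantom(spec)
        bone = pm.extract_bone_surface(volume)
        palate = pm.crop_mesh(bone, pm.RegionOfInterest(box=truth.roi_box))
        loops = pm.detect_defect_boundary(palate)
        assert len(loops) == 2
        areas = [lp.projected_area for lp in loops]
        assert areas[0] > areas[1]
        # the wider (4 mm) cleft lies at negative x
        assert loops[0].points[:, 0].mean() < 0 < loops[1].points[:, 0].mean()

    def test_min_gap_parameter_validated(self):
        with pytest.raises(ParameterError):
            pm.detect_defect_boundary(unit_square_mesh(), min_gap_mm=0.0)


class TestPatchFit:
    def test_plane_reproduced_exactly(self):
        sheet, loop = gridded_sheet(lambda x, y: 0.3 * x + 0.1 * y + 2.0)
        patch = fit_fill_patch(sheet, loop)
        v = tessellate_patch(patch, 64).vertices
        err = np.abs(v[:, 2] - (0.3 * v[:, 0] + 0.1 * v[:, 1] + 2.0))
        assert err.max() < 1e-6

    def test_quadratic_sheet_reproduced(self):
        """Quadratics lie in the cubic spline space and survive the
        smoothness penalty unchanged."""
        sheet, loop = gridded_sheet(lambda x, y: 0.05 * x**2)
        patch = fit_fill_patch(sheet, loop)
        v = tessellate_patch(patch, 64).vertices
        err = np.abs(v[:, 2] - 0.05 * v[:, 0] ** 2)
        assert err.max() < 1e-6

    def test_insufficient_support_raises(self):
        sheet, loop = gridded_sheet(lambda x, y: 0.0 * x)
        with pytest.raises(InsufficientSupportError):
            fit_fill_patch(sheet, loop, support_band_mm=1e-6, control_grid=(24, 24))

    def test_deterministic(self):
        sheet, loop = gridded_sheet(lambda x, y: 0.05 * x**2)
        p1 = fit_fill_patch(sheet, loop)
        p2 = fit_fill_patch(sheet, loop)
        assert np.array_equal(p1.control, p2.control)
        assert np.array_equal(p1.knots_u, p2.knots_u)

    def test_patch_json_round_trip(self):
        sheet, loop = gridded_sheet(lambda x, y: 0.05 * x**2)
        patch = fit_fill_patch(sheet, loop)
        back = pm.SurfacePatch.from_dict(patch.to_dict())
        u = np.linspace(0, 1, 7)
        assert np.allclose(back.evaluate(u, u), patch.evaluate(u, u), atol=1e-12)

    def test_invalid_patch_rejected(self):
        knots = _clamped_knots(8, 3)
        with pytest.raises(ParameterError):
            pm.SurfacePatch(
                degree_u=3,
                degree_v=3,
                knots_u=knots,
                knots_v=knots,
                control=np.zeros((8, 8, 3)),
                weights=np.zeros((8, 8)),  # weights must be positive
            )


class TestTessellate:
    def test_planar_unit_area(self):
        patch = planar_patch(extent=0.5)  # [-0.5, 0.5]^2 -> area 1
        mesh = tessellate_patch(patch, 64)
        assert abs(pm.mesh_surface_area(mesh) - 1.0) < 1e-9

    def test_quadratic_area_matches_quadrature(self):
        """Area of z = x^2 over [0,1]^2 equals the first-fundamental-form
        integral computed independently by scipy quadrature."""
        from palatometry.cleft_fill import _basis_matrix

        n_ctrl = 8
        knots = _clamped_knots(n_ctrl, 3)
        g = _greville(knots, 3)
        # exact control net for z = u^2 (quadratics lie in the cubic space)
        s = np.linspace(0, 1, 60)
        B = _basis_matrix(s, knots, 3)
        z_coef, *_ = np.linalg.lstsq(B, s**2, rcond=None)
        control = np.zeros((n_ctrl, n_ctrl, 3))
        control[..., 0] = g[:, None]
        control[..., 1] = g[None, :]
        control[..., 2] = z_coef[:, None]
        patch = pm.SurfacePatch(
            degree_u=3, degree_v=3, knots_u=knots, knots_v=knots, control=control
        )
        area = pm.mesh_surface_area(tessellate_patch(patch, 128))
        truth, _ = integrate.dblquad(lambda y, x: np.sqrt(1 + 4 * x * x), 0, 1, 0, 1)
        assert abs(area - truth) / truth < 0.005

    def test_tessellation_convergence(self):
        sheet, loop = gridded_sheet(lambda x, y: 0.05 * x**2)
        patch = fit_fill_patch(sheet, loop)
        a64 = pm.mesh_surface_area(tessellate_patch(patch, 64))
        a128 = pm.mesh_surface_area(tessellate_patch(patch, 128))
        assert abs(a64 - a128) / a128 < 0.005

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            tessellate_patch(planar_patch(), 1)


class TestTrim:
    def test_full_domain_outline_is_identity(self):
        patch = planar_patch(extent=10.0)
        mesh = tessellate_patch(patch, 64)
        e = 10.0 * (1 - 1e-9)
        outline = BoundaryLoop(
            points=np.array(
                [[-e, -e, 0], [e, -e, 0], [e, e, 0], [-e, e, 0]], dtype=float
            )
        )
        out = trim_to_outline(mesh, outline)
        assert abs(pm.mesh_surface_area(out) - mesh.area) / mesh.area < 1e-6

    def test_centred_square_area(self):
        patch = planar_patch(extent=10.0)
        mesh = tessellate_patch(patch, 64)
        outline = BoundaryLoop(
            points=np.array(
                [[-2.5, -2.5, 0], [2.5, -2.5, 0], [2.5, 2.5, 0], [-2.5, 2.5, 0]]
            )
        )
        out = trim_to_outline(mesh, outline)
        assert abs(pm.mesh_surface_area(out) - 25.0) / 25.0 < 0.01

    def test_trimming_never_adds_area(self):
        sheet, loop = gridded_sheet(lambda x, y: 0.05 * x**2)
        patch = fit_fill_patch(sheet, loop)
        tess = tessellate_patch(patch, 64)
        trimmed = trim_to_outline(tess, loop)
        assert pm.mesh_surface_area(trimmed) <= pm.mesh_surface_area(tess) + 1e-9

    def test_fill_at_least_planar_minimum(self):
        """A curved fill spanning a loop cannot have less area than the
        loop's projection onto its best-fit plane."""
        sheet, loop = gridded_sheet(lambda x, y: 0.05 * x**2)
        patch = fit_fill_patch(sheet, loop)
        trimmed = trim_to_outline(tessellate_patch(patch, 64), loop)
        pts = loop.points - loop.points.mean(axis=0)
        _, _, vt = np.linalg.svd(pts, full_matrices=False)
        flat = np.column_stack([pts @ vt[0], pts @ vt[1]])
        from shapely.geometry import Polygon

        planar_min = Polygon(flat).area
        assert pm.mesh_surface_area(trimmed) >= planar_min * (1 - 1e-6)

    def test_trimmed_boundary_close_to_loop(self):
        sheet, loop = gridded_sheet(lambda x, y: 0.05 * x**2)
        patch = fit_fill_patch(sheet, loop)
        tess = tessellate_patch(patch, 64)
        trimmed = trim_to_outline(tess, loop)
        edge = np.median(tess.edges_unique_length)
        rim = np.concatenate([lp.points for lp in mesh_boundary_loops(trimmed)])
        from scipy.spatial import cKDTree

        d, _ = cKDTree(loop.points).query(rim)
        assert d.max() < 2 * edge + 0.25  # rms-level fit slack on top

    def test_missing_uv_rejected(self):
        outline = BoundaryLoop(
            points=np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)
        )
        with pytest.raises(GeometryError):
            trim_to_outline(unit_square_mesh(), outline)
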