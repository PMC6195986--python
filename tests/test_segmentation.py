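"""Thresholding, connected components, iso-surfaces, and STL round trips."""

import numpy as np
import pytest

import palatometry as pm
from palatometry.errors import (
    EmptyMaskError,
    EmptySurfaceError,
    FormatError,
    ParameterError,
)


def sphere_volume(radius=10.0, spacing=0.5, hu_in=700.0, hu_out=-1000.0):
    pad = 3.0
    n = int(np.ceil(2 * (radius + pad) / spacing))
    coords = (np.arange(n) + 0.5) * spacing - (radius + pad)
    z, y, x = np.meshgrid(coords, coords, coords, indexing="ij")
    data = np.where(z * z + y * y + x * x <= radius * radius, hu_in, hu_out)
    return pm.CTVolume(data=data, spacing=(spacing,) * 3)


class TestThreshold:
    def test_cutoff_is_inclusive(self):
        data = np.full((3, 3, 3), -1000.0)
        data[1, 1, 0] = 139.0
        data[1, 1, 1] = 140.0
        data[1, 1, 2] = 141.0
        mask = pm.threshold_mask(pm.CTVolume(data=data, spacing=(1, 1, 1)))
        assert not mask.data[1, 1, 0]
        assert mask.data[1, 1, 1] and mask.data[1, 1, 2]

    def test_all_air_gives_empty_mask(self):
        vol = pm.CTVolume(data=np.full((4, 4, 4), -1000.0), spacing=(1, 1, 1))
        assert pm.threshold_mask(vol).count == 0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        vol = pm.CTVolume(
            data=rng.uniform(-1000, 1500, (8, 8, 8)), spacing=(1, 1, 1)
        )
        lo = pm.threshold_mask(vol, 100.0).data
        hi = pm.threshold_mask(vol, 300.0).data
        assert not np.any(hi & ~lo)  # raising the threshold never adds voxels

    def test_phantom_count_matches_generator(self):
        spec = pm.PhantomSpec(name="t", half_width=6.0, length=10.0)
        volume, truth = pm.generate_phantom(spec)
        assert pm.threshold_mask(volume).count == truth.bone_voxel_count


class TestLargestComponent:
    def _mask(self, data):
        return pm.BinaryMask(data=data, spacing=(1, 1, 1))

    def test_keeps_biggest_blob(self):
        data = np.zeros((5, 5, 10), dtype=bool)
        data[1:3, 1:3, 1:4] = True  # 12 voxels... trim to 10
        data[2, 2, 3] = False
        data[2, 2, 2] = False
        data[4, 4, 7:] = True  # 3 voxels
        out = pm.largest_component(self._mask(data))
        assert out.count == 10
        assert not out.data[4, 4, 7]

    def test_single_blob_identity(self):
        data = np.zeros((4, 4, 4), dtype=bool)
        data[1:3, 1:3, 1:3] = True
        out = pm.largest_component(self._mask(data))
        assert np.array_equal(out.data, data)

    def test_tie_break_smallest_linear_index(self):
        data = np.zeros((3, 3, 6), dtype=bool)
        data[0, 0, 4:6] = True  # earlier in C order? index (0,0,4) = 4
        data[2, 2, 0:2] = True  # index (2,2,0) = 2*9+2*3+0 = 24
        out = pm.largest_component(self._mask(data), connectivity=6)
        assert out.data[0, 0, 4] and not out.data[2, 2, 0]

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            pm.largest_component(self._mask(np.zeros((3, 3, 3), dtype=bool)))

    def test_bad_connectivity_rejected(self):
        data = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ParameterError):
            pm.largest_component(self._mask(data), connectivity=18)


class TestIsosurface:
    def test_sphere_area_within_2_percent(self):
        mesh = pm.extract_isosurface(sphere_volume(spacing=0.5))
        truth = 4 * np.pi * 10.0**2
        assert abs(mesh.area - truth) / truth < 0.02

    def test_cube_area_within_2_percent(self):
        """Sharp-edged solids are extracted without indicator smoothing:
        smoothing deliberately rounds corners (right for anatomy, wrong for
        a cube), while the raw crossing is accurate on axis-aligned faces."""
        spacing = 0.5
        n = 52
        coords = (np.arange(n) + 0.5) * spacing - 13.0
        z, y, x = np.meshgrid(coords, coords, coords, indexing="ij")
        inside = (np.abs(z) <= 10) & (np.abs(y) <= 10) & (np.abs(x) <= 10)
        vol = pm.CTVolume(np.where(inside, 700.0, -1000.0), spacing=(spacing,) * 3)
        mesh = pm.extract_isosurface(vol, smooth_sigma_vox=0.0)
        assert abs(mesh.area - 2400.0) / 2400.0 < 0.02

    def test_area_converges_with_spacing(self):
        """Halving the voxel size shrinks the sphere-area error."""
        truth = 4 * np.pi * 10.0**2
        errs = [
            abs(pm.extract_isosurface(sphere_volume(spacing=s)).area - truth) / truth
            for s in (1.0, 0.5)
        ]
        assert errs[1] < errs[0]

    def test_uniform_volume_raises(self):
        vol = pm.CTVolume(np.full((4, 4, 4), 500.0), spacing=(1, 1, 1))
        with pytest.raises(EmptySurfaceError):
            pm.extract_isosurface(vol)

    def test_world_coordinates_respect_origin(self):
        vol = sphere_volume(spacing=0.5)
        shifted = pm.CTVolume(vol.data, vol.spacing, origin=(5.0, -3.0, 2.0))
        m0 = pm.extract_isosurface(vol)
        m1 = pm.extract_isosurface(shifted)
        # origin is (z, y, x); mesh vertices are (x, y, z)
        assert np.allclose(
            m1.vertices.mean(axis=0) - m0.vertices.mean(axis=0),
            [2.0, -3.0, 5.0],
            atol=1e-6,
        )


class TestSTL:
    def _unit_square(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
            faces=[[0, 1, 2], [0, 2, 3]],
            process=False,
        )

    @pytest.mark.parametrize("dialect", ["binary", "ascii"])
    def test_unit_square_round_trip(self, tmp_path, dialect):
        path = tmp_path / f"sq_{dialect}.stl"
        pm.write_stl(self._unit_square(), path, dialect=dialect)
        back = pm.read_stl(path)
        assert abs(pm.mesh_surface_area(back) - 1.0) < 1e-6

    def test_dialects_agree(self, tmp_path):
        mesh = pm.extract_isosurface(sphere_volume(spacing=1.0))
        pm.write_stl(mesh, tmp_path / "b.stl", dialect="binary")
        pm.write_stl(mesh, tmp_path / "a.stl", dialect="ascii")
        ab = pm.mesh_surface_area(pm.read_stl(tmp_path / "a.stl"))
        bb = pm.mesh_surface_area(pm.read_stl(tmp_path / "b.stl"))
        assert abs(ab - bb) / bb < 1e-5

    def test_sphere_area_preserved_to_float32(self, tmp_path):
        mesh = pm.extract_isosurface(sphere_volume(spacing=0.5))
        pm.write_stl(mesh, tmp_path / "s.stl")
        back = pm.read_stl(tmp_path / "s.stl")
        assert abs(back.area - mesh.area) / mesh.area < 1e-4

    def test_malformed_stl_rejected(self, tmp_path):
        bad = tmp_path / "bad.stl"
        bad.write_bytes(b"\x00" * 10)
        with pytest.raises(FormatError):
            pm.read_stl(bad)

    def test_bad_dialect_rejected(self, tmp_path):
        with pytest.raises(ParameterError):
            pm.write_stl(self._unit_square(), tmp_path / "x.stl", dialect="vrml")
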