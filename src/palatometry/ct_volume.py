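"""CT volumes in Hounsfield units: containers, I/O, and display windowing.

Coordinate contract
-------------------
Voxel data is stored as a 3-D array indexed ``(z, y, x)`` (slice, row,
column); ``spacing`` and ``origin`` follow the same axis order and are in
millimetres.  The world position of voxel ``(i, j, k)`` is
``origin + (i, j, k) * spacing``.  Triangle meshes derived from a volume
live in world millimetres with conventional Cartesian ``(x, y, z)`` vertex
order; the dorsal direction is +z and the rostro-caudal (long) axis is +y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, MetadataError, ParameterError

AXIS_LABELS = ("z", "y", "x")


@dataclass
class CTVolume:
    """A 3-D grid of Hounsfield units with physical spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Hounsfield units (dimensionless).
    spacing : 3-tuple of float
        Per-axis voxel size in mm, ``(z, y, x)`` order; all > 0.
    origin : 3-tuple of float
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = field(default=AXIS_LABELS, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise MetadataError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if any(n < 2 for n in self.data.shape):
            raise MetadataError(f"every axis needs >= 2 voxels, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise MetadataError("HU data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map fractional ``(z, y, x)`` voxel indices to world mm (same order)."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass(frozen=True)
class WindowSetting:
    """A display window: linear HU ramp centred at ``level`` spanning ``width``."""

    level: float
    width: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ParameterError(f"window width must be > 0, got {self.width}")


#: Standard presets used when reviewing neonatal head CT.
BONE_WINDOW = WindowSetting(level=300.0, width=1500.0, name="bone")
SOFT_TISSUE_WINDOW = WindowSetting(level=40.0, width=350.0, name="soft_tissue")


def window_transform(volume: CTVolume | np.ndarray, window: WindowSetting) -> np.ndarray:
    """Map HU to display intensities in [0, 1] with a clamped linear ramp.

    ``level - width/2`` maps to 0, ``level + width/2`` to 1, and the level
    itself to mid-grey.
    """
    hu = volume.data if isinstance(volume, CTVolume) else np.asarray(volume, dtype=float)
    low = window.level - window.width / 2.0
    return np.clip((hu - low) / window.width, 0.0, 1.0)


def save_window_png(volume: CTVolume, window: WindowSetting, slice_index: int, path: str | Path) -> None:
    """Export one windowed axial slice as an 8-bit grayscale PNG (QC image)."""
    from PIL import Image

    img = window_transform(volume, window)[slice_index]
    Image.fromarray(np.round(img * 255).astype(np.uint8), mode="L").save(str(path))


def _format_for(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("nrrd", "nifti"):
            raise ParameterError(f"unknown volume format {fmt!r}")
        return fmt
    name = str(path).lower()
    if name.endswith(".nrrd") or name.endswith(".nhdr"):
        return "nrrd"
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    raise ParameterError(f"cannot infer volume format from {path!r}; pass format=")


def read_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read an NRRD or NIfTI-1 volume into the ``(z, y, x)`` contract.

    Raises
    ------
    FormatError
        If the file cannot be parsed as the named format.
    MetadataError
        If spacing metadata is missing, zero, or negative.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _format_for(path, format)
    if fmt == "nrrd":
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:
            raise FormatError(f"cannot read NRRD {path}: {exc}") from exc
        data = sitk.GetArrayFromImage(img)  # already (z, y, x)
        spacing = tuple(reversed(img.GetSpacing()))
        origin = tuple(reversed(img.GetOrigin()))
    else:
        import nibabel as nib

        try:
            img = nib.load(str(path))
        except Exception as exc:
            raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
        affine = img.affine
        rot = affine[:3, :3]
        if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
            raise MetadataError("only axis-aligned NIfTI affines are supported")
        data_xyz = np.asanyarray(img.dataobj)
        data = np.transpose(data_xyz, (2, 1, 0))
        zooms = np.abs(np.diag(rot))
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        t = affine[:3, 3]
        origin = (float(t[2]), float(t[1]), float(t[0]))
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise MetadataError(f"non-positive spacing {spacing} in {path}")
    return CTVolume(data=np.asarray(data), spacing=spacing, origin=origin)


def write_volume(volume: CTVolume, path: str | Path, format: str | None = None) -> None:
    """Write a :class:`CTVolume` as NRRD or NIfTI-1 (read_volume round-trips)."""
    path = Path(path)
    fmt = _format_for(path, format)
    if path.parent and not path.parent.exists():
        raise FormatError(f"directory does not exist: {path.parent}")
    if fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(volume.data)
        img.SetSpacing(tuple(reversed(volume.spacing)))
        img.SetOrigin(tuple(reversed(volume.origin)))
        sitk.WriteImage(img, str(path))
    else:
        import nibabel as nib

        sz, sy, sx = volume.spacing
        oz, oy, ox = volume.origin
        affine = np.diag([sx, sy, sz, 1.0])
        affine[:3, 3] = (ox, oy, oz)
        nib.save(nib.Nifti1Image(np.transpose(volume.data, (2, 1, 0)), affine), str(path))
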