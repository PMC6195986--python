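"""Synthetic CT phantoms of a curved palatal bone shell with known clefts.

The phantom emulates the imaging substrate of a neonatal-dog hard palate:
a thin bony shell shaped like a parabolic cylinder ``z = a*x**2`` (the
simplest surface with non-trivial, analytically integrable curvature — a
flat projection under-measures its area, which is exactly why the curved
model matters), pierced by cleft gaps of parametrically known outline,
optionally by sub-millimetre radiolucent suture slits, embedded in a
soft-tissue envelope surrounded by air.  Every phantom comes with a
brute-force quadrature ground truth so each pipeline stage is testable
without any real scan.

Default tissue values: bone +700 HU (neonatal bone is less mineralised
than adult bone but still well above the 140 HU bone cut-off), soft tissue
+40 HU, air -1000 HU.  Voxel membership is a voxel-centre test on a
cell-centred grid (centres at half-integer multiples of the spacing), so
the oracle stays exact; partial-volume effects are probed indirectly via
the spacing sweep in the standard suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

from .ct_volume import CTVolume
from .errors import GeometryError, ParameterError
from .morphometry import cleft_percentage


@dataclass
class PhantomSpec:
    """Parametric description of one palate phantom.

    The bony sheet is ``z = curvature * x**2`` thickened by ``thickness``
    along z, over ``(x, y) in [-half_width, half_width] x [0, length]`` mm.
    ``cleft_outlines`` are simple (x, y) polygons cut through the full
    shell; ``suture_slits`` are ``((x0, y0), (x1, y1), gap_mm)`` line
    segments cut through the shell with the given transverse gap.
    """

    name: str = "phantom"
    curvature: float = 0.02  # 1/mm
    half_width: float = 11.0  # mm (x in [-X, X])
    length: float = 24.0  # mm (y in [0, Y])
    thickness: float = 2.0  # mm
    cleft_outlines: list[Sequence[tuple[float, float]]] = field(default_factory=list)
    suture_slits: list[tuple[tuple[float, float], tuple[float, float], float]] = field(
        default_factory=list
    )
    hu_bone: float = 700.0
    hu_soft: float = 40.0
    hu_air: float = -1000.0
    spacing: float = 0.5  # mm, isotropic
    noise_sd: float = 0.0  # HU
    seed: int = 0
    soft_margin: float = 2.0  # mm of soft tissue around the shell box
    air_margin: float = 2.0  # mm of air beyond the soft tissue
    roi_inset: float = 1.0  # mm inset of the analysis box from the sheet rim

    def __post_init__(self) -> None:
        if self.thickness <= 0 or self.spacing <= 0:
            raise ParameterError("thickness and spacing must be > 0")
        if not (self.hu_bone >= 140.0 > self.hu_soft):
            raise ParameterError("need hu_bone >= 140 > hu_soft for threshold separability")
        if self.curvature < 0:
            raise ParameterError("curvature must be >= 0")
        domain = self.domain_polygon
        for outline in self.cleft_outlines:
            poly = Polygon(outline)
            if not poly.is_valid or poly.area == 0:
                raise GeometryError(f"cleft outline {outline!r} is not a simple polygon")
            if not poly.within(domain):
                raise GeometryError("cleft outline extends outside the sheet domain")
        for p0, p1, gap in self.suture_slits:
            if gap <= 0:
                raise ParameterError("suture gap must be > 0")

    @property
    def domain_polygon(self) -> Polygon:
        X, Y = self.half_width, self.length
        return Polygon([(-X, 0.0), (X, 0.0), (X, Y), (-X, Y)])

    @property
    def roi_box(self) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
        """Analysis box in world (x, y, z) mm for cropping the bone mesh."""
        X, Y, m = self.half_width, self.length, self.roi_inset
        z_top = self.curvature * X**2 + self.thickness
        pad = self.soft_margin + self.air_margin + 1.0
        return ((-X + m, m, -pad), (X - m, Y - m, z_top + pad))

    @property
    def roi_rectangle(self) -> Polygon:
        (x0, y0, _), (x1, y1, _) = self.roi_box
        return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


@dataclass
class GroundTruth:
    """Oracle values for one phantom (areas from dense quadrature)."""

    cleft_area_true: list[float]  # mm^2, per outline (clipped to the ROI)
    palate_area_true: float  # mm^2, intact oral sheet over the ROI
    percentage_true: int
    widths_true: list[tuple[float, float]]  # (min, max) mm per outline
    bone_voxel_count: int
    roi_box: tuple[tuple[float, float, float], tuple[float, float, float]]


def _sheet_integrand(a: float):
    return lambda x: np.sqrt(1.0 + 4.0 * a * a * x * x)


def closed_form_parabolic_area(a: float, half_width: float, length: float) -> float:
    """Exact area of the sheet ``z = a x^2`` over the full domain.

    ``length * [x*sqrt(1+4a^2x^2)/2 + asinh(2ax)/(4a)]`` evaluated at
    ``+-half_width`` (the flat limit ``2*X*Y`` as ``a -> 0``).
    """
    X = half_width
    if a == 0:
        return 2.0 * X * length
    F = lambda x: x * math.sqrt(1 + 4 * a * a * x * x) / 2 + math.asinh(2 * a * x) / (4 * a)
    return length * (F(X) - F(-X))


def true_surface_area(
    spec: PhantomSpec,
    region: Polygon | Sequence[tuple[float, float]] | None = None,
    rel_tol: float = 1e-6,
) -> float:
    """Curved area of the sheet over a region, by refining quadrature.

    The first fundamental form of ``z = a x^2`` gives
    ``area = integral over region of sqrt(1 + 4 a^2 x^2) dx dy``; the y
    direction integrates exactly to the chord length ``w(x)`` of the region
    at each x, and the x integral is evaluated with a midpoint rule split
    at polygon vertices, doubled until successive refinements agree to
    ``rel_tol``.

    Raises
    ------
    GeometryError
        If the region is not a simple polygon or lies outside the sheet.
    """
    if region is None:
        poly = spec.domain_polygon
    elif isinstance(region, Polygon):
        poly = region
    else:
        poly = Polygon(region)
    if not poly.is_valid or poly.is_empty:
        raise GeometryError("region is not a simple polygon")
    if not poly.within(spec.domain_polygon.buffer(1e-9)):
        raise GeometryError("region extends outside the sheet domain")
    f = _sheet_integrand(spec.curvature)
    xs = np.unique(np.asarray(poly.exterior.coords)[:, 0])
    for interior in poly.interiors:
        xs = np.union1d(xs, np.asarray(interior.coords)[:, 0])
    y0, y1 = poly.bounds[1] - 1.0, poly.bounds[3] + 1.0

    def chord(x: np.ndarray) -> np.ndarray:
        lines = shapely.linestrings(
            np.stack(
                [np.column_stack([x, np.full_like(x, y0)]),
                 np.column_stack([x, np.full_like(x, y1)])],
                axis=1,
            )
        )
        return shapely.length(shapely.intersection(lines, poly))

    total_prev = None
    n = 8
    while True:
        total = 0.0
        for a, b in zip(xs[:-1], xs[1:]):
            if b - a <= 0:
                continue
            xm = a + (np.arange(n) + 0.5) * (b - a) / n
            total += float(np.sum(chord(xm) * f(xm))) * (b - a) / n
        if total_prev is not None and (
            total == total_prev == 0.0
            or abs(total - total_prev) <= rel_tol * max(abs(total), 1e-300)
        ):
            return total
        total_prev = total
        n *= 2
        if n > 1 << 16:
            return total


def _region_widths(poly: Polygon, n_stations: int = 256) -> tuple[float, float]:
    """Min/max transverse (x) extent of an outline across y stations."""
    x0, y0, x1, y1 = poly.bounds
    eps = (y1 - y0) / n_stations / 2
    widths = []
    for y in np.linspace(y0 + eps, y1 - eps, n_stations):
        cut = poly.intersection(LineString([(x0 - 1, y), (x1 + 1, y)]))
        if cut.is_empty:
            continue
        bx0, _, bx1, _ = cut.bounds
        if bx1 > bx0:
            widths.append(bx1 - bx0)
    if not widths:
        raise GeometryError("outline has no transverse extent")
    return float(min(widths)), float(max(widths))


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Voxelize a phantom and compute its ground truth.

    HU is ``hu_bone`` where the voxel centre lies inside the thickened
    shell and outside every cleft polygon and suture slit, ``hu_soft`` in
    the surrounding soft-tissue envelope, ``hu_air`` elsewhere; Gaussian
    noise of ``noise_sd`` HU is added with the stated seed (identical seed,
    identical volume).
    """
    h = spec.spacing
    a, X, Y, t = spec.curvature, spec.half_width, spec.length, spec.thickness
    ms, ma = spec.soft_margin, spec.air_margin
    z_lo, z_hi = -(ms + ma), a * X**2 + t + ms + ma
    x_lo, x_hi = -(X + ms + ma), X + ms + ma
    y_lo, y_hi = -(ms + ma), Y + ms + ma

    def centres(lo, hi):
        n = int(np.ceil((hi - lo) / h))
        return lo + (np.arange(n) + 0.5) * h

    zc, yc, xc = centres(z_lo, z_hi), centres(y_lo, y_hi), centres(x_lo, x_hi)
    z = zc[:, None, None]
    y = yc[None, :, None]
    x = xc[None, None, :]

    sheet_xy = (np.abs(x) <= X) & (y >= 0) & (y <= Y)
    in_shell = sheet_xy & (z >= a * x**2) & (z <= a * x**2 + t)

    # cut clefts and sutures (through the full thickness)
    cut_xy = np.zeros((len(yc), len(xc)), dtype=bool)
    yy, xx = np.meshgrid(yc, xc, indexing="ij")
    pts = shapely.points(xx.ravel(), yy.ravel())
    for outline in spec.cleft_outlines:
        poly = Polygon(outline)
        cut_xy |= shapely.contains(poly, pts).reshape(cut_xy.shape)
    for p0, p1, gap in spec.suture_slits:
        seg = LineString([p0, p1])
        cut_xy |= (shapely.distance(pts, seg) <= gap / 2.0).reshape(cut_xy.shape)
    bone = in_shell & ~cut_xy[None, :, :]

    in_soft = (
        (np.abs(x) <= X + ms)
        & (y >= -ms)
        & (y <= Y + ms)
        & (z >= -ms)
        & (z <= a * X**2 + t + ms)
    )
    vol = np.full(bone.shape, spec.hu_air, dtype=np.float64)
    vol[in_soft & ~bone] = spec.hu_soft
    vol[bone] = spec.hu_bone
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)

    volume = CTVolume(
        data=vol,
        spacing=(h, h, h),
        origin=(float(zc[0]), float(yc[0]), float(xc[0])),
    )

    roi = spec.roi_rectangle
    cleft_areas = []
    widths = []
    for outline in spec.cleft_outlines:
        poly = Polygon(outline).intersection(roi)
        cleft_areas.append(true_surface_area(spec, poly))
        widths.append(_region_widths(Polygon(outline)))
    palate_area = true_surface_area(spec, roi)
    pct = cleft_percentage(sum(cleft_areas), palate_area) if cleft_areas else 0
    truth = GroundTruth(
        cleft_area_true=cleft_areas,
        palate_area_true=palate_area,
        percentage_true=pct,
        widths_true=widths,
        bone_voxel_count=int(bone.sum()),
        roi_box=spec.roi_box,
    )
    return volume, truth


def standard_suite() -> list[PhantomSpec]:
    """Deterministic fixture phantoms spanning the study conditions.

    Cleft widths 2, 5 and 10 mm bracket the clinically reported range
    (narrowest 2.1 mm, widest 9.6 mm); unilateral, midline and bilateral
    outlines are covered; one intact control carries only sub-millimetre
    suture slits; spacings 1.0 and 0.5 mm bracket the 0.5 mm slice
    thickness of the source scans.
    """
    sutures = [
        ((0.0, 2.0), (0.0, 20.0), 0.5),  # median palatine
        ((-9.0, 6.0), (-3.0, 6.0), 0.5),  # palatomaxillary, right
        ((3.0, 6.0), (9.0, 6.0), 0.5),  # palatomaxillary, left
    ]
    rect = lambda x0, x1, y0, y1: [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
    return [
        PhantomSpec(name="intact-sutures", suture_slits=sutures, seed=101),
        PhantomSpec(name="cleft-2mm-unilateral", cleft_outlines=[rect(-4.0, -2.0, 4.0, 20.0)], seed=102),
        PhantomSpec(name="cleft-5mm-midline", cleft_outlines=[rect(-2.5, 2.5, 4.0, 20.0)], seed=103),
        PhantomSpec(name="cleft-10mm-midline", cleft_outlines=[rect(-5.0, 5.0, 4.0, 20.0)], seed=104),
        PhantomSpec(
            name="bilateral-4mm-3mm",
            cleft_outlines=[rect(-6.5, -2.5, 5.0, 19.0), rect(2.5, 5.5, 5.0, 19.0)],
            seed=105,
        ),
        PhantomSpec(
            name="flat-trapezoid-2-8mm",
            curvature=0.0,
            cleft_outlines=[[(-1.0, 4.0), (1.0, 4.0), (4.0, 19.0), (-4.0, 19.0)]],
            seed=106,
        ),
        PhantomSpec(
            name="cleft-6mm-coarse",
            cleft_outlines=[rect(-3.0, 3.0, 4.0, 20.0)],
            spacing=1.0,
            seed=107,
        ),
        PhantomSpec(
            name="cleft-5mm-noisy",
            cleft_outlines=[rect(-2.5, 2.5, 4.0, 20.0)],
            noise_sd=30.0,
            seed=108,
        ),
    ]
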