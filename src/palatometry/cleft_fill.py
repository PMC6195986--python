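"""Virtual filling of palatal defects with spline surface patches.

The palatal region is cropped out of the bone mesh, defect outlines are
detected as holes in the oral-surface sheet, and each defect is filled with
a smooth tensor-product B-spline patch fitted to the surrounding palate by
penalized least squares (a deterministic surrogate for interactive knot
editing: samples are re-parameterized by closest-point projection and the
fit re-solved until the residual stops improving).  The patch is then
tessellated and trimmed to the defect outline, giving the cleft surface
whose area respects the natural curvature of the palate.

Outline localisation.  Marching cubes rounds the material corner where the
oral surface meets a cleft wall, so the hole in the strictly-ventral face
sheet is dilated by the smoothing chamfer.  The defect outline is therefore
read at mid-wall (faces with any ventral normal component reach halfway up
the vertical cleft wall, where the interface estimate is unbiased) and then
draped onto the oral surface for fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import trimesh
from scipy.interpolate import BSpline
from scipy.spatial import cKDTree
from shapely.geometry import LinearRing, MultiPolygon, Polygon
from shapely.validation import make_valid

from .errors import (
    EmptyResultError,
    FitFailureError,
    GeometryError,
    InsufficientSupportError,
    ParameterError,
)

DORSAL_AXIS = np.array([0.0, 0.0, 1.0])  # +z in mesh/world coordinates
LONG_AXIS = np.array([0.0, 1.0, 0.0])  # rostro-caudal


# ---------------------------------------------------------------------------
# regions of interest / cropping

@dataclass
class RegionOfInterest:
    """Axis-aligned box, set of half-space cutting planes, or explicit faces.

    ``box``: ``(min_xyz, max_xyz)`` in mm.  ``planes``: sequence of
    ``(point, normal)``; the kept side is the one the normal points into.
    ``faces``: explicit face indices.
    """

    box: tuple[Sequence[float], Sequence[float]] | None = None
    planes: Sequence[tuple[Sequence[float], Sequence[float]]] | None = None
    faces: Sequence[int] | None = None

    def __post_init__(self) -> None:
        given = sum(x is not None for x in (self.box, self.planes, self.faces))
        if given != 1:
            raise ParameterError("specify exactly one of box, planes, faces")
        if self.box is not None:
            lo, hi = (np.asarray(v, dtype=float) for v in self.box)
            if lo.shape != (3,) or hi.shape != (3,) or np.any(hi <= lo):
                raise ParameterError("ROI box must have positive extent in all axes")
            self.box = (tuple(lo), tuple(hi))
        if self.planes is not None:
            for point, normal in self.planes:
                if np.linalg.norm(np.asarray(normal, dtype=float)) == 0:
                    raise ParameterError("ROI plane normal must be non-zero")


def crop_mesh(mesh: trimesh.Trimesh, roi: RegionOfInterest) -> trimesh.Trimesh:
    """Cut a mesh down to a region of interest.

    Faces straddling a cutting plane (box side or explicit plane) are split
    at the plane, so cut edges are exact.

    Raises
    ------
    EmptyResultError
        If nothing of the mesh lies inside the ROI.
    """
    if len(mesh.faces) == 0:
        raise EmptyResultError("cannot crop an empty mesh")
    if roi.faces is not None:
        idx = np.asarray(roi.faces, dtype=int)
        if idx.size == 0:
            raise EmptyResultError("ROI face set is empty")
        out = mesh.submesh([idx], append=True)
    else:
        if roi.box is not None:
            lo, hi = (np.asarray(v) for v in roi.box)
            planes = [(lo, np.eye(3)[i]) for i in range(3)]
            planes += [(hi, -np.eye(3)[i]) for i in range(3)]
        else:
            planes = [(np.asarray(p, float), np.asarray(n, float)) for p, n in roi.planes]
        out = mesh
        for point, normal in planes:
            out = trimesh.intersections.slice_mesh_plane(
                out, plane_normal=normal, plane_origin=point
            )
            if out is None or len(out.faces) == 0:
                raise EmptyResultError("ROI retains no faces")
    out = out.copy()
    out.update_faces(out.nondegenerate_faces())
    out.remove_unreferenced_vertices()
    if len(out.faces) == 0:
        raise EmptyResultError("ROI retains no faces")
    return out


# ---------------------------------------------------------------------------
# boundary loops

def _polygons_in(geom) -> list[Polygon]:
    if isinstance(geom, Polygon):
        return [geom]
    out: list[Polygon] = []
    for g in getattr(geom, "geoms", []):
        out.extend(_polygons_in(g))
    return out


def _largest_polygon(geom) -> Polygon:
    """Largest polygonal component of a (possibly repaired) geometry."""
    polys = _polygons_in(geom)
    if not polys:
        raise GeometryError("geometry contains no polygonal component")
    return max(polys, key=lambda g: g.area)


@dataclass
class BoundaryLoop:
    """Ordered closed polyline (mm) bounding a gap in the palate sheet."""

    points: np.ndarray  # (n, 3), implicitly closed (last != first)
    ccw: bool = True  # orientation of the (x, y) projection

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise GeometryError("loop points must be an (n, 3) array")
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.abs(np.diff(pts, axis=0)) > 1e-12, axis=1)
        pts = pts[keep]
        if len(pts) < 3:
            raise GeometryError("a boundary loop needs at least 3 distinct points")
        self.points = pts

    @property
    def closed_points(self) -> np.ndarray:
        return np.vstack([self.points, self.points[:1]])

    def projected_polygon(self, drop_axis: int = 2) -> Polygon:
        """Shapely polygon of the loop projected along one axis (default z)."""
        keep = [i for i in range(3) if i != drop_axis]
        poly = Polygon(self.points[:, keep])
        if not poly.is_valid:
            poly = _largest_polygon(make_valid(poly))
        return poly

    @property
    def projected_area(self) -> float:
        return float(self.projected_polygon().area)

    def resampled(self, n: int) -> np.ndarray:
        """Approximately arc-length-uniform subset of ``n`` loop points.

        When the loop has at least ``n`` vertices, existing vertices are
        selected (they lie on the measured surface; interpolating along 3-D
        chords would fabricate off-surface points).  Sparser loops are
        interpolated.
        """
        pts = self.closed_points
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        t = np.linspace(0.0, s[-1], n, endpoint=False)
        if len(self.points) >= n:
            nearest = np.clip(np.searchsorted(s, t), 0, len(s) - 1)
            left = np.clip(nearest - 1, 0, len(s) - 1)
            pick = np.where(
                np.abs(s[left] - t) <= np.abs(s[nearest] - t), left, nearest
            )
            pick = np.unique(pick % len(self.points))
            return self.points[pick]
        out = np.empty((n, 3))
        for axis in range(3):
            out[:, axis] = np.interp(t, s, pts[:, axis])
        return out


def mesh_boundary_loops(mesh: trimesh.Trimesh) -> list[BoundaryLoop]:
    """Closed loops of boundary edges (edges used by exactly one face)."""
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = unique[counts == 1]
    if len(boundary) == 0:
        return []
    # chain edges into loops
    adjacency: dict[int, list[int]] = {}
    for a, b in boundary:
        adjacency.setdefault(int(a), []).append(int(b))
        adjacency.setdefault(int(b), []).append(int(a))
    unused = {tuple(e) for e in boundary.tolist()}
    loops = []
    while unused:
        a, b = min(unused)
        unused.discard((a, b))
        chain = [a, b]
        while chain[-1] != chain[0]:
            here = chain[-1]
            nxt = None
            for cand in adjacency[here]:
                key = (min(here, cand), max(here, cand))
                if key in unused:
                    nxt = cand
                    unused.discard(key)
                    break
            if nxt is None:
                break  # open chain (crop corner); drop it
            chain.append(nxt)
        if chain[-1] == chain[0] and len(chain) >= 4:
            pts = mesh.vertices[np.array(chain[:-1])]
            try:
                loops.append(BoundaryLoop(points=pts))
            except GeometryError:
                pass
    return loops


def _largest_face_patch(mesh: trimesh.Trimesh, face_index: np.ndarray) -> trimesh.Trimesh:
    """Largest edge-connected component (by area) of a face subset."""
    if face_index.size == 0:
        raise EmptyResultError("no faces selected")
    sub = mesh.submesh([face_index], append=True)
    parts = sub.split(only_watertight=False)
    if len(parts) == 0:
        return sub
    return max(parts, key=lambda p: p.area)


def oral_surface_sheet(
    mesh: trimesh.Trimesh,
    dorsal_axis: np.ndarray = DORSAL_AXIS,
    steep_cos: float = 0.85,
) -> trimesh.Trimesh:
    """The ventral (oral) surface sheet of the palate mesh.

    Keeps faces whose outward normals point ventrally (dot product with the
    dorsal axis below ``-steep_cos``) and returns the largest connected
    sheet.  The default ``steep_cos=0.85`` admits faces sloped up to ~32
    degrees — comfortably above the palate vault's own slope at this scale —
    while excluding defect walls and the corner-rounding skirt around
    holes, whose steep faces would otherwise inflate area tallies.
    """
    d = np.asarray(dorsal_axis, dtype=float)
    d = d / np.linalg.norm(d)
    keep = np.flatnonzero(mesh.face_normals @ d < -steep_cos)
    if keep.size == 0:
        raise EmptyResultError("mesh has no ventral-facing faces")
    return _largest_face_patch(mesh, keep)


def _loop_min_width(poly: Polygon) -> float:
    """Shorter side of the minimum-area rotated bounding rectangle."""
    rect = poly.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":
        return 0.0
    xy = np.asarray(rect.exterior.coords)[:-1]
    sides = np.linalg.norm(np.diff(np.vstack([xy, xy[:1]]), axis=0), axis=1)
    return float(sides.min()) if len(sides) else 0.0


def _drape_loop_heights(
    loop_xy: np.ndarray, sheet: trimesh.Trimesh, radius: float
) -> np.ndarray:
    """Heights of loop points from local plane fits of nearby sheet vertices."""
    verts = sheet.vertices
    tree = cKDTree(verts[:, :2])
    z = np.empty(len(loop_xy))
    for i, p in enumerate(loop_xy):
        r = radius
        idx = tree.query_ball_point(p, r)
        while len(idx) < 6 and r < 64 * radius:
            r *= 2.0
            idx = tree.query_ball_point(p, r)
        near = verts[idx]
        if len(near) < 3:
            _, j = tree.query(p)
            z[i] = verts[j, 2]
            continue
        dxy = near[:, :2] - p
        w = 1.0 / (1.0 + (np.linalg.norm(dxy, axis=1) / r) ** 2)
        A = np.column_stack([np.ones(len(near)), dxy])
        coef, *_ = np.linalg.lstsq(A * w[:, None], near[:, 2] * w, rcond=None)
        z[i] = coef[0]
    return z


DEFAULT_MIN_GAP_MM = 1.5
"""Suture/cleft discriminator: a sub-voxel suture slit can appear up to one
voxel wider in sampled data (~1 mm at 0.5 mm spacing), while the narrowest
clinically reported cleft fissure is 2.1 mm; 1.5 mm separates both with
margin."""


def detect_defect_boundary(
    mesh: trimesh.Trimesh,
    min_gap_mm: float = DEFAULT_MIN_GAP_MM,
    dorsal_axis: np.ndarray = DORSAL_AXIS,
) -> list[BoundaryLoop]:
    """Outlines of palatal defects in a cropped palate mesh.

    Holes in the oral-surface sheet narrower than ``min_gap_mm`` (unfused
    sutures, which the smoothing step typically bridges anyway) are
    excluded; the minimum transverse width of a gap is estimated as the
    shorter side of its minimum rotated bounding rectangle in the occlusal
    (x, y) projection.  Returned loops are draped onto the oral surface and
    ordered by enclosed projected area, largest first.  An intact palate
    yields an empty list.
    """
    if min_gap_mm <= 0:
        raise ParameterError("min_gap_mm must be > 0")
    d = np.asarray(dorsal_axis, dtype=float)
    d = d / np.linalg.norm(d)
    # mid-wall sheet: any ventral normal component
    keep = np.flatnonzero(mesh.face_normals @ d < 0.0)
    if keep.size == 0:
        return []
    sheet_mid = _largest_face_patch(mesh, keep)
    loops = mesh_boundary_loops(sheet_mid)
    if len(loops) <= 1:
        return []  # only the outer perimeter (or nothing): intact palate
    pairs = []
    for lp in loops:
        try:
            poly = lp.projected_polygon()
        except GeometryError:
            continue  # degenerate sliver (e.g. a wall loop with no xy extent)
        if not poly.is_empty and poly.area > 0:
            pairs.append((lp, poly))
    if len(pairs) <= 1:
        return []
    outer = int(np.argmax([p.area for _, p in pairs]))
    candidates = [
        (lp, poly)
        for i, (lp, poly) in enumerate(pairs)
        if i != outer and _loop_min_width(poly) >= min_gap_mm
    ]
    if not candidates:
        return []
    candidates.sort(key=lambda item: -item[1].area)
    # drape outlines onto the clean oral sheet
    sheet = oral_surface_sheet(mesh, dorsal_axis)
    edge_len = float(np.median(sheet.edges_unique_length))
    out = []
    for lp, poly in candidates:
        xy = lp.points[:, :2]
        z = _drape_loop_heights(xy, sheet, radius=max(2.0, 3.0 * edge_len))
        ccw = LinearRing(xy).is_ccw
        out.append(BoundaryLoop(points=np.column_stack([xy, z]), ccw=bool(ccw)))
    return out


# ---------------------------------------------------------------------------
# tensor-product spline patches

def _clamped_knots(n_ctrl: int, degree: int) -> np.ndarray:
    if n_ctrl <= degree:
        raise ParameterError(f"need more than degree+1={degree + 1} control points, got {n_ctrl}")
    interior = np.linspace(0.0, 1.0, n_ctrl - degree + 1)[1:-1]
    return np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])


def _basis_matrix(t: np.ndarray, knots: np.ndarray, degree: int, deriv: int = 0) -> np.ndarray:
    """Dense (len(t), n_ctrl) matrix of B-spline basis values or derivatives."""
    n = len(knots) - degree - 1
    spl = BSpline(knots, np.eye(n), degree, extrapolate=True)
    if deriv:
        spl = spl.derivative(deriv)
    return np.asarray(spl(np.clip(t, 0.0, 1.0)))


@dataclass
class SurfacePatch:
    """Tensor-product NURBS surface (unit weights make it a plain B-spline).

    Control points are world mm on an ``(nu, nv)`` grid; knot vectors are
    clamped and non-decreasing; the parametric domain is [0, 1]^2.
    """

    degree_u: int
    degree_v: int
    knots_u: np.ndarray
    knots_v: np.ndarray
    control: np.ndarray  # (nu, nv, 3)
    weights: np.ndarray | None = None  # (nu, nv), all > 0
    frame: dict | None = field(default=None, repr=False)  # fitting frame (plane)

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=float)
        self.knots_u = np.asarray(self.knots_u, dtype=float)
        self.knots_v = np.asarray(self.knots_v, dtype=float)
        nu, nv, three = self.control.shape
        if three != 3:
            raise ParameterError("control grid must be (nu, nv, 3)")
        for knots, degree, n in ((self.knots_u, self.degree_u, nu), (self.knots_v, self.degree_v, nv)):
            if len(knots) != n + degree + 1:
                raise ParameterError("knot count must equal n_ctrl + degree + 1")
            if np.any(np.diff(knots) < 0):
                raise ParameterError("knot vectors must be non-decreasing")
        if self.weights is None:
            self.weights = np.ones((nu, nv))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (nu, nv) or np.any(self.weights <= 0):
            raise ParameterError("weights must be positive on the control grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.control.shape[:2]

    def evaluate(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Evaluate at paired parameter values ``(u[i], v[i])`` -> (n, 3) mm."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        v = np.atleast_1d(np.asarray(v, dtype=float))
        Bu = _basis_matrix(u, self.knots_u, self.degree_u)
        Bv = _basis_matrix(v, self.knots_v, self.degree_v)
        wc = self.weights[..., None] * self.control  # (nu, nv, 3)
        num = np.einsum("ni,nj,ijk->nk", Bu, Bv, wc)
        den = np.einsum("ni,nj,ij->n", Bu, Bv, self.weights)
        return num / den[:, None]

    def evaluate_grid(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Evaluate on the tensor grid ``u x v`` -> (len(u), len(v), 3) mm."""
        Bu = _basis_matrix(np.asarray(u, float), self.knots_u, self.degree_u)
        Bv = _basis_matrix(np.asarray(v, float), self.knots_v, self.degree_v)
        wc = self.weights[..., None] * self.control
        num = np.einsum("ai,bj,ijk->abk", Bu, Bv, wc)
        den = np.einsum("ai,bj,ij->ab", Bu, Bv, self.weights)
        return num / den[..., None]

    def to_dict(self) -> dict:
        """JSON-ready control-net document."""
        return {
            "degree_u": self.degree_u,
            "degree_v": self.degree_v,
            "knots_u": self.knots_u.tolist(),
            "knots_v": self.knots_v.tolist(),
            "control": self.control.tolist(),
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SurfacePatch":
        return cls(
            degree_u=int(doc["degree_u"]),
            degree_v=int(doc["degree_v"]),
            knots_u=np.asarray(doc["knots_u"]),
            knots_v=np.asarray(doc["knots_v"]),
            control=np.asarray(doc["control"]),
            weights=np.asarray(doc["weights"]) if doc.get("weights") is not None else None,
        )


@dataclass
class FillResult:
    """Outcome of filling one defect."""

    patch: SurfacePatch
    fill_mesh: trimesh.Trimesh  # trimmed to the defect outline
    rms_fit: float  # mm
    iterations: int
    repair_mesh: trimesh.Trimesh | None = None  # trimmed to the residual sheet's hole


def _greville(knots: np.ndarray, degree: int) -> np.ndarray:
    n = len(knots) - degree - 1
    return np.array([knots[i + 1 : i + 1 + degree].mean() for i in range(n)])


def _pca_frame(points: np.ndarray, dorsal_axis: np.ndarray) -> dict:
    centroid = points.mean(axis=0)
    q = points - centroid
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    U, V, N = vt[0], vt[1], vt[2]
    if N @ dorsal_axis < 0:
        N = -N
    # deterministic in-plane signs: largest-|component| positive
    for vec in (U, V):
        if vec[np.argmax(np.abs(vec))] < 0:
            vec *= -1.0
    V = np.cross(N, U)  # right-handed, orthonormal
    return {"origin": centroid, "U": U, "V": V, "N": N}


def _plane_coords(points: np.ndarray, frame: dict) -> np.ndarray:
    q = points - frame["origin"]
    return np.column_stack([q @ frame["U"], q @ frame["V"], q @ frame["N"]])


def _bending_matrix(knots_u, knots_v, degree_u, degree_v, n_quad: int = 24) -> np.ndarray:
    """Thin-plate (bending) energy matrix over the unit parameter square."""
    uq = (np.arange(n_quad) + 0.5) / n_quad
    w = 1.0 / n_quad
    Bu0 = _basis_matrix(uq, knots_u, degree_u)
    Bv0 = _basis_matrix(uq, knots_v, degree_v)
    Bu2 = _basis_matrix(uq, knots_u, degree_u, deriv=2)
    Bv2 = _basis_matrix(uq, knots_v, degree_v, deriv=2)
    Bu1 = _basis_matrix(uq, knots_u, degree_u, deriv=1)
    Bv1 = _basis_matrix(uq, knots_v, degree_v, deriv=1)
    nu, nv = Bu0.shape[1], Bv0.shape[1]
    K = np.zeros((nu * nv, nu * nv))
    for A, B, fac in ((Bu2, Bv0, 1.0), (Bu1, Bv1, 2.0), (Bu0, Bv2, 1.0)):
        R = np.einsum("qi,rj->qrij", A, B).reshape(n_quad * n_quad, nu * nv)
        K += fac * w * w * (R.T @ R)
    # make the penalty blind to quadratic height fields: the fill should
    # continue the local quadric of the palate vault exactly (quadrics are in
    # the cubic spline space), with bending damping only the residual ripple
    uu, vv = np.meshgrid(uq, uq, indexing="ij")
    monomials = np.stack(
        [np.ones_like(uu), uu, vv, uu * uu, uu * vv, vv * vv], axis=-1
    ).reshape(-1, 6)
    A0 = np.einsum("qi,rj->qrij", Bu0, Bv0).reshape(n_quad * n_quad, nu * nv)
    Q, *_ = np.linalg.lstsq(A0, monomials, rcond=None)  # control nets of quadrics
    P = np.eye(nu * nv) - Q @ np.linalg.pinv(Q)
    return P.T @ K @ P


def fit_fill_patch(
    palate_mesh: trimesh.Trimesh,
    boundary: BoundaryLoop,
    support_band_mm: float = 3.0,
    degree: int = 3,
    control_grid: tuple[int, int] = (8, 8),
    rms_tol: float = 0.2,
    max_iter: int = 50,
    boundary_weight: float = 2.0,
    smoothness: float = 1e-2,
    n_boundary_samples: int = 200,
) -> SurfacePatch:
    """Fit a spline patch spanning a defect, matched to the palate curvature.

    The patch is a penalized least-squares fit to the boundary loop (heavily
    weighted, so the patch passes through the defect outline) and to the
    support band (palate vertices within ``support_band_mm`` of the loop).
    The thin-plate penalty extends the surface smoothly across the data-free
    defect interior.  Samples are re-parameterized by closest-point
    projection and the fit re-solved until the RMS residual improves by less
    than 1% or ``max_iter`` is reached.  Deterministic: no randomness.

    Raises
    ------
    InsufficientSupportError
        If the support band has fewer samples than control points.
    FitFailureError
        If the final RMS residual exceeds ``5 * rms_tol``.
    """
    nu, nv = control_grid
    if degree < 1 or nu <= degree or nv <= degree:
        raise ParameterError("control grid must exceed the spline degree")
    loop_pts = boundary.resampled(n_boundary_samples)
    verts = palate_mesh.vertices
    tree = cKDTree(loop_pts)
    dist, _ = tree.query(verts)
    band = verts[dist <= support_band_mm]
    if len(band) < nu * nv:
        raise InsufficientSupportError(
            f"support band has {len(band)} samples; need >= {nu * nv}"
        )
    pts = np.vstack([loop_pts, band])
    w = np.concatenate(
        [np.full(len(loop_pts), boundary_weight), np.ones(len(band))]
    )
    # normalise so band points have unit weight but boundary count doesn't
    # drown the band when loops are dense
    frame = _pca_frame(pts, DORSAL_AXIS)
    pqh = _plane_coords(pts, frame)
    margin = 0.02
    lo = pqh[:, :2].min(axis=0)
    hi = pqh[:, :2].max(axis=0)
    span = hi - lo
    if np.any(span <= 0):
        raise InsufficientSupportError("support band is degenerate (zero extent)")
    lo = lo - margin * span
    span = span * (1 + 2 * margin)
    uv = (pqh[:, :2] - lo) / span
    h = pqh[:, 2]

    knots_u = _clamped_knots(nu, degree)
    knots_v = _clamped_knots(nv, degree)
    K = _bending_matrix(knots_u, knots_v, degree, degree)
    lam = smoothness * float(w.sum())

    def solve(uv_now: np.ndarray) -> np.ndarray:
        Bu = _basis_matrix(uv_now[:, 0], knots_u, degree)
        Bv = _basis_matrix(uv_now[:, 1], knots_v, degree)
        A = np.einsum("ni,nj->nij", Bu, Bv).reshape(len(uv_now), nu * nv)
        Aw = A * w[:, None]
        lhs = A.T @ Aw + lam * K
        rhs = Aw.T @ h
        return np.linalg.solve(lhs, rhs)

    def build_patch(coef: np.ndarray) -> SurfacePatch:
        gu = _greville(knots_u, degree)
        gv = _greville(knots_v, degree)
        P = (
            frame["origin"]
            + np.multiply.outer(lo[0] + gu * span[0], frame["U"])[:, None, :]
            + np.multiply.outer(lo[1] + gv * span[1], frame["V"])[None, :, :]
            + coef.reshape(nu, nv)[..., None] * frame["N"]
        )
        return SurfacePatch(
            degree_u=degree,
            degree_v=degree,
            knots_u=knots_u,
            knots_v=knots_v,
            control=P,
            frame={**frame, "lo": lo, "span": span},
        )

    uv_now = uv.copy()
    rms_prev = np.inf
    coef = solve(uv_now)
    iterations = 1
    patch = build_patch(coef)
    rms = _weighted_rms_distance(patch, uv_now, pts, w)
    while iterations < max_iter and rms < rms_prev * 0.99:
        rms_prev = rms
        uv_now = _closest_param(patch, pts, uv_now)
        coef = solve(uv_now)
        patch = build_patch(coef)
        iterations += 1
        rms = _weighted_rms_distance(patch, uv_now, pts, w)
        if rms < 1e-9:
            break
    patch.frame["rms_fit"] = float(min(rms, rms_prev))
    patch.frame["iterations"] = iterations
    if min(rms, rms_prev) > 5 * rms_tol:
        raise FitFailureError(
            f"patch fit stalled at RMS {min(rms, rms_prev):.3f} mm (> 5 x rms_tol)"
        )
    return patch


def _weighted_rms_distance(patch, uv, pts, w) -> float:
    s = patch.evaluate(uv[:, 0], uv[:, 1])
    d2 = np.sum((s - pts) ** 2, axis=1)
    return float(np.sqrt(np.sum(w * d2) / np.sum(w)))


def _closest_param(patch: SurfacePatch, pts: np.ndarray, uv0: np.ndarray) -> np.ndarray:
    """One Gauss-Newton step of closest-point projection per sample."""
    u, v = uv0[:, 0].copy(), uv0[:, 1].copy()
    for _ in range(2):
        s = patch.evaluate(u, v)
        Bu1 = _basis_matrix(u, patch.knots_u, patch.degree_u, deriv=1)
        Bv0 = _basis_matrix(v, patch.knots_v, patch.degree_v)
        Bu0 = _basis_matrix(u, patch.knots_u, patch.degree_u)
        Bv1 = _basis_matrix(v, patch.knots_v, patch.degree_v, deriv=1)
        wc = patch.weights[..., None] * patch.control
        su = np.einsum("ni,nj,ijk->nk", Bu1, Bv0, wc)
        sv = np.einsum("ni,nj,ijk->nk", Bu0, Bv1, wc)
        r = pts - s
        # 2x2 normal equations per point
        a = np.sum(su * su, axis=1)
        b = np.sum(su * sv, axis=1)
        c = np.sum(sv * sv, axis=1)
        fu = np.sum(su * r, axis=1)
        fv = np.sum(sv * r, axis=1)
        det = a * c - b * b
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        du = (c * fu - b * fv) / det
        dv = (a * fv - b * fu) / det
        u = np.clip(u + du, 0.0, 1.0)
        v = np.clip(v + dv, 0.0, 1.0)
    return np.column_stack([u, v])


# ---------------------------------------------------------------------------
# tessellation and trimming

def _patch_with_derivatives(patch: SurfacePatch, uv: np.ndarray):
    """Patch points and first parametric derivatives at paired (u, v)."""
    u, v = uv[:, 0], uv[:, 1]
    Bu0 = _basis_matrix(u, patch.knots_u, patch.degree_u)
    Bv0 = _basis_matrix(v, patch.knots_v, patch.degree_v)
    Bu1 = _basis_matrix(u, patch.knots_u, patch.degree_u, deriv=1)
    Bv1 = _basis_matrix(v, patch.knots_v, patch.degree_v, deriv=1)
    wc = patch.weights[..., None] * patch.control
    s = np.einsum("ni,nj,ijk->nk", Bu0, Bv0, wc)
    su = np.einsum("ni,nj,ijk->nk", Bu1, Bv0, wc)
    sv = np.einsum("ni,nj,ijk->nk", Bu0, Bv1, wc)
    return s, su, sv


def tessellate_patch(patch: SurfacePatch, samples_per_direction: int = 64) -> trimesh.Trimesh:
    """Triangulate the patch on a regular parametric grid.

    The mesh carries per-vertex ``uv`` coordinates (used by
    :func:`trim_to_outline`).
    """
    n = samples_per_direction
    if n < 2:
        raise ParameterError("samples_per_direction must be >= 2")
    u = np.linspace(0.0, 1.0, n)
    v = np.linspace(0.0, 1.0, n)
    grid = patch.evaluate_grid(u, v)  # (n, n, 3)
    verts = grid.reshape(-1, 3)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    uv = np.column_stack([uu.ravel(), vv.ravel()])
    idx = np.arange(n * n).reshape(n, n)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.vertex_attributes["uv"] = uv
    if patch.frame is not None:
        mesh.metadata["param_frame"] = patch.frame
    mesh.metadata["source_patch"] = patch
    return mesh


def _triangulate_simple_polygon(coords: np.ndarray) -> list[tuple[int, int, int]]:
    """Ear-clipping triangulation of a simple polygon (indices into coords)."""
    n = len(coords)
    if n < 3:
        return []
    ring = LinearRing(coords)
    idx = list(range(n))
    if not ring.is_ccw:
        idx = idx[::-1]
    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(idx) > 3 and guard < 10 * n:
        guard += 1
        m = len(idx)
        clipped = False
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            p0, p1, p2 = coords[i0], coords[i1], coords[i2]
            cross = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p1[1] - p0[1]) * (p2[0] - p0[0])
            if cross <= 1e-14:
                continue  # reflex or degenerate
            # any other vertex inside?
            ok = True
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                q = coords[j]
                d0 = (p1[0] - p0[0]) * (q[1] - p0[1]) - (p1[1] - p0[1]) * (q[0] - p0[0])
                d1 = (p2[0] - p1[0]) * (q[1] - p1[1]) - (p2[1] - p1[1]) * (q[0] - p1[0])
                d2 = (p0[0] - p2[0]) * (q[1] - p2[1]) - (p0[1] - p2[1]) * (q[0] - p2[0])
                if d0 > 0 and d1 > 0 and d2 > 0:
                    ok = False
                    break
            if ok:
                tris.append((i0, i1, i2))
                idx.pop(k)
                clipped = True
                break
        if not clipped:
            break  # numerically stuck; remaining sliver is negligible
    if len(idx) == 3:
        tris.append((idx[0], idx[1], idx[2]))
    return tris


def trim_to_outline(fill_mesh: trimesh.Trimesh, boundary: BoundaryLoop) -> trimesh.Trimesh:
    """Remove parts of a fill surface protruding beyond the defect outline.

    The outline is projected into the patch's parametric domain (via
    closest-point on the tessellation), triangles with parametric centroid
    inside are kept, and straddling triangles are clipped at the outline.

    Raises
    ------
    GeometryError
        If the projected outline is not a simple polygon, or the fill mesh
        carries no ``uv`` parametrization.
    """
    if "uv" not in fill_mesh.vertex_attributes:
        raise GeometryError("fill mesh has no uv parametrization (use tessellate_patch)")
    uv = np.asarray(fill_mesh.vertex_attributes["uv"])
    frame = fill_mesh.metadata.get("param_frame")
    patch: SurfacePatch | None = fill_mesh.metadata.get("source_patch")
    if frame is not None and "lo" in frame and patch is not None:
        # invert the patch's occlusal (x, y) map at each outline point, so
        # the trimmed footprint matches the outline's transverse trace
        # exactly (projection along the fitting plane's normal would couple
        # height residuals into lateral shifts on tilted frames)
        q = boundary.points - frame["origin"]
        pq = np.column_stack([q @ frame["U"], q @ frame["V"]])
        uv_b = np.clip((pq - frame["lo"]) / frame["span"], 0.0, 1.0)
        target = boundary.points[:, :2]
        for _ in range(4):
            s, su, sv = _patch_with_derivatives(patch, uv_b)
            r = target - s[:, :2]
            a, b = su[:, 0], sv[:, 0]
            c, d = su[:, 1], sv[:, 1]
            det = a * d - b * c
            det = np.where(np.abs(det) < 1e-12, 1e-12, det)
            du = (d * r[:, 0] - b * r[:, 1]) / det
            dv = (a * r[:, 1] - c * r[:, 0]) / det
            uv_b = np.column_stack([uv_b[:, 0] + du, uv_b[:, 1] + dv])
    else:
        closest, _, tri_id = trimesh.proximity.closest_point_naive(fill_mesh, boundary.points)
        bary = trimesh.triangles.points_to_barycentric(fill_mesh.triangles[tri_id], closest)
        uv_b = np.einsum("nk,nkj->nj", bary, uv[fill_mesh.faces[tri_id]])
    poly = Polygon(uv_b)
    if not poly.is_valid:
        poly = _largest_polygon(make_valid(poly))
        if poly.is_empty:
            raise GeometryError("projected outline is not a simple polygon")
    poly = Polygon(poly.exterior)  # outline has no holes

    import shapely as _shp

    faces = fill_mesh.faces
    tri_uv = uv[faces]  # (nf, 3, 2)
    vert_inside = _shp.contains_xy(poly, uv[:, 0], uv[:, 1])
    n_in = vert_inside[faces].sum(axis=1)
    # the outline ring can cross a triangle regardless of where its vertices
    # lie (non-convex outline, or a polygon corner poking into a face), so
    # every face whose bbox meets the ring goes through exact clipping
    ring = poly.exterior
    tmin = tri_uv.min(axis=1)
    tmax = tri_uv.max(axis=1)
    boxes = _shp.box(tmin[:, 0], tmin[:, 1], tmax[:, 0], tmax[:, 1])
    ring_hits = _shp.intersects(boxes, ring)
    keep_whole = (n_in == 3) & ~ring_hits
    clip_faces = np.flatnonzero(ring_hits | ((n_in > 0) & (n_in < 3)))

    parts: list[trimesh.Trimesh] = []
    if keep_whole.any():
        parts.append(fill_mesh.submesh([np.flatnonzero(keep_whole)], append=True))
    verts3 = fill_mesh.vertices
    new_tris: list[np.ndarray] = []
    for fi in clip_faces:
        tri2 = tri_uv[fi]
        tri_poly = Polygon(tri2)
        if not tri_poly.is_valid or tri_poly.area == 0:
            continue
        pieces = tri_poly.intersection(poly)
        if pieces.is_empty:
            continue
        geoms = pieces.geoms if hasattr(pieces, "geoms") else [pieces]
        # barycentric mapping uv -> 3d within this (non-degenerate) face
        T = np.column_stack([tri2[1] - tri2[0], tri2[2] - tri2[0]])
        try:
            Tinv = np.linalg.inv(T)
        except np.linalg.LinAlgError:
            continue
        V = verts3[faces[fi]]
        for g in geoms:
            if g.geom_type != "Polygon" or g.area < 1e-14:
                continue
            coords = np.asarray(g.exterior.coords)[:-1]
            tris = _triangulate_simple_polygon(coords)
            if not tris:
                continue
            lam = (coords - tri2[0]) @ Tinv.T  # (m, 2) barycentric (b, c)
            p3 = V[0] + lam @ np.vstack([V[1] - V[0], V[2] - V[0]])
            for (i0, i1, i2) in tris:
                new_tris.append(np.vstack([p3[i0], p3[i1], p3[i2]]))
    if new_tris:
        flat = np.concatenate(new_tris)
        parts.append(
            trimesh.Trimesh(
                vertices=flat,
                faces=np.arange(len(flat)).reshape(-1, 3),
                process=False,
            )
        )
    if not parts:
        raise EmptyResultError("outline retains no part of the fill surface")
    out = trimesh.util.concatenate(parts)
    out.update_faces(out.nondegenerate_faces())
    out.remove_unreferenced_vertices()
    return out


def fill_defect(
    palate_mesh: trimesh.Trimesh,
    boundary: BoundaryLoop,
    hole_loop: BoundaryLoop | None = None,
    support_band_mm: float = 3.0,
    degree: int = 3,
    control_grid: tuple[int, int] = (8, 8),
    rms_tol: float = 0.2,
    max_iter: int = 50,
    samples_per_direction: int = 64,
) -> FillResult:
    """Fit, tessellate, and trim a fill patch for one defect.

    ``boundary`` is the defect outline (reported cleft area is the area of
    the patch trimmed to it).  ``hole_loop``, when given, is the residual
    oral sheet's hole boundary; the patch trimmed to it completes the
    virtually repaired palate for total-area accounting.
    """
    patch = fit_fill_patch(
        palate_mesh,
        boundary,
        support_band_mm=support_band_mm,
        degree=degree,
        control_grid=control_grid,
        rms_tol=rms_tol,
        max_iter=max_iter,
    )
    tess = tessellate_patch(patch, samples_per_direction)
    fill = trim_to_outline(tess, boundary)
    repair = trim_to_outline(tess, hole_loop) if hole_loop is not None else None
    return FillResult(
        patch=patch,
        fill_mesh=fill,
        rms_fit=float(patch.frame["rms_fit"]),
        iterations=int(patch.frame["iterations"]),
        repair_mesh=repair,
    )
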