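# Methods

This note records the models, numerical choices, and limitations behind
`palatometry`. It is written for someone who wants to trust (or challenge)
the numbers the pipeline produces.

## Coordinate contract

Volumes are arrays indexed `(z, y, x)` with per-axis spacing and origin in
millimetres; the world position of voxel `(i, j, k)` is
`origin + (i, j, k)·spacing`. All meshes live in world millimetres with
conventional `(x, y, z)` vertex order. The dorsal direction is +z and the
rostro-caudal (long) axis +y; both are configuration parameters of the
pipeline, not assumptions baked into the geometry code. One fixed
convention end to end prevents the classic area-scaling bugs with
anisotropic voxels. DICOM is deliberately out of scope; NRRD and NIfTI-1
cover the interchange needs, and only axis-aligned NIfTI affines are
accepted.

## Display windowing

`window_transform` is the standard clamped linear ramp: `level − width/2`
maps to 0, `level + width/2` to 1. The bundled presets are the bone window
(level 300 HU, width 1500 HU) and soft-tissue window (level 40 HU, width
350 HU) used when reviewing neonatal head CT. Windowing feeds QC images
only; all measurements run on raw HU.

## Segmentation and surface placement

Bone is `HU ≥ 140` (inclusive, so the boundary case is deterministic).
The threshold suits neonatal bone, which is less mineralised than adult
bone; the main bony component is kept (26-connectivity by default — thin
plates fragment under 6-connectivity at coarse spacing).

Surface extraction does **not** run marching cubes directly on the HU
field at 140. Around a hard threshold the data is effectively two-valued
(bone ≈ +700 HU against soft tissue ≈ +40 or air ≈ −1000), and linear
interpolation then places the 140-crossing at a fixed fraction between
voxel centres that depends on the neighbouring tissue value — a
systematic sub-voxel bias (measured +7.8% on the area of a 10 mm sphere at
0.5 mm voxels). Instead the default path binarises at the threshold,
smooths the indicator with a Gaussian (σ = 1 voxel), and extracts the 0.5
level: under uniform sub-voxel placement of the true interface this
estimate is mean-unbiased (sphere area error −0.2%), and it is what
clinical model-making pipelines effectively do. Two consequences are
documented rather than hidden:

- sharp edges are rounded over ≈ σ voxels (wrong for a cube, right for
  anatomy); sharp-edged solids should use `smooth_sigma_vox=0`;
- features thinner than about two voxels (sub-voxel suture slits) are
  bridged by the smoothing — which here is a feature, not a bug.

A `grayscale` path (smooth HU, extract at the threshold) remains available
for genuinely graded data.

## Defect outlines

The palate mesh has two sheets (oral and nasal) joined through cleft
walls. All areas are measured on the **oral (ventral) sheet**: faces whose
outward normal has `n·dorsal < −0.85` (slopes up to ≈ 32°, comfortably
above the ≈ 22° maximum slope of the modelled palate vault), largest
connected component. The stricter-than-hemisphere cut matters: marching
cubes rounds the material corner where the oral surface turns into a cleft
wall, and the steep "skirt" of that rounding would otherwise both dilate
hole outlines and inflate the residual sheet area (a 3.1% conservation
error at 1.0 mm spacing shrinks to 0.3% with the 32° cut).

Defect outlines are read at **mid-wall**: the face set with *any* ventral
normal component extends halfway down each vertical cleft wall, where the
smoothed-indicator 0.5 level estimates the wall position without corner
bias (hole areas within ≈ 1–2% at 0.5 mm voxels). Each outline is then
draped onto the oral sheet by local plane fits, giving a closed loop lying
on the palate surface. Gaps whose minimum transverse width (shorter side
of the minimum rotated bounding rectangle of the occlusal projection)
falls below `min_gap_mm` are excluded as unfused sutures. The default is
1.5 mm: a sub-voxel suture can appear up to one voxel wider in sampled
data (≈ 1.0 mm at 0.5 mm spacing), while the narrowest clinically reported
cleft fissure is 2.1 mm, so 1.5 mm separates the two populations with
margin on both sides. Only interior holes (including holes created by ROI
cropping) are supported; a marginal notch that remains open after cropping
is not detected — choose the crop box so the defect is enclosed.

## Spline filling

The interactive knot-editing workflow this automates ("adjust until the
fill matches the palate") is replaced by a deterministic penalized
least-squares fit. The patch is a tensor-product B-spline (the
unit-weight special case of NURBS; degree 3, 8×8 control net, clamped
uniform knots by default) parameterized over the best-fit plane of the
defect boundary plus a support band (palate vertices within 3 mm of the
loop). In-plane control coordinates sit at Greville abscissae, so the
patch's planar part is exactly affine and only the height field is fitted.

Objective: weighted least squares on boundary points (weight 2) and band
points (weight 1), plus a thin-plate (bending) penalty integrated over the
parameter square. Two numerical choices matter:

- **The penalty is projected to be blind to quadratic height fields.**
  Quadrics lie in the cubic spline space; removing them from the penalty's
  range means the fill continues the local quadric of the palate vault
  *exactly* (plane and quadratic test sheets reproduce to < 1e-6 mm at any
  smoothing strength), while the penalty still damps the voxel-scale
  ripple of marching-cubes data and extends the surface smoothly across
  the data-free defect interior.
- **The boundary is fitted, not interpolated.** The detected outline
  carries ± half-voxel staircase jitter; hard interpolation imprints that
  jitter as surface ripple and inflated area by ≈ 1% in testing. The fit
  must stay within `rms_tol` (0.2 mm default) of the boundary, which the
  weight-2 fit achieves (typical RMS ≈ 0.1 mm).

After each solve, sample parameters are updated by closest-point
projection (two Gauss–Newton steps per sample) and the system re-solved,
until the RMS residual improves by < 1% or `max_iter` (50). The fit is
fully deterministic. Failure modes are explicit: fewer support samples
than control points raises `InsufficientSupportError`; a final RMS above
`5 × rms_tol` raises `FitFailureError`.

## Trimming and area accounting

The tessellated patch (64×64 parametric grid; doubling changes phantom
areas by < 0.5%) is trimmed to an outline by classifying triangles in
parameter space and clipping straddlers exactly (shapely intersection +
ear clipping). The outline enters parameter space by inverting the
patch's occlusal `(x, y)` map with Newton iterations — closest-point or
plane projection would couple height residuals into systematic lateral
boundary shifts on tilted fitting frames (≈ +1% area on an off-midline
2 mm cleft).

Each defect patch is trimmed twice:

- to the **defect outline** → the reported cleft area;
- to the **residual sheet's hole loop** (which is chamfer-dilated) → the
  piece that completes the *virtually repaired* palate.

Total palate area = residual oral sheet + hole-completing fills. This
definition keeps the percentage well defined for arbitrarily wide clefts
and satisfies conservation: on phantoms, the intact twin's measured sheet
area matches residual + fill within 0.5% at 0.5 mm spacing. Whether a
"total palate area" should include the filled defect is genuinely
ambiguous; the repaired-palate definition is this package's choice and is
applied consistently.

Percentages are rounded half away from zero to an integer — the
convention that reproduces all ten published (total, cleft) → percentage
rows exactly (e.g. 79/142 = 55.6% → 56%). Cleft length is the extent
along the configured rostro-caudal axis; widths are diameters of
transverse cross-sections sampled along that axis, excluding the extreme
5% at each end (a closed outline necessarily tapers to zero width at its
ends, so end stations reflect corner geometry, not the fissure).

## Classification codes

The four-region numerical code (upper lip, primary palate, hard palate,
soft palate; right/left pairs or a single midline grade; grades 0–3) is a
plain codec: canonical output uses hyphens, the parser also accepts
en-dashes because typeset tables mix both. Severity grading from images
is deliberately **not** automated — grades are clinical input.

## Synthetic phantoms and what they do (not) show

The phantom is a parabolic-cylinder shell `z = a·x²` (default
a = 0.02 mm⁻¹, |x| ≤ 11 mm, y ∈ [0, 24] mm, thickness 2 mm — a
neonatal-dog-scale palate of ≈ 450 mm² with non-trivial, analytically
integrable curvature), voxelized by a voxel-centre membership test on a
cell-centred grid, with bone +700 HU, a 2 mm soft-tissue envelope at
+40 HU, air −1000 HU, and optional Gaussian noise. Cleft gaps are simple
polygons cut through the full thickness; suture slits are thin line
segments. Ground truth comes from quadrature of the first fundamental
form, refined until successive refinements agree to 1e-6 (and checked
against the closed-form antiderivative). The cell-centred grid means
geometry placed on cell faces is sampled generically; aligning polygon
edges exactly with voxel centres is a degenerate knife-edge case that
widens features by a full voxel.

The standard suite spans flat and curved shells, cleft widths 2/5/10 mm
(bracketing the clinically reported 2.1–9.6 mm), unilateral, midline and
bilateral outlines, a tapering 2→8 mm trapezoid, an intact control with
suture slits, spacings 0.5 and 1.0 mm, and a 30 HU-noise member. At
0.5 mm spacing the pipeline recovers every cleft area within ≈ 2% and
every percentage exactly; problem sizes (≈ 25×64×60 voxel volumes, the
whole suite plus intact twins in seconds on one CPU) were chosen to keep
the validation suite quick while staying at the scanner's reported slice
thickness.

What the phantoms do **not** emulate: partial-volume attenuation (voxel
membership is binary; resolution effects are probed via the spacing sweep
instead), scanner physics (beam hardening, reconstruction kernels),
realistic skull anatomy, or soft-tissue cleft margins. Passing the suite
therefore shows the *geometry pipeline* is unbiased at clinical voxel
sizes — not that 140 HU is the right threshold for any particular
scanner, nor that real palate surfaces are quadrics (the spline fit only
assumes smoothness; the quadric blindness is about what the penalty
ignores, not what the data must be).

## Known limitations

- At 1.0 mm spacing on a 2 mm shell the hole outline dilates by about one
  voxel per side (≈ +34% area on a 6 mm cleft): below roughly four voxels
  across a defect, the method is resolution-limited. Conservation still
  holds (0.3%), because dilation moves area between residual and fill
  rather than creating it.
- Marginal notches (defects open to the mesh border after cropping) are
  not detected.
- The indicator-smoothing surface rounds sharp edges; it is the right
  default for anatomy, the wrong one for CAD-like solids.
- Absolute areas from real scanners additionally depend on reconstruction
  kernel and threshold choice, which no phantom here calibrates.
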