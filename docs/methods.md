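# Methods

## Distortion model

The displacement of imaged content at a point `p = (x, y, z)` (mm, phantom
frame, origin at the phantom's diamond marker aligned to the isocenter) is

```
d(p) = d_gnl(p) + dB0(p) / BW * pixel_size * ê_freq
```

* `d_gnl` models gradient nonlinearity as one polynomial per output axis in
  monomials `x^i y^j z^k` (total degree ≤ 5). The constant term must be
  zero: distortion vanishes at the isocenter, which is also what justifies
  translation-only centre registration downstream.
* `dB0` is an off-resonance polynomial in Hz; its displacement acts along
  the frequency-encode axis only and scales with `pixel_size / BW_pixel`.
  Halving the pixel bandwidth exactly doubles this component.

`radial_model(max_gnl_mm, ...)` is the stock field: in-plane displacement
pointing radially outward with magnitude
`max * (0.7 u³ + 0.3 u⁵)`, `u = r / 170 mm`, which is the odd degree-3/5
polynomial `a3·v·r² + a5·v·r⁴` per axis (`v ∈ {x, y}`). The 170 mm
reference radius is the edge of the control-point lattice; default peak
magnitudes of 1, 1.5 and 3 mm bracket the range observed across 1.5 T and
3 T systems. Optional terms add a quadratic B0 map (`b0_max_hz · u²`) and a
through-plane component `dz_max · (z / 110 mm) · u²`. No scanner's real GNL
harmonics or B0 map are emulated — the fields are illustrative, chosen only
to have the right structure (smooth, zero at isocenter, growing outward).

## Phantom geometry and the 822-cell calibration

The phantom is a 400 mm disc, 220 mm thick, with 10 mm grid cells, 2 mm
resin walls, a flat stability cut on the 180° (−y) side and a solid diamond
marker (7 mm half-width) at the centre. A cell is *complete* when its full
extent lies inside the circle of `grid_inner_radius_mm` clipped by the cut;
the lattice nodes are the corners of complete cells.

`grid_inner_radius_mm = 175` and `cut_chord_offset_mm = 125` are calibrated
constants, found once by exhaustive enumeration, such that the default
build yields exactly 822 complete cells while the 15 cm / 180° grid
crossing falls cleanly outside the lattice (the cut removes it — which is
why the mark-point set realizes 11 of the 12 requested positions). The
enumeration also admits a 170 mm radius with the cut chord exactly at
−150 mm, but that leaves the 15 cm / 180° crossing sitting on the boundary;
the 175/125 solution was preferred as geometrically unambiguous. Wall
thickness and diamond size are rendering parameters only; node positions
depend on neither.

## Renderer

Volumes are rasterized analytically: each voxel is supersampled 3×3 in
plane and block-averaged (anti-aliasing), with voxel centres at
`pixel_size · (index − (matrix−1)/2)` — the isocenter lies on the central
voxel for odd matrices and between voxels for even ones. Slices are centred
on the phantom mid-plane, ordered foot → head. The Unity 3D acquisition is
emulated as 1.6 mm contiguous partitions; default slice counts (120/30/60)
are multiples of 30 to satisfy the layer-selection rule.

The reference (CT-role) volume is undistorted and noiseless, walls bright
over dark water. The MR-role volume inverts the contrast (T2-like: water
bright) and applies the distortion as an **inverse warp**: each image
position is pulled back through `p ↦ p + d(p)` by fixed-point iteration
(4 iterations, convergent for the |∇d| ≪ 1 fields used here), and the
analytic geometry is evaluated at the pre-image — so ground truth stays
exact at node positions instead of being resampled from a rasterized image.
The pre-image offset field, being as smooth as the polynomial field itself,
is solved on the pixel grid and bilinearly refined to the supersampled
grid (error ≪ 1 µm). A warning is raised when the peak displacement inside
the lattice exceeds half the cell pitch, where node assignment becomes
ambiguous. Noise is Rician — magnitude of the signal plus complex Gaussian
noise with `σ = water_intensity / SNR` — seeded by the model's seed; fixed
seeds reproduce volumes bit-for-bit.

## Control-point detection

Grid crossings are found by normalized cross-correlation with a cross
template (arm half-length = half a cell, arm width = wall thickness),
rendered with the same anti-aliasing as the images. The *absolute*
correlation is used, which makes the detector insensitive to the CT/T2
contrast inversion (within the grid, the two contrasts are affine-related,
so the response surfaces coincide up to sign — systematic detector biases
then largely cancel in the reference–test difference). Peaks pass
non-maximum suppression within 0.45 of a cell pitch and a 0.25 response
threshold, then are refined to sub-pixel: a 7×7 response patch is upsampled
(cubic, default factor 4) and a separable quadratic is fitted around the
maximum. Factor 4 was chosen because higher factors (an upsample of 32 is
accepted for fidelity runs) add cost without measurable accuracy gain
beyond the quadratic fit. Crossings whose template window leaves the image
are skipped.

The centre diamond is located the same way with a diamond template
(threshold 0.45; failure raises `CenterNotFoundError`). Because the solid
diamond hides the (0,0) crossing, the marker position substitutes for that
node. Matching translates detected points so the centre maps to (0, 0) —
translation-only registration, no rotation/scale — then pairs each lattice
node with the nearest detected point within a 5 mm gate (half a cell, the
largest unambiguous radius), one-to-one, greedily by ascending distance.
Unmatched nodes are excluded from all summaries (never imputed) and
counted in the logs.

Measured on noiseless synthetic data (512² presets), node positions are
recovered to < 0.2 mm within 15 cm of the centre; the outermost ring, whose
cross arms are clipped by the lattice rim, can reach ~0.8 mm of individual
bias, but reference–test cancellation keeps its effect on distortion
statistics an order of magnitude smaller.

## Distortion statistics

* Plane distortion: `sqrt((x1−x)² + (y1−y)²)` between the reference-image
  and test-image coordinates of a node after centre registration.
* Radial summaries are **cumulative discs** (all nodes within r, binned by
  the reference distance), not annuli, so the largest-radius row equals the
  whole-set mean ± SD identically. SDs are sample SDs (ddof = 1).
* `fraction_below` uses a strict `<` at the 2 mm default threshold;
  histogram bins are half-open `[k·bin, (k+1)·bin)`.
* Mark points sit at radii {50, 100, 150} mm × angles {0, 90, 180, 270}°
  measured clockwise from +y (`(x, y) = (r sin θ, r cos θ)`), minus the
  15 cm / 180° position lost to the cut: 11 realized points.
* Layer selection: the slice stack (a multiple of 30) is split into 30
  equal groups; the foot-most slice of the first group and the head-most
  slice of every other group are selected.
* The 3D change of a mark point between consecutive selected layers is
  `sqrt(Δx² + Δy² + Δz²)` with Δz the slice-position difference, so a
  geometrically perfect scan yields exactly the selected-layer spacing.
  This convention is deliberate (the alternative — zeroing the z-term and
  reporting pure in-plane drift — is available as `z_mode="planar"`); both
  modes are provided because reported 3D tables can follow either reading.
  Per-radius "average" rows pool the layer pairs of all angles at that
  radius.

## Dose impact

The module isolates the *geometric* component of distortion's dose effect;
IMRT optimization, electron-return-effect physics and electron-density
assignment are out of scope, and any externally computed dose grid on the
image geometry can be supplied. The default synthetic grid is a rotationally
symmetric 50 Gy plateau (target radius 190 mm) with a sigmoidal penumbra
(15 mm).

ROIs follow the standard layout: a 2×2 cm centre square plus 1×1 cm squares
at 5, 10, 15 and 17 cm at the mark-point angles, dropping positions lost to
the cut (4, 4, 3, 2 → 14 squares), plus a whole-phantom region. The angular
placement at 17 cm (0° and 90°) is an assumption; only the counts are
constrained. Mean dose is computed by midpoint quadrature of the bilinearly
interpolated grid over the ROI — exact for linear dose fields, which makes
the rigid-shift-on-a-ramp oracle (`rate = 100·g·s/D`) exact rather than
approximate, unlike voxel-overlap weighting of voxel-centre values. The
change rate displaces every quadrature point by the field before the
lookup, so square ROIs and the whole-phantom region are treated
identically, and the rate is invariant to rescaling the dose grid.

## Pipeline and reproducibility

A `RunConfig` fully determines a run; its SHA-256 hash and seed are embedded
in every bundle, and re-running a config reproduces the CSV/JSON outputs
byte-for-byte. Plane statistics use the central transverse slice of each
volume (the reference coordinates come from detection on the CT-role image,
not from the ideal lattice, mirroring how real scans are analyzed); 3D
tracking detects the selected layers only. The QA gate compares the
below-2-mm fraction against a configurable threshold (default 0.95) and is
reflected in the CLI exit status.

## Problem sizes and what the tests show

Tests and the acceptance script run single-slice plane analyses at the 512²
presets (one Unity 1008² null case), 30-slice stacks for layer tracking,
and 3–5 noise seeds per condition; these sizes make the full suite run in a
few minutes while leaving recovery errors (≤ ~0.03 mm against ground truth)
far below the acceptance margins. Passing recovery tests demonstrates that
the detection-and-statistics chain measures a known smooth field correctly
in the presence of Rician noise and contrast inversion. They do not
demonstrate performance on real scanners: the simulator omits susceptibility
effects at resin–water interfaces, sequence physics, coil profiles,
phantom-setup rotation and vendor distortion corrections, and its GNL/B0
fields are stylized rather than calibrated to any machine.

## Known limitations

* Translation-only registration; a rotated phantom setup is not corrected.
* Edge crossings clipped by the lattice rim carry individual detection
  bias (~0.5 px worst case) that only partially cancels.
* Whole-phantom dose sampling uses a 2 mm point grid rather than exact
  voxel-overlap integration.
* The DICOM writer emits a minimal single-frame MR series (geometry tags
  only), sufficient for round-tripping through this package.
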