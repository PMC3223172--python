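# Methods

Conventions, parameter defaults and numerical choices for `ctus_fusion`.

## Coordinate and transform conventions

- All transforms are **rigid** (rotation + translation), stored as z-y-x
  fixed-axes Euler angles in radians plus a translation in mm
  (`geometry.RigidTransform`). Column-vector convention: the composite
  rotation is `R = Rx(α) @ Ry(β) @ Rz(γ)` applied as `R @ x`.
- Angle extraction handles the gimbal-lock case |β| = π/2 by setting α = 0
  and folding the remaining rotation into γ. `from_matrix`
  re-orthonormalises via SVD and rejects reflections (det < 0).
- An ultrasound pixel (row, col) with pixel size (s_row, s_col) mm maps to
  the in-plane point (col·s_col, row·s_row, 0) — x along the beam-line
  (column) direction, y along depth (row), z normal to the image plane.
- Volumes are axis-aligned: world position = origin + index · spacing,
  with arrays indexed (x, y, z).

## Probe calibration (single fixed point)

Minimises Σᵢ ‖T_A · T_pose,i · T_cal · xᵢ‖² over the 6 parameters of
`T_cal` and the 3 translation parameters of `T_A` (the transform placing
the cross-wire at the tracker origin). The rotation of `T_A` is pinned to
identity: a rotation about a single point is unobservable from that point
alone, so fixing it removes the gauge freedom without restricting the
solution. The solver is `scipy.optimize.least_squares(method="lm")` with
multi-start (identity plus the eight axis-aligned rotations) and a
centroid-based initial wire offset. A `condition_flag` is raised when the
per-axis span of sensor orientations is below 10°, the regime in which the
out-of-plane component of `T_cal` becomes poorly conditioned. Residuals
are distances of each reconstructed wire position from their implied
origin, in mm; `mean_residual` is their mean.

## Registration

Horn's closed-form absolute orientation: build the 4×4 quaternion matrix
from the cross-covariance of centred point sets and take the eigenvector
of the largest eigenvalue. Degenerate (collinear or coincident) fiducial
sets are detected by the second singular value of the centred coordinates
falling below 1e−9 and rejected. FRE is the per-fiducial residual
distance; TRE evaluates held-out target points.

## Temporal synchronisation

The bath-floor distance is extracted per frame as the first bright row
below the transducer face in the centre column. The lag between the
image-derived and sensor-derived distance streams maximises a globally
normalised cross-correlation: the overlap dot product divided by the
product of the **full-signal** norms. Normalising globally (rather than
per-overlap Pearson) penalises short overlaps and suppresses the spurious
period-multiple peaks a periodic signal otherwise produces; ties resolve
toward the smaller |lag|. The Pearson correlation of the overlapping
segments at the chosen lag is reported alongside. Sign convention:
positive lag means the image stream trails the sensor stream, i.e.
`image[n] ≈ sensor[n − lag]`. At least 16 overlapping samples are
required; shorter overlaps raise `UndefinedLagError`.

## HU segmentation

Fixed windows, boundaries inclusive as stated: background < −300 HU,
fat −300..0, protein-rich 1..300, bone 301..3000; values above 3000 clamp
to bone. Implemented with `np.searchsorted` on edges (−300, 0.5, 300.5),
side="right", so integer HU land in the stated classes and fractional HU
split at the midpoints. An optional per-slice median prefilter
(`median_radius`, scikit-image disk footprint) removes impulsive
artefacts; radius 1 removes single-voxel impulses without eroding class
boundaries, larger radii trade boundary fidelity for smoothing.

## Quantitation

- Percent fat of a slice: 100 · A_fat / (A_fat + A_tumour). Undefined
  (raises) when both areas are zero.
- Tumour-size groups by volume (mm³): small [0, 75), medium [75, 150],
  large (150, ∞). Group sd is the sample standard deviation (ddof = 1),
  undefined and flagged for n = 1.
- Regressions are ordinary least squares (`scipy.stats.linregress`);
  r² is the squared correlation coefficient.
- Two-sample t-test is pooled-variance (`equal_var=True`); ANOVA is
  one-way (`scipy.stats.f_oneway`).
- Ellipsoid volume from two radii (prolate, a·b²): (4/3)π·a·b².
- The bundled reference table (`data/area_measurements.csv`) holds 12
  tumours with CT and histology areas; its printed percent columns are
  reproducible from the area columns to ±0.2 (rounding of the inputs).
  The group standard deviations mix rounding conventions: recomputing
  percentages at full precision reproduces 11 of the 12 printed
  mean/sd values, as does using the printed percent columns, but the two
  disagree by one rounding unit on one large-group sd each.

## Synthetic phantoms

All generators are seeded (`numpy.random.default_rng`) and deterministic.

- **Cross-wire**: samples probe orientations, picks a random image pixel,
  and solves the sensor translation so the wire constraint holds exactly
  before adding isotropic Gaussian pose/pixel noise. Default wire point
  (120, −40, 200) mm, pixel size 0.1 mm.
- **Fiducials**: random CT-space points mapped through the true transform
  plus Gaussian noise on the tracked side.
- **Mouse phantom**: air background at −1000 HU with a 2 mm fat slab
  (−120 HU; murine fat-pad range 1–3 mm), a 1.5 mm-radius bone cylinder
  (1000 HU) beneath it, and a 3 × 2.5 × 0.9 mm tumour ellipsoid (68 HU)
  embedded mid-slab; additive Gaussian HU noise, σ = 30 by default;
  0.3 mm isotropic spacing. Primitives paint in order and are clipped at
  the grid, so measured volumes match analytic ones only to within the
  voxelisation of their boundaries.
- **Grid phantom**: 5 × 10 discs at 8 mm pitch in a thin slab, with exact
  centre coordinates returned — used for TRE evaluation (micro-CT-like
  spacing down to 0.0489 mm is supported by the IO layer).
- **Bath floor**: sinusoidal floor distance (baseline 15 mm) rendered
  into frames at 0.1 mm/px and emitted as image and sensor streams with
  an injected integer lag.
- `simulate_fusion_tre` runs the full chain — calibrate from 93 noisy
  observations, register from 12 noisy fiducials, image the 50-target
  grid with a noisy pose — at a common tracking noise (default
  σ = 0.5 mm, which lands the composed TRE in the ~1 mm regime).

These phantoms exercise the geometry and statistics end-to-end; they do
not emulate ultrasound physics (speckle, attenuation, refraction), CT
reconstruction artefacts, tissue deformation, or respiratory motion.

## Fusion and resampling

CT slices along the ultrasound plane are resampled with
`scipy.ndimage.map_coordinates`: trilinear (order 1, fill −1000 HU) for
HU volumes, nearest-neighbour (order 0, fill background) for label maps.
Overlays blend per-class RGB (fat yellow, protein-rich pink, bone white,
background transparent) with `out = round(α·color + (1−α)·gray)`; α = 0
is bit-exact to the input frame.

## CLI and IO

NIfTI via nibabel (float32 HU, uint8 labels; spacing in the affine), PNG
via Pillow (mode L frames, RGB overlays), CSV logs with explicit headers.
Exit codes: 0 success, 2 validation/data errors, 64 usage errors.
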