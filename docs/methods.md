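# Methods

This note documents the models, numerical choices and known limitations of
`mosaictomo`, in the package's own terms.  Empirical statements below are
the ones the test suite and `scripts/acceptance.py` actually compute.

## Acquisition model

**Mosaic geometry.** A wide-field (half-acquisition) scan validly
reconstructs a circle whose diameter is set by the detector width and the
axis offset; only the inscribed square (side = diameter/√2) is carried into
the mosaic, and mosaic steps are square side (or tile height) minus the
configured overlap.  The scan order is a serpentine over the horizontal
grid with the vertical axis fastest and zigzagged, so every motion is a
single-axis step to an adjacent unmeasured tile.  The timing model charges
each scan a fixed wall time and each motion `distance/speed + overhead`;
measured per-move averages can override the speed model when available
(beamline logs often report averages that fold in effects the linear model
does not capture).

**Projector.** Parallel-beam line integrals are computed by rotating the
volume about the axis (bilinear resampling, (y,x) plane zero-padded to its
diagonal so no mass leaves the grid) and summing columns.  The detector row
grid coincides with the volume's z slices; units are optical depth
(attenuation in 1/m times path in m).  Mass is conserved to <0.5% per view.

**Contrast and illumination.** Contact intensity `exp(-OD)` is multiplied
in Fourier space by the single-material transfer `1 + (zδ/μ)|k|²` — the
exact inverse of the Paganin retrieval filter, sharing one frequency-
convention helper, so a noiseless forward + retrieval round trip is exact
to machine precision.  Two refinements keep the quadratic transfer
physical:

* the projected optical depth is band-limited with a Gaussian of σ = 1 px
  ("source blur", standing for finite source size and scintillator
  response) — voxel-sharp edges would otherwise drive the transfer to
  negative intensities;
* the transfer is applied with reflective padding (same rule as the
  retrieval), since FFT wrap-around at frame borders is likewise amplified
  by |k|².

The flat field is a smooth beam profile plus K drift components with
pronounced column structure (the mode that becomes rings downstream),
whose coefficients follow a stationary AR(1) process (σ = 5% of the mean
counts for the leading component, lag-one correlation 0.95).  Detector
counts get Poisson noise (5000 counts/pixel mean flat) plus Gaussian read
and dark noise; 50 darks and 300 flats are recorded once per mosaic.

**Phantom.** A cylindrical tissue body holds a foam "lung": overlapping
air spheres (radii 1.5–3 wall thicknesses) carved until the target air
fraction of the lung region is reached, a vertical trachea channel to the
top face (so connectivity-based segmentation has a physical seed), and a
few high-attenuation bone rods at 5× tissue.  Ground truth (air mask,
volume = mask count × voxel volume) is recorded at generation time;
the realized air fraction lands within ±5% (relative) of the target
because each sphere adds well under 1% of the region.  Because a
0.3 mm phantom at real soft-tissue attenuation (~60/m at 21 keV) would be
nearly transparent, the pipeline scales tissue attenuation so the body
diameter has a beamline-like optical depth (default 0.6); the filter
strength zδ/μ is unaffected since it depends only on δ/β and λ.

**Deformation.** A fixed, seeded, smooth unit-RMS random vector field
(control-point noise upsampled to the grid) scaled by `t × rate`, so the
displacement is zero at t = 0 and grows linearly; per tile it is evaluated
at the tile's predicted start time.  The desk-scale deformed condition
(0.03 vox/s over a ~90 s mosaic) accumulates a few voxels of mismatch
between the first and last tile — smooth and slow, matching the regime a
non-rigid stitcher is designed for; strongly nonlinear events (e.g. sudden
inflation of a collapsed region) are not modelled and would not be
correctable.

## Processing

**Dynamic flat-fielding.** Eigen-flats come from an SVD of the
dark-subtracted flat stack (frame-space Gram matrix; K = 5 by default).
Per projection, drift weights are fitted on sample-free wide-side margin
columns.  The fit is least squares with an empirical-Bayes ridge: the
pixel-noise variance is estimated from the plain fit's residual and the
prior weight variances are the PCA eigenvalues.  Plain margin-restricted
least squares amplifies Poisson noise into the weights whenever a
component has weak support in the margins; the ridge suppresses exactly
those directions while leaving noiseless (planted-weight) problems exact.
The margins must be genuinely sample-free *and* clear of the edge-
enhancement ringing, whose spatial tail length is √(zδ/μ) ≈ 7 px at the
default optics; the simulator therefore leaves ~24 columns of air beyond
the scanned core and fits on the outer 12.

**Paganin retrieval.** Angular frequency convention (rad/m); reflective
edge padding of width `max(64, 2√(zδ/μ)/pixel)`; non-positive pixels are
floored at 10⁻⁶ with a warning.  Both the thickness map T and the
dimensionless μT are returned; downstream stages consume μT.

**Reconstruction.** FBP with the exact real-space Ram-Lak kernel
(transform length forced even — odd lengths corrupt the DC term —,
optional Shepp-Logan apodization), trapezoidal angular weights for
non-uniform angle lists (with the wrap gap capped so limited-angle lists
are not misweighted), and linear detector interpolation about a sub-pixel
centre.  This is a deliberate replacement for Fourier-regridding
implementations: the claims being tested are geometric, and direct FBP is
an accepted equivalent at this scale.  For extended-FOV scans each
half-projection is completed across the rotation centre with its mirrored
complementary view *for filtering only* (the ramp filter is nonlocal and
needs the full object support), then only the view's own samples are
backprojected at the view's own angle; the default handling cuts at the
centre with a 1 px feather (an angular-weighting mode is available).  The
complementary-pair offset ε (default 0.04565°) is part of the angle model;
ignoring it measurably degrades reconstructions once structure sits at
radii of a hundred-plus pixels (displacement ≈ ε·r).

**Rotation-centre search.** Candidate centres are scored by the slice's
total negative mass: attenuation is nonnegative, and a mis-placed axis
produces arc artifacts with strong negative undershoot.  Histogram-entropy
sharpness is also implemented but is *not* the default: in planted-centre
validation on foam phantoms it selects range-edge centres, while the
negativity criterion recovers the planted axis to ≤0.1 px.  Sub-step
refinement is parabolic; flat score curves fall back to the range midpoint
and range-edge maxima are flagged.

**Stitching.** Pair registration: phase correlation of the nominally
aligned overlaps (sub-voxel by Fourier upsampling), NCC of the re-aligned
overlaps as the confidence score.  Local fields: NCC block matching on a
control-point grid placed so block and search window always fit inside
both tiles; peaks must clear an NCC threshold (0.5), a displacement bound,
*and* a prominence margin over the second-best peak (0.02) — near-constant
or self-similar foam blocks otherwise produce spurious matches.  Fields
are cleaned by a 5·MAD rule per component and smoothed by Gaussian-
weighted interpolation (σ = grid spacing).  Because phase correlation
estimates the rigid component more accurately than averaged block matches
(parabolic NCC refinement carries a systematic sub-voxel bias), each
pair's mean shift is removed from the field and only the non-uniform
residual is used as the warp.  Global tile origins minimize
`Σ confidence · |o_b − o_a − offset_ab|²` with the first tile anchored;
fields are then re-referenced to the solved origins (so cycle-closure
residuals do not leak into the warp) and composed with the reference
tile's own accumulated warp, in acquisition order, pulling every tile
toward the earliest tile's frame.  Blending uses per-axis linear ramp
weights falling to zero at tile borders; the std map uses the population
convention over contributing warped values and is zero where fewer than
two tiles contribute; a provenance map records the dominant tile per voxel
(255 = uncovered).

**Segmentation.** Iterative intermeans (Ridler–Calvard) is the
iso-threshold; air is below threshold.  The body cylinder is auto-fitted
to the middle slice's tissue outline (centroid + 99th-percentile radius,
3% shrink).  Connectivity is 26-neighbour, seeded at the top face where
the trachea enters.  The second pass thresholds a Gaussian-unsharp-masked
copy (σ = 2, amount 1) restricted to the mask dilated by **1 voxel**: the
dilation radius must stay below roughly half the septal wall thickness
(~3.5 voxels in the phantom), or the second pass merges the bands from
both sides of a thin wall and punches through it, inflating the volume by
10–20%.  Voxels without valid image data (uncovered mosaic borders) are
excluded like bone, since their fill value would otherwise be read as air.

## Problem sizes and what the tests show

The end-to-end study condition is a 2×1×2 mosaic of 100-voxel-diameter
tiles (48 voxels tall, 24-voxel overlap), 240 projections per scan — small
enough that the full chain runs in ~1.5 minutes, large enough that every
stage operates in its intended regime.  Against the generator's ground
truth, the pipeline recovers the airway volume to ~6% (stable across
seeds; stage-wise segmentation alone is 1–3%), non-rigid stitching lowers
the overlap std-map RMS by 5–20% relative to rigid placement on deformed
mosaics, and dynamic flat-fielding cuts the ring metric several-fold.

What passing these tests does *not* show: the simulator's edge enhancement
is the TIE transfer rather than full Fresnel propagation (no true fringe
structure, and negative-intensity clipping replaces the physical
nonnegativity of |field|²); each tile scans a cylindrical core cut from
the phantom, so interior-tomography truncation effects present in real
local tomography are absent; detector point-spread, polychromaticity and
scatter are not modelled; and the ~6% volume bias is specific to the
phantom's structure scale (walls near the resolution limit).  Real-data
artifact fractions and absolute airway volumes are therefore not claimed —
only the methods' internal consistency and their measurable benefits under
controlled conditions.

## Degenerate inputs and tie-breaks

Zero-overlap plans are reported (not errors) but steps beyond the tile
extent are; flat score curves return the range midpoint with a warning;
all-invalid displacement fields become identity warps and flag the pair;
disconnected tile graphs anchor each component at its nominal origin;
degenerate (single-valued) slices borrow the nearest valid slice's
threshold; an airway mask with no component at the seed face keeps the
largest component, with a warning.  All randomness flows through named
seeds; two runs with the same config are bit-identical.
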