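# Methods

## Measurement model

A slice image is modelled as three gray populations after luma
conversion: a near-black backdrop, the reddish meat matrix, and bright
whitish fat particles. The pipeline assumes (i) the slice is the
largest bright object in the frame, (ii) fat is strictly brighter than
meat inside the slice, and (iii) a single isotropic scale
`cm_per_pixel` converts pixel counts to areas (`A = N_px · s²`). A
slice is treated as representative of the whole product (the 3-D
problem is reduced to 2-D), so all quantities are per-slice-area.

Per particle *i* the package reports area *AF*ᵢ, perimeter *P*ᵢ and
roundness *RF*ᵢ = *P*ᵢ²/(4π·*AF*ᵢ). Roundness as defined here is the
reciprocal of circularity: exactly 1 for a continuous circle, 4/π for a
square, and unbounded for elongated shapes. Values slightly below 1 can
occur on digitized shapes (a rasterized disk's estimated perimeter can
undershoot the continuous one); this digitization error vanishes as the
particle grows. Visible fat content is VFC = 100·Σ*AF*ᵢ/*A*ₛ, a pure
area ratio and therefore independent of the calibration.

## Segmentation chain and its parameters

All tunables live in `PipelineConfig`; defaults in parentheses.

* **Grayscale**: BT.601 luma, round(0.299 R + 0.587 G + 0.114 B).
* **Contrast stretch** (`contrast_percentiles = (1, 99)`): linear map of
  the 1st/99th histogram percentiles to 0/255 with clipping; robust to a
  few outlier pixels, monotone in gray level. A constant raster is
  passed through unchanged.
* **Median filter** (`filter_window = 3` px): removes salt/pepper noise
  without displacing particle boundaries much; window 1 disables it.
* **Slice extraction**: the gray histogram is typically *tri*modal
  (backdrop/meat/fat), so the backdrop threshold is the lower threshold
  of a three-class Otsu split — a plain two-class Otsu can land between
  meat and fat and would call only the fat "slice". When the histogram
  has too few distinct levels for three classes the code falls back to
  two-class Otsu. The largest 8-connected component is kept and its
  holes filled (fat and voids belong to *A*ₛ).
* **Fat threshold** (`threshold_mode = "automatic"`): two-class Otsu
  computed over slice-interior pixels only; `"fixed"` uses a user gray
  level (pixels ≥ level are fat). In automatic mode the split is
  accepted only if the two classes separate with Ashman's
  D ≥ `bimodality_min_d` (3.0): splitting a unimodal (fat-free, noisy)
  interior yields D ≈ 2.6 regardless of the noise level, while a true
  fat/matrix separation scores far above 3; below the bar the slice is
  reported fat-free rather than halving the noise into spurious blobs.
* **Closing** (`closing_radius = 1`): dilation then erosion with a
  square structuring element of side 2r+1, closing thin dark seams of
  the matrix inside particles; the result is re-intersected with the
  slice so closing cannot leak past the slice outline.
* **Cleanup**: optional hole filling (`fill_holes = True`), removal of
  components under `min_particle_area_px` (4 px — sensor-noise scale,
  far below the smallest reportable 0–0.1 cm² class at any plausible
  calibration), then 8-connected labelling (diagonal touches join).
  Particles on the slice boundary are kept but flagged
  (`touches_border`).

## Perimeter estimation

Boundary-pixel counting overestimates a digitized disk's perimeter by
up to ~27 % and would bias every roundness upward, while line-intercept
(Crofton) estimators with 2 or 4 directions bias cornered shapes (a
100 px axis-aligned square comes out 5.5 % short, i.e. >10 % in
roundness). The package instead measures the marching-squares sub-pixel
contour of each particle, simplified by Douglas–Peucker with a 1 px
tolerance, and sums the polygon edge lengths: staircase artefacts on
smooth boundaries collapse to chords while genuinely straight edges are
preserved. Measured accuracy: digitized disks converge monotonically to
RF = 1 (RF ≈ 1.039/1.012/1.004 at radii 10/30/100 px), a 100 px square
gives RF within 1 % of 4/π, and a 2:1 ellipse within 1 % of its
closed-form value. Hole boundaries, when holes are not filled, count
toward the perimeter. A single-pixel particle falls back to its raw
(diamond) contour, giving a finite perimeter and roundness.

## Histogram, aggregation

The ten area classes are configurable lower bounds
(0, 0.1, 0.5, 1, 1.5, 2, 2.5, 3, 4, 5 cm²; last class open-ended),
consistent with reporting the 0–0.1 cm² class as intrinsic pork fat and
≥5 cm² as the largest pieces. Binning is lower-inclusive; a value on an
edge belongs to the upper class. Sample aggregation uses the arithmetic
mean and the n−1 sample SD over replicate images; a single replicate
reports SD 0 with a warning.

## Statistical layer

* **Duncan's multiple range test** after one-way ANOVA. The critical
  range for *r* consecutive ordered means is
  q(1−(1−α)^(r−1); r, df_within) · √(MS_within/n_h), with studentized-
  range quantiles computed numerically (they reproduce the classical
  tabulated values, e.g. 2.95/3.10/3.19 for r = 2/3/4 at 20 df) and n_h
  the harmonic mean group size. Sweeping proceeds from the widest range
  inward; a non-significant range shields all ranges nested inside it,
  so letter displays never have gaps. The letters are *protected*: when
  the omnibus F does not reject at α, no separation is claimed. This
  keeps the familywise false-separation rate of the display near the
  nominal level (measured ≈ 0.045 at α = 0.05 under a 16 × 15 null),
  which the unprotected sweep would not (its whole-range level alone is
  1−0.95¹⁵ ≈ 0.54). Zero within-group variance degenerates to exact
  comparison of means.
* **PCA on the correlation matrix**: variables standardized to unit
  n−1 variance, eigendecomposition of the correlation matrix, explained
  percentage = eigenvalue/p·100. Signs are fixed so each component's
  largest-magnitude loading is positive. Constant variables are
  rejected by name; samples lacking a chemical value are dropped with a
  warning.
* **Visible vs chemical fat**: ordinary least squares with
  R² = 1 − SS_res/SS_tot.

## Synthetic phantoms

`generate_phantom` renders a meat-colored disk (default luma ≈ 73) on a
near-black backdrop (≈ 10) with fat-colored ellipses (≈ 226), then
applies an optional linear illumination ramp (default 5 % across the
frame) and Gaussian pixel noise (default SD 8 gray levels). Particle
areas are lognormal (median 0.1 cm², σ = 0.8 — matching mean areas of
~0.08–0.14 cm² with maxima above 1 cm²), aspect ratios uniform in
[1, 3], positions rejection-sampled so particles lie fully inside the
slice and bounding circles are ≥ 3 px apart. Ground truth records each
particle's exact rasterized pixel area, so "true VFC" is exact by
construction. The default study is 16 samples × 15 replicates at
512 × 512 px and 0.02 cm/px (slice radius 220 px ⇒ 8.8 cm diameter),
with per-sample coverage targets 9–18 % and replicate-level coverage
jitter (relative SD 6 %); per-image seeds derive from one master seed
by fixed arithmetic, so any subset regenerates bit-identically.

What the phantoms deliberately do **not** emulate: meat-matrix texture
and color mottling, casing/edge artefacts, specular highlights,
non-elliptical or overlapping fat pieces, and camera optics
(vignetting beyond the linear ramp, chromatic effects). Passing the
recovery tests therefore demonstrates correctness of the measurement
chain under the stated image model, not segmentation robustness on
arbitrary photographs; on real images the automatic thresholds and the
closing radius are the knobs to revisit.

## Numerical conventions and degenerate inputs

Automatic thresholds follow the scikit-image convention (upper class
strictly above the threshold; relevant on discrete histograms where the
threshold can coincide with the matrix mode), while a user-fixed level
is inclusive. Duncan grouping is invariant to group input order (stable
sort on means). Empty particle lists give VFC 0 and undefined
(`None`) histogram frequencies; per-image mean/max statistics are NaN
when n = 0. An all-dark or constant image raises a "no slice found"
error rather than returning an empty mask.

## Problem sizes used by the test suite

Unit tests run on 256 px phantoms (≈ 15–20 particles each); recovery
and oracle tests use the full 512 px defaults with a handful of fixed
seeds; the Duncan null calibration uses 1000 simulated 16 × 15 studies
and the R² calibration 500 draws of 16 paired samples. These sizes make
the whole suite run in well under a minute while keeping every check at
the study's native geometry where it matters.

## Known limitations

Chemical fat enters only as an input column; nothing about extraction
chemistry is modelled. The headline field numbers that depend on the
unpublished per-sample chemical values (R², PC variance shares) are
validated in distribution (simulation) rather than by exact
reproduction. Roundness is reported per the reciprocal-circularity
definition; values for near-pixel-scale particles are dominated by
digitization and should not be over-interpreted. Color information is
not used for classification.
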