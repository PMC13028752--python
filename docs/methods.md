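# Methods and design notes

## The measurement problem

Red blood cells adhering to the wall of a microfluidic channel elongate
along the flow direction when wall shear stress is applied. Brightfield
frames (nominally 1600 × 1600 px at 0.6 µm/px) show the cells on a
background of flow streamlines: bands that vary smoothly along the flow
(X) axis and change sharply across it. The quantity of interest per cell
is the deformability index DI = (L_X − L_Y)/(L_X + L_Y), with L_X the
extent along the flow axis and L_Y the transverse extent; DI is
dimensionless, scale-free, 0 for a circle and < 1 always. Per image the
accepted cells' DIs are summed (DI_Total) and averaged (DI_Mean); per
donor, accepted-cell DIs are pooled across the images of one shear
condition (cell-weighted pooling — an image-weighted option exists).

Applied wall shear stress τ (dyn/cm²) converts to wall shear rate via
the Newtonian relation γ̇ = τ/μ; with τ in dyn/cm² (0.1 Pa) and μ in
mPa·s this is γ̇ = 100·τ/μ s⁻¹. The default μ = 1.12 mPa·s is the
measured viscosity of dextran-diluted RBC suspensions; the standard
sweep τ = 1…7 dyn/cm² then maps to ≈ 89…625 s⁻¹. Reported rates are
rounded to the nearest integer (one decimal below 10 s⁻¹). Two of the
conventionally quoted sweep values (178 and 535 s⁻¹) differ by one unit
from round(100·τ/1.12); they are quoted values, not roundings this
package reproduces, and are not used as checks.

## Shared preprocessing

Input frames are nominally monochrome RGB (equal channels); channel 0 is
used and a divergence of more than one intensity unit between channels
raises a warning rather than an error. Rotation alignment of the
streamlines to the X axis uses bilinear interpolation with edge
replication (a dark frame would survive background subtraction as false
objects). When the rotation angle is unknown, it is estimated by grid
search (default ±10° in 0.1° steps) maximizing the variance of row
means: with horizontal streamline bands of distinct brightness, the
row-mean profile is sharpest when aligned. The criterion needs bands
with distinct mean levels and a few hundred pixels of width; on small
crops (≲ 200 px) it becomes noisy at sub-degree scales.

## Sine-window pipeline

The kernel is the positive half-cycle of a sine, squared and normalized
to unit sum. Sampling is at midpoints, w_k ∝ sin²(π(k + ½)/n), so the
endpoints are non-zero and the kernel is well-defined down to n = 1;
default n = 100. An even-length kernel has no central sample and cannot
be centred on the pixel grid, so row convolution centres it by averaging
its two half-sample alignments (equivalently an odd kernel of length
n + 1 with the same mass); this makes the operator exactly symmetric:
constants map to zero residual everywhere and linear-in-X ramps map to
zero in the interior. Boundaries are edge-replicated.

Subtracting the row-filtered image removes the background but also
subtracts each cell's own kernel-smeared mass, leaving a shallow
negative trough ("gutter") across the ~n columns around every cell in
the rows it occupies, and reducing the cell's apparent amplitude by
roughly its row integral divided by n.

Contrast enhancement maps two percentiles of the residual to [0, 255]
with clipping, then smooths with an isotropic Gaussian (default σ = 1).
The default percentile window is (50, 99.9): the lower anchor pins the
background median to zero (clipping the negative residual — cells are
bright), and the high anchor keeps the stretched background narrow so
that Otsu binarization separates cells from background. A wide window
such as (1, 99) spreads the background over the whole intensity range on
sparse-cell images, and the Otsu criterion then prefers splits inside
the background structure (gutter vs. bands), which makes detection
unstable; both percentiles remain configurable.

Detection labels 8-connected components of the binarized image and keeps
those with equivalent-circle diameter 2·√(area/π) in 3–50 px. Each kept
component is measured by a direct least-squares conic fit to its
subpixel contour. The contour is taken at the component's half-plateau
level on the *unclipped* smoothed residual after per-row local-baseline
flattening: the baseline of each crop row is estimated from side strips
outside the component (which see the gutter) and removed, so the
half-level contour tracks the 50%-amplitude edge on all sides. Without
the flattening, the gutter pulls the X edges inward by ~0.5 px and the
fitted DI is biased low by ~0.02–0.04. If the conic fit is degenerate or
fewer than five contour points exist, the fallback is the second-moment
ellipse of the available points. Residual bias after flattening is the
blur-curvature shrink at the high-curvature cell tips (≈ σ²/2R), worth
about −0.01 in DI for 10–13 px cells.

Acceptance requires (a) L_X > L_Y, (b) L_X − L_Y ≥ 0.2·L_X (so every
accepted cell has DI ≥ 1/9), and (c) both fitted diameters inside size
windows, default 4 ≤ L_X ≤ 9 and 2.5 ≤ L_Y ≤ 7. The windows are applied
in `criteria_units`: `"pixels"` (default, the windows as conventionally
printed) or `"micrometers"` (converted with the grid calibration). At
0.6 µm/px the pixel reading corresponds to 2.4–5.4 µm — smaller than an
elongated RBC — and is disjoint from the DoG pipeline's 50–130 px area
window, so no cell could satisfy both pipelines at once; the micrometre
reading (6.7–15 px) is physically consistent with RBC size and with the
area window. The package's synthetic-recovery tests and the
cross-pipeline comparisons therefore use micrometre units, while the
printed pixel default is preserved for users who want the literal rule.

## DoG pipeline

A difference of Gaussians G(σ₁) − G(σ₂), σ₁ = 0.7 and σ₂ = 16 px,
band-passes the image so cells appear as compact bright regions; a white
top-hat with a 1 × 45 horizontal line element then removes elongated
horizontal streaks (even element lengths are promoted to odd for
symmetry). Binarization is at the Otsu threshold scaled by 1.06,
foreground at or above the threshold. Otsu's threshold is computed on a
256-bin histogram spanning the observed value range (the classic 8-bit
formulation does not apply to real-valued band-pass output); near-ties
within 1e−10 relative of the maximal between-class variance break toward
the smallest threshold so the result is stable against summation-order
rounding. Components touching the border are removed; components with
area 50–130 px inclusive are kept.

Each component is measured by the farthest pair of pixel centres
(searched exactly over the convex hull; equal-distance pairs break
lexicographically): L_X is that distance + 1, the pair defines the
orientation, and L_Y is the peak-to-peak perpendicular projection of all
pixel centres + 1. The +1 pixel-extent convention makes a single-file
row of k pixels measure k. Cells with DI > 0.35 are rejected as
artifacts.

The farthest-pair rule has an intrinsic quantization artifact at this
cell scale: near-diagonal corner pairs of the raster often beat the true
major axis by a fraction of a pixel, tilting the measured axis by a few
degrees, inflating L_Y via the projection, and biasing DI low by
0.02–0.04 for elongated cells (verified on ideal half-coverage rasters,
independent of filtering or thresholding). This is a property of the
measurement definition, not of its implementation, and it is the main
reason the DoG pipeline's absolute DI runs below the sine-window
pipeline's on identical cells — mirroring the systematic offset between
the corresponding tools in practice.

## Synthetic data generator

Images: `n_bands` horizontal bands tile the frame with logistic edges of
width ~1.5 px; each band carries a mean brightness offset and a smooth
along-X modulation (Gaussian-filtered white noise with 1/e
autocorrelation length `x_smoothness_scale`, default 250 px, ≥ 200 px
enforced so the background is smooth relative to cells), scaled by
`band_amplitude` (default 12) around `base_level` 120, plus optional
i.i.d. Gaussian noise (default SD 2). Cells are anti-aliased filled
ellipses (4×4 subpixel coverage) added brightly by default; rejection
sampling places non-overlapping cells (centre separation above the sum
of semi-majors) fully inside the frame. Default cell windows emulate
shear-elongated RBCs at 0.6 µm/px: semi-axes a ∈ [4.8, 6.8] and
b ∈ [3.3, 4.9] px jointly constrained to true DI ∈ [0.13, 0.27] and
area πab ∈ [55, 125] px — inside both pipelines' acceptance windows
(micrometre reading) with margin. Test images are 400 × 400 px rather
than full camera frames; this keeps the cell density per row comparable
to sparse real fields while making the suite fast, and no quantity in
the package depends on frame size.

What the generator does *not* emulate: phase-contrast halos, defocus,
cell-to-cell optical variation, membrane fluctuation, partial overlaps
with mid-range coverage, or flow motion blur. Recovery results on
synthetic images therefore demonstrate correctness of the measurement
chain (segmentation → axis measurement → DI → aggregation) under known
geometry, not end-to-end accuracy on real micrographs.

Cohorts: mean DI per donor and shear follows a saturating response
DI(τ) = DI_max·τ/(τ_half + τ) — the simplest monotone form with a
plateau, consistent with elongation approaching a maximum at high
shear. Group defaults are least-squares fits of this form to the
published healthy (DI_max 0.2173, τ_half 0.4024) and CLL (0.1873,
0.4373) mean profiles of the farthest-point pipeline, so simulated
effect sizes resemble realistic cohorts (this is a calibration
convenience, not a reproduction claim). Donor heterogeneity is a
Gaussian random intercept (SD 0.010) plus residual noise (SD 0.006),
chosen once so the between-donor spread at one shear (~0.012) matches
what such assays report; group sizes default to 13 healthy / 9 patients.
Values are clipped to [0.01, 0.99].

## Statistical layer

The mixed model is DI ~ group * shear + (1 | donor), with shear as a
*categorical* factor (7 levels ⇒ df1 = 6, matching the repeated-measures
design) and sum-to-zero coding so that coefficient blocks give Type III
tests directly. Variance components come from a REML fit (statsmodels
MixedLM). F statistics use the GLS fixed-effect covariance at the
estimated variance components; denominator degrees of freedom follow the
Satterthwaite approach: the covariance of the variance-component
estimates is the inverse observed information of the closed-form
restricted likelihood (numerical Hessian; the random-intercept structure
makes the likelihood cheap via the Woodbury identity), and each
eigencomponent of the contrast covariance contributes
ν = 2λ²/(∇λᵀ A ∇λ), combined as in the standard multi-df recipe. On
balanced two-group designs this reproduces the classical split-plot
denominators (N − 2 for group, (N − 2)(s − 1) for shear and
interaction) and it matches R's lmerTest to four decimals on unbalanced
designs (kept as a test oracle). Effect sizes are partial eta squared,
η²p = F·df1/(F·df1 + df2).

Mann–Whitney U uses exact enumeration when the smaller group has ≤ 8
observations and no ties, otherwise the tie-corrected normal
approximation without continuity correction (so identical samples give
p = 1 exactly). No multiplicity correction is applied across shear
levels by default; Holm step-down is available. Bland–Altman reports the
mean difference (sine-window minus DoG by convention, the direction with
positive bias), 1.96·SD limits (sample SD), the fraction of differences
inside the limits, and the OLS slope of differences on pairwise means
with its t test for proportional bias. The 1.96 multiplier follows the
classic definition rather than a t quantile.

## Numerical choices and degenerate inputs

- Intensities are carried as float64 end to end; quantization to 8 bits
  happens only on image export (clip to [0, 255], round half up).
- Constant images: rotation estimation returns 0 with a warning; Otsu
  raises; the enhancement step returns zeros with a warning when the
  percentile window is degenerate.
- The rotation estimate ties break toward the smallest |angle|; the
  farthest-pair ties break lexicographically; Otsu near-ties break
  toward the smallest threshold — every search in the package is
  deterministic.
- Empty images are legal everywhere: zero accepted cells produce
  DI_Total 0 and a flagged (None) DI_Mean.
- Seeds: every stochastic routine takes a seed or Generator and is
  reproducible bit for bit; test sizes (400 px frames, 10–50 images,
  100–500 cohort replicates) are the package's own choices for a fast,
  statistically meaningful suite.

## Known limitations

- The DoG axis convention's quantization bias (above) caps its absolute
  DI accuracy near ±0.03 for 8–13 px cells; ranking and group contrasts
  are unaffected.
- The sine-window pipeline's enhancement defaults assume sparse bright
  cells; densely packed fields would push the high percentile into the
  cell intensity distribution and change the effective threshold.
- Donor aggregation assumes images of one condition are exchangeable;
  there is no correction for within-channel position effects.
- The mixed model supports exactly two groups and a single random
  intercept (no random slopes), matching the target study design.
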