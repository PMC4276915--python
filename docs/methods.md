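# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinate and intensity conventions

Positions are `(row, col)`, 0-based, origin at the center of the
top-left pixel; subpixel positions are real-valued in the same frame.
Physical units enter only through `pixel_size_um` (µm per pixel edge;
default 3.0, the scale at which the conventional 15 µm matching
tolerance equals 5 px). Camera intensities are integers in
`[0, 2^bit_depth − 1]` (8-bit by default, 256 gray levels); internal
processing is in floats to avoid quantization artifacts in centroid and
gradient math. Channel order is the plate-configuration order and is
preserved in every output; a secretion pattern is the tuple of channel
labels in that order.

## Level one: spot detection

Detection operates purely on gray values. Color in fluorescence well
images is presentation: each fluorophore is imaged through its own
filter, so any hue substitution at constant luminance leaves the
analysis bit-identical (color input is collapsed with fixed ITU-R 709
luminance weights).

**Background.** Level = median; scale = normalized median absolute
deviation (MAD × 1.4826). Both are robust to the few percent of pixels
covered by spots.

**Thresholding.** Pixels `>= level + t·scale` (background-relative,
default `t` = 5) or `>= t` (absolute) form the candidate mask;
connected components use 8-connectivity with raster-scan labeling. The
default `t = 5` sits far enough in the Gaussian tail that a blank
512×512 well yields essentially no false regions of more than a few
pixels, while real spots (peak ≈ 150 over background ≈ 12) are cut at a
level that preserves most of their area.

**Separation.** Regions holding ≥ 2 local maxima of the
Gaussian-smoothed image (σ = `smoothing_sigma_px`, default 1.0) at
least `separation_min_distance_px` apart (default 5) are split by
marker-based watershed on the inverted smoothed intensity. Equal maxima
closer than the minimum distance are deduplicated deterministically:
higher intensity wins, ties go to the smaller `(row, col)`. Total
labeled area is conserved by construction.

**Measurement.** Per region: subpixel center = intensity-weighted
centroid; `gradient_score` = mean intensity within radial distance
`R/2` of the center over the mean in the annulus `(R/2, R]`, with
`R = sqrt(area/π)` the equivalent-disc radius — 1.0 for a flat disc,
rising with the steepness of the center-to-periphery fade;
`radial_cv` = coefficient of variation of boundary-pixel distances to
the center (boundary = member pixels with a non-member 8-neighbor) — 0
for a perfect disc, larger for ragged or elongated regions. Degenerate
single-pixel regions get `gradient_score = 1.0` and `radial_cv = 0.0`
by convention (so only the size filter governs their fate); the same
convention applies when the core or annulus is empty.

**Filtering.** Retained iff
`min_area ≤ area ≤ max_area` ∧ `peak ≥ min_peak` ∧
`gradient ≥ min_gradient` ∧ `radial_cv ≤ max_radial_cv`; rejections are
tallied under the first failing filter in that fixed order. One
parameter set is held per channel, mirroring per-filter camera tuning.

## Level two: center matching

Candidate pairs are all cross-channel spot pairs with Euclidean
center distance ≤ `max_center_distance_px` (a closed ball, so a pair at
exactly the tolerance matches). Pairs are processed greedily in
ascending distance (ties by channel order, then centers); a pair merges
its two groups only if the union still has at most one spot per channel
and all pairwise member distances stay within tolerance. This
all-pairs condition prevents chaining: two far-apart spots can never be
joined through a middle one. Unmerged spots become singletons, so the
groups partition the input and per-channel marginals of the resulting
subpopulation counts equal the per-channel spot counts exactly.

The matching distance is measured between intensity-weighted centroids,
not peak pixels: center shifts between analytes arise from asymmetric
spot mass (different secretion kinetics, cell movement), which the
centroid tracks and the brightest pixel does not. Whether commercial
readers use greedy, mutual-nearest or optimal assignment is not public;
the greedy-with-constraints rule is deterministic and is bounded on
small instances by an independently implemented oracle in the test
suite.

**Default tolerance.** `max(1, 15 µm / pixel_size_um)` px — 5 px at
3 µm/px. The tolerance is exposed rather than scaled with spot size;
the 15 µm figure is an empirical value for medium-sized spots.

**Coincidence limit.** Null model for random multi-stain calls: per
shuffle, one channel beyond the first (cycled) has its centers
displaced by a single random toroidal translation of the frame, and
matching is re-run. Toroidal translation (rather than full re-scatter)
preserves each channel's internal spatial pattern, including
clustering, and only destroys cross-channel alignment. Reported per
shuffle: the fraction of spots landing in multi-channel groups and the
number of multi-channel groups; for sparse uniform fields the latter
converges to the closed form `n₁·n₂·π·d²/A`, which the tests verify to
within Monte-Carlo error.

## Bleed-over and exposure QC

The single-stain panel check runs level one on every filter image of
every single-fluorophore control well. PASS requires ≥ 1 on-target spot
and at most `tolerance_count` off-target spots per filter (default 0 —
the literal "no off-target signal" reading; a nonzero option exists
because noise can create rare false spots). An empty on-target channel
yields INDETERMINATE rather than FAIL, since absence of bleed-over
cannot then be distinguished from assay failure. The check detects
bleed-over; it does not correct it (no spectral unmixing).

Exposure warnings: overexposure when more than 1% of pixels sit at full
scale; underexposure when the 99.5th percentile falls below 5% of full
scale. The underexposure limit is lenient by design so that sparse but
healthy wells do not warn.

## The simulator

`simulate_well` emulates the acquisition chain the analysis assumes,
per channel: `(background + Σ spots, mixed across channels by the
bleed-over matrix) × gain × exposure + Gaussian noise`, clipped to the
camera range and rounded to integers. Clipping models saturation;
`clip=False` / `quantize=False` switch it off for exact
intensity-conservation checks.

**Spot profile.** `I(r) = peak · (1 − r/R)^s` for `r ≤ R`, else 0 —
radially symmetric, maximal at the center, fading monotonically to zero
at the nominal radius, with the exponent `s` (`gradient_shape`, default
2.0) controlling how sharply intensity falls toward the periphery. Its
continuous integral is `2π·peak·R²/((s+1)(s+2))`, used as a quadrature
cross-check. Profiles are evaluated at pixel centers (no per-pixel area
integration); the small resulting bias is identical for simulator and
detector, so recovery tests are unaffected.

**Defaults** (one well): 512×512 px at 3 µm/px (a ~1.5 mm field),
3 channels (FITC/Cy3/Cy5), 60 cells with nominal centers at least 25 px
apart (rejection sampling with an explicit retry budget), spot radius
~N(5, 1) px truncated at ≥ 1 px, peak ~N(160, 25) truncated positive on
a background of 12 with noise σ = 2 (8-bit range) — mid-range images
that trigger no exposure warnings. Secretion patterns are drawn
uniformly over all 2^k−1 subsets unless explicit probabilities or
per-cell patterns are given, so every subpopulation is exercised.
Per-channel center jitter is Gaussian with σ = 1 px (~3 µm): the
reported inter-analyte center shift is "µm-range" without a stated
distribution, so one pixel at the default scale is taken as the
representative magnitude and varied in tests.

**Seed protocol.** One master seed per well;
`SeedSequence(seed).spawn(5)` children are consumed in the fixed order
placement → patterns → morphology → jitter → noise, making wells
bit-reproducible and each stage independently re-drawable.

**What it does not emulate.** No optics (PSF, vignetting, filter
spectra — bleed-over is an abstract mixing matrix), no secretion-kinetic
time course (jitter is its only trace), no membrane texture or well-rim
artifacts, no spot-size correlation with secretion pattern. Passing
recovery tests therefore demonstrates the correctness of the analysis
chain under the stated statistical structure, not performance on real
plate images with structured backgrounds.

## Problem sizes in tests and the acceptance script

Recovery is scored over 20 simulated wells of 60 cells (3 channels,
512×512 px, jitter σ = 1 px, tolerance 5 px): level-one recall and
precision and the level-two pattern misclassification rate (unmatched
cells + spurious groups + pattern mismatches, over cells). The
coincidence null uses two channels of 50 uniform spots on a 1000×1000 px
field with 200 shuffles. Matcher equivalence is checked on 200 random
instances of ≤ 3 channels × ≤ 8 spots. These sizes give stable
statistics (≈ 2000 spots, ≈ 1200 cells) while keeping the full suite in
seconds.

## Known limitations

- The gradient and separation formulas are documented equivalents of
  undisclosed vendor algorithms; agreement is established against
  simulator ground truth, not against a commercial reader.
- Greedy matching is order-deterministic but not globally optimal; on
  dense fields an optimal assignment could differ. At realistic spot
  densities and the default tolerance the difference is within the
  coincidence limit.
- No illumination-field correction or well-rim masking; heavily
  vignetted images should be corrected upstream.
- The misclassification metric attributes every spurious group to a
  pattern error; with noisy real images it is therefore conservative.
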