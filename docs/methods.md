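# Methods

## The measurement problem

Foam-cell assays compare *populations* of cells across chemical
conditions: does adding a sterol mixture shift the distribution of
per-cell lipid content, size or shape? The raw data are pairs of
co-registered fluorescence rasters per well — nuclei in blue, neutral
lipids in red — in which cells vary widely in brightness, touch each
other, and sometimes carry more than one nucleus. The package's job is
to identify single cells reliably enough that per-cell feature
distributions, not hand-picked examples, carry the comparison.

## Segmentation model

Segmentation treats a grayscale raster (blue channel for nuclei, the
per-pixel blue/red maximum for whole cells) in three stages.

**Foreground mask.** Intensities are contrast-stretched between the
1st and 99th percentiles, edges are found as the Sobel gradient
magnitude and thresholded, and the resulting outlines are solidified
by dilation, hole filling and erosion with a disk of radius
`morph_radius_px` (default 2 px); connected components below
`min_object_area_px` (default 30 px²) are dropped. A second pass uses
this binary as a mask on the enhanced grayscale and re-binarises it so
the final foreground follows the true signal boundary rather than the
dilated edge band, again closing and cleaning the result.

Two numerical choices in this stage deviate from the obvious defaults,
for cause:

- *Gradient threshold.* Gradient-magnitude histograms are unimodal and
  heavily skewed toward zero, a shape on which Otsu's bimodal
  criterion locks onto the strongest edges (bright nuclei) and
  discards the boundaries of dim cells. The default is therefore the
  triangle method, which thresholds just above the noise shoulder; a
  fixed numeric override (`gradient_threshold`) is available.
- *Second binarisation.* Because bright and dim cells coexist in one
  image, the masked-intensity histogram is multi-modal and a global
  Otsu threshold erases the dimmest cells. The second pass instead
  thresholds at the 99.5th percentile of the *out-of-mask* (background)
  enhanced intensities — a background-referenced cut that keeps any
  cell brighter than the noise, regardless of how bright its
  neighbours are.
- *Contrast stretch guard.* In sparse images the foreground can occupy
  under 1% of pixels, putting the 99th percentile in the background
  and amplifying noise to full range; the stretch ceiling therefore
  never drops below half the image maximum.

**Seed landscape.** The Euclidean distance transform of the foreground
is negated so cell centres become basins, and basins shallower than a
depth *h* are removed with the extended-minima (h-minima) transform.
The surviving minima are the watershed markers; `h_blue` defaults to
0.6 and `h_merged` to 1.0 (2.0 suits coarser merges), both in
pixel-distance units. Raising *h* can only merge markers, never create
them, so over-segmentation decreases monotonically in *h*.

**Watershed.** A marker-controlled watershed floods the negated
distance map inside the foreground, one label per marker, leaving
ridge pixels as background. Connectivity is 8-neighbour throughout
(component labelling, minima, flooding) to avoid splitting diagonal
strands.

## Nucleus validation

A nucleus is *contained* in a candidate segment when more than
`nucleus_overlap_fraction` (default 0.5) of its pixels fall inside it;
each nucleus counts toward at most one segment (its majority holder,
ties to the lower label). Segments are accepted only with exactly one
contained nucleus and no pixel on the outermost rows or columns — the
strict reading of border contact. This single rule simultaneously
removes non-cell debris (no nucleus), unresolved clusters and
multinucleate cells (several nuclei), and cells clipped by the field
of view. Multinucleate macrophages are thereby excluded *by design*;
that is a deliberate trade of completeness for single-cell purity.
Zero accepted cells is a valid per-image outcome and is logged, not
raised.

## Intensity features and normalisation

Per-cell red intensity is the mean of the red channel under the cell's
label. To compare across wells and conditions, every mean is divided by
the brightest red pixel over *all* images of the batch — one constant
per batch, not per image or condition — and multiplied by a reporting
scale of 255, so values land on a familiar 8-bit "au" axis and a cell
sitting at the batch maximum scores exactly 255. The normalisation
cancels any global gain shared by the batch. Raw camera counts are
assumed; no background subtraction or flat-field correction is applied.

Geometry comes from the standard second-moment conventions: area is
the pixel count (scaled by `pixel_size_um²` when the batch is
calibrated; the default 1.0 leaves areas in px² and flags outputs as
uncalibrated), eccentricity is that of the moment-equivalent ellipse
(0 for a circle, → 1 for a line), perimeter is boundary-step length.
Regions under 3 pixels have degenerate moments and report eccentricity
0 with a warning. Pooled in-cell pixel intensities are summarised as
count-density histograms: equal-width bins on [0, 255] normalised so
bin *area* sums to one, making conditions with different cell counts
directly comparable.

## Statistical decision rules

Two-sample comparisons follow a fixed tree. Each sample is tested for
normality (Shapiro-Wilk, p < 0.05) and the pair for variance equality
(Levene, p < 0.05); non-normality in either sample routes to the
two-sided Mann-Whitney test (mid-ranks for ties, normal approximation
at larger n), otherwise equal variances give the pooled t-test and
unequal variances Welch's t-test. The tree itself fixes only the three
destinations; Shapiro-Wilk and Levene are this package's choices
(powerful at n in the tens-to-hundreds; Levene robust to
non-normality) and both are swappable via arguments. No
multiple-testing correction is applied — comparisons are reported
per-pair, with the stricter *notable* bar at p < 0.001 doing the
practical gate-keeping.

Correlations between red intensity and area are computed with both
Pearson and Spearman: both significant ⇒ a trusted linear relation;
Spearman only ⇒ "possible non-linear" (monotone but not linear, or
outlier-driven); anything else ⇒ not significant. Pearson-only
significance is deliberately distrusted because the feature
distributions are typically non-normal with outliers.

Population summaries report mean ± SEM (SD/√n, SD with the n−1
denominator), median, and the 1st/99th percentiles computed by linear
interpolation between order statistics — stated explicitly because
1–99 whiskers are sensitive to the convention. Percent changes between
condition means are rounded to the nearest integer percent. Agreement
with manual tracing treats each cell's manual area â as the mean of
its repeated traces and scores 100·|â − a*|/â per cell, plus the
counts of cells whose manual estimate falls below, above or on the
automated value.

## Synthetic data: what it does and does not emulate

The generator renders what the pipeline must be able to parse: filled
elliptical cells (semi-axes uniform on 7–14 px) with one interior
elliptical nucleus each (3.5–5.5 px, capped relative to the cell's
minor axis so nuclei stay strictly interior), uniform per-cell red
intensity drawn from a truncated normal on [0, 1], nucleus intensity
0.8 on a 0.05 background, and additive Gaussian noise (σ = 0.02)
clipped to gamut. Decoys exercise the validation filter: binucleate
cells (rendered 1.6× larger so two separated nuclei fit — mirroring
the larger footprint of real multinucleate macrophages) and cells
clipped by the image border. A `cluster_fraction` places cells with
slight envelope overlaps to form small clusters, and a droplet variant
re-renders a fraction of cell pixels as bright puncta to mimic lipid
bodies and heavy-tailed pixel histograms. Interior cells keep a 5 px
envelope gap so ground truth is unambiguous; placement is by bounded
rejection sampling. The same seed reproduces rasters bit-for-bit.

Default condition intensities (control μ = 0.30, treated μ = 0.474,
σ = 0.05) program a +58% mean shift of the size seen between vehicle
and sterol-treated populations, with per-cell spreads comparable to
the 20–40 au SDs typical of such data after 0–255 normalisation.

Not emulated: point-spread blur, vignetting and uneven illumination,
bright-field rendering, intra-cell texture beyond the droplet variant,
large dense clusters, or segmentation-adversarial shapes. Passing
tests therefore demonstrate the pipeline's logic — exact nucleus
accounting, unbiased area and intensity recovery, correct routing of
the statistics — under clean optics, not robustness to every artefact
of real microscopes.

## Problem sizes

Test fixtures use 512×512 images with 55–60 cells (50 interior
mononucleate plus binucleate/border decoys) for the segmentation
checks, and 2 conditions × 4 wells × 80 cells (≈ 320 accepted cells
per condition) for end-to-end effect recovery; the null error rate is
estimated from 500 simulated Gaussian condition pairs of n = 100.
These sizes put sampling error well below the effects being checked
(SEM of a condition mean ≈ 2 au) while a full suite run stays in the
tens of seconds.

## Known limitations

- Cells inside large, dense clusters that the distance-transform
  watershed cannot split are excluded (no contained nucleus or several
  of them), biasing samples toward isolated cells; a membrane-channel
  variant would be needed to resolve such clusters.
- The border rule discards every edge-touching cell, so very large
  cells are slightly under-sampled near the frame.
- Batch-maximum normalisation is sensitive to a single hot pixel in
  any image of the batch; inputs are assumed free of dead/hot pixels.
- Pixel calibration is taken on faith from the manifest; with the
  default 1.0 all areas are px² and flagged uncalibrated.
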