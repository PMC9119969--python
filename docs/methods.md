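# Methods

## Texture segmentation (imaging core)

All image pipelines share one segmentation primitive built on local
Shannon entropy. Intensities are kept on a 0–255 scale (stored as floats,
quantised to 256 integer bins only for histogramming), because the
Ki67-positivity cutoff of 10 is defined on that scale and silent
renormalisation would change its meaning. Entropy is reported in bits
(base 2) of the 256-bin histogram in a square window (default 9×9); both
the Gaussian denoise and the entropy window use reflective (symmetric)
border padding so frame edges are not biased toward either class.

The pipeline is: Gaussian denoise (σ = 2 for phase contrast, σ = 1 for
fluorescence) → pixel-wise local entropy → threshold → edge compensation →
morphological cleanup (opening radius 1, closing radius 3, removal of
components under 25 px; 8-connectivity throughout).

**Threshold choice.** The default threshold is the midpoint of the 0.5th
and 99.5th entropy percentiles — i.e. halfway between the background and
texture plateaus. Otsu's method (available via config) works when the two
classes are comparably abundant but splits the majority mode once one
class covers more than roughly 80% of the frame, which is exactly the
regime of near-blank and near-confluent fields and of late wound frames.
The extreme-percentile midpoint only requires each plateau to contribute
≳0.5% of pixels. When even that fails — the frame is single-class — the
decision falls back to the absolute entropy scale: a map whose low extreme
exceeds 2 bits is fully textured (denoised background sits well below
1 bit, cell-scale speckle well above 3), and a map whose high extreme is
below 2 bits is blank. Such frames yield all-true/all-false masks with a
warning rather than an error.

**Edge compensation.** Thresholding the entropy ramp at the plateau
midpoint places the detected boundary about half a window beyond the true
texture edge (the window "sees" texture before it reaches it), and the
preceding Gaussian denoise diffuses texture outward by a further
σ-dependent amount. The thresholded mask is therefore eroded by
`window//2 − round(σ/2)` pixels (3 px for the σ = 2 phase pipeline, 4 px
for the σ = 1 fluorescence pipeline) immediately after thresholding. With
this compensation the confluence estimate is unbiased to well under one
percentage point across 5–95% coverage on synthetic fields; without it the
bias reaches +15 points at mid-coverage. The radius is config-exposed.

**Hole filling** is off by default: a monolayer's enclosed acellular gaps
are genuine background, and filling them inflated confluence by ~13 points
at 75% coverage on synthetic fields. Closing (radius 3) already repairs
small segmentation dropouts. The flag remains available for assays where
enclosed dark regions are known artefacts.

## Proliferation assays

Confluence is the masked fraction of the frame, in percent. Growth curves
aggregate replicates per timepoint with sample (n−1) standard deviation; a
single replicate reports sd 0 with an explicit `sd_defined=False` flag.

Nuclei are segmented from the nuclear-stain (405) channel; with
well-separated nuclei each 8-connected component is one nucleus. An
optional distance-transform watershed split for touching nuclei sits
behind a config flag, off by default, keeping the default pipeline the
plain connected-components reading. The Ki67 call applies the strict rule
mean₄₈₈ > 10 per region, computed on the **raw** 488 frame — the σ = 1
denoise is applied to the 405 channel for segmentation only, so the
printed cutoff keeps its meaning on unprocessed intensities. A field with
zero nuclei reports its positive percentage as missing (NaN), never 0, so
empty fields cannot bias condition averages. Nuclear MFI is the mean 488
intensity over the union of nuclear pixels (area weighting follows
automatically from pooling pixels).

## Wound assay

The wound mask estimates the cellular region as for confluence but from a
band-passed frame (difference of Gaussians, σ_low = 2, σ_high = 16): the
band-pass keeps cell-scale texture while suppressing slow illumination
gradients that the raw-intensity route would misread. A large closing
(radius 8) bridges intracellular gaps, and the wound is the complement,
retaining only its largest connected component by default — a scratch is a
single contiguous region, and smaller cell-free pockets are biological
holes, not wound. Recovery is `100·(A₀ − A_t)/A₀` with A₀ from the same
well's time-zero frame; negative recoveries (a growing wound) are reported
and flagged, never clipped.

## CMC breakpoint estimator

The estimator follows the classical dye-solubilisation construction: fit
straight lines to the unimeric and micellar regimes and report the
abscissa of their intersection. Implementation details that matter on
noisy data:

- Candidate splits leave at least 3 points per segment; with 10 points
  that gives 5 candidates. Fitting is in linear concentration coordinates
  (the solubilisation plot is drawn against wt%, not log wt%); a log-x
  option exists behind a flag.
- Under log-spaced sampling the unimeric segment spans only ~2% of the
  abscissa range, so its OLS slope is typically *statistically
  unidentifiable* (slope SE an order of magnitude above any physical
  slope), which makes the raw intersection heavy-tailed (the denominator
  m₂ − m₁ can approach zero). When the unimeric slope is insignificant
  (|m| < 2 SE) the segment is refitted as a flat baseline — the physically
  expected unimeric behaviour, since below the CMC the probe remains
  unsolubilised.
- Splits are ranked by total SSE; preference goes to splits whose
  intersection lies in the gap between their own segments (a split whose
  lines cross elsewhere is internally inconsistent). If no candidate is
  consistent, the best in-range intersection is clipped into its gap. If
  no intersection lies in the data range at all — parallel lines, a
  single-regime curve — a `NoIntersectionError` is raised.
- The reported `cmc_` is the median of this point estimator over 99
  residual-bootstrap replicates of the fitted continuous two-segment
  model. The breakpoint's likelihood is nearly flat above the kink when
  the kink amplitude is comparable to the noise, so the point estimator's
  sampling distribution is strongly right-skewed; the bootstrap median is
  far better centred while leaving noiseless data untouched (zero
  residuals short-circuit the bootstrap, and the estimate equals the exact
  intersection to 1e−9). The point estimate, both lines, the split index
  and the per-candidate SSE table are all exposed as fitted attributes.

Known limitation: when the first concentration above the breakpoint sits
within ~1 noise sd of the unimeric extrapolation, the data cannot decide
between adjacent splits and the estimate's *mean* over many replicates
remains biased upward by 10–35% even though its median is essentially
unbiased; no estimator we evaluated (including a Bayes posterior mean with
known noise) centres the mean under those conditions. The bias and RMSE
grow monotonically with the noise level.

## Standard curve and LDH

The quadratic calibration ΔA = a·x² + b·x + c is fitted by least squares
on ≥4 points with >3 distinct abscissae; R² = 1 − SSE/SST, with the
convention R² = 0 (flagged `degenerate_`) when SST = 0. Inversion solves
the quadratic and keeps the real root on the monotone branch containing
the calibration midpoint, restricted to [0, 1.1 × calibration max];
anything else raises an out-of-range error rather than silently
extrapolating. LDH release normalises background-subtracted signals
(A₄₉₀ − A₆₉₀) between the medium-blank mean (0%) and the lysis-control
mean (100%); a lysis mean at or below the blank mean is an invalid-control
error.

## Comparative-CT and statistics

Technical replicates are averaged on the Ct scale (not on fold changes)
before ΔCt/ΔΔCt; the control condition's fold change is exactly 1 by
construction, and adding any constant to every Ct leaves all fold changes
unchanged. Missing reference measurements are listed explicitly. Gene-set
overlap is reported as a percentage of the query set (with the
intersection and both set sizes, so the other direction is recoverable),
case-normalised, with an empty query yielding a missing value. Statistics
follow the bench conventions: one-way ANOVA with all-pairs Tukey HSD
(family α = 0.05, adjusted p-values reported, statsmodels implementation
cross-checked against an independent one in tests), pooled-variance
unpaired t-tests, and two-tailed Pearson correlation. No cross-gene
multiple-testing correction is applied by default, mirroring per-gene
testing practice; Benjamini–Hochberg is a one-liner away via statsmodels
for users who want it.

## Synthetic data: what it does and does not emulate

The generators reproduce the *properties the pipelines exploit*, not
microscope optics:

- **Phase fields.** The cell mask is a level set of a correlated Gaussian
  random field (correlation length = mean cell radius, default 6–12 px),
  thresholded at the exact area quantile, so the ground-truth confluence
  hits its target to a small fraction of a percentage point and both
  cellular and background phases form patches at the cell scale — the
  regime in which a 9×9 entropy window can resolve them. Inside the mask,
  pixels are uniform speckle (background ± texture_contrast, default
  100 ± 80); outside, constant background; everywhere, Gaussian read noise
  (sd 2). Uniform speckle rather than two-level salt-and-pepper keeps the
  inside-vs-outside entropy margin at ~3 bits (a two-level texture adds
  exactly one bit over the background noise entropy, too small a margin to
  segment reliably).
- **Fluorescence fields.** Nuclei are non-overlapping discs (radius 5–7 px,
  centres ≥28 px apart by rejection sampling; impossible packings raise an
  explicit error). The 405 channel gives nuclei wide uniform speckle
  (0.4–1.6 × the nominal level) so they carry high local entropy; the 488
  channel assigns each nucleus its class mean (default 25 positive, 3
  negative, straddling the cutoff 10). The positive count is
  positive_fraction × n rounded half away from zero — deterministic and
  documented. Setting min_separation = 0 produces overlapping nuclei for
  robustness testing.
- **Wound series.** A centred cell-free stripe whose width follows
  A_t = A₀(1 − recovery_t/100) up to integer rounding, in a fully
  confluent textured field; straight edges, either orientation.
- **Solubilisation curves and Ct tables.** Exact two-segment polylines and
  exact ΔΔCt inversions plus additive Gaussian noise.

None of the image generators model point-spread functions, uneven
illumination, photobleaching, debris, or out-of-focus light. Passing
recovery tests therefore demonstrates that the pipelines are unbiased and
self-consistent under the stated texture model, not that they are robust
to every real-microscopy artefact; the band-pass wound route and the
config-exposed parameters are the intended adaptation points for real
data.

All generators draw every random quantity from a single
`numpy.random.default_rng(seed)` stream per call, so identical spec + seed
reproduce outputs bit-exactly.

## Problem sizes and determinism of the reproduction script

`scripts/acceptance.py` uses five 640×640 fields of 200 nuclei per Ki67
condition, five 384×384 four-frame wound series per migration condition,
and 100 ten-point solubilisation curves (noise sd = 2% of the noiseless ΔA
range) — sizes at which each quantity's Monte-Carlo error is comfortably
inside the tolerances the assays themselves quote, while the whole script
completes in well under a minute. Every seed derives from the `--seed`
argument through named child streams, so runs are exactly repeatable.
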