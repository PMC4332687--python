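# Methods

## Block statistics and the contrast map

The image is partitioned into non-overlapping `window × window` blocks
anchored at pixel (0, 0); trailing rows/columns that do not fill a block are
discarded, so the map dimensions are `(⌊H/n⌋, ⌊W/n⌋)` — a 700×700 image with
the default window of 4 gives 175×175. Non-overlapping blocks (rather than a
sliding window) are forced by that geometry: 700/4 = 175 only holds for a
decimating grid. Each block yields the mean ⟨I⟩, the sample standard
deviation σ (n−1 denominator, n = window² pixels), and the contrast
C = σ/⟨I⟩.

Numerical choices:

- A block with mean 0 (possible in masked or underexposed photographs) is
  flagged *invalid* rather than producing an undefined contrast; every
  downstream mean is over valid cells only, with an explicit minimum-cell
  rule (below).
- Contrast is **not** clamped to [0, 1]. The ideal fully-developed-speckle
  statistic is bounded by 1, but a 16-pixel sample of a negative-exponential
  intensity distribution is heavy-tailed enough that the sample σ/mean can
  exceed 1; clamping would bias region means and hence the contrast ratio.
- The window must be ≥ 2 (a 1×1 block has no sample standard deviation).

## Regions, masking, and the contrast ratio

Analysis is restricted to the centrally illuminated part of the map, where
the beam profile is approximately homogeneous. The central mask keeps the
centered sub-grid of linear size `⌈fraction × dim⌉` per axis; the fraction
defaults to 0.5 and is configurable because the source protocol never
quantifies "central portion" — 0.5 keeps a comfortable margin against
Gaussian-beam falloff while retaining thousands of cells at the default
geometry.

Region rectangles are specified in pixel coordinates (0-based, half-open,
row-major) and converted to block coordinates by the rule: a block belongs
to a region iff its top-left pixel lies inside the rectangle. This rule is
deliberately simple and testable; at window 4 the worst-case boundary error
is 3 pixels, negligible against the region insets used everywhere.

A region mean contrast is the arithmetic mean over valid, masked cells
inside the region and requires at least `min_cells` (default 25) usable
cells, so a mean is never dominated by a handful of noisy blocks. The
per-sample biomarker is

    CR = 1 − ⟨C_sound⟩ / ⟨C_lesion⟩,

positive when the lesion's contrast exceeds the sound region's. CR is
reported signed; silently taking absolute values would hide a reversed
(pathological) measurement. One textual inconsistency in the source
literature is worth documenting: the defining formula and the map figures
imply lesion contrast is *higher* than sound contrast (positive CR), while
the accompanying prose describes the lesion "signal" as *lower*. This
package implements the formula as printed and makes no attempt to guess the
prose's intent; both readings agree on the magnitudes.

Outlier handling is explicit only: a manifest row can carry an exclusion
flag, but nothing is excluded automatically, because no defensible automatic
criterion exists for n = 8 groups.

## Synthetic speckle phantoms

The generator synthesizes fully developed polarized speckle by drawing a
complex circular-Gaussian random field, low-pass filtering it in the
frequency domain with a circular (disk) cutoff, and taking the squared
magnitude. This Fourier route was chosen over random-phasor ray summation
because it gives direct, calibrated control of the grain size and is fast at
700×700. The resulting intensities follow the negative-exponential law
P(I) = exp(−I/⟨I⟩)/⟨I⟩ with ideal global contrast 1.

**Grain calibration.** The intensity autocorrelation of speckle from a disk
aperture follows |2J₁(x)/x|², which reaches half maximum at x ≈ 1.61633.
Mapping the autocorrelation FWHM to the requested `grain` (pixels) fixes
the cutoff radius at ρ_c = 1.61633/(π·grain) ≈ 0.5145/grain cycles/pixel
(`GRAIN_CUTOFF_CONSTANT`); the calibration is pinned by a test on the
measured lag-1 autocorrelation at grain 2.

**Contrast control.** Averaging N independent patterns gives global contrast
1/√N — the standard mechanism by which multiple scattering or
depolarization reduces speckle contrast. A two-region erosion phantom
places low-N, low-mean speckle left of a boundary column ("lesion") and
high-N, high-mean speckle on the right ("sound"), reproducing the two
qualitative signatures of eroded enamel — lower mean backscatter, higher
local contrast — and giving the analytic ground truth
CR = 1 − √(N_lesion/N_sound). Region rectangles returned with the phantom
are inset by 2×grain from the image edges and the boundary so boundary
mixing cannot contaminate region statistics. Sub-seeds for the two halves
are spawned from `numpy.random.SeedSequence(seed)` (child 0 = lesion,
1 = sound), making every phantom a pure function of its config.

**Default experiment.** The packaged 4-group experiment uses 8 phantoms per
group at 700×700 px, grain 1.5, with (N_sound, N_lesion) =
(3,2), (5,3), (8,3), (16,5) and lesion means graded 95→80 against a sound
mean of 120. The analytic CRs — 0.183, 0.225, 0.388, 0.441 — mirror the
graded response an in-vitro erosion model produces across 10–40 min etching
groups; the pairs were chosen once from the 1 − √(N_l/N_s) law.

**What the phantom does and does not emulate.** It reproduces the intensity
statistics (exponential law, controlled grain, 1/√N contrast, region-wise
mean and contrast differences) but none of the physics of enamel — no prism
microanatomy, no partial polarization, no camera read noise or quantization
beyond the optional 16-bit export, no illumination falloff. Passing tests
therefore demonstrate that the *analysis* recovers known speckle statistics
correctly, not that erosion in real teeth produces any particular CR value.

**Distribution validation.** `validate_exponential` runs a one-sample
Kolmogorov–Smirnov test of subsampled intensities against the exponential
law parameterized by their own sample mean. Subsampling at ≥ 4× grain
spacing decorrelates neighboring grains so the i.i.d. null approximately
holds; fitting the mean makes the test mildly conservative, which is the
safe direction for a validity gate.

## Statistical battery

All p-values are two-tailed and α = 0.05 throughout.

- **Pearson correlation** (duration vs group mean CR): r by the
  product-moment formula, p from t = r·√((k−2)/(1−r²)) on k−2 df; |r| = 1
  returns p = 0. At k = 4 the tail has the closed form 1 − |t|/√(2+t²),
  which the implementation matches to 6 decimals. The reference computation
  correlates the four *group means* with duration, which reproduces the
  published r = 0.9737, p = 0.0263 exactly.
- **One-sample t-test** against the 0% reference. The source protocol names
  no test for this comparison; a two-tailed one-sample t is the natural
  member of the parametric battery behind a Shapiro–Wilk gate.
- **One-way ANOVA**: classical between/within decomposition, F = MSB/MSW,
  p from the F distribution. Cross-checked against `scipy.stats.f_oneway`
  and against F = t² for two groups; type-I error calibrated at 5% ± 2% on
  2000 null replicates.
- **Tukey HSD** (Tukey–Kramer for unequal n): q = |mean_i − mean_j| /
  √(MSW/2·(1/n_i + 1/n_j)), adjusted p from scipy's studentized-range
  distribution.
- **Shapiro–Wilk** (scipy's W) is a *gate*: p ≤ 0.05 logs a warning but the
  parametric path proceeds, because this package implements only the
  parametric analysis; nonparametric fallbacks are out of scope.

## Pipeline and reproducibility

A run manifest is plain text (CSV + JSON sidecar); all outputs are CSV,
JSON and PNG; the run log records the package version, every effective
parameter, every output path and every exclusion, and all simulation
randomness flows from one master seed. CLI exit codes: 0 success, 2 partial
(some samples failed, run completed), 1 fatal.

## Problem sizes used in the test suite

The suite validates the speckle laws at 512×512 (KS tests, 1/√N law) and
runs phantom-recovery and graded-experiment checks at 320×320 with 20 seeds
per configuration — large enough that the Monte-Carlo error on a mean CR is
~0.002 while the whole suite completes in well under a minute. Recovery at
the full 700×700 geometry is identical in expectation (contrast statistics
are intensive; image size only shrinks the variance) and is exercised by
the default CLI experiment.

## Known limitations

- Sample contrast carries a small negative finite-sample bias (correlated
  pixels within a 4×4 block reduce the expected sample variance); the bias
  largely cancels in the contrast *ratio* when both regions share the same
  grain, leaving a residual ~0.01–0.02 underestimate of CR at grain 1.5.
- Block membership by top-left pixel makes region edges coarse at the
  window scale.
- No image registration between white-light and laser frames, no RAW
  support, no demosaicing: images are assumed already interpolated by the
  camera. Saturation is never removed, only warned about (> 1% saturated
  pixels), because clipped pixels truncate the exponential law.
- CR is not calibrated to mineral loss or lesion depth; no such calibration
  data exists in scope.
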