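# Methods

`mammoiq` computes physical image-quality metrics for mammographic
acquisitions from repeated phantom images. This note records the models
behind each metric, the defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical choices that
affect reproducibility.

## Input model

Every metric consumes an `ImageStack`: n repeated, co-registered 2-D
acquisitions of the same phantom with a pixel pitch in mm. Pixel values are
treated as given linear detector units ("ADU"); no raw/processed
distinction is made. Coordinates are 0-based row-major `(row, col)`, ROIs
half-open. Physical margins (e.g. excluding 1 cm of phantom edge before
uniformity analysis) convert to `round(margin/pitch)` pixels per axis —
exact for the pitches of interest (10 mm is 200 px at 0.05 mm, 100 px at
0.10 mm).

## SNR map and nonuniformity index

From n ≥ 2 repeats, per-pixel mean and SD maps give SNR = mean/SD. The SD
uses the sample convention (n−1): unbiased in variance at the n = 10 this
is designed for, and stated explicitly so results are reproducible. Pixels
with exactly zero SD have undefined SNR; they are flagged invalid and
excluded from block statistics rather than zero-filled, which would bias
the block minimum downward.

The nonuniformity index over the per-block means m_i of the SNR map is

    NUI = (max m_i − min m_i) / ((max m_i + min m_i)/2).

NUI is scale-free, so it is computed on the un-normalized SNR map; dividing
the map by its maximum (the display convention) cancels exactly, which the
test-suite asserts. Default block size is 5 mm of detector — 100 px at
0.05 mm pitch, 50 px at 0.10 mm — so block statistics sample the same
physical gain-field area at either pitch. Blocks must tile the analysis
region exactly; a 4000×3200 region in 100×100 blocks gives 1280 blocks.

## Noise power spectrum

Noise images are differences of two same-condition acquisitions:
fixed-pattern structure cancels, stochastic variance doubles. Two pairing
schemes: `circular` (image k minus image k+1 mod n; n noise images from n
acquisitions, correlated but mean-unbiased) and `independent` (disjoint
pairs, n/2 images). Circular is the analysis default; variance-sensitive
estimates and oracle tests use the independent scheme.

For each noise ROI (default centered 128×128), the ROI mean is subtracted,
the 2-D DFT taken, and the squared modulus scaled by ΔxΔy/(NxNy); the
average over noise images is halved for the subtraction. No apodization
window is applied: difference images carry no fixed-pattern gradient, and a
config flag exists for data where that assumption fails. Units are
ADU²·mm²; for white noise of SD σ the spectrum plateaus at σ²ΔxΔy and
integrates back to σ² (Parseval), which acceptance checks at the 5% level.

1-D summaries: a radial profile (annular mean over |f|, DC excluded, bins
beyond the smaller axial Nyquist discarded) and axial profiles built from
the 3 frequency lines adjacent to — not on — each axis, following standard
detector-NPS practice since the on-axis lines carry residual row/column
pattern; ± frequencies are folded. Anisotropy ratios NPS_x/NPS_r and
NPS_y/NPS_r are formed on common bins (radial profile linearly
interpolated), and a two-sided Wilcoxon signed-rank test of the log-ratios
against zero asks whether a direction systematically departs from the
radial average. The signed-rank test was chosen over a t-test because the
per-bin ratio distribution is skewed and bin counts are modest; its type-I
rate is calibrated (~5% at α = 0.05) in the test-suite. Note the test is
exact-null over frequency bins of a single spectrum estimate; it detects
systematic spectral anisotropy, not acquisition-to-acquisition variability.

## Mass CNR

CNR = (mean_signal − mean_background)/SD_background, with the background
taken from the *same* local ROI (default 300×300 px at 0.05 mm, 150×150 at
0.10 mm) after masking the mass — a local background avoids bias from
spatially varying gain and from edge-enhancement halos around the mass in
reconstructed images. Default segmentation ("geometric"): Gaussian smooth
at 1/4 the nominal radius, locate the extremum blob (polarity
auto-detected; a MAD-based check raises `CentroidUnstableError` when no
blob stands 4 noise-SDs above background), take the intensity-weighted
centroid, and mask a disk of 1.2× the nominal radius — the dilation keeps
halo pixels out of the background statistics. An Otsu-threshold method is
available for irregular objects. The background SD uses the same n−1
convention as the SNR module.

## Slanted-edge MTF

Chain: per-scan-line subpixel edge location (centroid of the absolute
finite difference in a ±8 px window around the strongest transition, with
a noise-floor check per line) → edge angle by least-squares regression of
edge coordinate on line index → composite ESF from every pixel's signed
perpendicular distance to the regressed line, pooled into 0.1-px bins →
4-parameter fit ESF(x) = a + b·erf((x−x0)/(σ_e√2)) → analytic LSF (a
Gaussian of SD σ_e, area 2b) sampled at 1/4 pixel pitch over ±8σ_e → DFT,
zero-padded 8× for fine frequency sampling, normalized at f = 0 → f50/f10
by linear interpolation at the first downward crossing, reported up to the
detector Nyquist 1/(2·pitch).

Choices and rationale:

- **Erf model, analytic derivative.** Under low-contrast, scattered
  conditions the raw ESF is noisy; fitting the erf model and
  differentiating analytically is exact for the modeled family and needs
  no window. The RMS fit residual is always reported, and a model-free
  numerical-differentiation LSF (`lsf_numeric`) exists as a cross-check,
  because an erf cannot represent long scatter tails.
- **Frame pooling.** Repeated edge acquisitions are pooled at the
  ESF-binning stage with per-frame edge regression (robust to inter-frame
  drift), not MTF-averaged; both behaviors are reachable through the API.
- **Binning.** Distances are binned in pixel units with floor(x+0.5):
  round-half-to-even would alternately empty bins when distances fall
  exactly on bin edges (the axis-aligned degenerate case). An angle of
  0.5–5° gives uniform subpixel phase coverage; outside that the composite
  ESF raises if central bins go unfilled.
- **Accuracy.** For a Gaussian PSF of SD σ the closed forms
  f50 = √(ln2/(2π²σ²)) and the analog with ln10 hold; the full chain
  recovers f50 to ~2·10⁻⁵ relative noise-free and well inside 5% at 1%
  noise with 10 frames, and recovers generated angles of 0.97°/1.54°
  within ±0.05° at 1% noise.

## Contrast-detail scoring

The phantom model is a 16×16 grid: rows are gold-disk thicknesses
(default 0.03–2.0 µm, geometric), columns diameters (0.06–2.0 mm,
geometric); each cell holds a center disk plus one eccentric disk at one
of four corner positions (offset cell/4 along both axes). Scoring is a
4-AFC task: a transparent template-matching observer correlates a
zero-mean disk template of the cell's diameter — rendered with the same
rim model as the synthetic disks and blurred by the configured system
PSF — at the four candidate positions after patch-mean subtraction, and
picks the argmax (ties break deterministically to the lowest corner
index). On noise-only cells the observer is correct 25% ± 2% over 4000
presentations. Per-image phantom jitter is handled by registering the grid
to the known, configured offsets; the observer does not re-estimate the
grid from the image.

Thresholds at the conventional 62.5% level (midpoint of guess rate 0.25
and 1):

- **CD curve** (threshold thickness per diameter): least-squares fit of
  p(t) = 0.25 + 0.75/(1+exp(−k(ln t − µ))), solved at the level (at 62.5%
  the threshold is exactly e^µ); falls back to monotone interpolation in
  ln t; thresholds clamped at the thickness range bounds are flagged.
- **Threshold diameter per thickness row** (the D_min entering IQFinv):
  the discrete rule — smallest diameter detected in ≥ 62.5% of
  presentations; rows where nothing qualifies return the largest diameter,
  flagged. The fitted rule serves the CD curve and the discrete rule
  serves the index; both are exposed.

IQFinv = 100/Σ_{i=1..16} C_i·D_{i,min} with C_i in µm and D in mm, reported
unitless. IQFinv values are observer-dependent: scores from this
template observer are comparable across configurations scored by the same
observer, not across different readers (human or plugin-based), so only
orderings and formula behavior carry over to other readers.

## Synthetic generators

Generators produce the statistical structure each analysis assumes, with
ground truth recorded, so the pipeline is testable end-to-end without
acquired data:

- **Flat fields:** mean × polynomial gain field + Gaussian noise, white or
  colored (anisotropic Gaussian kernel, then rescaled to the target
  marginal SD so anisotropy tests isolate spectral shape from total
  power); optionally signal-dependent (∝ √gain).
- **Edges:** background + contrast·Φ(d/σ_psf) sampled at pixel centers —
  the ESF is then *exactly* erf with spread σ_psf, making the Gaussian-MTF
  closed forms exact ground truth.
- **Masses:** antialiased disk + blur + noise; analytic CNR = contrast/SD
  in the zero-blur limit.
- **CD grids:** disk amplitude = thickness × contrast-per-µm (default
  30 ADU/µm against 15 ADU noise, placing the detection transition inside
  the thickness ladder), PSF blur, per-image integer-pixel jitter (integer
  by default to avoid interpolation confounds in observer tests), noise
  added after the shift. Cells are 4.8 mm (96 px at 0.05 mm): the smallest
  size at which the 2.0 mm disk fits beside the corner position.

Two presets bundle the comparison conditions, 10 repeats per phantom:
**DM-like** (0.05 mm pitch, σ_psf 0.08 mm, white noise SD 15 ADU, flat
gain) and **SM-like** (0.10 mm pitch, σ_psf 0.17 mm, noise colored along x
with 0.12 mm correlation length and 1.7× SD, 10% gain gradient) —
caricatures of a direct-conversion detector versus a reconstruction-blurred,
noise-amplified synthesized view. Under these presets every cross-metric
ordering holds: NUI_DM < NUI_SM, the SM x-anisotropy test rejects while
DM's does not, f50/f10 higher for DM, CNR_DM > CNR_SM at every mass size
(ratios ≈ 1.5–1.7 under the defaults), IQFinv_DM > IQFinv_SM with SM
thresholds elevated most at small diameters.

What the generators do **not** emulate: X-ray transport, scatter, AEC,
detector cascades (noise is additive Gaussian, not quantum-cascade),
vendor reconstruction algorithms, or anatomical backgrounds. Passing tests
therefore demonstrate correctness of the estimators and the qualitative
mode orderings under controlled statistics — not agreement with any
particular scanner's absolute numbers.

The CNR comparison uses the accreditation-phantom mass ladder
{20, 10, 7.5, 5} mm scaled 1:4 to {5, 2.5, 1.875, 1.25} mm so every mass
fits its local 15 mm analysis ROI with background to spare.

## Numerical notes and limitations

- All stochastic steps take explicit seeds; identical config + inputs give
  identical reports.
- The anisotropy test's p-value is uniform under isotropic noise by
  construction, so "no significant anisotropy" is itself a statistical
  statement with α false-positive probability.
- `freq_at_mtf` returns the Nyquist frequency, flagged by equality, when a
  level is never reached within the band.
- Problem sizes in the test-suite and the acceptance script (128² NPS
  ROIs, 256²/128² edge ROIs, 400²/200² flat fields, 10 repeats, 4.8 mm CD
  cells) are the package's standard desk-scale configurations; all scale
  up through the config objects.
- Degenerate inputs raise rather than guess: zero-SD pixels in all blocks,
  empty ESF bins at too-small slant angles, undetectable mass blobs,
  all-identical anisotropy ratios, fully-undetected CD columns (flagged
  bound, not an error).
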