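# Methods

This note documents the models, defaults, and design choices behind
`ffakit`, and what the synthetic validation does and does not
demonstrate about real angiography data.

## Pipeline model

A fundus fluorescein angiography (FFA) series is an ordered set of
grayscale frames of one eye in one session, each timestamped in seconds
post-injection. The pipeline treats intensity as a unitless float in
[0, 1] from the moment of decoding (normalized by container bit depth),
so all downstream arithmetic is camera-independent; absolute
radiometric calibration is out of scope, which is why the headline
readouts are within-eye ratios (percent change between sessions) rather
than absolute intensities.

Acquisition-time recovery tries configured sources in order (default:
embedded metadata → filename pattern → CSV sidecar → burned-in
timestamp). Burned-in `mm:ss` overlays are decoded by normalized
cross-correlation against a packaged 5×7 digit atlas rather than a
general OCR engine: the character set is ten digits and a colon, the
match threshold is 0.7, and two templates within 0.02 correlation raise
an ambiguity error instead of guessing. DICOM `AcquisitionTime` is used
only when the study config supplies the injection clock time to anchor
it.

## Registration

Frames are aligned to the series' brightest frame (mean intensity
inside the field of view), i.e. the early bright phase, which has the
strongest vascular contrast. Two strategies are dispatched by species:

* **Keypoint (primates).** FAST segment-test corners (arc length 9,
  radius-3 circle, threshold 0.04 in normalized intensity), scored by
  the largest threshold at which the corner survives, 3×3 non-maximum
  suppression, at most 15,000 keypoints retained per image. Each
  keypoint gets an intensity-centroid orientation over a radius-15
  patch and a 256-bit steered binary descriptor; the sampling pattern
  is a constant table (a fixed-seed PCG64 draw, identical on every
  platform) so descriptors are machine-independent. Matches pass a 0.8
  best/second-best Hamming ratio; a similarity transform is fitted by
  RANSAC (2,000 iterations, 2 px inlier tolerance, seed from config)
  and refined by complex least squares on the consensus set. The
  transform class is similarity because fundus cameras rotate and zoom
  slightly between captures.
* **Frequency (rodents).** Hann-windowed phase correlation; the
  translation is the argmax of the inverse-transformed normalized
  cross-power spectrum, refined to sub-pixel by upsampled local
  correlation. Murine frames rarely yield enough stable corners for
  descriptor matching, while their motion is predominantly
  translational. `peak_ratio` (main peak over the best non-adjacent
  peak) measures how committal the correlation surface is.

Exclusion gates, applied per frame with reason codes: mean FOV
intensity < 0.02 (blink/dark), Laplacian energy < 10% of the
reference's (defocus), < 50 keypoints, < 10 RANSAC inliers, mean
inlier residual > 3 px, or peak_ratio < 1.5. A series with more than
half its frames excluded fails outright. These thresholds are package
choices; the quality-gate *concept* (bad frames excluded, not
silently averaged) is the contract. Aligned frames are resampled
bilinearly; pixels pulled from outside the canvas are flagged invalid
and ignored by the projection and by all regional statistics.

## Regional quantification

Primate analysis uses the standard ETDRS partition — 1 mm central disk
(fovea), 1–3 mm annulus (parafovea), 3–6 mm annulus (perifovea), and
the remaining FOV (extrafovea) — around an explicitly supplied macula
center; there is deliberately no automatic fovea detection. Radii in
pixels are `(d/2)·1000/pixel_scale_µm`; without a pixel scale a
fractional fallback of (0.055, 0.165, 0.33)×image width is used and
flagged. Rasterization is pixel-center-in-region, so the three inner
regions tile the 6 mm disk exactly. Mice have no macula; the whole FOV
is one region.

Large vessels are bright tubes in FFA and would swamp the parenchymal
leakage signal, so they are masked before averaging: Sato tubeness
(bright-ridge polarity) at large-vessel scales (default σ =
2–8 px), thresholded at a quantile of the in-FOV response (default
0.85) and dilated 3 px to cover anti-aliased tube skirts and
resampling smear. The quantile/dilation defaults were set by measuring
residual vessel contamination of the parenchymal mean on generator
scenes with known vessel masks; they are config knobs because the
right coverage depends on how much of the field the resolved
vasculature occupies (a sparser tree wants a higher quantile). A mask
covering more than half the FOV raises rather than silently eating the
analysis region.

Illumination correction (white top-hat, disk radius ⌈min(h,w)/8⌉) is
available for the registration path but intensities are always
extracted from the aligned *raw* frames: diffuse leakage is a broad,
low-frequency signal, and any morphological high-pass would subtract
exactly the quantity being measured.

## Temporal metrics

Real timestamps jitter around the acquisition schedule, so records are
snapped to the nominal grid (default 30–600 s every 30 s) within 25% of
the step; collisions keep the nearer frame. Cumulative intensity sums
only timepoints present in *every* series of the cohort, so missing
captures cannot bias the sum. Phase windows follow angiographic
convention: early [0, 60) s, intermediate [120, 240] s, late
(240, end] s; the 60–120 s gap is intentionally unassigned. Decay
profiles are percent-of-maximum with a clearance time at the first
post-peak crossing of a configurable threshold (default 50%). The
circadian readout is per-subject percent change, `100·(PM−AM)/AM` of
the chosen metric, averaged across subjects (mean headline, median also
reported) — per-subject-first, because that is the quantity the paired
tests operate on.

## Statistics

The paired AM/PM comparison is gated by an Anderson–Darling normality
test **on the paired differences** (the quantity the paired *t*
assumes normal): case-3 statistic (mean and variance estimated),
small-sample adjustment `A²* = A²(1 + 0.75/n + 2.25/n²)`, verdict
banded against the standard critical values (0.752 at α = 0.05, 1.159
at 0.005; the 0.0005 band bound, 1.565, comes from the standard
upper-tail approximation since printed tables stop earlier). Normal →
paired *t*; otherwise Wilcoxon matched-pairs signed-rank, two-tailed,
zeros dropped (classic, not Pratt), mid-ranks for ties, exact p by
dynamic programming over sign assignments up to n = 25 and a
tie-corrected, continuity-corrected normal approximation beyond. Data
are never transformed toward normality; the test switches instead.
With fewer than 8 pairs the gate is undefined and the nonparametric
branch is used.

Designs with both eyes per subject use a linear mixed model (fixed
session effect, optional group and interaction for the two-way form,
subject random intercept, REML via statsmodels MixedLM); a singular fit
falls back to the fixed-effects OLS analogue with a logged note.
Families of comparisons carry Šidák-adjusted p values,
`1−(1−p)^m`, computed via `expm1/log1p` to survive tiny p.

## Synthetic study model

The generator exists to give every stage a checkable oracle. One
subject-session is: a recursive bifurcating vessel tree (Murray-style
child widths `w·2^(−1/3)`, default 6 trunks, depth 4, trunk width 6 px
at the default 256 px image) over a two-scale Gaussian random texture
(σ = 2 and 6 px, amplitude 0.035) emulating background fundus
granularity, inside a circular FOV (radius 0.46×image) with radial
vignetting (strength 0.15) and a dark surround.

Dye kinetics: vascular term `K·x^α·e^{α(1−x)}` with
`x = (t−t0)/(αβ)` (a gamma-variate normalized to peak K at
`t0+αβ` = 30 s), plus a leakage term `L·(1−e^{−(t−t0)/τ_L})`
rendered as spatially uniform extravascular background — leaked dye is
diffuse, not vessel-bound. Defaults: t0 = 2 s, α = 0.15, β = 186.67 s,
K = 0.55, L = 0.025, τ_L = 120 s, giving a fast fill, a 30 s peak, a
slow recirculation-like decline that keeps vessels visible (hence
registrable) through the late phase, and a whole-field mean that peaks
early and settles to a leakage-dependent plateau. The circadian dial is
δ: `L_PM = (1+δ)·L_AM`. Per-subject variation: L lognormal (15%), K
lognormal (5%), background level N(0.08, 0.005). Motion is rigid jitter
of the whole imaged field (uniform ±6 px, ±2° for primates) — i.e. the
applied transform is exactly what registration must recover. Noise is
additive Gaussian (σ = 0.01) plus signal-dependent Gaussian
(0.02·√I). Scene and noise use separate RNG streams so anatomy can be
held fixed while motion/noise vary.

The ground-truth JSON stores per-frame transforms, noiseless region
means, and the analytic late-phase percent change per subject:
`100·δ·L·ḡ/(b0+L·ḡ)` with ḡ the mean leakage saturation over
late timepoints — vignetting and texture means cancel in the ratio.

**What passing does and does not show.** The simulator validates the
machinery: geometric recovery, masking selectivity, metric arithmetic,
statistical calibration, and that the pipeline's estimate tracks a
known injected effect through every stage. It does not certify
performance on real data: real FFA has non-rigid eye motion within
frames, pathology, media opacity, capillary-scale structure, vendor
overlays, and gain drift, none of which are modelled. The residual
~0.3–0.5 point downward bias of the recovered percent change relative
to the analytic value is real and understood: unmasked vessel light
adds a session-independent pedestal to the parenchymal mean, diluting
the ratio; tighter masking shrinks it at the cost of analysis area.

## Problem sizes

Default validation sizes, chosen for desk-scale runs: 256×256 px
frames, 20-frame schedules, 15-subject cohorts for end-to-end recovery;
50 seeded alignments for registration recovery; 100–1000 Monte-Carlo
replicates for test calibration (enough that the MC standard error is
small against the calibration bands). All are configuration, not
constants.

## Known limitations

* Cross-session (longitudinal) registration is not implemented; AM and
  PM series are analyzed in their own frames of reference, which is
  sufficient for region-level means but not for pixel-level maps.
* Frequency-domain registration recovers translation only; rotation
  would need a log-polar extension.
* The vessel mask is intensity-ridge-based; it does not separate
  arteries from veins and will under-mask vessels far from the
  configured scales.
* No pharmacokinetic modelling: the leakage readout is a relative
  signal change, not a permeability coefficient.
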