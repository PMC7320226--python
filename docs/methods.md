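# Methods

## Pipeline model and assumptions

The package implements the classical NIR-HSI diagnosis chain for two tissue
classes (normal, cancerous) on a dark background:

1. **Reflectance calibration.** `R = ρ (I − D)/(W − D)` with a white panel
   of certified reflectance ρ and a lights-off dark frame. The white
   reference may be a full frame or a per-band vector (panel-averaged). With
   a vector white, the spatial part of the illumination field is *not*
   divided out and survives as a per-pixel multiplicative factor — the
   regime in which the spectral angle classifier's scale invariance matters.
   Calibrated values are clamped to [0, 1.5] (count logged); noise can push
   values slightly past 1, and a loose cap bounds outliers without erasing
   signal.
2. **Background masking.** One band (default 1181 nm, nearest grid center)
   is thresholded — Otsu by default, fixed value on request. Pixels above
   threshold are scene; all later statistics use scene pixels only.
3. **Grow-ROI spectrum extraction.** A seed of the `n` in-mask pixels
   nearest a chosen point (ties row-major) defines frozen per-band
   statistics; the ROI is the connected component (8-connectivity default)
   of pixels within `mean ± max(m·std, floor)` of the seed *at every band*.
   Freezing the seed statistics makes the fixed point independent of visit
   order, so the implementation computes it directly as a connected
   component of the static acceptance map (tests verify equality with a
   literal breadth-first growth). Standard deviations are population ones
   throughout. The per-band acceptance rule is deliberately strict — a
   scalar-summary rule would admit more pixels; see "Growth multiplier"
   below for the consequence.
4. **PCA band selection.** PCA of the pooled, band-mean-centered training
   pixels (SVD of the centered table; eigenvalues are sample variances,
   divisor n−1; loading sign fixed so each vector's largest-magnitude entry
   is positive). Wavelengths are selected at interior local extrema of the
   leading loading curves whose prominence is ≥ 15% of that component's
   loading range (endpoints excluded). Centering only, no per-band variance
   scaling: reflectance bands share units, and correlation-mode PCA would
   reweight the extrema.
5. **SAM classification.** One pooled reference per class (pixel-count-
   weighted mean over all training ROI pixels, restricted to the selected
   bands; band-set wavelengths resolve to the nearest grid center, erroring
   beyond half the local band spacing). Each masked pixel gets the class of
   minimum spectral angle; the cosine is clamped to [−1, 1] before arccos;
   ties go to the earlier library entry (count logged); no rejection
   threshold by default.
6. **Evaluation.** Accuracy (TP+TN)/total with cancer positive, plus
   sensitivity and specificity; pixels are pooled across test scenes for
   the headline number and a per-scene table is written alongside
   (unclassified pixels count as errors; truth codes outside
   {normal, cancer} are excluded).

### Components examined

By default the smallest set of leading components whose cumulative variance
fraction reaches 97% is examined — restricted to components that
individually explain at least 1%. The floor is a noise guard: with
measurement noise the eigenvalue spectrum has a long flat tail, and the
unrestricted cumulative rule would drag in dozens of noise components whose
loading wiggles are meaningless. If 97% is unreachable within the eligible
components, all of them are used. An explicit component list overrides the
rule. On the default phantom study this yields {PC1, PC2}.

## The phantom generator

The generator emulates the structure of *ex vivo* specimen acquisitions:
168 bands over 900–1700 nm (~5 nm spacing), 14-bit counts, a dark plastic
background, a central tissue slab (~70% of the frame) with elliptical
cancerous lesions, a white panel imaged under unit illumination, and a
lights-off dark frame.

Endmembers follow `R_c(λ) = B_c(λ) · (1 − Σ_k A_ck · g(λ; μ_k, σ_k))` with
linear baselines (normal 0.30→0.38, cancer 0.42→0.52 across 900→1700 nm —
cancerous tissue brighter everywhere) and Gaussian features at
μ ∈ {975, 1075, 1215, 1275, 1390, 1450} nm. Positive depths are absorption
dips — 975 (O–H second overtone, weakest), 1215 (C–H second overtone),
1450 (O–H first overtone, strongest) — and negative depths are the
reflectance shoulders between absorption bands (1075, 1275 nm). Depths:
normal {0.08, −0.08, 0.14, −0.09, 0.05, 0.18}, cancer
{0.145, −0.12, 0.20, −0.15, 0.034, 0.26}; widths {20, 20, 20, 20, 25, 14} nm.

The alternation of dips and shoulders is deliberate: on a discrete loading
curve, local extrema alternate max/min, so two same-sign neighbouring
features always bracket a saddle extremum of equal prominence between them.
A design with six same-sign dips therefore cannot yield exactly six selected
wavelengths at the feature centers — the selection would include off-center
saddles. With the alternating design the five class-contrasting features
appear as clean PC1 extrema.

The 1390 nm band is different: its mean depth is nearly class-neutral
(0.05 vs 0.034 cancels against the baselines), but its depth fluctuates
pixel-to-pixel in both classes (Gaussian, σ = 0.116 in depth units, width
25 nm) — a "hydration variability" mode. That mode forms the second
principal component, whose loading peaks at 1390 nm, so the sixth wavelength
enters through PC2 while PC1 contributes the other five — reproducing the
reported structure in which one optimal wavelength originates from the
second component and the leading two components carry ~95% + ~3% of the
variance.

Forward model: `counts = dark + gain · L(λ) · R · illum(row, col) + ε`,
with `gain = (white_level − dark_level)/ρ_panel`, a fixed lamp envelope
`L(λ)` peaking near 1300 nm, a smooth random low-order polynomial
illumination field of amplitude 0.15 (unit mean; the field's random
coefficients are drawn even at amplitude 0, so studies differing only in
amplitude are draw-for-draw paired), and additive Gaussian noise of
σ = 170 counts — about SNR 25 in reflectance at mid-scale, i.e.
σ_R ≈ 0.014. Counts are rounded and clipped to the 14-bit range by default;
`quantize=False` keeps float counts so that calibrating a noiseless,
gradient-free scene recovers the endmembers to machine precision (with
quantization the recovery is within one count, ~1e-4 in reflectance).
`PhantomConfig.noiseless()` switches off noise, illumination gradient,
hydration variability and quantization together.

A study spawns per-scene random streams from one master seed
(`numpy.random.SeedSequence`), making the whole study bit-reproducible.
Training scenes carry auto-generated seed points: the deepest interior
point (Euclidean distance transform) of the lesion and of the normal
region.

The closed-form class-contrast profile — baseline difference minus the
difference spectrum, i.e. cancer's excess absorption — thresholded at half
its maximum yields exactly three contiguous wavelength regions, intersecting
950–1050, 1150–1250 and 1400–1500 nm. (Thresholding the raw difference
spectrum itself would be dominated by the baseline brightness gap rather
than the absorption structure.)

### What the phantom does *not* model

No radiative transfer or photon migration; hard class edges (no spectral
mixing at lesion borders); no specular glare or moisture films; no
inter-patient spectral variability beyond the hydration mode; noise is
Gaussian and signal-independent. Passing the phantom study therefore
demonstrates the pipeline's correctness and its illumination insensitivity,
not clinical performance on real tissue.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `mask_band_nm` | 1181 nm | band thresholded for the background mask |
| `mask_method` | `"otsu"` | parameter-free threshold; fixed value for reproducible overrides |
| `seed_pixels` | 4 | seed size for ROI growth |
| `std_multiplier` (module) | 0.2 | growth tolerance in seed-std units |
| `std_multiplier` (study config) | 12 | see below |
| `zero_std_floor` | 0.01 | absolute tolerance where the seed std is 0 |
| `connectivity` | 8 | neighbourhood for growth |
| `prominence` | 0.15 | extremum filter, fraction of loading range |
| `cumulative_variance` / `variance_floor` | 0.97 / 0.01 | component rule |
| `max_angle` | none | optional SAM rejection threshold (radians) |
| phantom `noise_sigma` | 170 counts | ≈ SNR 25 in reflectance at mid-scale |
| phantom `illumination_amplitude` | 0.15 | multiplicative field range ±15% |
| phantom `variability_sigma` | 0.116 | hydration-mode depth std |

**Growth multiplier.** The historical tolerance for this procedure is "20%
of a standard deviation", and `grow_roi` keeps 0.2 as its default. But that
convention originates from tools whose acceptance test is a scalar summary;
here acceptance is per-band over all 168 bands, and the probability that a
noisy pixel passes 168 simultaneous ±0.2σ̂ tests is essentially zero — a
4-pixel seed then never grows. The committed study config therefore sets
the multiplier the way practitioners do: raise it until the grown region
covers the lesion while containing only lesion pixels. A sweep over master
seeds shows 100% class purity of grown ROIs (zero impure pixels out of
>110 000 grown) for multipliers up to at least 15, with ROIs of hundreds to
thousands of pixels from 10 upward; the study default is the midpoint, 12.
Degenerate growth is not silently harmful — it only starves the references
(20 pixels per class) and costs several accuracy points — but the grown
regime is both more faithful to the published procedure and more stable.

## Numerical choices

- PCA via SVD of the centered table (stable for many pixels); tests verify
  agreement with a brute-force covariance eigendecomposition to 1e-8 and
  with scikit-learn.
- Loading extrema via `scipy.signal.find_peaks` on ±loading with an
  absolute prominence of `prominence × (max − min)`; strictly interior.
- SAM cosine clamped to [−1, 1]; double precision throughout.
- Otsu threshold from scikit-image; uniform band images short-circuit to a
  degenerate mask with a warning instead of erroring.
- Seed tie-breaks: lexicographic (distance, row, column) — deterministic.
- ENVI I/O supports data types 1/4/5/12 and both byte orders; unknown
  header keys are preserved in `meta` and logged, never fatal.

## Problem sizes

Default scenes are 96×96×168 (the spatial scale of a few-centimetre
specimen at ~0.8 mm/pixel); the default study is 5 training + 24
verification scenes and runs in well under a minute on one core, so the
full acceptance study is recomputed from scratch on every run rather than
cached. The scaled-down scenes used in unit tests (48×48, 20×20) keep the
same spectral axis.

## Known limitations

- One pooled reference per class; multi-reference libraries per class are
  not implemented (the `ReferenceLibrary` is n-class general, though).
- The six-wavelength outcome is a property of spectra whose features are
  prominent and alternating at the 0.15 prominence level; on other data the
  extrema rule can select more or fewer bands — that is inherent to the
  method, not a defect.
- `run_study` writes masks, ROIs, reports, maps and metrics always, but
  raw/reflectance cubes only with `save_cubes=True`, to bound disk use.
- No ROC sweeps or confidence intervals; the evaluation mirrors the plain
  confusion-matrix protocol.
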