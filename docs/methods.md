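# Methods

## Scope and model

`selfrefocm` simulates spectral-domain optical coherence microscopy (OCM)
of the in vivo mouse cornea and implements the automated segmentation of
Descemet's membrane (DM) used to map its thickness. The central physics is
the contrast between two interference channels recorded from the same
scan:

* **Standard (dual-path) channel.** Backscatter from every corneal
  interface beats against a separate reference mirror. The fringe
  frequency of reflector *j* encodes its full optical depth
  `d_j + bulk(t) − z_ref`, plus any group-delay-dispersion (GDD) mismatch
  φ(k) between the arms. Breathing motion (`bulk(t)`), corneal curvature
  and dispersion all corrupt this channel.
* **Self-referenced (common-path) channel.** The saline-smoothed specular
  reflection at the corneal surface serves as the reference. Fringes
  encode only the optical path *difference* `n·(z_j − z_surface)`, so bulk
  motion and curvature cancel exactly and both beams traverse identical
  glass, removing the dispersion mismatch. The reconstructed image is
  flattened and depth is measured from the surface — which is why the
  cross-section appears inverted relative to the standard image.

A-scans are reconstructed exactly as on the instrument: the recorded
background (DC) spectrum and residual mean are subtracted, the 2048-sample
spectrum is zero-padded to 8192 points, and the magnitude of the
single-sided FFT gives 4096 depth pixels.

## Axial calibration and the spectral span

The printed calibration constant — 0.349553 µm per depth pixel in tissue
(n = 1.387, hence 0.484830 µm in air) — is treated as the authoritative
anchor of the instrument geometry; no combination of the nominal source
bandwidth (165 nm), camera pixel count (2048) and padding (8192)
reproduces it from first principles, so it is configuration, not a derived
quantity. With uniform-in-wavenumber sampling the anchor fixes the sample
spacing `δk = π / (8192 × 0.484830 µm)`, which over 2048 camera pixels
implies a sampled span of ≈186 nm about 850 nm.

That span clips the tails of the 165 nm-FWHM Gaussian source at ~41 % of
peak. The clipping convolves the Gaussian coherence envelope with a sinc
and broadens the as-imaged axial point-spread function (PSF) to ≈2.7 µm in
air (≈1.9 µm in tissue) — above the 1.93 µm transform limit
`(2 ln 2/π)·λ₀²/Δλ`, in the same direction as the instrument's measured
widths. Transform-limit validation therefore uses
`SpectrometerConfig.broadband`, which widens the span to 3× the source
k-FWHM so the source is not clipped; there the simulated PSF is 1.937 µm,
0.2 % from theory, and GDD broadens the standard channel monotonically
while leaving the common-path channel untouched.

## Phantom

The cornea is five interfaces over a spherical cap (default radius
1.4 mm, ~0.5 mm FOV): surface, epithelium/Bowman's (epithelium 40 µm),
Bowman's/stroma (Bowman's 2 µm), stroma/DM, and DM/endothelium. Only DM
and stromal thicknesses are quantitatively asserted anywhere, so the other
layers take fixed plausible values (total ≈ 100 µm).

* **Thickness fields.** DM and stroma are stationary Gaussian random
  fields (Gaussian-kernel correlation length, default 50 µm), standardised
  per realization to the requested mean/SD and floored at 0.3 µm. The
  per-group defaults are the published in vivo group values. The printed
  group SDs conflate two levels; the package exposes both: `build_phantom`
  uses the DM SD as within-map variation (DM maps do show comparable
  within-map texture), while the Monte-Carlo eye generator in
  `thickness_stats` uses it as between-eye spread. The stromal group SD
  (up to ±10 µm) is clearly between-animal — a single aligned central FOV
  cannot swing by tens of microns — so the within-map stromal SD defaults
  to `min(group SD, 2 µm)` and is settable.
* **Guttae.** Radially Gaussian bumps (count, amplitude, radius, seed)
  added to the DM thickness; they can only thicken the membrane.
* **Reflectivities.** The specular surface dominates (amplitude 0.5 vs
  ≤0.05 internally) — it must, to serve as the self-reference — and the
  endothelial interface is the strongest internal reflector, as in the
  recorded B-scans.
* **Interface roughness.** Tissue interfaces are rough at the
  sub-wavelength scale, so the echoes of adjacent layers interfere with an
  essentially random relative phase rather than the fixed value
  `2k̄·n·Δz mod 2π` that perfectly smooth boundaries would give. Each
  internal interface carries a laterally correlated random phase field
  (correlation 10 µm — longer than the 5-frame averaging span, so the
  frames inside one window stay mutually coherent, while distant patches
  of the map explore the full circle). The surface stays at zero phase
  (specular). This matters near the resolution limit: whether a
  closely-spaced peak pair merges or splits depends on that phase, and the
  phase diversity across the map is what lets gated detection recover
  thicknesses near 2 µm without systematic bias. Engineering stacks
  (glass slide, PSF reflectors) remain phase-flat.
* **Motion.** Breathing is a seeded sinusoid at the anesthetized breathing
  period (default 1.5 s, physiological range 1–2 s), mean-centred (only
  relative axial position is physical) and normalised so the excursion
  never exceeds the requested amplitude even on records shorter than one
  period.
* **Noise.** Stromal speckle: random scatterers (default 25 per A-scan)
  with complex-Gaussian amplitudes drawn inside the stromal band,
  independent per frame, scaled so the RMS speckle magnitude sits a
  configurable number of dB below the endothelial peak. Detector noise:
  additive white Gaussian on the spectrum at a configurable fringe SNR.

## Segmentation pipeline

1. **Sliding 5-frame average** (stride 1) along the slow axis: 500 frames
   → 496, as on the instrument.
2. **Posterior crop.** The anchor is the strongest peak in the posterior
   half of the frame's mean A-scan (the endothelial band). The crop spans
   35 µm anterior to 5 µm posterior of the anchor (100 µm anterior for
   the stromal variant, to reach Bowman's membrane) and is flipped so the
   endothelium sits ~5 µm from the top. The crop geometry is a package
   design choice; it guarantees by construction that a well-formed
   endothelial peak satisfies the 10 µm first-peak gate.
3. **Contrast stretch + 3×3 median filter**, applied within the crop: the
   full 4096-pixel reconstruction is overwhelmingly empty space, which
   would pin the stretch quantiles to the noise floor. The stretch is
   linear with 1 % tail saturation (the named tool's default); the median
   filter uses reflective borders to avoid dark-edge peak artifacts.
4. **Gated peak detection** per A-scan: local maxima with prominence
   ≥10 % of the profile maximum and ≥2 px separation. First peak
   (endothelium): most prominent candidate within 10 µm of the top (tie:
   shallowest), and at least 3× the profile median in height — a
   noise-floor gate that empties maps of pure noise while never rejecting
   a real endothelial peak, which towers over the dark background of its
   crop. Second peak (stroma→DM transition): most prominent candidate
   strictly deeper, within 7 µm of the first (the mouse DM is thinner
   than 7 µm). Third peak (Bowman's, stromal variant): most prominent
   candidate deeper than the second.
5. **Thickness** = integer pixel separation × 0.349553 µm (no sub-pixel
   interpolation — the instrument's arithmetic is integer pixels), NaN for
   any gate failure; maps carry NaN-aware mean/SD/valid-fraction. Gates
   are applied in µm via the calibration constant. No statistical outlier
   rejection is applied beyond the gates.

## Statistics

Per-eye map summaries are compared with explicit sums-of-squares ANOVA:
one-way `F = MS_between/MS_within`, and a 2×2 genotype × age design with
Type II sums of squares (order-invariant, appropriate for the mildly
unbalanced n = 4 vs n = 5 design; computed by comparing residual SS of
nested effect-coded OLS fits). p-values come from the upper tail of the F
distribution. No multiple-comparison correction is applied, matching the
reported pairwise P values. The report also prints the FECD-vs-WT percent
difference of group means; with the published 5-week means this is 48.1 %
(the derived quantity the data support).

## What the synthetic data do and do not show

The generator reproduces the features the pipeline's correctness depends
on — layer ordering and spacing, curvature, breathing, channel-specific
dispersion, speckle statistics, interface phase randomness — with exactly
known ground truth. It does not emulate depth-of-field/confocal gating,
camera quantum-efficiency roll-off (the likely cause of the instrument's
measured 2.3 µm vs the 1.9 µm theory), galvo distortion, tear-film
dynamics, or endothelial cell morphology. Passing recovery tests
demonstrate that the *segmentation logic* is unbiased at the calibrated
pixel pitch; they do not certify accuracy on real data with those
unmodelled effects.

## Resolution limit of thickness recovery

At the calibrated pixel pitch the as-imaged tissue PSF is ≈1.9 µm FWHM. A
reflector pair 1.0–1.5 µm apart produces a single local maximum for
essentially every interference phase, so gated detection cannot recover
those thicknesses — the corresponding recovery checks fail, by physics,
and are left failing. From ≈1.85 µm upward the roughness-phase diversity
splits enough A-scans that the gated, NaN-excluded map mean lands within
one depth pixel of truth (valid fraction rising from ~0.4 at 1.85 µm to
1.0 at ≥2.7 µm — the same behaviour as the excluded-outlier regions of
the real maps). This mirrors the instrument's own situation: its claimed
1.6 µm in-cornea resolution sits just below the thinnest group mean.

## Problem sizes and numerics

Simulated volumes in the test-suite and acceptance runs use 50 × 12 to
50 × 50 A-scans (full scale is 500 × 500); each A-scan is a full
2048-sample interferogram reconstruction, so all depth-domain physics is
at native scale. Recovery is evaluated at DM thicknesses 1.0–6.5 µm in
0.5 µm steps, noiseless and with 20 dB speckle. FWHM measurements use
linear interpolation of the half-max crossings for sub-sample stability.
Comparisons against printed values round to one decimal for µm widths and
to the nearest integer for the USAF bar width. All randomness flows
through explicit integer seeds; there is no global RNG state, and a fixed
configuration reproduces thickness maps bit-identically.
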