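# Methods

## Measurement model

A vessel cross-section on an OCT B-scan is reduced to a 1-D grayscale
density profile `v(x)` along a user-drawn measurement line (µm positions,
uniform step).  Before any profile is taken the raster is resampled to an
isotropic 1:1 µm/px grid (`aspect_normalize`, bilinear, target pitch = the
finer of the two input pitches), because OCT axial and transverse
resolutions differ (5 µm and 6 µm for the reference device) and distances
are only meaningful on an isotropic grid.  Profile sampling is bilinear at
sub-pixel coordinates; the original workflow's 800 % magnification step is
not emulated as discrete resampling, since the edge crossing is solved
analytically on the continuous chord.

Coordinates are continuous µm with the origin at the top-left *pixel
centre*; a pixel `(row, col)` sits at `(x, y) = (col·pitch_x, row·pitch_y)`.

### FWHM edge localization

Per profile the two vessel walls are the two most prominent extrema of the
3-point-averaged curve at the configured polarity (default `dark_walls`:
walls are valleys), with at least one opposite-polarity lumen extremum
between them.  Profiles failing this are rejected with
`BandDetectionError`, mirroring the manual rule of only measuring images
that clearly show the wall.  Each wall has two flanks, bounded inward and
outward by the *adjacent* qualifying opposite-polarity extremum
(prominence ≥ 5 grayscale by default; if the outward segment has none, its
most extreme sample).  Per flank:

* half level = midpoint of the smoothed maximum and minimum within the
  flank;
* chord = the line through the two consecutive **raw** samples with the
  largest absolute difference in the flank (ties broken toward the pair
  nearest the wall extremum);
* edge = chord ∩ half level, required to land inside the flank.

Numerical choices and their rationale:

* **"Median value between the maximum and minimum"** is read as the
  arithmetic midpoint — the half-maximum convention the method is named
  after — not a statistical median of flank samples.
* **Extrema on the smoothed curve, chord on the raw curve.**  The 3-point
  average is applied to the peak/trough *values* only; the chord wording
  ("largest difference between continuous points") refers to the measured
  samples.  `detect_edges(chord_on="smoothed")` switches the chord to the
  averaged curve for sensitivity analysis.
* **The chord is exactly the line through two consecutive samples** — two
  points determine it; no wider regression window is used.
* **smooth3 endpoints** keep their raw values (no truncated windows); wall
  edges never sit at profile termini.
* **Prominence threshold** 5 grayscale (configurable) suppresses
  speckle-induced micro-extrema during band and shoulder detection.
* **Flank adjacency.**  Bounding flanks by the *nearest* qualifying
  opposite extremum (rather than the single most prominent lumen
  extremum) keeps flanks tight under speckle; otherwise consecutive-sample
  noise on the long lumen plateau can exceed the true edge gradient and
  the chord lands on noise.  On clean profiles both rules coincide.

### Vessel parameters

Outer diameter = span of the outer edge pair; lumen diameter = span of the
inner pair.  Each vessel is measured in triplicate and the replicate
diameters are averaged arithmetically (deviating counts are accepted with
a warning).  Wall thickness is `(outer − lumen)/2`; AVR is computed from
the **averaged** diameters (ratio of means).  The alternative — the mean
of per-replicate ratios — is exposed as `mean_replicate_avr` but cannot
populate an `EyeRecord`, whose invariant fixes `AVR = RAOD/RVOD` exactly.
Published per-arm AVR means are means over eyes, so they need not equal
the ratio of the published column means either.

### Zone B

Two conventions for the measurement annulus around the optic disc are
provided and never conflated: `ring` — the positioning-ring reading, radii
(0.5 D, 0.75 D) from concentric circles of 1 and 1.5 disc diameters — and
`standard` — the conventional zone B, 0.5–1.0 disc diameters from the disc
margin, radii (0.75 D, 1.0 D).  The two disagree; callers choose
explicitly.

## Synthetic phantoms

`render_profile` builds a piecewise-constant template
(background | wall | lumen | wall | background) centred on the profile,
convolves it **analytically** with a Gaussian PSF (each step becomes a
normal CDF, so there is no discrete-convolution error), and optionally
multiplies unit-mean gamma speckle (shape k, variance 1/k) — the standard
surrogate for multiplicative coherent-imaging noise.  `render_bscan` is
the 2-D analogue (lumen disk in a wall annulus, discrete 2-D Gaussian
blur, i.i.d. per-pixel speckle) with ground truth quoted for the vertical
centre line.  Ground-truth edges are the template discontinuities.

Defaults: outer 147 µm / lumen 114 µm (a typical measured arteriole),
pitch 5 µm (device axial resolution), PSF sigma 5 µm, intensities
wall/lumen/background 60/200/140 (dark walls between a mid-gray fundus
background and a brighter lumen interior — arbitrary but documented; all
detection properties are invariant to positive affine intensity changes),
polarity `dark_walls` because the walls present as valleys on the density
curve; `bright_walls` is retained since display inversion varies between
devices.  No published noise or contrast figures exist for the reference
device, so speckle defaults are not calibrated to it; tests that need
noise state their shape parameter explicitly.

What the phantoms deliberately omit: retinal layering, vessel shadowing,
motion artifacts, pulsation, and correlated speckle.  Passing recovery
tests therefore demonstrates correctness of the estimator on idealized
geometry, not clinical accuracy on real B-scans.

### Known estimator bias at wide PSF

For an *isolated* blurred step the half-level crossing sits exactly at the
step.  A wall band of width `t` blurred with sigma comparable to `t/2` is
not an isolated step: the valley minimum is elevated by roughly
`(1 − Φ(t/2σ))·(ΔI_outer + ΔI_inner)`, the observed half level rises with
it, and the crossing shifts toward the background — about 0.8 µm per outer
edge at σ = 5 µm and over 4 µm at σ = 8 µm for t = 16.5 µm, confirmed
against a dense-grid evaluation of the continuous blurred curve.  Edge
recovery is therefore sub-pixel only in the device-realistic regime
(σ ≲ 3 µm for 5 µm axial resolution; mean error ≈ 0.5 µm over random
12–20 µm walls); averaged over σ uniform on [0, 8] µm the mean error is
≈ 1.6 µm noiseless and ≈ 3.3 µm with 10 % speckle.  This is a property of
the FWHM-with-observed-extrema definition itself, not of the
implementation (an independent brute-force oracle of the same definition
agrees to < 0.3 µm).

## Cohort simulation

`simulate_cohort` draws the four diameters (RALD, RAOD, RVLD, RVOD) per
eye from per-arm normal summaries and recomputes AWT, VWT, AVR row-wise,
so the defining identities hold in every record.  Two correlations shape
the joint distribution:

* `lumen_outer_corr` (default 0.9) between a vessel's lumen and outer
  diameter within an eye.  The published wall-thickness SDs (≈ 2.5 µm)
  are far smaller than the diameter SDs (≈ 12 µm), which back-solves to a
  lumen/outer correlation near 0.9; it also keeps negative simulated wall
  thicknesses vanishingly rare.
* `within_subject_corr` (default 0.9) between repeated conditions of the
  same subject (left/right eye, pre/post stenting), equicorrelated via a
  Kronecker covariance (conditions ⊗ variables).  The published paired
  statistics (e.g. paired |t| ≈ 14.8 on a 4 µm shift with ≈ 11.5 µm arm
  SDs at n = 50) imply within-subject correlations of ≈ 0.9–0.99; 0.9 is
  used as a conservative round value.

Artery and vein diameters are drawn independently of each other, so the
simulated AVR spread emerges from the ratio distribution (≈ 0.09–0.10 at
the reference summaries, matching the published 0.09).  `simulate_study`
composes the full layout — control subjects with two eyes, stenosis
subjects with ipsilateral/contralateral eyes before and after stenting —
with arm sizes 59/50 and the reference per-arm summaries as defaults.

## Statistics battery

* Student pooled-variance t is the default independent test — it
  reproduces the published between-group statistics exactly (e.g. RAOD
  t = 4.870), where Welch gives 4.877; Welch remains an option.
* Pearson chi-square without Yates correction reproduces the published
  2×2 statistics (1.456, 2.062, 3.845); Yates is available behind a flag,
  and Fisher's exact p is attached whenever an expected count is below 5.
* All p-values are two-tailed at alpha 0.05; no multiplicity correction is
  applied, matching the study design.
* Paired statistics are computed from per-subject data only: they cannot
  be recovered from printed summary rows, which lack the within-subject
  correlation.
* The Mann-Whitney U uses the exact null for tie-free arms up to n = 25
  and the tie-corrected normal approximation beyond.
* `build_tables` runs the eight within/between contrasts, joining paired
  arms on `subject_id`, routing each parameter through the Shapiro-Wilk
  gate (on differences for paired contrasts, on both arms for independent
  ones), and skipping — with a reason — any contrast whose arms are
  missing.

## Problem sizes in the test suite

Monte-Carlo checks use 2,000 replicate cohorts for type-I calibration and
for the mean-t comparison (MC standard error ≈ 0.005 on the rejection
rate, ≈ 0.025 on the mean statistic), 200 phantoms per edge-recovery
ensemble, and full permutation enumeration for rank-test cross-checks up
to 8 observations per arm.

## Known limitations

* Wide-PSF edge bias, as quantified above.
* No automatic vessel finding: measurement lines are user input (ROI
  files), matching the manual line-placement protocol.
* The cohort simulator reproduces first and second moments and the two
  stated correlations only; it does not model measurement failure,
  missing eyes, or non-normal parameter distributions.
* Speckle is i.i.d. per sample; real OCT speckle is spatially correlated
  at roughly the PSF scale, so noise robustness results are optimistic.
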