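# Methods

## The statistic

A numerosity display is a set of items (usually dark circles) on a
mid-gray background. `numspec` summarizes such a display by its
**aggregate first-harmonic Fourier power**:

1. Normalize the image to 0 on the background and 1 in the items
   (`binary_mask`), or to the signed Weber contrast of each item
   (`signed_deviation`, used for analyses that manipulate contrast).
2. Take the 2-D DFT (unscaled forward transform) and collect the
   magnitude |F(u,v)| into annular bins of 1 cycle/image — bin *k*
   covers radial frequency (k−0.5, k+0.5], k = 1…canvas/2; the DC term
   is excluded. This is the radial power spectral density (PSD).
3. Find the end of the first harmonic *f*₁: the lowest frequency above
   the global PSD peak where the PSD is below 25% of the peak **and**
   the first or second discrete derivative of the PSD attains a local
   maximum. "Attains a local maximum" is evaluated with one bin of
   alignment tolerance, because a forward and a backward difference
   place "the derivative at *f*" half a bin apart; ties break toward
   the lower frequency, and if no candidate exists the global PSD
   minimum above the peak is used. The intent of the rule is to find
   the sharpest change in the spectrum while ignoring single-bin
   ripples from pixelation and DFT discretization.
4. Sum the PSD over bins 1…*f*₁ and divide by canvas² · √2.

With these conventions a single full-contrast circle has power ≈ 1 at
any resolution (measured 0.96–1.02 for diameters 4–200 px on a 768 px
canvas), and power is exactly linear in item contrast. The magnitude
PSD is the definition that reproduces this unit anchor; the
squared-magnitude alternative is available (`psd_definition="power"`)
but is not the default.

**Known limitation (large items).** Once the first spectral minimum
falls below ~4 cycles/image — circles larger than ~200 px on a 768 px
canvas — 1-cycle annular bins can no longer isolate it; the detector
lands on the second minimum and the power rises to ~1.45. This is the
high-diameter analogue of the inaccurate-rendering caveat at diameters
below 3 px. Property tests therefore assert size invariance over
4–200 px.

The **second harmonic** is obtained by re-applying the same detection
rule to the sub-spectrum above *f*₁; its aggregate power runs at ~0.51
of the first harmonic's across all display configurations. For shapes
whose spectrum depends on orientation (polygons, stars), the
**orientation-resolved** variant splits the frequency half-plane into
36 sectors of 5° and finds a separate *f*₁ per sector. Detection inside
a narrow sector runs on the sector's mean |F| per bin with empty bins
interpolated (annulus occupancy within a 5° sector is too ragged to
difference), while summation uses the actual coefficients; a sector
with fewer than 3 occupied bins reuses the global limit.

## Display generators

All geometry is in pixels on a 768×768 canvas; the 0.75° stimulus
region maps to a 350 px radius (466.7 px/°, configurable). Rendering
uses pixel-center membership with no anti-aliasing, so a spec
rasterizes deterministically. Items paint in list order, which lets
illusory-contour inducers carve background-colored notches into dots.

*Placement.* Items are placed uniformly in a circular region subject
to a minimum edge-to-edge gap. Sparse displays use rejection sampling
(bounded retries). Dense displays — e.g. 175 items with 24 px gaps,
a packing fraction of 0.60 that exceeds the ~0.55 jamming limit of
random sequential addition — use pairwise collision relaxation from a
random start, which keeps the arrangement disordered; a jittered
lattice was rejected because its periodicity puts Bragg peaks in the
spectrum and corrupts *f*₁ detection.

*Configurations.* The four display families conserve, across
numerosities: total item area (reference: one 160 px circle),
individual diameter (56 px), or total circumference (that of a 160 px
circle); the high-density family uses the constant-area sizes but
groups all items inside a half-radius sub-region placed randomly
(fully contained) in the stimulus region. These constants are not
published; they were chosen once to resemble the published example
displays. The within-configuration minimum gap (also unpublished)
defaults to 2 px.

*Generalization series.* Single circles of 1–240 px diameter; seven
16 px circles spaced randomly but evenly in group areas of 50–528 px
diameter, with the minimum center-to-center distance scaling with the
area so that all items touch at 50 px; numerosities 1–175 of 16 px
circles at ≥24 px gaps in a 700 px region; regular polygons with 3–10
corners (30 px vertex radius) plus a circle; stars with 3–10 points
(30 px outer, 10 px inner radius). Dot pairs are 30 px dots joined by
4 px bars (length = edge-to-edge separation) or by background-colored
inducers carved 10 px into each dot; control variants split the
element at its midpoint and rotate each half 90° about its dot center,
changing each dot identically without forming a connection.

*Contrast experiments.* The geometry of the published contrast
manipulations is not stated. This package uses the seven-circle group
generator with the group-area diameter drawn per display from the same
50–528 px range as the spacing series (the two analyses describe their
displays identically), items allowed to touch. Under this one
condition the package reproduces both reported effects it was not
calibrated on: mixing black and white items raises mean power by
~1.6%, and widening the per-item contrast range from 0.1 to 0.85
raises mean power by ~10–13%. The third reported effect — the ~300%
widening of the 95% interval of per-display power — is reproduced in
expectation but with very large sampling noise at the prescribed 80
displays per condition (SD ≈ 200 percentage points across seeds):
displays whose group area approaches the 50 px touching limit flip the
first-harmonic detector into a regime where it reflects the whole
group rather than the items, and the 2.5th-percentile estimate from 80
displays is dominated by how many such displays are drawn. Narrow and
wide conditions share geometries (a paired design; each condition's
marginal distribution is unaffected).

## Response models

The averaged stimulus cycle is 44 TRs of 2.1 s: numerosities 1–7
ascending at 2 TRs each, 8 TRs at the 20-item baseline, 7–1
descending, 8 more baseline TRs. The long baseline periods
discriminate small from large tuning widths; tuned predictors evaluate
the log-Gaussian in its far tail at 20, monotonic predictors use the
feature value at 20.

*HRF.* SPM-convention double gamma (peak delay 6 s, undershoot delay
16 s, unit dispersions, undershoot ratio 1/6), sampled at the TR,
truncated at 30 s (<1% of L1 mass lost), unit peak. Convolution is
circular over the 44-TR cycle because the stimulus repeats
continuously.

*Monotonic model.* Neural amplitude is the log- (default) or
linearly-scaled feature value; after HRF convolution, baseline and β
come from a two-parameter OLS GLM. The scaling mode is chosen globally
per feature by summed variance explained (ties → log).

*Tuned model.* Amplitude = exp(−(ln x − ln μ)²/(2σ²)). Candidate grid:
60 log-spaced μ in [1.05, 6.95] (within the presented range; outside
it the parameters are not identifiable and predictions degenerate to
monotonic curves), 40 log-spaced σ in [0.05, 2] log-units. The best
candidate is selected by Pearson correlation of the convolved
predictor with the data, then amplitude and baseline are refit by GLM.
Monotonic ground truth drives the fitted μ to a grid boundary — the
behavior that motivates restricting μ.

*Cross-validation.* Split halves with identical design: tuning
parameters and the scaling mode transfer frozen; baseline and scaling
are refit on the held-out half; a monotonic β may not change sign
(a sign flip clamps β to 0, recording r²_cv ≤ 0). Variance explained
is pooled across stimulus configurations as Σ explained variance / Σ
total variance, so configurations with more signal variance weigh
more.

## Synthetic cohorts

Synthetic voxels have the structure of the deposited per-voxel data:
44-TR averaged cycles in odd/even split-half replicates, an
eccentricity label, a map label, and known generating parameters.
Noise is white Gaussian (AR(1) optional, off by default); the noise SD
of each voxel is set from a map-level eccentricity profile via
VE = σ²_signal/(σ²_signal + σ²_noise), so the expected fit quality
follows the generating curve — a declining cumulative-Gaussian sigmoid
for early-visual maps, a flat or humped quadratic for association
maps. What the generator does **not** emulate: empirical fMRI noise
spectra, spatial correlation between voxels, drift, and
between-session amplitude changes; passing round-trip tests therefore
demonstrates correctness of the estimation machinery, not performance
on real recordings.

At a target VE of 0.5 (SNR ≈ 1), ≥90% of voxels are assigned to their
generating model family by cross-validated comparison. Tuned voxels
generated with μ < 1 read as monotonically decreasing (β < 0) and pin
an in-range tuned fit at the 1.05 boundary; note that the in-range
log-Gaussian, being the same family, fits such voxels essentially as
well, so "decreasing sites are low-μ tuned sites" is an
interpretation, not a model-comparison outcome.

## Eccentricity statistics

Voxel fits are binned by pRF eccentricity at 0.2° from 0 to 5.5° (the
last bin is the partial 5.4–5.5°); empty bins drop. Profiles are
either a four-parameter cumulative-Gaussian sigmoid
VE(e) = min + (max−min)(1 − Φ((e − inflection)/slope)) or a
three-parameter quadratic, fit by bounded least squares with 5
multi-starts. Fits are bootstrapped: 1000 resamples of the unbinned
voxels (pooled across participants; per-participant resampling is a
config option), each resample re-binned and re-fit; the point estimate
is the per-parameter median and the 95% envelope the 2.5/97.5
percentiles of the fitted curves per eccentricity. Non-convergent
resamples are redrawn, capped at 10%. The family is selected by the
correlation between the fitted curve at the bin centers and the bin
means (ties and degenerate correlations → quadratic).

Paired model comparisons use two-sided Wilcoxon signed-rank tests
(exact null for n ≤ 25) with Benjamini–Hochberg FDR across the
declared comparison family; voxel inclusion (some model's R² > 0.2)
uses fitting-half variance explained only, never the evaluation half.
The network-response comparison normalizes published response lines
globally (mean response at the smallest numerosity → 0, at the largest
→ 1, preserving between-line offsets), linearly rescales each
candidate nonlinearity (aggregate-power curve, log, free quadratic) to
all points at once, and compares per-line Pearson correlations between
candidates with paired t-tests. A quadratic fit to an n^0.47 curve
over 1–30 has a negative (compressive) quadratic coefficient.

## Problem sizes and determinism

All randomness flows from explicit `numpy` Generators; the same seed
reproduces displays, cohorts, and fits bit-identically. The analysis
drivers and the acceptance script use deliberately modest problem
sizes — e.g. 21 log-spaced numerosities spanning 1–175 at 10 displays
each for the power-law fit, 80 displays per contrast condition
(matching the published protocol), 400-voxel cohorts, 100–200
bootstrap resamples in tests (1000 by default in the library) — which
keep a full run in the minutes range while leaving every estimate well
inside its tolerance except the sampling-limited interval-width ratio
discussed above.
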