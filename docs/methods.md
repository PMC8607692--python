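# Methods

This note records the models, conventions and numerical choices behind
`sparkline`, and what the synthetic studies do and do not demonstrate.

## Image model and conventions

A line-scan image is a matrix `data[x, t]` — space (axis 0, `dx` μm/pixel)
by time (axis 1, `dt` ms/line; 2.5 ms at the 400 lines/s acquisition rate
the package targets).  All boxes are half-open `[start, end)` in
pixel/line units.  Fluorescence is analysed as F/F₀.

**Baseline F₀** is estimated per spatial position as the mean of the
samples at or below that position's temporal median (the "lower-half
mean").  This is robust to sparks occupying less than half of a pixel's
timeline and needs no event detection to bootstrap; a second pass excludes
pixels flagged as events by the background model.  On pure noise the
lower-half mean sits below the true mean (for Gaussian noise by
≈ 0.51 σ/0.64), so μ of the normalized image is slightly above 1; the
background model measures μ rather than assuming it.

**Background statistics** (μ, σ) are estimated iteratively: pixels above
μ + cri·σ seed candidate events, which are grown through their 8-connected
neighbourhood above μ + 2σ (so spark flanks do not inflate σ), and μ, σ
are recomputed on the remainder until the mask is stable (≤ 5 passes).
`cri` defaults to 3.8, the conventional detection multiplier.  Constant
images are rejected as degenerate; a mask that would cover more than half
the image stops the iteration with a warning.

## Synthetic sparks

A spark is separable in space and time:

    dF/F₀(x, t) = A · exp(−(x−x₀)²/(2σₓ²)) · k(t)
    k(t) = c · (1 − e^{−(t−t₀)/τᵣ}) · e^{−(t−t₀)/τ_d},   t ≥ t₀

with `c` normalizing `k` to unit peak, so the rendered maximum equals `A`.
The kinetic peak is at `t₀ + τᵣ ln(1 + τ_d/τᵣ)` (closed form, used as an
oracle in tests).  Defaults: FWHM ~ N(2.0, 0.25²) μm (σₓ = FWHM/2√(2 ln 2)),
τᵣ ~ N(5, 1²) ms, τ_d ~ N(20, 4²) ms with τ_d ≥ τᵣ, which yields FDHM
≈ 19 ms — the ~2 μm / ~20 ms scale typical of cardiomyocyte sparks.
Noise is i.i.d. Gaussian on the F/F₀ scale (σ = 0.1 by default), clipped
at zero; an optional Poisson photon mode exists behind a flag.  SNR of a
spark is defined as `A / noise σ`, which makes the μ + 3.8σ criterion
directly interpretable: SNR < 3.8 means sub-threshold.

Ground-truth boxes are the half-maximum support of the noise-free spark
padded by 2 pixels/lines — the same footprint the characterization stage
fits.

**Cohort presets.**  `wt_like` (amplitude mean 0.55, ~12 sparks/cell),
`rs_like` (mean 0.40, ~20 sparks/cell — the high-frequency/low-amplitude
diseased pattern) and `iso_like` (mean 0.70, faster rise τᵣ ≈ 3.5 ms,
~16 sparks/cell — β-adrenergic stimulation).  Amplitudes are log-normal
with 30% CV; counts are Poisson.  Only the amplitude means are anchored to
the two-population contrast the package is meant to emulate; the CV and
count means are realistic choices fixed once.

**What the simulator does not model:** photon (Poisson) statistics by
default, photobleaching, calcium waves and whole-cell transients, cell
edges and motion, spatially correlated detector noise.  Tests passing on
this generator therefore demonstrate the correctness of the algorithms
under the stated noise model, not performance on any particular
microscope's recordings.

## Threshold detector

Boxcar 3×3 smoothing, thresholding at μ + cri·σ (σ of the *unsmoothed*
background, as in the classical method), 8-connected components, area
filter (min 8 px), then growth of each component to the μ + 2σ contour so
that characterization sees the full event.  Detections carry score 1.0
(the method is binary).  Because smoothing divides the noise σ by ~3 while
attenuating spark peaks only mildly, the effective amplitude cutoff is
sharp: recall is ~1 above 5σ and ~0 at 2σ, with essentially zero false
positives on pure noise at the default operating point.

## Learning-based detector

A region-proposal design scaled to desk size: 64×64 tiles (50% overlap),
median/MAD standardization per tile, a backbone of two stride-1 3×3
convolutions each followed by 2×2 average pooling, one residual block at
stride 4, and three 1×1 heads — objectness, spark/background
classification, and 4-parameter box regression — over 3 anchors per
feature cell ((14, 8), (18, 12), (24, 16) px×lines, sized to spark
half-maximum footprints at the default calibration).  The network is
implemented directly on numpy (im2col convolutions with hand-written
backward passes, Adam); the default configuration (~6k parameters,
≤ 200 tiles, 60 epochs) trains in about a minute on one CPU and is
bit-deterministic under its seed.

Anchor labeling: positive at IoU ≥ 0.5 with a truth box (every truth also
claims its best anchor), negative below IoU 0.4, ignored between.  Truth
fragments that belong mostly to a neighbouring tile mark overlapping
anchors as ignored rather than background.  The loss is balanced binary
cross-entropy on both heads plus smooth-L1 box regression on positives;
negatives are selected by online hard-example mining (the highest-scoring
negatives per batch), which is what teaches the network to reject
"ring" anchors that see a spark flank inside their receptive field.  The
narrow ignore band and OHEM together cut false positives by two orders of
magnitude at unchanged recall in ablations on held-out images.

Inference: anchors scored by the geometric mean of the two heads,
thresholded at 0.5, decoded with center offsets clipped to ±1 anchor size
(regression is only trained on positives, so untrained offsets must not
scatter boxes), NMS at IoU 0.3, then peak-based deduplication: each
detection's intensity peak is refined by hill-climbing on the 3×3-smoothed
image, and detections whose refined peaks coincide within about half a
spark footprint (9 px × 6 lines) collapse onto the highest-scoring,
largest box.  This step exists because flank detections have boxes too
dissimilar for IoU NMS while sharing the same underlying intensity peak.

Because tiles are standardized by their median and MAD, the network
effectively learns a matched filter in units of the local noise σ: a 2σ
spark integrates to a high-significance blob over its ~100-pixel
footprint even though every single pixel is statistically insignificant.
That is the mechanism by which the detector recovers the [2σ, 3.8σ) bin
that the threshold rule discards, at ≤ 0.5 false positives per image in
the benchmark study.

Training on simulator output (rather than hand-labeled recordings) is a
deliberate choice: the ground truth is exact, including events far below
any manual-labeling threshold.

## Characterization

For each detection, profiles through the peak: spatial = 3 scan lines
averaged, over the box padded by 50% of its width per side; temporal = 3
spatial pixels averaged, over the box padded by 100% of its duration per
side.  The spatial profile is fitted with `a + A·exp(−(x−x₀)²/2σₓ²)`
(FWHM = 2√(2 ln 2)·σₓ); the temporal profile with `b + A·k(t; t₀, τᵣ, τ_d)`.
Because the rising limb holds only ~2 samples at 2.5 ms/line, the temporal
fit surface is multi-modal in (t₀, τᵣ): the fit takes the best of six
starts over (τᵣ, τ_d) ∈ {2, 5, 10} × {12, 30} ms.  Rise time (10–90%),
t50 (peak to half decay) and FDHM are read off the fitted curve by dense
scan at 0.1·dt with linear interpolation at the crossings.  Fits with
r² < 0.2 are flagged invalid rather than raised; amplitude (max of the
3×3-smoothed F/F₀ − 1 within the box) is always reported.  An FDHM whose
half-max support outlives the recorded trace is flagged as a lower bound.

**Known limitation — rise time at 400 lines/s.**  The recovery study (300
sparks per condition, truth boxes as detections) gives median relative
errors at SNR 3.3 of ≈ 6% (amplitude), ≈ 9% (FWHM), ≈ 11% (FDHM) but
≈ 23% (rise time); at SNR 1.75 ≈ 20/18/21/34%.  A control experiment
initializing the fit at the true parameters still yields 20%/33% median
rise-time error, i.e. the uncertainty is the statistical floor of
estimating a ~3.5 ms quantity from 2.5 ms samples of a 3-pixel profile,
not an optimization artifact.  Rise-time estimates at this line rate
should be treated as distribution-level, not per-event, measurements.

## Event-based classification

Event features are {amplitude, FWHM, FDHM, rise time, t50} — spark
frequency is a cell-level quantity (events·(100 μm)⁻¹·s⁻¹), reported but
deliberately not fed to the event model, which is strictly event-based.
The model is an L2-penalized logistic regression on z-scored features
(objective: binomial deviance + l2/2·‖w‖², intercept unpenalized;
l2 = 10⁻³ keeps weights finite under perfect separation); the fit is
delegated to scikit-learn with C = 1/l2 and verified against a
brute-force grid search of the penalized likelihood in the tests.
Invalid events are excluded, never imputed.  Conventions where a choice
had to be made: an event with p exactly 0.5 is labelled the second class;
a cell with tied vote counts takes the class with the larger summed
probability mass and is flagged.

Majority voting amplifies accuracy per the exact binomial tail: at 15
events/cell and 75% per-event accuracy, P(Bin(15, 0.75) ≥ 8) = 0.9827,
and the measured cohort accuracy matches within Monte-Carlo error.  On
fully simulated cohorts with the default presets, per-event accuracy is
~0.7 (the Bayes limit of the 0.55 vs 0.40 amplitude contrast at 30% CV),
giving ~0.85–0.9 cell accuracy at 12–20 events/cell; near-perfect cell
classification requires either stronger feature separation or more events
per cell than the default presets provide.

## Reproducibility and problem sizes

Every stochastic component takes a seed; the CLI fans a single global seed
out to stages by fixed offsets, and deterministic mode reproduces CSV/JSON
outputs byte-for-byte.  The benchmark studies use 300 sparks per recovery
condition, 100 noise-only 512×2000 images for the false-positive rate,
200 sparks per recall point, 12 training images (≤ 200 tiles) and 16 test
images for the detector comparison, and 200×15 constructed events for the
vote study — sizes at which every study completes in minutes on one CPU
while keeping Monte-Carlo error well below the effect sizes of interest.
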