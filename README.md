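# sparkline

Detection, morphometric characterization and event-based cell
classification of Ca²⁺ sparks in confocal line-scan images of
cardiomyocytes.

Ca²⁺ sparks are the elementary sarcoplasmic-reticulum Ca²⁺ release events
of heart muscle cells: ~2 μm wide, ~20 ms long, recorded with a confocal
microscope scanning one line along the cell at ~400 lines/s.  Spark
properties (frequency, amplitude, FWHM, FDHM, rise time, t50) change under
cardiac disease, so they are widely used readouts — but the classical
detection rule, thresholding the normalized image at μ + 3.8σ of the
background noise, systematically discards low-amplitude events and skews
every downstream statistic, most severely in diseased cells whose sparks
are smaller and more frequent.

`sparkline` provides the full analysis chain for researchers working with
such recordings:

* **`linescan`** — TIFF I/O, per-position baseline F₀ (lower-half temporal
  mean), F/F₀ normalization, and background (μ, σ) estimation with
  iterative spark exclusion.
* **`simulate`** — a ground-truthed generator: sparks are separable
  `A·exp(−(x−x₀)²/2σₓ²) · k(t)` profiles with
  `k(t) ∝ (1−e^{−(t−t₀)/τᵣ})·e^{−(t−t₀)/τ_d}` on i.i.d. Gaussian noise in
  F/F₀ units; two-population cohorts (`wt_like`, `rs_like`, `iso_like`)
  emulate normal vs high-frequency/low-amplitude diseased cells.
* **`detect`** — the traditional μ + criσ threshold detector
  (boxcar smoothing, 8-connected components, growth to the μ + 2σ contour),
  and a learning-based detector: a small residual convolutional backbone
  over 64×64 tiles with anchor boxes sized to spark footprints, an
  objectness/classification head and box regression, trained on simulator
  output.  Because tiles are standardized by median/MAD, the network scores
  amplitude in units of the local noise σ and recovers events well below
  the 3.8σ rule.
* **`characterize`** — per-event morphometrics from profile fits: spatial
  Gaussian (FWHM = 2√(2 ln 2)·σₓ) and the kinetic model above (rise time
  10–90%, t50, FDHM read off the fitted curve by dense scan).
* **`classify`** — the event-based model: an L2-penalized logistic
  regression `p(B|z) = logistic(β₀ + w·z)` on z-scored event features,
  then a majority vote over a cell's events.  With per-event accuracy
  p > 0.5 and n events per cell, cell accuracy follows the binomial tail
  P(Bin(n, p) > n/2) — which is how ~75% event accuracy becomes ~99% cell
  accuracy at n = 15.
* **`sparkline` CLI** — `simulate`, `detect`, `train-detector`,
  `characterize`, `train-classifier`, `classify-cells`, `compare`, `run`
  (full pipeline with reproducibility manifests).

## Worked example

```python
import sparkline as sl
from sparkline.detect.nn import DetectorConfig, NeuralSparkDetector

# ground-truthed training images, spark amplitudes 2-8 sigma
train = sl.generate_detection_set(n_images=12, sparks_per_image=6,
                                  amp_range_sigma=(2, 8), seed=11)
detector = NeuralSparkDetector(DetectorConfig(seed=7)).fit(train)

# a sub-threshold spark: amplitude 3 sigma < the 3.8 sigma rule
spec = sl.SparkSpec(x0=9.0, t0=200.0, amp=0.30, sigma_x=0.849,
                    tau_rise=5.0, tau_decay=20.0)
img, truth = sl.generate_image([spec], noise_sigma=0.1, shape=(128, 400), seed=1)

bg = sl.estimate_background(img)
print(len(sl.detect_threshold(img, bg)))   # 0  (missed at mu + 3.8 sigma)
dets = detector.predict(img)
print(len(dets))                            # 1  (recovered by the detector)
feats = sl.characterize_spark(img, dets[0])
print(round(feats.amplitude, 2), round(feats.fwhm, 2), round(feats.fdhm, 1))
# 0.34 1.76 14.2   -> peak dF/F0, FWHM in um, FDHM in ms
```

The generating values are amplitude 0.30, FWHM 2.0 μm, FDHM ≈ 19 ms: a
single event at SNR 3 carries this much fit noise, which is why the
recovery studies report medians over hundreds of events.

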