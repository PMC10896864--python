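# Methods

## Problem and model

Invasive intracranial pressure (ICP) monitoring in traumatic brain injury
requires drilling into the skull. The working hypothesis of optical ICP
monitoring is that the pressure surrounding cerebral arteries modulates the
morphology of the cardiac pulse seen in a transcranial (forehead,
near-infrared) photoplethysmogram (PPG). This package implements the full
estimation chain from a raw cerebral PPG plus an invasive reference to a
regression-based non-invasive estimate (nICP), and a synthetic generator in
which the hypothesis holds *by construction*, so every stage can be validated
without clinical recordings.

The chain is:

1. **Denoising.** Movement artifacts and photodetector saturation are
   detected on the raw PPG and removed *synchronously* from PPG and ICP, so
   paired samples stay aligned. Saturation = runs near the observed signal
   rails (running min/max), spanning at least 50 ms, that are also flat
   (peak-to-peak within a quarter of the rail margin) — a quiescent
   diastolic baseline passing near the session minimum is not saturation.
   Movement = 1-s sliding windows whose peak-to-peak amplitude deviates from
   a 2-minute rolling median by more than `artifact_z` robust (MAD)
   z-scores; the rolling baseline keeps slow physiologic amplitude trends
   (e.g. during hypertensive episodes, where the morphology map itself
   shrinks the pulse) from being flagged. Flagged regions are dilated by
   0.5 s on each side. Surviving spans shorter than 10 s are discarded: the
   slowest filter time constant is 1/0.1 Hz = 10 s, so shorter spans cannot
   be filtered or pulse-segmented reliably. Run duration is counted as the
   time *spanned*, (n−1)/rate, which is what lets a clean sinusoid whose
   crest sits within the rail margin for exactly 50 ms pass unflagged.
2. **AC/DC decomposition.** Zero-phase (forward–backward) 2nd-order
   Butterworth filters: bandpass 0.8–10 Hz for the cardiac (AC) component,
   lowpass 0.1 Hz for the baseline (DC). Zero-phase application was chosen
   to preserve fiducial timing; it squares the magnitude response, and the
   tests assert measured gains against |H(f)|² of the design. The
   normalized signal is `10 · AC / DC`, which cancels optical gain (tested
   as an exact invariance); spans where |DC| falls below 10⁻³ of its median
   are rejected as artifact, since the ratio is then meaningless.
3. **Pulse segmentation and features.** Systolic peaks by local-maximum
   detection (minimum separation one minimal cardiac period at 180 bpm,
   prominence ≥ 25 % of the span's median peak-to-peak amplitude); feet are
   the minima between consecutive peaks, plus boundary feet before the
   first and after the last peak so uninterrupted spans yield one pulse per
   beat. Pulses with duration outside 40–180 bpm or amplitude further than
   3 MAD from the span median are dropped (MAD floored at 5 % of the median
   so near-identical clean pulses survive). Eleven features per pulse, all
   after subtracting the foot value: amplitude (peak height); pulse width
   at half amplitude (first up-crossing to last down-crossing, linearly
   interpolated); rise and decay times (foot→peak, peak→end); secant
   up/downslopes (±amplitude/time); trapezoidal area under the curve;
   systolic and diastolic areas split at the dicrotic notch — the first
   local minimum of the lightly smoothed pulse after the peak, falling back
   to the peak itself when absent, which guarantees sys + dia = auc for
   every pulse; their ratio; and the signed max/min ratio of the second
   derivative (SDPPG), computed by Savitzky–Golay smoothing-differentiation
   (order 3, 110 ms window scaled with rate) applied twice, with the
   filter-edge region excluded from the extrema search. Width-at-half-amplitude
   and secant slopes are conventions; foot-to-foot width and extremal
   first-derivative slopes are the plausible alternatives and are noted as
   such.
4. **Windowing.** Consecutive non-overlapping 60-s wall-clock windows;
   features are per-feature medians over the pulses whose foot falls in the
   window, paired with the mean of the retained invasive ICP samples in the
   window. Windows with fewer than 20 pulses (half of the slowest plausible
   beat count in 60 s) or mean ICP outside 5–40 mmHg are dropped. 48 h of
   uninterrupted monitoring therefore yields at most 2880 observations.
5. **Stratified split.** Because sedated patients spend most of the time at
   normal pressure, observations are binned into 5-mmHg ICP strata
   (5–10, …, 35–40). Within each stratum, a seeded shuffle assigns
   round(20 %) to test (only when the stratum holds ≥ 3 observations), then
   round(20 %) of the remainder to validation, rest to training, so every
   represented pressure level reaches both training and testing. The
   validation holdout is stratified the same way for consistency. Splitting
   is per *observation* (windows of one patient can land in different
   splits), replicating the published protocol; `by_patient=True` /
   `--by-patient` offers the leakage-free alternative but is not the
   default.
6. **Regression.** A bagged ensemble of 30 CART regression trees, maximum
   depth 8 (edges from the root), all 11 features available at every node,
   each tree grown on an independent seeded bootstrap resample of the
   training set (same size, with replacement). The trees are written from
   scratch: exhaustive search over features and midpoints between
   consecutive sorted unique values, minimizing summed child SSE, ties
   broken toward the lowest feature index then lowest threshold, leaves
   predicting the node mean with at least `min_leaf = 5` rows (a guard the
   published depth-8 setting leaves unstated). Predictions are therefore
   convex combinations of training targets and cannot extrapolate. The
   estimator is scikit-learn compatible (`fit`/`predict`,
   `get_params`/`set_params`, clonable, pipeline-ready).
7. **Evaluation.** Bland–Altman bias and limits of agreement
   (bias ± 1.96·SD of est − ref differences, SD with n−1), Pearson r with
   its p-value, r², RMSE, and a regression-fit R² (1 − SSres/SStot) as an
   auxiliary field since squared-r and fit-R² differ whenever the estimate
   is biased or mis-scaled. ROC for intracranial hypertension labels
   (reference ≥ 15 mmHg, the sedated-patient threshold) swept over all
   distinct estimate values, AUC by trapezoid; the reported operating point
   applies the *matched* 15 mmHg cut-off to the estimate, with the
   Youden-optimal point recorded alongside, because a single published
   sensitivity/specificity pair does not identify the cut-off convention.
   Per-patient reports exclude patients with ≤ 100 test observations from
   the summary; summaries are mean ± SD with a normal-approximation 95 % CI
   (mean ± 1.96·SD/√n) — a convention, not a published formula.

## Synthetic generator

`nicp.simulate` produces sessions with known ground truth. ICP is a
mean-reverting random walk on a 1-s grid around 12 mmHg (stationary SD
2.5 mmHg) with smooth sigmoid plateau events (default 2 per session, up to
14 mmHg high, 3–10 min), clipped to 5–40 mmHg; the defaults keep well over
60 % of windows below 15 mmHg, mirroring actively managed patients. Each
cardiac pulse is a two-Gaussian waveform (systolic wave + delayed dicrotic
wave) chosen for its closed forms — fiducials, areas and derivatives are
analytic and serve as oracles in the feature tests. Per-beat parameters
follow local ICP through a monotone map: amplitude × e^(−0.025/mmHg),
systolic-peak time +1 %/mmHg, dicrotic ratio +1.2 %/mmHg, all relative to
12 mmHg. The raw optical signal adds a 100-unit DC baseline with 0.01 Hz
drift and 0.25 Hz respiratory modulation, white noise (SD 3 % of pulse
amplitude), and injected artifacts at recorded intervals: movement-noise
bursts (2–8 s, 80 % of the artifact budget) and exact-rail saturation
plateaus (0.5–3 s, 20 %), together covering `artifact_fraction` (default
5 %) of the session. A proximal (extracerebral) channel with fixed,
ICP-independent morphology is generated and carried but unused by the
default pipeline. Beat timing is a Gaussian inter-beat process at
70 ± 3 bpm.

What the generator does *not* emulate: real cerebral hemodynamics
(autoregulation, Windkessel dynamics, venous effects), inter-patient
morphology variability, sensor drift, or the true quantitative
ICP→morphology mapping — which is precisely the open scientific question.
Passing the recovery study therefore shows the *pipeline* is lossless
enough to recover a morphology-encoded pressure signal; it says nothing
about whether real foreheads encode one.

## End-to-end study and negative control

The acceptance study simulates 20 patients × 4 h at 100 Hz (a desk-scale
stand-in for the published 40-patient, up-to-48-h cohort), runs the entire
pipeline, and requires pooled test r ≥ 0.8 and |bias| ≤ 0.5 mmHg — the
structural analogue of the published r = 0.83 and bias = −0.22 mmHg, on a
generator where the hypothesis is true by construction. The negative
control zeroes all three morphology-map gains: the PPG then carries no ICP
information and pooled r must collapse to 0 ± 0.1, proving the pipeline
(and in particular the per-observation split) cannot hallucinate signal
from the features alone. Each study takes roughly two minutes on one CPU;
per-patient sessions are processed sequentially so memory stays near one
session (~35 MB of samples).

## Numerical choices and degenerate inputs

- Filtering uses `scipy.signal.sosfiltfilt`; peak finding
  `scipy.signal.find_peaks`; Savitzky–Golay coefficients from scipy with
  cached polynomial-fit edge matrices (bit-equivalent to scipy's
  `mode="interp"`, measured identical to 1e-8).
- CSV I/O reads with `float_precision="round_trip"` so session and
  observation tables round-trip exactly at text precision.
- Tree ties are resolved deterministically (lowest feature, lowest
  threshold); all randomness — ICP walks, beats, noise, artifacts,
  bootstrap draws, split shuffles — flows from explicit seeds, and
  identical seeds give bit-identical outputs.
- Degenerate pulses (non-positive amplitude, zero diastolic area, flat
  second derivative, < 15 samples) are rejected individually rather than
  poisoning a window; windows and spans that end up empty simply produce no
  observations.
- Per-patient metrics that are undefined (constant reference → no r;
  single-class reference → no ROC) are reported as absent and excluded from
  that metric's summary only.

## Known limitations

- The greedy CART is not the globally optimal depth-k tree (no CART is);
  tests pin it to a brute-force oracle at depth 1, where greedy *is*
  optimal, and to an independent naive greedy implementation at depth 2.
- Exact numeric parity with MATLAB's Regression Learner "bagged trees"
  preset is not attainable (its leaf-size/split defaults are unpublished)
  and is not claimed.
- The band-power SNR reported by the denoiser (10·log10 of 0.8–10 Hz power
  over out-of-band power, Welch PSD) is this package's definition;
  published SNR-improvement percentages rest on an unstated definition and
  are not comparable.
- The per-observation split inherits the published protocol's optimism:
  windows of the same patient occur on both sides of the partition. The
  negative control bounds how much signal that alone can fabricate (none,
  at the cohort sizes used), but for clinical claims the `by_patient`
  split is the honest option.
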