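# Methods

This document describes the signal-processing model implemented by
`neovitals`, the parameter defaults, what the synthetic generators do and do
not emulate, and the numerical choices that required judgement.

## 1. Camera chain

### 1.1 Skin segmentation (`neovitals.skin`)

Pixel-colour classifiers (Gaussian-mixture or naive-Bayes over RGB, with an
HSL conversion utility) map each frame to a skin-probability map; a 0.5
threshold yields the mask. Quality of a mask is measured by
intersection-over-union (IOU) against ground truth. Training minimises a
class-weighted cross-entropy: the skin class is up-weighted by
λ = (#non-skin / #skin) so sparse skin regions are not swamped
(`segmentation_loss(scores, labels, lam)`); `unified_loss` combines the
detection and segmentation terms with non-negative weights. Models serialise
to JSON round-trip exactly.

### 1.2 PPGi extraction (`neovitals.ppgi`)

The PPGi sample for a frame is the mean of the green plane over the skin
mask (per-channel variants are available). Empty masks give NaN and an
invalid sample. The value is invariant to spatial resolution (pixel
replication leaves it unchanged). An activity index per second is the mean
relative symmetric difference of consecutive masks; seconds above 0.02 are
"active" (motion).

### 1.3 Filtering (`neovitals.filters`)

Two linear-phase FIR cascades (Hamming windowed-sinc), applied with
group-delay compensation so outputs are time-aligned with inputs:

- cardiac: 40th-order low-pass at 4.5 Hz then 60th-order high-pass at
  1.5 Hz — band 1.5–4.5 Hz, i.e. 90–270 beats/min;
- respiratory: 100th-order high-pass at 0.3 Hz then 80th-order low-pass at
  2.0 Hz — band 0.3–2.0 Hz, i.e. 18–120 breaths/min.

Measured contracts at 20 frames/s: cardiac ≥ −3 dB on [1.8, 4.0] Hz and
≤ −20 dB below 1.0 Hz and above 5.5 Hz; respiratory ≥ −3 dB on
[0.5, 1.6] Hz and ≤ −20 dB below 0.1 Hz and above 2.5 Hz. Gaps of up to
0.5 s in the input are bridged by linear interpolation; longer gaps split
the signal into independently filtered segments, with edge transients
(one filter length) marked invalid.

### 1.4 Beat detection and beat quality (`neovitals.detect`, `neovitals.cardiac`)

The boxed slope-sum function (BSSF) transforms the filtered signal into a
windowed sum of positive slopes — window ⌈0.150 s × f_s⌉ samples (3 at
20 frames/s). An armed adaptive threshold (initialised from the first 2 s,
decaying with a 2 s time constant, refractory 60/270 s) marks pulse onsets;
the peak is the local maximum at the end of the upslope.

Each beat receives an SQI: five hard gates (physiological interval, local
interval consistency, amplitude outlier, activity overlap, change-point
proximity) multiplied by a multiscale dynamic-time-warping similarity
between the beat (resampled to a canonical length, z-normalised) and a
running template. Window SQI is the mean beat SQI over the trailing 8 s.

### 1.5 Heart-rate estimators (`neovitals.cardiac`)

All estimators run on a 1 Hz grid over trailing 8 s windows:

- **count**: (n_peaks − 1) · 60 / span of peaks;
- **fft**: argmax of the 4096-point zero-padded spectrum in 1.5–4.5 Hz;
- **ar8**: dominant in-band pole of an order-8 Burg autoregressive model;
- **arbest**: orders 6–12; candidate orders are those where the pole
  frequency and the model spectral-response argmax agree within 1 beat/min;
  the candidate with the largest pole magnitude wins; if none, the order-8
  spectral peak is used and flagged as a fallback.

Estimates outside 90–270 beats/min are invalid. An optional quality-weighted
random-walk Kalman smoother (process and measurement variance 4, measurement
variance inflated by SQI⁻², SQI < 0.3 treated as missing) stabilises the
series.

### 1.6 Change-point detection (`neovitals.changepoint`)

Sudden lighting changes appear as step changes of the PPGi mean level and
corrupt beats near them. Steps are found by Bayesian online change-point
detection: constant hazard 1/300 per sample, Normal-Gamma observation model
(μ₀=0, κ₀=0.2, α₀=1, β₀=0.2) with Student-t predictive, run-length
posterior truncated at 400. Two details matter:

- the noise scale is estimated from first differences (std(diff)/√2), which
  is robust to the very level shifts being detected;
- truncation *merges* the two oldest run-length hypotheses (keeping the
  parameters of the more probable one) instead of dropping the longest run —
  dropping it would delete the maximum-a-posteriori hypothesis for long
  stationary stretches and fabricate a collapse exactly `max_run` samples
  after the previous change point.

A change point is a collapse of the MAP run length confirmed by the MAP
tracking the new segment for the following ~0.7 s (rejects single-outlier
collapses). Samples within 1 s of a change point are invalid for beat/breath
scoring.

### 1.7 Respiratory chain (`neovitals.respiratory`)

Twelve channels: three PPGi colour means, four skin-shape statistics (area,
perimeter, centroid x/y) and five ellipse moments (major/minor axis,
orientation, eccentricity, area) from a moment-based ellipse fit of the
largest connected mask component. Each channel is respiratory-filtered, then
breaths are detected twice: by the mean-average-curve detector (upward
crossings through a 2 s centred moving average, 0.5 s refractory) and by
BSSF with a 300 ms upslope and 500 ms refractory. The window SQI is **zero
whenever the two detectors disagree on the breath count** (15 s window),
otherwise the mean breath score. Per-channel rates (counting convention as
for HR) are fused across channels with SQI/variance weights through the
Kalman layer; rates outside 18–120 breaths/min are invalid.

## 2. Reference chain (`neovitals.reference`)

- **ECG SQI**: F1 agreement (150 ms matching window) between two independent
  QRS detectors — slope-sum and a derivative/energy detector whose threshold
  is median + 8·MAD of its integrated envelope, so broadband noise does not
  trigger it and F1 collapses on noise.
- **PPG SQI**: beats segmented as fixed-duration windows centred on detected
  peaks; each beat is correlated with the **leave-one-out** template with the
  detection anchor (±3 samples of 40) excluded — otherwise pure noise scores
  ≈ 0.55 because every segment shares the anchor maximum and contributes to
  its own template.
- **Reference HR**: valid only when |HR_ECG − HR_PPG| ≤ 5 beats/min **and**
  both SQIs exceed 0.5 (strict); the value is the mean of the two.
- **Respiration surrogates**: EDR (R-wave morphology), RSA (beat-interval
  modulation) and RPA (R-peak amplitude) resampled to 4 Hz.
- **Reference RR**: the mean of a count-based fusion and an AR-based fusion
  of the surrogate + impedance channels, valid only when the two methods
  agree within 5 breaths/min. The AR path uses **order 4** on 10 s windows:
  order 8 on 40-sample windows is ill-conditioned (spurious poles, p90 error
  tens of breaths/min), while a single dominant respiratory component is
  captured by 4 coefficients (p90 error ≈ 0.6 breaths/min). This was chosen
  on conditioning grounds, not tuned to any acceptance threshold.

## 3. Evaluation (`neovitals.evaluate`)

Validity mask = presence AND no-intervention AND reference-valid, per
second, with an exclusion-category summary. Agreement statistics over valid
seconds where both series are valid: MAE, bias, bias-removed mean absolute
deviation (MAD), Bland–Altman 95 % limits of agreement, pooled Pearson
correlation (reported as NaN when degenerate), and estimated-time % (valid
camera estimates / valid seconds). Gap analysis bins maximal runs of
valid-but-unestimated seconds; the adjusted percentage treats gaps ≤ G
seconds as estimated and is monotone non-decreasing in G, equalling the raw
percentage at G = 0. Group differences (e.g. motion vs quiet SQI) use a
one-sided permutation test.

Open question resolved: the correlation is pooled Pearson over seconds (a
per-session average is not computable from a single synthetic session).

## 4. Synthetic generators (`neovitals.scenes`)

### What is emulated

- Video: a skin-coloured filled ellipse (RGB [210, 160, 135]) on a dark
  background ([55, 58, 66]), 120×160 px at 20 frames/s. The green plane
  carries the cardiac pulse sin(2πft) + 0.3 sin(4πft) at fractional depth
  `ppgi_amplitude` (default 0.03); the minor axis and vertical centroid
  breathe at fractional depth `shape_amplitude` (0.04). Per-pixel texture
  noise (sd 4), **global frame-level noise (sd 0.3)** — without a common
  noise component the spatial mean would average pixel noise away and make
  the extraction unrealistically easy — motion bursts (smooth random
  centroid trajectories), multiplicative lighting steps, absence intervals.
- HR/RR schedules: constants, step lists or callables; beat and breath
  instants are integer crossings of the integrated rate phase, so counts
  match the schedule integral exactly.
- Monitor waveforms from the *same* event times: ECG at 500 Hz with R-wave
  amplitude and baseline respiratory modulation **and a 4 % respiratory
  modulation of the beat rate** (so EDR, RPA *and* RSA are all recoverable —
  without rate modulation RSA would be flat); PPG at 125 Hz with a dicrotic
  wave; impedance pneumography at 64 Hz; 1 Hz monitor numerics from trailing
  event windows.

### What is not emulated

Real skin chromophores and camera spectral response, specular reflections,
compression artefacts, clinical interventions (hands in frame), ECG
electrode artefacts, apnoea/bradycardia events, and non-elliptical anatomy.
Absolute clinical error statistics therefore do not transfer; the generators
support *algorithm verification* (ground-truth recovery, gating behaviour,
invariances), not clinical validation.

## 5. Problem sizes and runtime (single CPU)

- Full test suite: 197 tests, ≈ 70 s (including the shared 10-minute
  acceptance scene, ≈ 48 s).
- Acceptance script: ≈ 50 s (12 000 frames of 120×160 video through the full
  pipeline, 1000 IOU oracle cases, 15 AR tones, 60 s reference chain).
- Memory: frames are generated lazily; the pipeline streams a single pass,
  so a 10-minute scene needs only per-frame features in memory (≈ a few MB).

## 6. Known limitations

- The AR-best model-order selection assumes a single dominant cardiac
  component; polyphonic interference (e.g. strong mains flicker inside the
  band) is not modelled.
- Change-point detection assumes approximately Gaussian level noise; slow
  ramps are not detected (by design — only steps gate beats).
- The respiratory count/AR agreement rule can reject valid seconds during
  rapid rate transitions (both methods lag differently).
- Reference gating is strict (> 0.5 SQI, ≤ 5 beats/min agreement); on noisy
  input it prefers dropping seconds over emitting doubtful references.
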