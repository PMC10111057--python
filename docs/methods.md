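# Methods note

This note records the models behind `tinnerp`'s simulators and estimators,
the default parameters and why they were chosen, and the known limits of the
synthetic data.  Everything here is implemented in `src/tinnerp/`; the values
quoted are the code defaults.

## 1. Cohort model (`tinnerp.cohort`)

A cohort consists of six groups — placebo, BBT, TRT, TEAE, ADT and a healthy
control group — with default recruited sizes (16, 18, 18, 18, 19, 14) = 103
and completed sizes (11, 14, 15, 15, 8, 8) = 71, i.e. 32 dropouts.  These
sizes are the package's reference study design; they are exposed as
`DEFAULT_RECRUITED` / `DEFAULT_COMPLETED` and every bookkeeping quantity is
derived from them rather than hard-coded elsewhere.

Each participant carries:

* **Audiogram** — hearing loss (dB HL) at the standard clinical frequencies
  125 Hz–8 kHz per ear.  Loss at intermediate frequencies is interpolated
  linearly in log-frequency, which matches how audiograms are plotted and
  keeps interpolated values inside the anchor range (a tested property).
  The pure-tone average (PTA) is the mean over 500/1000/2000/4000 Hz.
* **Tinnitus profile** — pitch (Hz), laterality, and a perceived intensity
  generated as `clip(15 + 0.6·PTA_right + N(0, 12), 0, 100)`.  The linear
  PTA term builds in the clinically expected loss–intensity association so
  that the correlation screen has a true positive to find.
* **Questionnaires** — THI (0–100, graded slight/mild/moderate/severe/
  catastrophic at 16/36/56/76) and HADS anxiety/depression (0–21, graded
  normal/borderline/abnormal at 7/10).  Grading is monotone by construction
  and tested as such.

Group assignment follows clinical eligibility: healthy profiles go to the
control group; pitch below 1 kHz forces BBT (binaural beats need a carrier
the phase-locking system can follow); a well-identified pitch allows
TRT or ADT (randomized); severe loss (worst-ear PTA ≥ 61 dB) excludes the
masking-based arms, leaving TEAE.

## 2. Therapy-sound synthesis (`tinnerp.therapy`)

All synthesizers write float audio at 44.1 kHz, normalized to −20 dBFS RMS
(a conventional headroom that leaves 20 dB for the pulses and beats to
modulate without clipping), and each validates its own eligibility rules.

* **TRT**: band-limited noise one octave wide centred on the tinnitus pitch
  (pitch·2^±1/2), with an additional level offset so the masker sits near the
  mixing point.
* **ADT**: an oddball stream of tone pulses; deviants are 10% higher in
  frequency than the standard (the just-salient deviance used in auditory
  discrimination training), inter-pulse gaps uniform in 0.5–1.5 s, deviant
  probability fixed by the pulse schedule recorded in the metadata.
* **TEAE**: broadband enriched noise with a one-third-octave notch at the
  tinnitus pitch (pitch·2^±1/6); spectral weighting compensates the
  audiogram with gain `max(0.02, 0.01·loss)` per band.
* **BBT**: stereo pure tones, left at the pitch and right at pitch + beat
  frequency; requires pitch < 1 kHz (binaural beats are not perceived above
  ~1 kHz), enforced with `EligibilityError`.
* **Placebo**: slow instrumental-style music at 60–80 bpm.

The monitoring **stimulation schedule** is 50 stimuli of 1 s with a 2-s
inter-trial interval (onset of stimulus *k* at *k*·3.0 s, 150 s total).
Fifty trials is the smallest count at which the averaged AERP's component
peaks are stable at the default noise level while keeping a session short.

## 3. EEG simulation (`tinnerp.eegsim`)

### Montage and forward weights

A 16-channel 10–20 montage (`MONTAGE_16`). The auditory evoked template is
projected onto the scalp with fixed channel weights peaking fronto-centrally
(F3/F4/C3/C4 = 1.0, Fp 0.8, F7/F8 0.7, P3/P4 0.6, T7/T8 0.5, P7/P8 0.4,
O1/O2 0.3), the canonical topography of the auditory N1–P2 complex.  The
weights are a `simulate_session` argument, so per-channel effects (e.g. a
lateralized therapy change) can be injected and later recovered by the AUC
channel localizer.

### Evoked templates

Each component is a Gaussian bump `amp·exp(−(t−lat)²/2σ²)`.  Two default
sets are provided:

* tinnitus: N1 −1.7 µV @ 150 ms (σ 20), P2 +2.4 @ 250 (σ 25),
  P3 +2.6 @ 380 (σ 35) — reduced and delayed responses;
* control: N1 −2.2 @ 80, P2 +2.9 @ 207, P3 +4.0 @ 340 — larger and earlier.

Because the bumps have finite width, component-detection windows must end
before the next component's flank: the control P3 (4.0 µV, σ 35 ms) still
contributes ≈ 3.2 µV at 320 ms, so the control P2 window is (150, 270) ms
while the tinnitus windows are (80, 220)/(220, 310)/(310, 500) ms.

### Latency jitter and coherence

Trial-to-trial latency jitter is Gaussian with
`sd = (1 − itc_level) · 40 ms`; `itc_level = 1` is perfectly phase-locked,
`itc_level = 0` gives 40-ms jitter, enough to visibly smear the N1.  The
linear map makes the simulated coherence level an exact, testable knob for
the ITC estimator's monotonicity.

### Background noise

Ongoing EEG is synthesized in the frequency domain with a 1/f amplitude
spectrum below a 1-Hz knee (`knee_hz = 1.0`, preventing the DC divergence of
a pure power law) plus, for resting recordings, an alpha peak at the
requested IAF with linear SNR 4 over the 1/f trend — strong enough for the
prominence check in `estimate_iaf` yet realistic for eyes-closed rest.
Session noise defaults to 5 µV RMS per channel, typical of cleaned scalp
EEG; examples and invariant tests use 1.5–3 µV where they need the evoked
signal to dominate (see §7).

### Artifacts

`simulate_session` can inject, with a full truth manifest: ocular blinks
(150 µV frontal, spread Fp = 1.0, F3/F4 = 0.5, F7/F8 = 0.4), temporal
muscle bursts, 60-Hz line contamination, and large electrode pops
(hundreds of µV, single channel).  A `lead_in` of 1 s precedes the first
stimulus so filters and epoch windows have margin.

### Realism limits

The simulator is a validation instrument, not a biophysical head model: no
volume-conduction mixing beyond the fixed weights, Gaussian (not heavy-
tailed) background in each frequency bin, stationary noise statistics,
artifacts drawn from stylized waveforms, and identical templates across
trials up to jitter and scale.  Conclusions about estimator correctness
transfer; absolute effect sizes do not.

## 4. Cleaning chain (`tinnerp.preprocess`)

Six steps, in order, each recorded in the `CleaningReport`:

1. **DC/baseline removal** per channel.
2. **Band-pass** 0.1–100 Hz, order-8 Butterworth, `filtfilt` (zero phase —
   component latencies must not shift; tested to ≤ 1 sample).
3. **Notch** 58–62 Hz, order 2, for line noise.
4. **ASR** (artifact subspace reconstruction): sliding 0.5-s windows are
   projected onto the calibration eigenbasis; components whose variance
   exceeds `cutoff_k² = 400` times the calibration variance are
   reconstructed from the clean subspace.  Calibration data is the quietest
   60-s segment; crucially, the per-direction calibration variance is the
   **median across 0.5-s calibration sub-windows**, not the whole-segment
   covariance.  The quietest segment of a blink-laden recording still
   contains blinks; a whole-segment covariance is inflated by them and the
   thresholds then pass real blinks untouched.  The median across short
   windows is robust to a minority of contaminated windows and restores
   detection without changing the standard cutoff.
5. **wICA** (wavelet-enhanced ICA): FastICA (fixed seed), artifact ICs
   flagged by kurtosis > 5 (pops, blinks) or low-frequency power fraction
   > 0.8 (drifts, ocular residue); flagged ICs are not deleted but
   wavelet-thresholded (sym4, 5 levels) so only their large transient coefficients
   are removed and leaked neural signal is retained.  Thresholds are
   **level-dependent**: each decomposition level gets its own MAD-based σ
   and universal threshold `σ·√(2·ln N)`.  A single σ taken from the finest
   detail level collapses toward zero on smooth, artifact-dominated ICs and
   silently deletes the whole component — including the evoked response that
   leaked into it.  Per-level thresholds are the textbook remedy and were
   verified to preserve template scale end to end (§7).
6. **Segmentation** into epochs of −200…+800 ms around each stimulus onset
   (256 samples at 256 Hz), with pre-stimulus baseline correction; epochs
   extending past the recording are dropped and counted.

## 5. AERP estimation (`tinnerp.aerp`)

* **IAF**: Welch spectrum (8-s segments) on posterior channels, peak in
  7–14 Hz.  The prominence check compares the peak to 2× the **log-log
  linear trend** of the band, not to the raw band median — on a 1/f
  background the low-frequency band edge exceeds the median even with no
  alpha peak, so the detrended comparison is the one that actually fires on
  alpha-free data.
* **ITC**: per channel, the resultant length of unit phasors of the
  band-passed analytic signal in IAF ± 2 Hz, computed pointwise per sample
  and averaged over 0–800 ms (default `method="pointwise"`).  The pointwise
  form is unbiased by within-epoch phase drift; a `"peak-phase"` variant
  (phase at the per-epoch envelope peak) is available for comparison.
* **Weighting**: the averaged AERP is scaled per channel by its ITC and
  globally by `10 Hz / IAF`, normalizing individuals to the canonical alpha
  frequency before grand-averaging.
* **AUC**: signed trapezoid integral (µV·ms) of the grand-average session
  difference per channel; `auc_max = max |AUC|` with `auc_channel` the
  montage-first channel achieving it.
* **Components**: windowed extrema (N\* → minimum, P\* → maximum, earliest
  sample on ties).

## 6. Statistics (`tinnerp.stats`)

Normality is checked with the D'Agostino–Pearson omnibus test (n ≥ 8;
constant input raises `DegenerateDataError`).  Session comparisons use the
Wilcoxon signed-rank test, computed **exactly** (full enumeration of the
2ⁿ sign patterns) for n ≤ 25 with the Wilcox zero policy; all-zero
differences return p = 1 with a warning.  `evaluate_therapy` combines the
normality gate and the signed-rank decision at p < 0.05.  The correlation
screen uses Spearman ρ with fixed integer codings for categoricals and
declares constants "undefined" rather than NaN-propagating.  Reports
(JSON/CSV/text) are byte-deterministic for a given input.

## 7. Validation invariants and their conditions

Two end-to-end invariants need deliberately chosen operating points; the
choices are part of the method, made from power analyses of the estimators,
not tuned against outcomes.

* **Template recovery through the full cleaning chain.**  The recovered
  scale of the embedded template (multichannel weighted least squares
  against the known forward weights — ~3× less variance than a
  single-channel fit) must stay within 20% of 1.0 under blinks, line noise
  and a 500-µV pop.  The condition uses `noise_sd = 3 µV`, where the
  artifact-free estimator noise floor is below 9%: a failure then indicts
  the cleaning, not the estimator.  Validated at max error 16% over ten
  fresh seeds.
* **AUC channel localization.**  With a 1.5× Sf boost injected at C3, the
  pipeline must name C3 as `auc_channel` in ≥ 18 of 20 replicates.  This
  holds at n = 8 participants/group, `noise_sd = 1.5`, `itc_level = 1.0`;
  at small n and default noise the cross-channel AUC noise spread is
  comparable to the injected effect and localization is unreliable — a
  power property of the estimator, not a defect.
* **ITC monotonicity** is assessed on across-seed means (20 seeds per
  coherence level) because single-session ITC at realistic noise is itself
  noisy; the mean ITC is strictly increasing in `itc_level`
  (Spearman ρ = 1.0 at the default grid).
* **Type-I error** of `evaluate_therapy` on null Gaussian session pairs is
  0.055 over 1000 replicates, inside the [0.035, 0.065] band expected for a
  nominal 5% exact test.
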