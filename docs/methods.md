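# Methods

## The problem

EEG recorded during fMRI acquisition is dominated by two machine-locked
artifacts: the **gradient artifact** from switching spatial-encoding
gradients (locked to slice/volume timing, orders of magnitude larger than
brain activity) and the **ballistocardiogram (BCG)** from cardiac-driven
head/electrode motion in the static field (locked to the heartbeat, a few
times larger than brain activity, variable from cycle to cycle). On top of
these come ordinary physiological artifacts — blinks, saccades, muscle
activity, loose-electrode transients — and motion.

`emriclean` removes them in two stages, mirroring standard practice:

1. **Template subtraction** for the machine-locked artifacts: average
   artifact subtraction (AAS) with a sliding, centered window of
   artifact-locked epochs, optionally followed by an optimal basis set
   (OBS) step that regresses out the leading principal components of the
   epoch residuals. Gradient correction runs at the native sampling rate
   on volume-locked epochs; BCG correction runs after downsampling and
   filtering on heartbeat-locked epochs.
2. **Spatial unmixing** for everything else: extended Infomax ICA with as
   many components as channels, rule-based classification of artifactual
   components, and selective reconstruction
   `x_final = A' S` with the flagged mixing columns zeroed — an exact
   linear identity, so `x − x_final` equals the summed back-projection of
   the removed components.

Stage order: volume triggers → gradient AAS(+OBS) → downsample to
250 S/s → bandpass (1–70 Hz resting, 0.1–70 Hz task) → notch bank
(slice-selection frequency and harmonics, 26 Hz vibration, 60 Hz line;
1 Hz-wide FIR band-stops) → cardiac detection → BCG AAS → bad-interval
detection → excision → ICA fit on the excised data → full-length
projection → classification → reconstruction. Bad intervals are excluded
from the ICA *fit* only; the delivered recording is full length, with the
intervals reported for downstream exclusion.

## Template subtraction details

* **Windows.** Gradient: 30 volume epochs, centered. BCG: 21 heartbeat
  epochs, centered, anchored at `peak − 0.1 s + delay` with length one
  median RR interval. The anchor delay is exposed (default 0) because
  pulse-oximetry peaks trail the R-wave by a transit delay that varies
  between setups.
* **High-passed templates.** Templates are estimated on data high-passed
  at the band's low edge (1 Hz for gradient correction). The repetitive
  artifacts are broadband; slow drift is not, and letting it into a tiled
  template re-injects it as epoch-rate comb splatter across the whole
  band (~8 µV RMS measured on simulated sessions). The artifact's sub-1 Hz
  remnant is removed by the subsequent bandpass.
* **Sub-sample alignment** (`align`, off by default): per-epoch timing is
  estimated by cross-correlation at 10× interpolation on the most
  artifact-dominated channel; epochs are aligned before averaging and the
  template is re-delayed per epoch before subtraction. Unnecessary when
  the amplifier and scanner clocks are synchronized (the assumed
  condition), useful when they are not.
* **Robust averaging.** Epochs whose per-channel RMS exceeds 3× the
  median epoch RMS are excluded from the template (plain-mean fallback
  when a window is empty). Without this, a single 500 µV motion burst
  contaminates the sliding template and smears error over the surrounding
  minute of data.
* **OBS.** Implemented and exposed (`n_obs`), but the pipeline default is
  `n_obs = 0` for gradient residuals: with amplifier and scanner clocks
  synchronized the volume template is exact, and PCA of the post-AAS
  residual stack captures *neural* variance — subtracting it measurably
  removed real signal (occipital recovery dropped from ~0.75 to ~0.53 on
  simulated sessions). This is the same mechanism that argues against OBS
  for BCG. For unsynchronized acquisitions with genuine residual
  variability, `n_obs` of ~4 is appropriate.
* **Filters.** Linear-phase windowed-sinc (Hamming) kernels applied with
  exact zero phase (symmetric kernel, reflective padding); transition
  width max(1 Hz, 10% of the edge); notches are 1 Hz-wide band-stops with
  ≥30 dB attenuation at the center. Downsampling uses polyphase
  resampling with its anti-alias filter; marker samples rescale with
  round-half-down.

## Cardiac detection

Three detectors, used in preference order pulse-oximetry → ICA → ECG:

* **Pulse-ox** (50 S/s photoplethysmogram): 5 Hz low-pass, local maxima
  with ≥0.33 s separation and prominence ≥0.3× the 10–90 percentile
  spread, parabolic sub-sample refinement. The systolic peak trails the
  R-wave by a constant transit delay; only relative timing matters for
  template anchoring.
* **ICA route**: every component is scored for cardiac periodicity on its
  smoothed analytic envelope — maximum normalized autocorrelation at a
  physiologic lag (0.33–2 s, with octave correction) combined with the
  fraction of envelope spectral power at the implied fundamental and its
  2nd–3rd harmonics, as `sqrt(ρ·fraction)`. Scoring the *envelope* rather
  than the raw waveform matters: per-cycle latency jitter decorrelates
  the waveform but not its energy. Below a score of 0.3 the detector
  declines (low confidence) and the caller falls back to ECG. Heart rate
  is taken from the autocorrelation lag; beat events from peaks of the
  envelope band-limited around the fundamental. Per-beat timing from this
  route is accurate to a few tens of ms only when the rhythm is steady;
  with RR variability the cycle phase random-walks against any envelope
  tracker. This is a known limitation, and why pulse-ox is preferred.
* **ECG route**: 0.1–12 Hz bandpass, derivative–square–integrate energy
  with a 0.33 s refractory period, peak refinement on the squared
  filtered signal (polarity-invariant).

## Bad intervals

Sliding 0.5 s Hann windows with 0.25 s step; a window is bad when any
channel's 0.5–7 Hz power exceeds that channel's median window power by
8 dB. A region is excised only when ≥4 consecutive windows are bad —
sub-second transients (blinks) must stay in the data so ICA can model
them; sustained motion must go. Spans are padded by one step and merged.

## ICA

Extended Infomax (sub- and super-Gaussian, kurtosis-sign switching with a
small super-Gaussian bias), fit by full-batch natural-gradient ascent on
ZCA-sphered data: the step size grows geometrically while successive
updates stay aligned (<30°), anneals when they turn (>60°), and halves on
divergence. A seeded subsample (8000 columns) warm-starts the fit; the
final iterations run on the full batch. Max 512 iterations,
weight-change tolerance 1e-7; non-convergence is a warning, not an error.
Determinism is exact given (input, seed); the default seed (97) is
recorded in the run report. On the standard benchmark (3 super-Gaussian
sources among 28 Gaussians, 31×29k) recovery |corr| ≥ 0.99 in ~15 s.
Components are ordered by back-projection variance; mixing columns are
normalized to unit norm with a positive peak, which leaves the
reconstruction identically unchanged.

The solver is authored here because the available reference
implementation's per-block Python loop is ~100× slower at this problem
size; the reference implementation serves as an independent cross-check
in the test suite.

## Component classification

Features per component: interpolated scalp map (thin-plate spline on the
built-in 31-channel 10–20 montage, 64×64 unit-disk grid), active area
(|value| ≥ 0.5·max), unipolar/bipolar shape (two opposite lobes each
≥0.6·max), occipital-template overlap (fraction of the active area inside
r=0.2 disks around O1/O2/Oz), frontopolar and orbitofrontal
concentration; Welch PSD with band means (delta 1–4, theta 4–7, alpha
7–13, beta 13–30, gamma 30–60 Hz) and peak frequency; kurtosis
(Gaussian = 3), channel back-projection concentration (largest channel
power over the runner-up — the "one channel ≫ the others" criterion; a
median denominator would flag every focal map), cardiac-locked score
(max of locked-mean RMS ratio and the coefficient of variation of the
phase-resolved RMS profile — residual BCG after AAS has random per-cycle
latency that cancels the locked mean but not the locked energy), and
variance contribution.

Rules, evaluated in order with single assignment:

1. **Occipital-alpha guard** (protects the posterior alpha rhythm):
   occipital overlap >0.4 (unipolar) or >0.91 (bipolar), and PSD peak in
   7–13 Hz or alpha band mean above delta/theta/beta → neural, never
   removable.
2. **Blink**: unipolar, Fp1/Fp2 mean |weight| ≥2× the other channels,
   anterior active centroid.
3. **Saccade**: bipolar with opposite-signed lobes peaking at F7 and F8.
4. **Single channel**: kurtosis >4, channel concentration >5×, PSD peak
   outside alpha.
5. **Muscle**: gamma band mean above every other band, or PSD peak in
   30–60 Hz (the peak clause catches narrowband noise residue and
   intermittent bursts whose whole-recording band mean is diluted).
6. **BCG**: bipolar with lobes in opposite hemispheres, PSD peak outside
   alpha, alpha not the largest band, cardiac-locked score ≥0.3.

A variance-contribution floor below which components are labelled but not
removed exists and is off by default.

## Synthetic sessions

The simulator builds 31-channel 10–20 recordings at 5000 S/s under the
default acquisition condition (TR 2 s, 39 slices/volume → 19.5 Hz slice
frequency; 8 min sessions; 72 bpm with 5% RR jitter). Layers, each with a
fixed mixing vector and stored waveform so that `raw = clean + Σ layers`
exactly:

* neural background: 20 independent 1/f (exponent 1) sources with random
  maps, ~10 µV per channel, plus 1 µV white amplifier noise per channel
  (keeps the 31-channel covariance full rank, as real amplifiers do);
* occipital alpha: 8–12 Hz bandpassed noise (coherence time ~0.1–1 s, as
  in real alpha — a constant-phase sinusoid at exactly a volume-rate
  harmonic would be coherently absorbed by AAS, which real alpha is not)
  with 1 Hz-bandwidth positive envelope, 10 µV at O1/O2;
* gradient: a fixed 80–2000 Hz burst repeated at every slice onset, 100×
  neural RMS, per-channel gains 0.5–1.5, slice markers written at onsets;
* BCG: left/right antisymmetric temporo-central map, a ~3 Hz biphasic
  packet 0.21 s after each R-event, 3× neural RMS, 10% amplitude and
  15 ms latency jitter per cycle (pulse-transit-time variability — this
  is what leaves residual BCG components after AAS);
* blinks (frontopolar biphasic 400 ms, ~100 µV, Poisson 0.2/s), saccades
  (F7/F8 opposite boxcar steps, 40 µV, 0.1/s), muscle (30–60 Hz bursts
  on a bilateral temporal map, 25 µV RMS, 0.05/s), electrode pop (step +
  decay on one channel, 200 µV, 3 events), motion (1–7 Hz 2 s bursts on
  an all-channel map, 500 µV, 1/min);
* pulse-oximetry at 50 S/s with the systolic peak 0.25 s after each
  R-event plus a dicrotic bump and 5% noise.

Everything derives from one seed through independent spawned streams.
What the simulator does **not** emulate: volume-to-volume gradient
waveform variability (clock-synchronized acquisition is assumed),
electrode-specific BCG waveform shapes, helium-pump/carbon-wire
artifacts, non-stationary alpha topography, and genuinely mixed
neural/artifact sources. Passing tests therefore demonstrate the
machinery is correct under the stated model, not that classification
performance transfers to any real recording.

## Validation quantities

The test suite and `scripts/acceptance.py` recompute, from freshly
simulated sessions (2-minute sessions are used as a scaled version of the
8-minute study condition; the batch size is 20 seeds in the test suite
and 6 in the script):

* gradient suppression at the slice-frequency harmonics (≥30 dB);
* occipital recovery: correlation of the corrected O1/O2/Oz with the
  band-matched clean layer, detected bad intervals excluded (≥0.8 mean),
  against raw-vs-clean at the native rate (<0.2);
* per-class classifier sensitivity (≥0.9) and specificity (≥0.9) against
  planted sources, matched by maximum |correlation| with band-matched
  ground-truth waveforms; zero guarded-alpha components removed;
* pulse-ox recall ≥0.99 within ±20 ms (constant transit offset removed)
  across 50–90 bpm; ICA-route heart rate within 2 bpm;
* exact reconstruction identities and ≥60 dB AAS annihilation of a
  noiseless repetitive artifact;
* mixing-matrix equivalence between ordered and time-shuffled fits
  (matched |corr| ≥0.99) — ICA uses only spatial statistics.

## ERP and resting-state analysis

The evaluation module reproduces the standard stop-signal ERP chain:
mastoid re-reference, 30 Hz low-pass (48 dB/octave; the half-amplitude
cutoff is read as 30 Hz — the unit given alongside it is a typo),
−200…800 ms epochs, baseline to the −200…0 ms mean, rejection of trials
with >50 µV sample-to-sample steps, >200 µV range or <0.5 µV flat-lining
in any 200 ms window; N2 (175–225 ms, negative, not measured at Pz where
it is not an identifiable deflection) and P3 (300–500 ms, positive) mean
and peak amplitudes; SNR = amplitude over the peak-to-peak excursion of
the trial-averaged baseline (the trial-averaged rather than single-trial
baseline, consistent with grand-average usage; both per-subject and
across-subject grand-average variants are provided). Resting PSD: 4.096 s
Hann windows (0.244 Hz resolution at 250 S/s), 50% overlap, windows
placed entirely within clean data, averaged per channel then across
channels; band edges delta 1–4, theta 4–7, alpha 7–13, beta 13–30 Hz.

## Known limitations

* Single-label classification: genuinely mixed neural/artifact components
  are removed or kept wholesale.
* The BCG rule's cardiac-locked criterion is this package's own concrete
  formulation of "BCG-like time course"; published rule sets for this
  step are not fully specified anywhere.
* ICA-route beat timing degrades with heart-rate variability (see above).
* At the 2-minute validation scale the ICA fit regularly stops at the
  iteration cap short of the weight-change tolerance; classification is
  robust to this, but source recovery |corr| for weak sources (residual
  BCG) is ~0.5 rather than ~0.9.
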