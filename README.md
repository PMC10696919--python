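# emriclean

Automatic artifact reduction for EEG recorded simultaneously with fMRI.

EEG acquired inside a scanner during functional imaging is buried under
two machine-locked artifacts — the **gradient artifact** from switching
spatial-encoding gradients (slice/volume-locked, ~100× brain activity)
and the **ballistocardiogram (BCG)** from cardiac-driven motion in the
static field (heartbeat-locked, ~3× brain activity) — plus the usual
blinks, saccades, muscle activity, loose-electrode transients, and
motion. `emriclean` removes all of them without manual intervention, for
anyone processing EEG-fMRI cohorts too large to clean by hand.

The pipeline combines the two standard strategies:

1. **Average artifact subtraction (AAS)** with a sliding, centered
   template window for the machine-locked artifacts — volume-locked
   epochs for the gradient (optionally with an optimal-basis-set residual
   step), heartbeat-locked epochs for the BCG (template over 21 cardiac
   cycles; heartbeats from pulse oximetry, from the EEG itself via ICA,
   or from an ECG channel) — plus downsampling to 250 S/s, bandpass
   (1–70 Hz rest, 0.1–70 Hz task) and 1 Hz-wide notches at the
   slice-selection frequency and harmonics (19.5, 39, 58.5 Hz for
   39 slices at TR = 2 s), vibration (26 Hz) and line (60 Hz) noise.
2. **Extended Infomax ICA** (components = channels, `x = A·S`) fitted on
   the recording with automatically detected bad intervals excised,
   followed by rule-based classification of components (BCG, blink,
   saccade, single-channel, muscle) from their scalp maps, spectra and
   time courses — with a guard that never removes occipital alpha — and
   selective reconstruction `x_final = A'·S` with flagged mixing columns
   zeroed.

A fully ground-truthed session simulator (31-channel 10–20 montage at
5000 S/s with separately stored artifact layers, `raw = clean + Σ layers`
exactly) makes every stage testable without any data download.

## Worked example

Simulate an EEG-fMRI session and clean it:

```sh
emriclean simulate --duration 120 --seed 1 --out demo/
emriclean run --eeg demo/session.vhdr --pulseox demo/pulseox.txt \
    --tr 2.0 --slices 39 --mode rest --out demo/out/
```

The run prints its report (abridged):

```json
{
 "notches_hz": [19.5, 26.0, 39.0, 58.5, 60.0],
 "cardiac": {"source": "pulseox", "hr_bpm": 72.46, "n_beats": 144},
 "bad_intervals": {"n_spans": 6, "total_seconds": 11.93},
 "components": {"0": "blink", "4": "bcg", "5": "muscle",
                "28": "single_channel", "29": "saccade", "30": "muscle"},
 "n_removed": 6
}
```

meaning: heartbeats were taken from the pulse-oximetry waveform
(72 bpm), ~12 s of motion-contaminated data were excluded from the ICA
fit, and six independent components were classified as artifacts and
removed from the reconstruction. Running the same session through the
in-memory pipeline (below), the corrected occipital channels correlate
0.92–0.95 with the simulator's artifact-free neural layer (band-matched,
bad intervals excluded), against ≤ 0.07 for the raw recording.

The same functionality is available as a library:

```python
from emriclean import SimConfig, simulate_session, RunConfig, run_pipeline
from emriclean.synthetic_data import simulate_pulseox

session = simulate_session(SimConfig(duration=120.0, seed=1))
pulse = simulate_pulseox(session.cfg, session.truth["r_peaks"])
result = run_pipeline(session.raw, RunConfig(), pulseox=(pulse, 50.0))
print(result.report["components"], result.report["bad_intervals"])
```

`emriclean evaluate erp|psd` computes stop-signal ERP measures
(N2/P3 mean and peak amplitude and their SNRs, after amplitude-based
trial rejection) and resting-state band power (4.096 s Hann windows,
0.244 Hz resolution) from corrected recordings.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

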