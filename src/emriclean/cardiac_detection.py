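"""Cardiac cycle detection.

Heartbeat-locked template subtraction needs one event per cardiac cycle, in
the EEG timebase. Three detectors are provided, mirroring how such events
are obtained in practice:

* :func:`detect_pulseox_peaks` — peak detection on a pulse-oximetry
  waveform (50 S/s photoplethysmogram), which is immune to MRI-induced
  electrical artifacts;
* :func:`detect_cardiac_ica` — pick the most cardiac-periodic independent
  component of the (already gradient-corrected) EEG itself and peak-detect
  its analytic envelope;
* :func:`detect_ecg_rpeaks` — a derivative-square-integrate R-peak detector
  for a simultaneously recorded ECG channel.

The pipeline prefers pulse oximetry when supplied, then the ICA route, and
falls back to ECG when the ICA confidence is low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_io import EEGRecording

__all__ = [
    "CardiacSeries",
    "CardiacCycles",
    "CardiacDetectionError",
    "LowConfidenceError",
    "detect_pulseox_peaks",
    "detect_cardiac_ica",
    "detect_ecg_rpeaks",
]

#: physiologic RR interval bounds (s): 30–180 bpm
RR_MIN_S = 0.33
RR_MAX_S = 2.0


class CardiacDetectionError(RuntimeError):
    pass


class LowConfidenceError(CardiacDetectionError):
    """The ICA route found no sufficiently cardiac-periodic component;
    callers should fall back to ECG."""


@dataclass
class CardiacSeries:
    """An auxiliary cardiac waveform (pulse-ox or ECG)."""

    waveform: np.ndarray
    rate: float
    source: str = "pulseox"  # {pulseox, ecg}

    def __post_init__(self):
        self.waveform = np.asarray(self.waveform, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.waveform.size <= 2 * self.rate:
            raise ValueError("cardiac series must be longer than 2 s")


@dataclass
class CardiacCycles:
    """Detected heartbeat events as strictly increasing samples in the EEG
    timebase."""

    peaks: np.ndarray
    hr_bpm: float
    source: str  # {pulseox, ica, ecg}
    confidence: float = 1.0
    eeg_rate: float = 250.0

    def __post_init__(self):
        self.peaks = np.asarray(self.peaks, dtype=int)
        if np.any(np.diff(self.peaks) <= 0):
            raise ValueError("peaks must be strictly increasing")


def _validated_cycles(
    peaks_eeg: np.ndarray, eeg_rate: float, source: str, confidence: float
) -> CardiacCycles:
    peaks_eeg = np.unique(np.asarray(peaks_eeg, dtype=int))
    if peaks_eeg.size < 3:
        raise CardiacDetectionError(f"{source}: too few peaks detected")
    rr = np.diff(peaks_eeg) / eeg_rate
    med = float(np.median(rr))
    if not (RR_MIN_S <= med <= RR_MAX_S):
        raise CardiacDetectionError(
            f"{source}: median RR {med:.3f} s outside physiologic range"
        )
    hr = 60.0 / med
    return CardiacCycles(
        peaks=peaks_eeg, hr_bpm=hr, source=source, confidence=confidence, eeg_rate=eeg_rate
    )


def detect_pulseox_peaks(
    series: CardiacSeries, eeg_rate: float, eeg_offset: float = 0.0
) -> CardiacCycles:
    """Systolic peak detection on the pulse-oximetry waveform.

    Local maxima with a minimum separation of 0.33 s and a prominence of at
    least 0.3x the 10–90 percentile amplitude spread; peak times are mapped
    into the EEG timebase via the rate ratio and ``eeg_offset`` (seconds).
    """
    if series.source != "pulseox":
        raise ValueError("series.source must be 'pulseox'")
    w = series.waveform
    p10, p90 = np.percentile(w, [10, 90])
    spread = p90 - p10
    if spread <= 0:
        raise CardiacDetectionError("pulseox: waveform has no amplitude variation")
    # the pulse wave lives below ~5 Hz; smoothing removes sensor noise that
    # would otherwise wander the argmax across the rounded systolic top
    if series.rate > 12.0:
        sos = signal.butter(2, 5.0, btype="low", fs=series.rate, output="sos")
        w = signal.sosfiltfilt(sos, w)
    peaks, _ = signal.find_peaks(
        w, distance=max(1, int(round(RR_MIN_S * series.rate))), prominence=0.3 * spread
    )
    if peaks.size == 0:
        raise CardiacDetectionError("pulseox: no peaks found")
    # parabolic sub-sample refinement around each discrete maximum
    t = peaks.astype(float)
    inner = (peaks > 0) & (peaks < w.size - 1)
    pm, p0, pp = w[peaks[inner] - 1], w[peaks[inner]], w[peaks[inner] + 1]
    denom = pm - 2 * p0 + pp
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (pm - pp) / denom, 0.0)
    t[inner] += np.clip(shift, -0.5, 0.5)
    t = t / series.rate + eeg_offset
    return _validated_cycles(np.round(t * eeg_rate), eeg_rate, "pulseox", 1.0)


def smoothed_envelope(source: np.ndarray, rate: float) -> np.ndarray:
    """Analytic-signal amplitude envelope, smoothed to one bump per cycle."""
    env = np.abs(signal.hilbert(source))
    win = max(3, int(round(0.1 * rate)) | 1)
    kernel = np.hanning(win)
    return signal.fftconvolve(env, kernel / kernel.sum(), mode="same")


def cardiac_periodicity_score(
    source: np.ndarray, rate: float
) -> tuple[float, float]:
    """Score how cardiac-periodic a time course is.

    Returns ``(score, fundamental_hz)``. Periodicity is measured on the
    amplitude envelope (robust to the cycle-to-cycle latency jitter that
    decorrelates the raw waveform): the maximum normalized autocorrelation
    at a lag in the physiologic RR range — corrected down an octave when
    half the lag is nearly as strong — combined with the fraction of
    envelope spectral power at the implied fundamental +-0.5 Hz and its
    2nd-3rd harmonics, as sqrt(rho * fraction).
    """
    env = smoothed_envelope(source, rate)
    x = env - env.mean()
    n = x.size
    lag_lo = int(RR_MIN_S * rate)
    lag_hi = min(int(RR_MAX_S * rate), n - 1)
    if lag_hi <= lag_lo or not x.any():
        return 0.0, np.nan
    ac = signal.fftconvolve(x, x[::-1], mode="full")[n - 1 :]
    if ac[0] <= 0:
        return 0.0, np.nan
    ac = ac / ac[0]
    lag = lag_lo + int(np.argmax(ac[lag_lo : lag_hi + 1]))
    # octave correction: a bump train has nearly equal peaks at RR and 2 RR
    half = lag // 2
    if half >= lag_lo:
        cand = half - 2 + int(np.argmax(ac[half - 2 : half + 3]))
        if ac[cand] >= 0.6 * ac[lag]:
            lag = cand
    rho = float(max(ac[lag], 0.0))
    f0 = rate / lag
    freqs, psd = signal.welch(x, fs=rate, nperseg=min(n, 2048))
    total = psd.sum()
    if total <= 0:
        return 0.0, f0
    in_band = np.zeros_like(freqs, dtype=bool)
    for k in (1, 2, 3):
        in_band |= np.abs(freqs - k * f0) <= 0.5
    frac = float(psd[in_band].sum() / total)
    return float(np.sqrt(rho * frac)), f0


def detect_cardiac_ica(
    rec: EEGRecording, seed: int = 97, threshold: float = 0.3
) -> CardiacCycles:
    """Detect heartbeats from the EEG itself via ICA.

    Decomposes the (gradient-corrected, downsampled, filtered) recording,
    scores every component for cardiac periodicity, and peak-detects the
    analytic envelope of the winner. The confidence is the periodicity
    score; below ``threshold`` a :class:`LowConfidenceError` is raised so
    the caller can fall back to ECG.
    """
    from .ica_engine import fit_infomax

    dec = fit_infomax(rec.data, seed=seed)
    best_score, best_i, best_f0 = 0.0, -1, np.nan
    for i in range(dec.S_short.shape[0]):
        score, f0 = cardiac_periodicity_score(dec.S_short[i], rec.rate)
        if score > best_score:
            best_score, best_i, best_f0 = score, i, f0
    if best_i < 0 or best_score < threshold:
        raise LowConfidenceError(
            f"best cardiac periodicity score {best_score:.3f} below {threshold}"
        )
    envelope = smoothed_envelope(dec.S_short[best_i], rec.rate)
    # one phase-locked peak per cycle: band-limit the envelope around the
    # fundamental before picking maxima
    sos = signal.butter(
        2, [0.6 * best_f0, 1.4 * best_f0], btype="bandpass", fs=rec.rate, output="sos"
    )
    narrowband = signal.sosfiltfilt(sos, envelope - envelope.mean())
    dist = max(1, int(round(0.6 * rec.rate / best_f0)))
    peaks, _ = signal.find_peaks(narrowband, distance=dist)
    cycles = _validated_cycles(peaks, rec.rate, "ica", float(best_score))
    # the autocorrelation lag estimates the rate more robustly than the
    # median interval of the tracked peaks
    cycles.hr_bpm = 60.0 * best_f0
    return cycles


def detect_ecg_rpeaks(
    series: CardiacSeries, eeg_rate: float, eeg_offset: float = 0.0
) -> CardiacCycles:
    """R-peak detection on an ECG channel.

    The series is bandpassed 0.1–12 Hz, differentiated, squared, and
    integrated over a 150 ms window; peaks of the integrated energy with a
    0.33 s refractory period mark beats, each refined to the local maximum
    of the squared filtered signal. Squaring makes the detector
    polarity-invariant.
    """
    if series.source != "ecg":
        raise ValueError("series.source must be 'ecg'")
    w = series.waveform
    fs = series.rate
    sos = signal.butter(4, [0.1, min(12.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, w)
    energy = np.gradient(filt) ** 2
    win = max(1, int(round(0.15 * fs)))
    integ = signal.fftconvolve(energy, np.ones(win) / win, mode="same")
    thresh = 0.3 * np.percentile(integ, 98)
    peaks, _ = signal.find_peaks(
        integ, distance=max(1, int(round(RR_MIN_S * fs))), height=thresh
    )
    if peaks.size == 0:
        raise CardiacDetectionError("ecg: no QRS energy peaks found")
    # refine to the squared-amplitude maximum near each energy peak
    refined = []
    half = int(round(0.1 * fs))
    sq = filt ** 2
    for p in peaks:
        a, b = max(0, p - half), min(sq.size, p + half + 1)
        refined.append(a + int(np.argmax(sq[a:b])))
    t = np.asarray(refined) / fs + eeg_offset
    return _validated_cycles(np.round(t * eeg_rate), eeg_rate, "ecg", 1.0)
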