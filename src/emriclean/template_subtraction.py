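"""Epoch-template artifact correction and filtering.

Average artifact subtraction (AAS) removes artifacts that repeat at known
event times — MRI gradient switching locked to volume onsets, and the
ballistocardiogram (BCG) locked to heartbeats — by subtracting, at each
event, the mean of the surrounding artifact-locked epochs. The optimal basis
set (OBS) step additionally regresses out the leading principal components
of the epoch residuals to capture cycle-to-cycle artifact variability.

The processing order is: gradient AAS+OBS at the native rate, downsample to
250 S/s, bandpass, notch bank, then BCG AAS after cardiac detection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .core_io import EEGRecording, Marker

__all__ = [
    "TemplateConfig",
    "FilterPlan",
    "aas_correct",
    "obs_residual_removal",
    "gradient_correct",
    "bcg_correct",
    "downsample",
    "apply_filters",
    "slice_frequency",
    "slice_notches",
]


@dataclass
class TemplateConfig:
    """Sliding-template parameters.

    window
        Number of epochs averaged per template (centered sliding window,
        inclusive of the current epoch).
    n_obs
        Principal components of the epoch residuals to regress out after the
        mean subtraction; 0 disables the OBS step.
    align
        Sub-sample alignment of epochs before averaging (off by default:
        amplifier and scanner clocks are assumed synchronized).
    template_highpass_hz
        When set, templates are estimated on (and subtracted from) the
        high-passed portion of the data only; the low-frequency path is
        left untouched. Broadband repetitive artifacts live above ~1 Hz,
        while slow neural drift in the template would otherwise be
        re-injected as epoch-rate splatter across the band.
    robust_exclude
        Epochs whose RMS exceeds this multiple of the median epoch RMS
        (per channel) are left out of the template average, so that
        non-repetitive transients (motion bursts, blinks) do not
        contaminate the artifact template. 0 or None disables.
    """

    window: int = 30
    n_obs: int = 0
    align: bool = False
    template_highpass_hz: float | None = None
    robust_exclude: float | None = 3.0

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.n_obs < 0:
            raise ValueError("n_obs must be >= 0")


@dataclass
class FilterPlan:
    """Bandpass plus a bank of band-rejection (notch) filters."""

    band: tuple[float, float] = (1.0, 70.0)
    notches: list[float] = field(default_factory=list)
    notch_bandwidth: float = 1.0

    def validate(self, rate: float) -> None:
        low, high = self.band
        nyq = rate / 2.0
        if not (0 <= low < high < nyq):
            raise ValueError(f"invalid passband {self.band} for rate {rate}")
        for c in self.notches:
            if c >= nyq:
                raise ValueError(f"notch at {c} Hz is at/above Nyquist ({nyq} Hz)")
        if self.notch_bandwidth <= 0:
            raise ValueError("notch_bandwidth must be positive")


# ---------------------------------------------------------------------------
# AAS / OBS
# ---------------------------------------------------------------------------

def _epoch_lags(stack: np.ndarray, oversample: int = 10, max_shift: int = 5) -> np.ndarray:
    """Per-epoch sub-sample lag against the first epoch, estimated by
    cross-correlation at ``oversample``-fold interpolation on the channel
    with the strongest (most artifact-dominated) signal."""
    ch = int(np.argmax(np.sqrt((stack**2).mean(axis=(1, 2)))))
    epochs = stack[ch]
    n_ep, length = epochs.shape
    up = signal.resample_poly(epochs, oversample, 1, axis=1)
    ref = up[0] - up[0].mean()
    span = max_shift * oversample
    lags = np.zeros(n_ep)
    for j in range(1, n_ep):
        x = up[j] - up[j].mean()
        xc = signal.fftconvolve(x, ref[::-1], mode="full")
        center = x.size - 1
        window = xc[center - span : center + span + 1]
        lags[j] = (int(np.argmax(window)) - span) / oversample
    return lags


def _fractional_shift(arr: np.ndarray, shift: float) -> np.ndarray:
    """Shift a 1-D array by a (possibly fractional) number of samples via
    linear interpolation, edge-padded."""
    n = arr.size
    pos = np.arange(n) + shift
    return np.interp(pos, np.arange(n), arr)


def _epoch_matrix(n_samples: int, events: np.ndarray, pre: int, post: int):
    """Usable epochs: start index per event, skipping boundary epochs."""
    starts, kept = [], []
    for i, ev in enumerate(events):
        a, b = ev + pre, ev + post
        if a < 0 or b > n_samples:
            continue
        starts.append(a)
        kept.append(i)
    return np.asarray(starts, dtype=int), np.asarray(kept, dtype=int)


def aas_correct(
    rec: EEGRecording,
    events: np.ndarray,
    epoch_span: tuple[int, int],
    cfg: TemplateConfig | None = None,
) -> EEGRecording:
    """Average-artifact subtraction at the given event samples.

    For each event, the per-channel mean over the surrounding ``cfg.window``
    epochs (centered window, inclusive) is subtracted over
    ``[event+pre, event+post)``. Samples outside all epochs are untouched.
    Epochs extending past the recording are skipped; epochs overlapping the
    next event are subtracted only up to the midpoint (with a warning).
    """
    cfg = cfg or TemplateConfig()
    events = np.asarray(events, dtype=int)
    if events.size < 2:
        raise ValueError("need at least 2 events for template subtraction")
    events = np.sort(events)
    pre, post = epoch_span
    length = post - pre
    if length <= 0:
        raise ValueError("epoch_span must satisfy post > pre")

    starts, kept = _epoch_matrix(rec.n_samples, events, pre, post)
    if starts.size < 2:
        raise ValueError("fewer than 2 usable epochs inside the recording")

    work = rec.data
    if cfg.template_highpass_hz:
        sos = signal.butter(
            4, cfg.template_highpass_hz, btype="high", fs=rec.rate, output="sos"
        )
        work = signal.sosfiltfilt(sos, rec.data, axis=1)

    idx = starts[:, None] + np.arange(length)[None, :]
    stack = work[:, idx]  # (channels, epochs, length)
    n_ep = starts.size

    lags = None
    if cfg.align and n_ep > 1:
        lags = _epoch_lags(stack)
        aligned = np.empty_like(stack)
        for j in range(n_ep):
            if lags[j] == 0.0:
                aligned[:, j] = stack[:, j]
            else:
                for c in range(stack.shape[0]):
                    aligned[c, j] = _fractional_shift(stack[c, j], lags[j])
        stack = aligned

    half = cfg.window // 2
    out = rec.data.copy()

    # overlap handling: subtract only up to the midpoint toward the neighbour
    gaps = np.diff(events[kept]) if kept.size > 1 else np.array([], dtype=int)
    overlaps = bool(gaps.size) and int(gaps.min()) < length
    if overlaps:
        warnings.warn(
            "epochs overlap neighbouring events; truncating at midpoints",
            stacklevel=2,
        )

    # outlier epochs (motion, blinks) are excluded from template averaging
    if cfg.robust_exclude:
        rms = np.sqrt(np.mean(stack**2, axis=2))  # (channels, epochs)
        med = np.median(rms, axis=1, keepdims=True)
        weights = (rms <= cfg.robust_exclude * np.maximum(med, 1e-300)).astype(float)
    else:
        weights = np.ones(stack.shape[:2])

    # cumulative weighted mean via prefix sums for the centered sliding window
    csum = np.concatenate(
        [
            np.zeros((rec.n_channels, 1, length)),
            np.cumsum(stack * weights[:, :, None], axis=1),
        ],
        axis=1,
    )
    csum_plain = None  # built only if some window loses every epoch
    wsum = np.concatenate(
        [np.zeros((rec.n_channels, 1)), np.cumsum(weights, axis=1)], axis=1
    )
    for j in range(n_ep):
        lo = max(0, j - half)
        hi = min(n_ep, lo + cfg.window)
        lo = max(0, hi - cfg.window)
        count = wsum[:, hi] - wsum[:, lo]  # (channels,)
        num = csum[:, hi] - csum[:, lo]
        # fall back to the plain mean on channels where every epoch was excluded
        empty = count == 0
        if empty.any():
            if csum_plain is None:
                csum_plain = np.concatenate(
                    [np.zeros((rec.n_channels, 1, length)), np.cumsum(stack, axis=1)],
                    axis=1,
                )
            num[empty] = (csum_plain[:, hi] - csum_plain[:, lo])[empty]
            count = np.where(empty, hi - lo, count)
        template = num / count[:, None]
        if lags is not None and lags[j] != 0.0:
            # re-delay the aligned template to this epoch's own timing
            template = np.stack(
                [_fractional_shift(template[c], -lags[j]) for c in range(template.shape[0])]
            )
        a = starts[j]
        b = a + length
        t0 = 0
        if overlaps:
            # truncate at the midpoint between overlapping neighbour epochs
            if j > 0 and starts[j - 1] + length > a:
                t0 = (starts[j - 1] + length - a + 1) // 2
            if j < n_ep - 1 and b > starts[j + 1]:
                b -= (b - starts[j + 1] + 1) // 2
        out[:, a + t0 : b] -= template[:, t0 : b - a]
    return rec.copy(data=out)


def obs_residual_removal(epoch_stack: np.ndarray, n_obs: int) -> np.ndarray:
    """Regress the first ``n_obs`` principal components of the demeaned
    epoch stack out of every epoch.

    ``epoch_stack`` is (epochs, samples) for one channel. ``n_obs`` = 0 is
    the identity.
    """
    stack = np.asarray(epoch_stack, dtype=float)
    if stack.ndim != 2:
        raise ValueError("epoch_stack must be 2-D (epochs x samples)")
    if n_obs == 0:
        return stack.copy()
    n_ep = stack.shape[0]
    if n_obs >= n_ep:
        raise ValueError(f"n_obs ({n_obs}) must be < number of epochs ({n_ep})")
    demeaned = stack - stack.mean(axis=0, keepdims=True)
    # principal component waveforms = leading right singular vectors
    _, _, vt = np.linalg.svd(demeaned, full_matrices=False)
    basis = vt[:n_obs]  # (n_obs, samples), orthonormal
    fit = (demeaned @ basis.T) @ basis
    return stack - fit


def gradient_correct(rec: EEGRecording, cfg: TemplateConfig | None = None) -> EEGRecording:
    """Remove the MRI gradient artifact: volume-locked AAS then OBS.

    Requires volume-kind markers (see
    :func:`emriclean.core_io.derive_volume_triggers`); operates at the
    native sampling rate, before downsampling. The epoch length is the
    median inter-volume interval. Templates are formed on data high-passed
    at 1 Hz so that slow neural drift never enters them; the artifact's
    sub-1 Hz remnant is removed by the subsequent bandpass.
    """
    cfg = cfg or TemplateConfig(window=30, n_obs=0, template_highpass_hz=1.0)
    volumes = rec.marker_samples("volume")
    if volumes.size == 0:
        raise ValueError(
            "no volume markers present; run derive_volume_triggers first"
        )
    if volumes.size < 2:
        raise ValueError("need at least 2 volume markers")
    length = int(np.median(np.diff(np.sort(volumes))))
    corrected = aas_correct(rec, volumes, (0, length), cfg)
    if cfg.n_obs > 0:
        starts, _ = _epoch_matrix(corrected.n_samples, np.sort(volumes), 0, length)
        if starts.size > cfg.n_obs:
            idx = starts[:, None] + np.arange(length)[None, :]
            work = corrected.data
            if cfg.template_highpass_hz:
                sos = signal.butter(
                    4, cfg.template_highpass_hz, btype="high", fs=corrected.rate, output="sos"
                )
                work = signal.sosfiltfilt(sos, corrected.data, axis=1)
            for ch in range(corrected.n_channels):
                resid_stack = work[ch, idx]
                fit = resid_stack - obs_residual_removal(resid_stack, cfg.n_obs)
                corrected.data[ch, idx] -= fit
    return corrected


def bcg_correct(
    rec: EEGRecording,
    cycles,
    cfg: TemplateConfig | None = None,
    anchor_delay_s: float = 0.0,
) -> EEGRecording:
    """Remove the ballistocardiogram by heartbeat-locked AAS.

    Epochs are anchored at ``peak + anchor_delay - 0.1 s`` and span one
    median RR interval; the template is the mean over a sliding 21-epoch
    window (the plain AAS choice — no OBS, which can remove neural
    activity). Run after downsampling and filtering.
    """
    cfg = cfg or TemplateConfig(window=21, n_obs=0)
    peaks = np.asarray(getattr(cycles, "peaks", cycles), dtype=int)
    if peaks.size < max(2, cfg.window // 2):
        raise ValueError(
            f"too few cardiac events ({peaks.size}) for a {cfg.window}-cycle template"
        )
    rr = np.diff(np.sort(peaks))
    median_rr = float(np.median(rr))
    if not (0.33 * rec.rate <= median_rr <= 2.0 * rec.rate):
        raise ValueError("cardiac detection failed: implausible median RR interval")
    pre = int(round((anchor_delay_s - 0.1) * rec.rate))
    length = int(round(median_rr))
    return aas_correct(rec, peaks, (pre, pre + length), cfg)


# ---------------------------------------------------------------------------
# Downsampling and filtering
# ---------------------------------------------------------------------------

def downsample(rec: EEGRecording, target_rate: float = 250.0) -> EEGRecording:
    """Anti-alias filter and decimate to ``target_rate`` (default 250 S/s,
    i.e. a 4 ms sample interval). Marker samples are rescaled with
    round-half-down."""
    if target_rate > rec.rate:
        raise ValueError("target rate must not exceed the current rate")
    if target_rate == rec.rate:
        return rec.copy()
    frac = Fraction(target_rate / rec.rate).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(rec.data, up, down, axis=1)
    ratio = rec.rate / target_rate
    n_new = data.shape[1]
    markers = []
    for m in rec.markers:
        s = int(math.ceil(m.sample / ratio - 0.5))  # round half down
        if 0 <= s < n_new:
            markers.append(Marker(label=m.label, sample=s, kind=m.kind))
    return rec.copy(data=data, rate=float(target_rate), markers=markers)


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def _fir_kernel_bandpass(low: float, high: float, rate: float) -> np.ndarray:
    """Linear-phase windowed-sinc (Hamming) bandpass; separate high/low
    sections combined by convolution, each with transition width
    max(1 Hz, 10% of its edge)."""
    kernels = []
    if low > 0:
        trans = max(1.0, 0.1 * low)
        taps = _odd(int(round(3.3 * rate / trans)))
        kernels.append(signal.firwin(taps, low, fs=rate, pass_zero=False, window="hamming"))
    trans = max(1.0, 0.1 * high)
    taps = _odd(int(round(3.3 * rate / trans)))
    kernels.append(signal.firwin(taps, high, fs=rate, pass_zero=True, window="hamming"))
    kern = kernels[0]
    for k in kernels[1:]:
        kern = np.convolve(kern, k)
    return kern


def _fir_kernel_notch(center: float, bandwidth: float, rate: float) -> np.ndarray:
    half = bandwidth / 2.0
    trans = half  # transition half the stop width keeps the notch narrow
    taps = _odd(int(round(3.3 * rate / trans)))
    return signal.firwin(
        taps, [center - half, center + half], fs=rate, pass_zero=True, window="hamming"
    )


def _zero_phase(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Exact zero-phase application of a symmetric odd-length FIR kernel,
    with edge reflection padding."""
    pad = len(kernel) // 2
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = signal.fftconvolve(padded, kernel[None, :] if data.ndim == 2 else kernel, mode="same")
    return out[..., pad:-pad]


def apply_filters(rec: EEGRecording, plan: FilterPlan) -> EEGRecording:
    """Apply the bandpass and every notch in the plan, zero-phase."""
    plan.validate(rec.rate)
    data = rec.data
    kern = _fir_kernel_bandpass(plan.band[0], plan.band[1], rec.rate)
    data = _zero_phase(data, kern)
    for c in plan.notches:
        data = _zero_phase(data, _fir_kernel_notch(c, plan.notch_bandwidth, rec.rate))
    return rec.copy(data=data)


def slice_frequency(n_slices: int, tr_seconds: float) -> float:
    """fMRI slice-selection frequency: slices per volume / TR.

    For 39 slices at TR = 2 s this is 19.5 Hz.
    """
    if n_slices <= 0 or tr_seconds <= 0:
        raise ValueError("n_slices and tr_seconds must be positive")
    return n_slices / tr_seconds


def slice_notches(n_slices: int, tr_seconds: float, high_edge: float) -> list[float]:
    """The slice frequency and its harmonics below the passband's high edge."""
    f0 = slice_frequency(n_slices, tr_seconds)
    return [f0 * k for k in range(1, int(high_edge / f0) + 1) if f0 * k < high_edge]
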