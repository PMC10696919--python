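"""Validation computations: ERP segmentation and measures, trial rejection,
SNR, and resting-state band PSD.

The ERP path follows standard stop-signal practice: mastoid re-reference,
30 Hz low-pass, segmentation from -200 to 800 ms around the stimulus,
baseline correction to the 200 ms pre-stimulus mean, amplitude-based trial
rejection, then mean/peak amplitudes in the N2 (175–225 ms, negative-going)
and P3 (300–500 ms, positive-going) windows. SNR is the component
amplitude over the peak-to-peak excursion of the trial-averaged baseline.

The resting-state path averages Hann-tapered moving-window FFTs (4.096 s
windows, 50% overlap, 0.244 Hz resolution at 250 S/s) over windows that lie
entirely inside clean data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core_io import EEGRecording
from .interval_rejection import BadIntervals

__all__ = [
    "ERPSet",
    "ERPMeasures",
    "PSDResult",
    "ERP_WINDOWS",
    "PSD_BANDS",
    "segment_erp",
    "reject_trials",
    "erp_measures",
    "erp_snr",
    "grand_average",
    "resting_psd",
]

EPOCH_SPAN_S = (-0.2, 0.8)
BASELINE_SPAN_S = (-0.2, 0.0)

#: component measurement windows in seconds post-stimulus, with the polarity
#: of the expected deflection
ERP_WINDOWS = {"N2": (0.175, 0.225, -1), "P3": (0.300, 0.500, +1)}

PSD_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (7.0, 13.0),
    "beta": (13.0, 30.0),
}

REJECT_STEP_UV = 50.0
REJECT_RANGE_UV = 200.0
REJECT_FLAT_UV = 0.5
REJECT_WINDOW_S = 0.2


@dataclass
class ERPSet:
    """trials x channels x time tensor (µV), -200..800 ms epochs."""

    trials: np.ndarray
    rate: float
    labels: list[str]
    rejected: np.ndarray = None  # bool per trial
    reject_reasons: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=float)
        if self.rejected is None:
            self.rejected = np.zeros(self.trials.shape[0], dtype=bool)
        if not self.reject_reasons:
            self.reject_reasons = [""] * self.trials.shape[0]

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_kept(self) -> int:
        return int((~self.rejected).sum())

    @property
    def times(self) -> np.ndarray:
        n = self.trials.shape[2]
        return EPOCH_SPAN_S[0] + np.arange(n) / self.rate

    def average(self) -> np.ndarray:
        """Trial-averaged waveform over kept trials (channels x time)."""
        kept = self.trials[~self.rejected]
        if kept.shape[0] == 0:
            raise ValueError("no surviving trials to average")
        return kept.mean(axis=0)


@dataclass
class ERPMeasures:
    """(channel, window) -> mean amplitude, peak amplitude, SNRs."""

    mean_amplitude: dict[tuple[str, str], float]
    peak_amplitude: dict[tuple[str, str], float]
    mean_snr: dict[tuple[str, str], float] = field(default_factory=dict)
    peak_snr: dict[tuple[str, str], float] = field(default_factory=dict)
    noise: dict[str, float] = field(default_factory=dict)


@dataclass
class PSDResult:
    freqs: np.ndarray
    per_channel: np.ndarray  # channels x freqs
    mean: np.ndarray  # cross-channel average
    band_means: dict[str, float]
    resolution: float
    n_windows: int


# ---------------------------------------------------------------------------
# ERP
# ---------------------------------------------------------------------------

def segment_erp(
    rec: EEGRecording,
    stim_markers: np.ndarray | None = None,
    lowpass_hz: float = 30.0,
    reref: str = "mastoids",
) -> ERPSet:
    """Re-reference, low-pass, segment and baseline-correct.

    ``stim_markers`` defaults to the recording's stimulus-kind markers.
    Mastoid re-referencing subtracts the TP9/TP10 average; the low-pass is
    a zero-phase Butterworth with a 48 dB/octave roll-off. Trials that
    under- or over-run the recording are dropped.
    """
    if stim_markers is None:
        stim_markers = rec.marker_samples("stimulus")
    stim_markers = np.asarray(stim_markers, dtype=int)
    if stim_markers.size == 0:
        raise ValueError("no stimulus markers to segment around")

    data = rec.data.copy()
    if reref == "mastoids":
        for lab in ("TP9", "TP10"):
            if lab not in rec.labels:
                raise ValueError(f"mastoid reference requires channel {lab}")
        ref = (data[rec.channel_index("TP9")] + data[rec.channel_index("TP10")]) / 2.0
        data = data - ref[None, :]
    elif reref not in (None, "none"):
        raise ValueError(f"unknown reref {reref!r}")

    if lowpass_hz:
        sos = signal.butter(4, lowpass_hz, btype="low", fs=rec.rate, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)

    pre = int(round(EPOCH_SPAN_S[0] * rec.rate))
    post = int(round(EPOCH_SPAN_S[1] * rec.rate))
    nbase = -pre
    trials = []
    for m in np.sort(stim_markers):
        a, b = m + pre, m + post
        if a < 0 or b > rec.n_samples:
            continue
        ep = data[:, a:b]
        baseline = ep[:, :nbase].mean(axis=1, keepdims=True)
        trials.append(ep - baseline)
    if not trials:
        raise ValueError("no usable trials (all overlap the recording edges)")
    return ERPSet(trials=np.stack(trials), rate=rec.rate, labels=list(rec.labels))


def _sliding_range_exceeds(x: np.ndarray, win: int, limit: float, below: bool = False) -> bool:
    """Any length-``win`` window where max-min exceeds (or, with ``below``,
    stays under) ``limit``. x is (channels, time)."""
    from numpy.lib.stride_tricks import sliding_window_view

    if x.shape[1] < win:
        return False
    v = sliding_window_view(x, win, axis=1)
    rng = v.max(axis=-1) - v.min(axis=-1)
    return bool((rng < limit).any()) if below else bool((rng > limit).any())


def reject_trials(erp: ERPSet) -> ERPSet:
    """Flag trials violating any amplitude rule on any channel:

    (a) a sample-to-sample step over 50 µV;
    (b) a max-min excursion over 200 µV within any 200 ms window;
    (c) flat-lining — max-min under 0.5 µV within some 200 ms window.
    """
    win = int(round(REJECT_WINDOW_S * erp.rate))
    rejected = erp.rejected.copy()
    reasons = list(erp.reject_reasons)
    for t in range(erp.n_trials):
        x = erp.trials[t]
        fired = []
        if np.abs(np.diff(x, axis=1)).max() > REJECT_STEP_UV:
            fired.append("step>50uV")
        if _sliding_range_exceeds(x, win, REJECT_RANGE_UV):
            fired.append("range>200uV")
        if _sliding_range_exceeds(x, win, REJECT_FLAT_UV, below=True):
            fired.append("flat<0.5uV")
        if fired:
            rejected[t] = True
            reasons[t] = ",".join(fired)
    return ERPSet(
        trials=erp.trials,
        rate=erp.rate,
        labels=erp.labels,
        rejected=rejected,
        reject_reasons=reasons,
    )


def _window_slice(times: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (times >= lo) & (times <= hi)


def erp_measures(
    erp: ERPSet, channels: list[str] | None = None
) -> ERPMeasures:
    """Mean and peak amplitude per channel and window on the trial average.

    The peak follows each component's polarity (N2 negative-going minimum,
    P3 positive-going maximum). N2 is not measured at Pz, where it is not
    an identifiable deflection.
    """
    if channels is None:
        channels = ["Fz", "FCz", "Cz", "Pz"]
    present = [c for c in channels if c in erp.labels]
    if not present:
        raise ValueError("no requested channels present in the ERP set")
    avg = erp.average()
    times = erp.times
    mean_amp: dict[tuple[str, str], float] = {}
    peak_amp: dict[tuple[str, str], float] = {}
    for ch in present:
        row = avg[erp.labels.index(ch)]
        for name, (lo, hi, pol) in ERP_WINDOWS.items():
            if name == "N2" and ch == "Pz":
                continue
            sel = _window_slice(times, lo, hi)
            seg = row[sel]
            mean_amp[(ch, name)] = float(seg.mean())
            peak_amp[(ch, name)] = float(seg.min() if pol < 0 else seg.max())
    return ERPMeasures(mean_amplitude=mean_amp, peak_amplitude=peak_amp)


def erp_snr(erp: ERPSet, channels: list[str] | None = None) -> ERPMeasures:
    """SNR per channel and window.

    Noise is the difference between the largest positive and largest
    negative peak of the trial-averaged pre-stimulus baseline; peak SNR is
    window peak / noise and mean SNR is window mean / noise. Zero noise
    (possible only for synthetic data) yields an infinite sentinel.
    """
    meas = erp_measures(erp, channels)
    avg = erp.average()
    times = erp.times
    base = _window_slice(times, BASELINE_SPAN_S[0], BASELINE_SPAN_S[1] - 1e-12)
    for ch in {c for c, _ in meas.mean_amplitude}:
        row = avg[erp.labels.index(ch)]
        noise = float(row[base].max() - row[base].min())
        meas.noise[ch] = noise
        for name in ERP_WINDOWS:
            if (ch, name) not in meas.mean_amplitude:
                continue
            if noise <= 0:
                warnings.warn(f"zero baseline noise at {ch}; SNR set to inf", stacklevel=2)
                meas.mean_snr[(ch, name)] = np.inf
                meas.peak_snr[(ch, name)] = np.inf
            else:
                meas.mean_snr[(ch, name)] = meas.mean_amplitude[(ch, name)] / noise
                meas.peak_snr[(ch, name)] = meas.peak_amplitude[(ch, name)] / noise
    return meas


def grand_average(erps: list[ERPSet]) -> ERPSet:
    """Across-subject grand average as a single-trial ERP set (each input's
    kept-trial average becomes one 'trial')."""
    if not erps:
        raise ValueError("no ERP sets supplied")
    labels = erps[0].labels
    rate = erps[0].rate
    for e in erps[1:]:
        if e.labels != labels or e.rate != rate:
            raise ValueError("ERP sets must share channels and rate")
    avgs = np.stack([e.average() for e in erps])
    return ERPSet(trials=avgs, rate=rate, labels=labels)


# ---------------------------------------------------------------------------
# resting-state PSD
# ---------------------------------------------------------------------------

def resting_psd(
    rec: EEGRecording,
    bad: BadIntervals | None = None,
    window_s: float = 4.096,
    overlap: float = 0.5,
) -> PSDResult:
    """Averaged moving-window FFT over clean data.

    Hann windows of ``window_s`` seconds with 50% overlap are placed only
    where they fit entirely inside kept (non-bad) data; their periodograms
    are averaged per channel, then across channels. Band means cover
    delta/theta/alpha/beta.
    """
    nwin = int(round(window_s * rec.rate))
    step = max(1, int(round(nwin * (1.0 - overlap))))
    spans = bad.spans if bad is not None else []
    keep_edges = []
    prev = 0
    for a, b in spans:
        if a > prev:
            keep_edges.append((prev, a))
        prev = max(prev, b)
    if prev < rec.n_samples:
        keep_edges.append((prev, rec.n_samples))

    taper = np.hanning(nwin)
    scale = 1.0 / (rec.rate * (taper ** 2).sum())
    freqs = np.fft.rfftfreq(nwin, 1.0 / rec.rate)
    acc = np.zeros((rec.n_channels, freqs.size))
    n_windows = 0
    for a, b in keep_edges:
        for s in range(a, b - nwin + 1, step):
            seg = rec.data[:, s : s + nwin]
            seg = (seg - seg.mean(axis=1, keepdims=True)) * taper
            spec = np.abs(np.fft.rfft(seg, axis=1)) ** 2 * scale
            spec[:, 1:-1] *= 2.0  # one-sided
            acc += spec
            n_windows += 1
    if n_windows == 0:
        raise ValueError("not enough clean data for a single PSD window")
    per_channel = acc / n_windows
    mean = per_channel.mean(axis=0)
    band_means = {}
    for name, (lo, hi) in PSD_BANDS.items():
        sel = (freqs >= lo) & (freqs < hi)
        band_means[name] = float(mean[sel].mean()) if sel.any() else 0.0
    return PSDResult(
        freqs=freqs,
        per_channel=per_channel,
        mean=mean,
        band_means=band_means,
        resolution=rec.rate / nwin,
        n_windows=n_windows,
    )
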