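"""Ground-truthed synthetic EEG-fMRI sessions.

Every pipeline stage needs data with a known answer: the simulator builds a
31-channel 10–20 recording at 5000 S/s containing a neural layer (1/f
background plus occipital alpha) and separately stored artifact layers —
slice-locked gradient artifact, heartbeat-locked ballistocardiogram with
cycle-to-cycle variability, blinks, horizontal saccades, muscle bursts, an
electrode pop on one channel, and low-frequency motion bursts. The raw
recording is exactly the clean layer plus the sum of artifact layers, and
all event times and mixing vectors are recorded, so suppression and
classification can be scored bit-exactly.

Default condition: 8-minute session, TR 2 s, 39 slices per volume (slice
frequency 19.5 Hz), heart rate 72 bpm. Artifact amplitudes follow their
field-typical scales relative to the ~10 µV neural background: gradient
100x, BCG 3x at peak, blinks ~100 µV frontopolar.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as _sig

from .core_io import (
    EEGRecording,
    Marker,
    default_montage,
    write_brainvision,
    write_pulseox,
)

__all__ = ["SimConfig", "SimSession", "simulate_session", "simulate_pulseox", "write_fixture"]

ARTIFACT_NAMES = ("gradient", "bcg", "blink", "saccade", "muscle", "pop", "motion")


@dataclass
class SimConfig:
    duration: float = 480.0  # seconds
    eeg_rate: float = 5000.0
    tr: float = 2.0
    slices_per_volume: int = 39
    hr_bpm: float = 72.0
    hr_jitter: float = 0.05  # fractional RR cycle-to-cycle jitter
    bcg_amp_jitter: float = 0.10  # fractional per-cycle amplitude jitter
    bcg_latency_jitter_s: float = 0.015  # per-cycle onset jitter (pulse transit time)
    # amplitudes, µV
    neural_amp: float = 10.0  # per-channel background RMS
    sensor_noise_amp: float = 1.0  # per-channel amplifier noise RMS (full rank)
    alpha_amp: float = 10.0  # alpha source RMS at its strongest electrode
    gradient_amp: float = 1000.0  # peak, 100x neural RMS
    bcg_amp: float = 30.0  # peak, 3x neural RMS
    blink_amp: float = 100.0
    saccade_amp: float = 40.0
    muscle_amp: float = 25.0  # burst RMS
    pop_amp: float = 200.0
    motion_amp: float = 500.0
    # event rates, per second
    blink_rate: float = 0.2
    saccade_rate: float = 0.1
    muscle_rate: float = 0.05
    motion_rate: float = 1.0 / 60.0
    n_pops: int = 3
    n_neural_sources: int = 20
    bad_channel: str | None = "P8"
    pulseox_rate: float = 50.0
    pulseox_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.duration < 30:
            raise ValueError("duration must be >= 30 s")
        if not (30 <= self.hr_bpm <= 180):
            raise ValueError("hr_bpm must be within [30, 180]")
        for name in (
            "neural_amp", "alpha_amp", "gradient_amp", "bcg_amp", "blink_amp",
            "saccade_amp", "muscle_amp", "pop_amp", "motion_amp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimSession:
    cfg: SimConfig
    raw: EEGRecording
    clean: EEGRecording
    #: artifact name -> (channel mixing vector, source waveform)
    layers: dict[str, tuple[np.ndarray, np.ndarray]]
    #: neural ground truth for component matching
    neural_maps: np.ndarray  # channels x sources
    neural_sources: np.ndarray  # sources x samples
    alpha_map: np.ndarray
    alpha_source: np.ndarray
    truth: dict = field(default_factory=dict)

    def layer_data(self, name: str) -> np.ndarray:
        """Channel-space contribution of one artifact layer."""
        vec, wave = self.layers[name]
        return np.outer(vec, wave)

    def artifact_source_bank(self) -> dict[str, np.ndarray]:
        """Named source waveforms for max-|correlation| component matching."""
        bank = {name: wave for name, (vec, wave) in self.layers.items() if wave.any()}
        bank["alpha"] = self.alpha_source
        return bank


def _channel_map(labels: list[str], values: dict[str, float], floor: float = 0.0) -> np.ndarray:
    vec = np.full(len(labels), floor)
    for lab, v in values.items():
        vec[labels.index(lab)] = v
    return vec


def _one_over_f(rng: np.random.Generator, n: int, rate: float, exponent: float = 1.0) -> np.ndarray:
    """Unit-RMS spectrally shaped Gaussian noise with power ~ 1/f^exponent."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], 0.3) ** (-exponent / 2.0)
    spec = shape * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _poisson_times(
    rng: np.random.Generator, rate: float, duration: float, min_gap: float = 1.0
) -> np.ndarray:
    if rate <= 0:
        return np.array([])
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(1.0, duration - 2.0, size=n))
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= min_gap:
            kept.append(t)
    return np.array(kept)


def _add_at(wave: np.ndarray, start: int, shape: np.ndarray) -> None:
    a = max(0, start)
    b = min(wave.size, start + shape.size)
    if b > a:
        wave[a:b] += shape[a - start : b - start]


def _r_peak_samples(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    rr0 = 60.0 / cfg.hr_bpm
    t = 0.5
    peaks = []
    while True:
        s = int(round(t * cfg.eeg_rate))
        if s >= n:
            break
        peaks.append(s)
        t += rr0 * float(np.clip(1.0 + cfg.hr_jitter * rng.standard_normal(), 0.6, 1.6))
    return np.array(peaks, dtype=int)


def simulate_session(cfg: SimConfig | None = None) -> SimSession:
    """Build one fully ground-truthed session. Deterministic given the seed."""
    cfg = cfg or SimConfig()
    rate = cfg.eeg_rate
    n = int(round(cfg.duration * rate))
    montage = default_montage()
    labels = list(montage.positions)
    n_ch = len(labels)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("neural", "alpha", "gradient", "bcg", "blink", "saccade",
             "muscle", "pop", "motion", "cardiac", "pulseox", "sensor"),
            np.random.SeedSequence(cfg.seed).spawn(12),
        )
    }

    # --- neural layer -----------------------------------------------------
    rng = streams["neural"]
    sources = np.stack(
        [_one_over_f(rng, n, rate) for _ in range(cfg.n_neural_sources)]
    )
    maps = rng.standard_normal((n_ch, cfg.n_neural_sources))
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    maps *= cfg.neural_amp
    clean_data = maps @ sources
    if cfg.sensor_noise_amp > 0:
        # independent amplifier noise keeps the sensor covariance full rank
        clean_data += cfg.sensor_noise_amp * streams["sensor"].standard_normal(
            (n_ch, n)
        )

    rng = streams["alpha"]
    # narrowband (8-12 Hz) noise carrier: real alpha has a short coherence
    # time, not a constant-phase sinusoid
    sos = _sig.butter(4, [8.0, 12.0], btype="bandpass", fs=rate, output="sos")
    carrier = _sig.sosfiltfilt(sos, rng.standard_normal(n))
    # 1 Hz-bandwidth amplitude modulation (waxing/waning), kept positive
    sos = _sig.butter(2, 1.0, btype="low", fs=rate, output="sos")
    mod = _sig.sosfiltfilt(sos, rng.standard_normal(n))
    mod = 1.0 + 0.8 * mod / max(mod.std(), 1e-12)
    envelope = np.clip(mod, 0.0, None)
    alpha_source = carrier * envelope
    alpha_source /= alpha_source.std()
    alpha_map = _channel_map(
        labels, {"O1": 1.0, "O2": 1.0, "Oz": 0.8, "POz": 0.5, "P3": 0.2, "P4": 0.2}
    ) * cfg.alpha_amp
    clean_data = clean_data + np.outer(alpha_map, alpha_source)

    layers: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    truth: dict = {}

    # --- gradient artifact: identical waveform at every slice onset -------
    rng = streams["gradient"]
    slice_period = cfg.tr * rate / cfg.slices_per_volume
    n_slices_total = int(np.floor((n - 1) / slice_period)) + 1
    slice_onsets = np.round(np.arange(n_slices_total) * slice_period).astype(int)
    slice_onsets = slice_onsets[slice_onsets < n]
    grad_wave = np.zeros(n)
    if cfg.gradient_amp > 0:
        shape_len = int(np.ceil(slice_period))
        burst = rng.standard_normal(shape_len)
        b, a = _sig.butter(2, [80.0, 2000.0], btype="bandpass", fs=rate)
        burst = _sig.lfilter(b, a, burst)
        burst *= cfg.gradient_amp / np.abs(burst).max()
        for s in slice_onsets:
            _add_at(grad_wave, s, burst)
    grad_map = 0.5 + streams["gradient"].uniform(0, 1, size=n_ch)
    layers["gradient"] = (grad_map, grad_wave)
    truth["slice_onsets"] = slice_onsets
    markers = [Marker(label="R128", sample=int(s), kind="slice") for s in slice_onsets]

    # --- ballistocardiogram ----------------------------------------------
    rng = streams["bcg"]
    r_peaks = _r_peak_samples(cfg, streams["cardiac"], n)
    bcg_wave = np.zeros(n)
    if cfg.bcg_amp > 0 and r_peaks.size:
        rr_med = np.median(np.diff(r_peaks)) / rate if r_peaks.size > 1 else 60.0 / cfg.hr_bpm
        dur = 0.7 * rr_med
        tt = np.arange(int(dur * rate)) / rate
        shape = np.sin(2 * np.pi * 3.0 * tt) * np.exp(-(((tt - dur / 3) / (dur / 3.5)) ** 2))
        shape /= np.abs(shape).max()
        delay = int(round(0.21 * rate))
        for p in r_peaks:
            amp = 1.0 + cfg.bcg_amp_jitter * rng.standard_normal()
            lat = int(round(cfg.bcg_latency_jitter_s * rate * rng.standard_normal()))
            _add_at(bcg_wave, p + delay + lat, amp * shape)
        bcg_wave *= cfg.bcg_amp / max(np.abs(bcg_wave).max(), 1e-12)
    bcg_map = _channel_map(
        labels,
        {
            "T7": 1.0, "C3": 0.8, "CP5": 0.8, "P7": 0.7, "TP9": 0.9, "FC5": 0.6, "P3": 0.4,
            "T8": -1.0, "C4": -0.8, "CP6": -0.8, "P8": -0.7, "TP10": -0.9, "FC6": -0.6, "P4": -0.4,
        },
        floor=0.0,
    )
    layers["bcg"] = (bcg_map, bcg_wave)
    truth["r_peaks"] = r_peaks
    truth["hr_bpm"] = float(60.0 * rate / np.median(np.diff(r_peaks))) if r_peaks.size > 1 else np.nan

    # --- blinks -----------------------------------------------------------
    rng = streams["blink"]
    blink_times = _poisson_times(rng, cfg.blink_rate, cfg.duration, min_gap=1.0)
    blink_wave = np.zeros(n)
    if cfg.blink_amp > 0:
        dur = 0.4
        tt = np.linspace(0, 1, int(dur * rate))
        shape = np.sin(np.pi * tt) ** 2 - 0.35 * np.sin(2 * np.pi * tt)  # biphasic lid sweep
        shape *= cfg.blink_amp / np.abs(shape).max()
        for bt in blink_times:
            _add_at(blink_wave, int(bt * rate), shape * rng.uniform(0.8, 1.2))
    blink_map = _channel_map(
        labels,
        {"Fp1": 1.0, "Fp2": 1.0, "Fz": 0.35, "F3": 0.3, "F4": 0.3, "F7": 0.25, "F8": 0.25},
        floor=0.02,
    )
    layers["blink"] = (blink_map, blink_wave)
    truth["blink_times"] = blink_times

    # --- horizontal saccades ----------------------------------------------
    rng = streams["saccade"]
    sacc_times = _poisson_times(rng, cfg.saccade_rate, cfg.duration, min_gap=2.0)
    sacc_wave = np.zeros(n)
    if cfg.saccade_amp > 0:
        edge = int(0.03 * rate)
        for k, st in enumerate(sacc_times):
            hold = rng.uniform(0.3, 0.8)
            m = int(hold * rate)
            shape = np.ones(m + 2 * edge)
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
            shape[:edge] = ramp
            shape[-edge:] = ramp[::-1]
            sign = 1.0 if k % 2 == 0 else -1.0
            _add_at(sacc_wave, int(st * rate), sign * cfg.saccade_amp * shape)
    sacc_map = _channel_map(
        labels, {"F7": 1.0, "F8": -1.0, "Fp1": 0.3, "Fp2": -0.3, "F3": 0.15, "F4": -0.15}
    )
    layers["saccade"] = (sacc_map, sacc_wave)
    truth["saccade_times"] = sacc_times

    # --- muscle bursts ------------------------------------------------------
    rng = streams["muscle"]
    muscle_times = _poisson_times(rng, cfg.muscle_rate, cfg.duration, min_gap=3.0)
    muscle_wave = np.zeros(n)
    if cfg.muscle_amp > 0:
        sos = _sig.butter(4, [30.0, 60.0], btype="bandpass", fs=rate, output="sos")
        for mt in muscle_times:
            dur = rng.uniform(1.0, 2.0)
            m = int(dur * rate)
            burst = _sig.sosfiltfilt(sos, rng.standard_normal(m))
            burst *= np.hanning(m)
            burst *= cfg.muscle_amp / max(burst.std(), 1e-12)
            _add_at(muscle_wave, int(mt * rate), burst)
    muscle_map = _channel_map(
        labels,
        {
            "T7": 1.0, "T8": 0.9, "FC5": 0.7, "FC6": 0.65, "CP5": 0.5, "CP6": 0.45,
            "F7": 0.3, "F8": 0.3, "P7": 0.25, "P8": 0.25,
        },
        floor=0.03,
    )
    layers["muscle"] = (muscle_map, muscle_wave)
    truth["muscle_times"] = muscle_times

    # --- electrode pop on one channel --------------------------------------
    rng = streams["pop"]
    pop_wave = np.zeros(n)
    pop_times = np.array([])
    if cfg.bad_channel is not None and cfg.pop_amp > 0 and cfg.n_pops > 0:
        pop_times = np.sort(rng.uniform(5.0, cfg.duration - 5.0, size=cfg.n_pops))
        for pt in pop_times:
            s = int(pt * rate)
            m = min(n - s, int(4.0 * rate))
            drift = np.exp(-np.arange(m) / (1.5 * rate))
            _add_at(pop_wave, s, rng.choice([-1.0, 1.0]) * cfg.pop_amp * drift)
    pop_map = (
        _channel_map(labels, {cfg.bad_channel: 1.0})
        if cfg.bad_channel is not None
        else np.zeros(n_ch)
    )
    layers["pop"] = (pop_map, pop_wave)
    truth["pop_times"] = pop_times
    truth["bad_channel"] = cfg.bad_channel

    # --- motion bursts ------------------------------------------------------
    rng = streams["motion"]
    motion_times = _poisson_times(rng, cfg.motion_rate, cfg.duration, min_gap=6.0)
    motion_wave = np.zeros(n)
    motion_spans = []
    if cfg.motion_amp > 0:
        sos = _sig.butter(4, [1.0, 7.0], btype="bandpass", fs=rate, output="sos")
        for mt in motion_times:
            m = int(2.0 * rate)
            burst = _sig.sosfiltfilt(sos, rng.standard_normal(m))
            burst *= np.hanning(m)
            burst *= cfg.motion_amp / max(np.abs(burst).max(), 1e-12)
            s = int(mt * rate)
            _add_at(motion_wave, s, burst)
            motion_spans.append((s, min(n, s + m)))
    motion_map = 0.5 + rng.uniform(0, 1, size=n_ch)
    layers["motion"] = (motion_map, motion_wave)
    truth["motion_spans"] = motion_spans

    # --- assemble -----------------------------------------------------------
    raw_data = clean_data.copy()
    for vec, wave in layers.values():
        if wave.any():
            raw_data += np.outer(vec, wave)

    clean = EEGRecording(data=clean_data, rate=rate, labels=labels, markers=list(markers))
    raw = EEGRecording(data=raw_data, rate=rate, labels=labels, markers=list(markers))
    return SimSession(
        cfg=cfg,
        raw=raw,
        clean=clean,
        layers=layers,
        neural_maps=maps,
        neural_sources=sources,
        alpha_map=alpha_map,
        alpha_source=alpha_source,
        truth=truth,
    )


def simulate_pulseox(cfg: SimConfig, r_peaks: np.ndarray) -> np.ndarray:
    """50 S/s photoplethysmogram with the systolic peak 0.25 s after each
    R-event plus additive noise."""
    r_peaks = np.asarray(r_peaks)
    if r_peaks.size == 0:
        raise ValueError("no R-peak events supplied")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(12)[10])
    rate = cfg.pulseox_rate
    n = int(round(cfg.duration * rate))
    t_peaks = r_peaks / cfg.eeg_rate + 0.25
    wave = np.zeros(n)
    width = 0.12
    span = int(1.0 * rate)
    for tp in t_peaks:
        c = int(round(tp * rate))
        idx = np.arange(max(0, c - span), min(n, c + span))
        tau = idx / rate - tp
        wave[idx] += np.exp(-0.5 * (tau / width) ** 2) + 0.3 * np.exp(
            -0.5 * ((tau - 0.25) / 0.16) ** 2
        )
    wave += cfg.pulseox_noise * rng.standard_normal(n)
    return wave


def write_fixture(session: SimSession, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the raw recording (BrainVision triplet), the pulse-ox text
    series, and the ground-truth JSON. Returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    stem = os.path.join(out_dir, "session")
    vhdr, vmrk, eeg = write_brainvision(session.raw, stem)
    po_path = os.path.join(out_dir, "pulseox.txt")
    pulse = simulate_pulseox(session.cfg, session.truth["r_peaks"])
    write_pulseox(po_path, pulse, session.cfg.pulseox_rate)
    truth_path = os.path.join(out_dir, "truth.json")
    truth = {
        "config": asdict(session.cfg),
        "r_peaks": [int(x) for x in session.truth["r_peaks"]],
        "hr_bpm": session.truth["hr_bpm"],
        "blink_times": [float(x) for x in session.truth["blink_times"]],
        "saccade_times": [float(x) for x in session.truth["saccade_times"]],
        "muscle_times": [float(x) for x in session.truth["muscle_times"]],
        "pop_times": [float(x) for x in session.truth["pop_times"]],
        "motion_spans": [[int(a), int(b)] for a, b in session.truth["motion_spans"]],
        "bad_channel": session.truth["bad_channel"],
        "mixing_vectors": {
            name: [float(v) for v in vec] for name, (vec, _) in session.layers.items()
        },
    }
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1)
    return {"vhdr": vhdr, "vmrk": vmrk, "eeg": eeg, "pulseox": po_path, "truth": truth_path}
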