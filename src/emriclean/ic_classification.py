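"""Feature extraction and rule-based artifact classification of ICs.

Each independent component is summarized by three feature groups:

* **topographic** — the mixing column interpolated over the 2-D scalp
  projection: unipolar/bipolar shape, active area, lobe centroids, overlap
  with the occipital template, frontopolar/orbitofrontal concentration;
* **spectral** — the component PSD with band means (delta 1–4, theta 4–7,
  alpha 7–13, beta 13–30, gamma 30–60 Hz) and the peak frequency;
* **temporal** — kurtosis, per-channel back-projected power concentration,
  cardiac-cycle-locked amplitude, and back-projection variance fraction.

Five rules flag components as BCG, blink, saccade, single-channel, or
muscle artifacts. An occipital-alpha guard runs first: components whose
map covers the occipital template (O1, O2, Oz) and whose spectrum is
alpha-dominant are never removed, protecting posterior alpha rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal, stats

from .core_io import EEGRecording, Montage, default_montage
from .ica_engine import ICADecomposition, RemovalSet

__all__ = [
    "TopoFeatures",
    "SpectralFeatures",
    "TemporalFeatures",
    "ICLabel",
    "BANDS",
    "compute_features",
    "alpha_guard",
    "rule_bcg",
    "rule_blink",
    "rule_saccade",
    "rule_single_channel",
    "rule_muscle",
    "classify_all",
]

BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (7.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 60.0),
}

ALPHA_BAND = (7.0, 13.0)

GRID_SIZE = 64
ACTIVE_FRACTION = 0.5  # grid cells with |value| >= 0.5 * max are "active"
BIPOLAR_LOBE_FRACTION = 0.6  # each opposite-signed lobe >= 0.6 * max|weight|
OCCIPITAL_DISK_RADIUS = 0.2


@dataclass
class TopoFeatures:
    weights: np.ndarray  # per-channel, unit norm
    grid: np.ndarray  # GRID_SIZE x GRID_SIZE, NaN outside the head disk
    polarity: str  # {unipolar, bipolar}
    occipital_overlap: float
    frontopolar_ratio: float  # mean|w| at Fp1/Fp2 over mean|w| elsewhere
    orbitofrontal_ratio: float
    active_centroid: tuple[float, float]
    pos_lobe_centroid: tuple[float, float] | None
    neg_lobe_centroid: tuple[float, float] | None
    pos_peak_channel: str | None
    neg_peak_channel: str | None


@dataclass
class SpectralFeatures:
    freqs: np.ndarray
    psd: np.ndarray
    band_means: dict[str, float]
    peak_freq: float

    def alpha_is_max_band(self) -> bool:
        return all(
            self.band_means["alpha"] >= v
            for k, v in self.band_means.items()
            if k != "alpha"
        )


@dataclass
class TemporalFeatures:
    kurtosis: float  # Gaussian => 3
    channel_projection_ratio: float  # max over channels vs the runner-up
    cardiac_locked_score: float
    contribution: float


@dataclass
class ICLabel:
    component: int
    label: str  # {neural, bcg, blink, saccade, single_channel, muscle}
    evidence: dict = field(default_factory=dict)

    @property
    def artifactual(self) -> bool:
        return self.label != "neural"


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _head_grid():
    g = np.linspace(-1, 1, GRID_SIZE)
    gx, gy = np.meshgrid(g, g)
    return gx, gy, gx ** 2 + gy ** 2 <= 1.0


def _topo_grid(weights: np.ndarray, xy: np.ndarray) -> np.ndarray:
    gx, gy, inside = _head_grid()
    rbf = interpolate.RBFInterpolator(xy, weights, kernel="thin_plate_spline")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    grid = rbf(pts).reshape(GRID_SIZE, GRID_SIZE)
    grid[~inside] = np.nan
    return grid


def _centroid(xy: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    tot = w.sum()
    if tot <= 0:
        return (0.0, 0.0)
    return (float((xy[:, 0] * w).sum() / tot), float((xy[:, 1] * w).sum() / tot))


def topo_features(weights: np.ndarray, labels: list[str], montage: Montage) -> TopoFeatures:
    w = np.asarray(weights, dtype=float)
    norm = np.linalg.norm(w)
    if norm > 0:
        w = w / norm
    xy = montage.xy(labels)
    grid = _topo_grid(w, xy)

    wmax = np.abs(w).max()
    pos_peak = neg_peak = None
    pos_cent = neg_cent = None
    bipolar = False
    if wmax > 0:
        pos_mask = w >= BIPOLAR_LOBE_FRACTION * wmax
        neg_mask = -w >= BIPOLAR_LOBE_FRACTION * wmax
        bipolar = bool(pos_mask.any() and neg_mask.any())
        if pos_mask.any():
            pos_peak = labels[int(np.argmax(w))]
            pos_cent = _centroid(xy[pos_mask], w[pos_mask])
        if neg_mask.any():
            neg_peak = labels[int(np.argmin(w))]
            neg_cent = _centroid(xy[neg_mask], -w[neg_mask])

    # active area on the interpolated grid
    gx, gy, inside = _head_grid()
    absg = np.abs(grid)
    gmax = np.nanmax(absg)
    active = inside & (absg >= ACTIVE_FRACTION * gmax) if gmax > 0 else inside & False

    occ_xy = montage.xy(sorted(montage.occipital))
    occ_template = np.zeros_like(inside)
    for ox, oy in occ_xy:
        occ_template |= (gx - ox) ** 2 + (gy - oy) ** 2 <= OCCIPITAL_DISK_RADIUS ** 2
    occ_template &= inside
    n_active = int(active.sum())
    overlap = float((active & occ_template).sum() / n_active) if n_active else 0.0

    absw = np.abs(w)
    fp = [i for i, l in enumerate(labels) if l in montage.frontopolar]
    of = [i for i, l in enumerate(labels) if l in montage.orbitofrontal]
    rest_fp = [i for i in range(len(labels)) if i not in fp]
    rest_of = [i for i in range(len(labels)) if i not in of]

    def _ratio(sel, rest):
        if not sel:
            return 0.0
        denom = absw[rest].mean() if rest else 0.0
        return float(absw[sel].mean() / denom) if denom > 0 else np.inf

    act_w = absw.copy()
    act_w[absw < ACTIVE_FRACTION * wmax] = 0.0
    return TopoFeatures(
        weights=w,
        grid=grid,
        polarity="bipolar" if bipolar else "unipolar",
        occipital_overlap=overlap,
        frontopolar_ratio=_ratio(fp, rest_fp),
        orbitofrontal_ratio=_ratio(of, rest_of),
        active_centroid=_centroid(xy, act_w),
        pos_lobe_centroid=pos_cent,
        neg_lobe_centroid=neg_cent,
        pos_peak_channel=pos_peak,
        neg_peak_channel=neg_peak,
    )


def spectral_features(source: np.ndarray, rate: float) -> SpectralFeatures:
    nperseg = min(source.size, int(round(4.096 * rate)))
    freqs, psd = signal.welch(
        source - source.mean(), fs=rate, window="hann", nperseg=nperseg
    )
    band_means = {}
    for name, (lo, hi) in BANDS.items():
        sel = (freqs >= lo) & (freqs < hi)
        band_means[name] = float(psd[sel].mean()) if sel.any() else 0.0
    above_dc = freqs >= 1.0
    peak = float(freqs[above_dc][np.argmax(psd[above_dc])]) if above_dc.any() else 0.0
    return SpectralFeatures(freqs=freqs, psd=psd, band_means=band_means, peak_freq=peak)


def cardiac_locked_score(source: np.ndarray, peaks: np.ndarray | None, rate: float) -> float:
    """How strongly a time course is locked to the cardiac cycle, in [0, ~1].

    Each peak-to-peak cycle is resampled to the median RR length, giving a
    cycles x phase matrix. Two complementary statistics are taken:

    * the RMS of the phase-locked mean over the component RMS — high when
      the waveform repeats with stable latency (raw BCG);
    * the coefficient of variation of the phase-resolved RMS profile —
      high when the *energy* is locked to cardiac phase even if latency
      jitter cancels the mean (residual BCG after template subtraction).

    The score is the larger of the two. For cardiac-unrelated stationary
    activity both statistics scale as ~1/sqrt(cycles).
    """
    if peaks is None or len(peaks) < 3:
        return 0.0
    peaks = np.asarray(peaks, dtype=int)
    peaks = peaks[(peaks >= 0) & (peaks < source.size)]
    if peaks.size < 3:
        return 0.0
    rr = np.diff(peaks)
    target = int(np.median(rr))
    if target < 2:
        return 0.0
    cycles = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        seg = source[a:b]
        if seg.size < 2:
            continue
        pos = np.linspace(0, seg.size - 1, target)
        cycles.append(np.interp(pos, np.arange(seg.size), seg))
    if len(cycles) < 3:
        return 0.0
    mat = np.asarray(cycles)
    denom = np.sqrt(np.mean(source ** 2))
    if denom <= 0:
        return 0.0
    mean_score = float(np.sqrt(np.mean(mat.mean(axis=0) ** 2)) / denom)
    phase_rms = np.sqrt(np.mean(mat ** 2, axis=0))
    m = phase_rms.mean()
    energy_score = float(phase_rms.std() / m) if m > 0 else 0.0
    return max(mean_score, energy_score)


def temporal_features(
    dec: ICADecomposition, i: int, peaks: np.ndarray | None, rate: float
) -> TemporalFeatures:
    src = dec.S_full[i] if dec.S_full is not None else dec.S_short[i]
    kurt = float(stats.kurtosis(src, fisher=False))
    # back-projected power per channel; unit-norm S would scale all equally
    ch_power = dec.A[:, i] ** 2 * src.var()
    srt = np.sort(ch_power)[::-1]
    ratio = float(srt[0] / srt[1]) if srt.size > 1 and srt[1] > 0 else np.inf
    total_var = sum(
        (dec.A[:, j] ** 2).sum() * (dec.S_full[j] if dec.S_full is not None else dec.S_short[j]).var()
        for j in range(dec.n_components)
    )
    contrib = float((dec.A[:, i] ** 2).sum() * src.var() / total_var) if total_var > 0 else 0.0
    return TemporalFeatures(
        kurtosis=kurt,
        channel_projection_ratio=ratio,
        cardiac_locked_score=cardiac_locked_score(src, peaks, rate),
        contribution=contrib,
    )


def compute_features(
    dec: ICADecomposition,
    rec: EEGRecording,
    cycles=None,
    montage: Montage | None = None,
) -> list[tuple[TopoFeatures, SpectralFeatures, TemporalFeatures]]:
    """All three feature groups for every component. Deterministic."""
    montage = montage or default_montage()
    labels = dec.labels if dec.labels is not None else rec.labels
    peaks = np.asarray(cycles.peaks) if cycles is not None else None
    out = []
    for i in range(dec.n_components):
        src = dec.S_full[i] if dec.S_full is not None else dec.S_short[i]
        out.append(
            (
                topo_features(dec.A[:, i], labels, montage),
                spectral_features(src, rec.rate),
                temporal_features(dec, i, peaks, rec.rate),
            )
        )
    return out


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------

def alpha_guard(topo: TopoFeatures, spec: SpectralFeatures) -> bool:
    """Protect occipital alpha: the map must overlap the occipital template
    (> 0.4 unipolar, > 0.91 bipolar) and the spectrum must be
    alpha-dominant (peak in 7–13 Hz, or alpha mean above delta, theta and
    beta means)."""
    thresh = 0.91 if topo.polarity == "bipolar" else 0.4
    if topo.occipital_overlap <= thresh:
        return False
    if ALPHA_BAND[0] <= spec.peak_freq <= ALPHA_BAND[1]:
        return True
    a = spec.band_means["alpha"]
    return all(a > spec.band_means[b] for b in ("delta", "theta", "beta"))


def rule_bcg(
    topo: TopoFeatures,
    spec: SpectralFeatures,
    temp: TemporalFeatures,
    locked_threshold: float = 0.3,
) -> bool:
    """Ballistocardiogram: bipolar left/right hemispheric map, spectrum not
    alpha-dominant, and a heartbeat-locked time course."""
    if topo.polarity != "bipolar":
        return False
    if topo.pos_lobe_centroid is None or topo.neg_lobe_centroid is None:
        return False
    if topo.pos_lobe_centroid[0] * topo.neg_lobe_centroid[0] >= 0:
        return False  # lobes must sit in opposite hemispheres
    if ALPHA_BAND[0] <= spec.peak_freq <= ALPHA_BAND[1]:
        return False
    if spec.alpha_is_max_band():
        return False
    return temp.cardiac_locked_score >= locked_threshold


def rule_blink(topo: TopoFeatures, temp: TemporalFeatures) -> bool:
    """Blink: unipolar frontopolar map (Fp1/Fp2 at least twice the mean of
    the other channels) with an anterior active centroid."""
    return (
        topo.polarity == "unipolar"
        and topo.frontopolar_ratio >= 2.0
        and topo.active_centroid[1] > 0.5
    )


def rule_saccade(topo: TopoFeatures) -> bool:
    """Horizontal saccade: two opposite-signed lobes peaking at the
    orbitofrontal electrodes F7 and F8."""
    if topo.polarity != "bipolar":
        return False
    peaks = {topo.pos_peak_channel, topo.neg_peak_channel}
    return peaks == {"F7", "F8"}


def rule_single_channel(
    topo: TopoFeatures, spec: SpectralFeatures, temp: TemporalFeatures
) -> bool:
    """Single bad channel: spiky time course (kurtosis > 4), back-projected
    power concentrated > 5x in one channel, and no alpha peak."""
    return (
        temp.kurtosis > 4.0
        and temp.channel_projection_ratio > 5.0
        and not (ALPHA_BAND[0] <= spec.peak_freq <= ALPHA_BAND[1])
    )


def rule_muscle(spec: SpectralFeatures) -> bool:
    """Muscle/EMG (and broadband noise): gamma band mean power above every
    other band, or the PSD peak sitting in the gamma range — the latter
    clause also catches narrowband noise (line/vibration residue) and
    intermittent bursts whose band mean is diluted by quiet stretches."""
    g = spec.band_means["gamma"]
    if all(g > v for k, v in spec.band_means.items() if k != "gamma"):
        return True
    return BANDS["gamma"][0] <= spec.peak_freq <= BANDS["gamma"][1]


def classify_all(
    features: list[tuple[TopoFeatures, SpectralFeatures, TemporalFeatures]],
    bcg_locked_threshold: float = 0.3,
    min_contribution: float = 0.0,
) -> tuple[list[ICLabel], RemovalSet]:
    """Assign exactly one label per component.

    The guard is evaluated first (guarded components are neural); then the
    rules in order blink, saccade, single-channel, muscle, BCG — most
    spatially specific first. The removal set is every non-neural id whose
    variance contribution reaches ``min_contribution``.
    """
    labels: list[ICLabel] = []
    removal = RemovalSet()
    for i, (topo, spec, temp) in enumerate(features):
        ev = {
            "occipital_overlap": topo.occipital_overlap,
            "polarity": topo.polarity,
            "frontopolar_ratio": topo.frontopolar_ratio,
            "kurtosis": temp.kurtosis,
            "channel_projection_ratio": temp.channel_projection_ratio,
            "cardiac_locked_score": temp.cardiac_locked_score,
            "peak_freq": spec.peak_freq,
            "contribution": temp.contribution,
        }
        if alpha_guard(topo, spec):
            lab = "neural"
            ev["alpha_guard"] = True
        elif rule_blink(topo, temp):
            lab = "blink"
        elif rule_saccade(topo):
            lab = "saccade"
        elif rule_single_channel(topo, spec, temp):
            lab = "single_channel"
        elif rule_muscle(spec):
            lab = "muscle"
        elif rule_bcg(topo, spec, temp, bcg_locked_threshold):
            lab = "bcg"
        else:
            lab = "neural"
        labels.append(ICLabel(component=i, label=lab, evidence=ev))
        if lab != "neural" and temp.contribution >= min_contribution:
            removal.ids.append(i)
            removal.labels[i] = lab
            removal.evidence[i] = ev
    return labels, removal
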