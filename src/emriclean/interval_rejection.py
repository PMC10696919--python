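"""Automatic bad-interval marking and excision.

Motion and instrumental artifacts produce short stretches of very high
low-frequency power. These are detected with a sliding-window band-power
criterion (0.5–7 Hz, 8 dB above the per-channel median window power),
merged, padded, and excised before ICA fitting. The excised-to-original
sample mapping is kept so that sources can later be projected onto the
full-length recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import EEGRecording, Marker

__all__ = ["BadIntervals", "IndexMap", "detect_bad_intervals", "excise", "merge_spans"]


def merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping or touching half-open spans."""
    out: list[list[int]] = []
    for a, b in sorted((int(a), int(b)) for a, b in spans):
        if b <= a:
            continue
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


@dataclass
class BadIntervals:
    """Sorted, non-overlapping half-open [start, end) sample spans."""

    spans: list[tuple[int, int]]
    rate: float

    def __post_init__(self):
        self.spans = merge_spans(self.spans)

    @property
    def total_samples(self) -> int:
        return sum(b - a for a, b in self.spans)

    @property
    def total_seconds(self) -> float:
        return self.total_samples / self.rate

    def contains(self, sample: int) -> bool:
        return any(a <= sample < b for a, b in self.spans)

    def to_tsv(self, path, reason: str = "auto") -> None:
        with open(path, "w") as fh:
            fh.write("start_s\tend_s\treason\n")
            for a, b in self.spans:
                fh.write(f"{a / self.rate:.4f}\t{b / self.rate:.4f}\t{reason}\n")


@dataclass
class IndexMap:
    """Strictly increasing kept-to-original sample indices (length K)."""

    kept_to_original: np.ndarray

    def __post_init__(self):
        self.kept_to_original = np.asarray(self.kept_to_original, dtype=int)
        if np.any(np.diff(self.kept_to_original) <= 0):
            raise ValueError("index map must be strictly increasing")

    def __len__(self) -> int:
        return self.kept_to_original.size

    def __getitem__(self, i):
        return int(self.kept_to_original[i])


def detect_bad_intervals(
    rec: EEGRecording,
    freq_lo: float = 0.5,
    freq_hi: float = 7.0,
    threshold_db: float = 8.0,
    window_s: float = 0.5,
    step_s: float = 0.25,
    min_contiguous: int = 4,
) -> BadIntervals:
    """Mark stretches whose 0.5–7 Hz power exceeds the channel's median
    window power by ``threshold_db``.

    Sliding Hann-tapered windows of ``window_s`` seconds with ``step_s``
    step; a window is bad when any channel exceeds its own median across
    windows by the threshold. A region is rejected only when at least
    ``min_contiguous`` consecutive windows are bad (the default of the
    continuous-rejection routine this mirrors), so isolated sub-second
    transients such as blinks stay in the data for ICA to model; sustained
    motion is excised. Rejected runs are merged and padded by one step on
    each side.
    """
    nwin = int(round(window_s * rec.rate))
    step = int(round(step_s * rec.rate))
    if rec.n_samples < nwin:
        raise ValueError("recording shorter than one analysis window")
    starts = np.arange(0, rec.n_samples - nwin + 1, step)
    taper = np.hanning(nwin)
    freqs = np.fft.rfftfreq(nwin, 1.0 / rec.rate)
    band = (freqs >= freq_lo) & (freqs <= freq_hi)

    # (channels, windows) band power
    seg = rec.data[:, starts[:, None] + np.arange(nwin)[None, :]] * taper
    spec = np.fft.rfft(seg, axis=-1)
    power = (np.abs(spec[..., band]) ** 2).sum(axis=-1)  # (channels, windows)

    med = np.median(power, axis=1, keepdims=True)
    ratio_db = 10.0 * np.log10(
        np.divide(power, med, out=np.full_like(power, np.inf), where=med > 0)
    )
    with np.errstate(invalid="ignore"):
        bad_win = np.any(
            np.where(med > 0, ratio_db >= threshold_db, power > 0), axis=0
        )

    # keep only runs of >= min_contiguous consecutive bad windows
    spans = []
    run_start = None
    for k, flag in enumerate(list(bad_win) + [False]):
        if flag and run_start is None:
            run_start = k
        elif not flag and run_start is not None:
            if k - run_start >= min_contiguous:
                a = max(0, int(starts[run_start]) - step)
                b = min(rec.n_samples, int(starts[k - 1]) + nwin + step)
                spans.append((a, b))
            run_start = None
    return BadIntervals(spans=spans, rate=rec.rate)


def excise(rec: EEGRecording, bad: BadIntervals) -> tuple[EEGRecording, IndexMap]:
    """Remove bad spans, concatenating the kept segments in order.

    Markers inside excised spans are dropped; the rest are remapped. The
    returned :class:`IndexMap` recovers original sample positions.
    """
    keep = np.ones(rec.n_samples, dtype=bool)
    for a, b in bad.spans:
        if a < 0 or b > rec.n_samples:
            raise ValueError(f"span [{a}, {b}) outside recording")
        keep[a:b] = False
    if not keep.any():
        raise ValueError("no data left after excising bad intervals")
    kept_idx = np.flatnonzero(keep)
    # original -> kept position (only valid where keep)
    new_pos = np.cumsum(keep) - 1
    markers = [
        Marker(label=m.label, sample=int(new_pos[m.sample]), kind=m.kind)
        for m in rec.markers
        if keep[m.sample]
    ]
    out = rec.copy(data=rec.data[:, keep], markers=markers)
    return out, IndexMap(kept_to_original=kept_idx)
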