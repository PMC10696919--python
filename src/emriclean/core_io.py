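"""Data model and BrainVision I/O.

The central container is :class:`EEGRecording`: a channels-by-samples matrix
of amplitudes in microvolts together with the sampling rate, ordered channel
labels, and event markers (slice triggers, volume triggers, stimuli).
Recordings are read from and written to the BrainVision triplet
(``.vhdr``/``.vmrk``/``.eeg``), the native format of MR-compatible EEG
amplifiers. All sample indexing is 0-based and half-open internally;
BrainVision's 1-based marker positions are converted at the file boundary.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Marker",
    "Montage",
    "EEGRecording",
    "DEFAULT_MARKER_KINDS",
    "default_montage",
    "read_brainvision",
    "write_brainvision",
    "read_pulseox",
    "write_pulseox",
    "derive_volume_triggers",
]

#: Default mapping from marker label to marker kind. "R128" is the
#: conventional scanner slice-trigger label; "Volume" is written by
#: :func:`derive_volume_triggers`. Stimulus codes ("S  1", "S 23", ...)
#: are matched by pattern below.
DEFAULT_MARKER_KINDS = {"R128": "slice", "Volume": "volume"}

_STIM_RE = re.compile(r"^S\s*\d+$")

MARKER_KINDS = ("slice", "volume", "stimulus", "other")


def classify_marker_label(label: str, mapping: dict[str, str] | None = None) -> str:
    mapping = DEFAULT_MARKER_KINDS if mapping is None else mapping
    if label in mapping:
        return mapping[label]
    if _STIM_RE.match(label):
        return "stimulus"
    return "other"


@dataclass(frozen=True)
class Marker:
    """An event at a 0-based sample index."""

    label: str
    sample: int
    kind: str = "other"

    def __post_init__(self):
        if self.sample < 0:
            raise ValueError(f"marker sample must be >= 0, got {self.sample}")
        if self.kind not in MARKER_KINDS:
            raise ValueError(f"unknown marker kind {self.kind!r}")


@dataclass(frozen=True)
class Montage:
    """2-D projected scalp positions on the unit-disk head (nose at +y).

    ``positions`` maps channel label to an (x, y) coordinate with |coord| <= 1.
    Region membership used by the topographic classification rules is derived
    from the label sets below.
    """

    positions: dict[str, tuple[float, float]]
    occipital: frozenset[str] = frozenset({"O1", "O2", "Oz"})
    frontopolar: frozenset[str] = frozenset({"Fp1", "Fp2"})
    orbitofrontal: frozenset[str] = frozenset({"F7", "F8"})

    def __post_init__(self):
        for lab, (x, y) in self.positions.items():
            if x * x + y * y > 1.0 + 1e-9:
                raise ValueError(f"position of {lab} outside unit disk")

    def xy(self, labels) -> np.ndarray:
        missing = [l for l in labels if l not in self.positions]
        if missing:
            raise KeyError(f"montage is missing positions for {missing}")
        return np.array([self.positions[l] for l in labels], dtype=float)

    def hemisphere(self, label: str) -> str:
        x = self.positions[label][0]
        if x < -1e-9:
            return "left"
        if x > 1e-9:
            return "right"
        return "midline"


def _ring(angle_deg: float, r: float) -> tuple[float, float]:
    # angle measured from +y (nose), positive clockwise toward the right ear
    a = np.deg2rad(angle_deg)
    return (r * np.sin(a), r * np.cos(a))


#: Built-in 31-channel 10-20 set (BrainCap-MR style). Coordinates are the
#: standard schematic projection: outer ring at radius 0.9, ears at +/-x.
_DEFAULT_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": _ring(-18, 0.9),
    "Fp2": _ring(18, 0.9),
    "F7": _ring(-54, 0.9),
    "F8": _ring(54, 0.9),
    "T7": _ring(-90, 0.9),
    "T8": _ring(90, 0.9),
    "P7": _ring(-126, 0.9),
    "P8": _ring(126, 0.9),
    "O1": _ring(-162, 0.9),
    "O2": _ring(162, 0.9),
    "TP9": _ring(-108, 1.0),
    "TP10": _ring(108, 1.0),
    "F3": (-0.35, 0.43),
    "F4": (0.35, 0.43),
    "C3": (-0.45, 0.0),
    "C4": (0.45, 0.0),
    "P3": (-0.35, -0.43),
    "P4": (0.35, -0.43),
    "FC1": (-0.21, 0.23),
    "FC2": (0.21, 0.23),
    "FC5": (-0.62, 0.26),
    "FC6": (0.62, 0.26),
    "CP1": (-0.21, -0.23),
    "CP2": (0.21, -0.23),
    "CP5": (-0.62, -0.26),
    "CP6": (0.62, -0.26),
    "Fz": (0.0, 0.45),
    "Cz": (0.0, 0.0),
    "Pz": (0.0, -0.45),
    "POz": (0.0, -0.675),
    "Oz": (0.0, -0.9),
}


def default_montage() -> Montage:
    """The built-in 31-channel 10-20 montage."""
    return Montage(positions=dict(_DEFAULT_POSITIONS))


def read_montage(path: str | os.PathLike) -> Montage:
    """Read a montage from a 3-column text table: label, x, y."""
    positions = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 3:
                raise ValueError(f"bad montage line: {line!r}")
            positions[parts[0]] = (float(parts[1]), float(parts[2]))
    return Montage(positions=positions)


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    rate: float
    labels: list[str]
    markers: list[Marker] = field(default_factory=list)
    montage_ref: str = "default"
    reference: str = "FCz"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        for m in self.markers:
            if not (0 <= m.sample < self.n_samples):
                raise ValueError(
                    f"marker {m.label!r} at sample {m.sample} outside [0, {self.n_samples})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def markers_of_kind(self, kind: str) -> list[Marker]:
        return [m for m in self.markers if m.kind == kind]

    def marker_samples(self, kind: str) -> np.ndarray:
        return np.array([m.sample for m in self.markers_of_kind(kind)], dtype=int)

    def channel_index(self, label: str) -> int:
        return self.labels.index(label)

    def copy(self, **changes) -> "EEGRecording":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        if "markers" not in changes:
            out.markers = list(self.markers)
        return out


# ---------------------------------------------------------------------------
# BrainVision triplet I/O
# ---------------------------------------------------------------------------

_BINARY_FORMATS = {
    "IEEE_FLOAT_32": np.dtype("<f4"),
    "INT_16": np.dtype("<i2"),
}

_KIND_TO_BV_TYPE = {
    "slice": "Response",
    "volume": "Response",
    "stimulus": "Stimulus",
    "other": "Comment",
}


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    cur: dict[str, str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith((";", "#")):
            continue
        if line.startswith("[") and line.endswith("]"):
            cur = sections.setdefault(line[1:-1], {})
        elif "=" in line and cur is not None:
            key, val = line.split("=", 1)
            cur[key.strip()] = val.strip()
    return sections


def read_brainvision(
    header_path: str | os.PathLike,
    marker_kinds: dict[str, str] | None = None,
) -> EEGRecording:
    """Read a BrainVision ``.vhdr`` triplet into an :class:`EEGRecording`.

    Data are returned in microvolts regardless of the on-disk resolution and
    unit; marker positions are converted from BrainVision's 1-based samples
    to 0-based indices. Both MULTIPLEXED and VECTORIZED binary orientations
    and IEEE_FLOAT_32 / INT_16 formats are supported.
    """
    header_path = os.fspath(header_path)
    if not os.path.exists(header_path):
        raise FileNotFoundError(f"header file not found: {header_path}")
    with open(header_path, encoding="utf-8") as fh:
        head = _parse_ini(fh.read())

    common = head.get("Common Infos", {})
    binary = head.get("Binary Infos", {})
    chans = head.get("Channel Infos", {})
    base = os.path.dirname(header_path)

    data_file = os.path.join(base, common["DataFile"])
    marker_file = os.path.join(base, common["MarkerFile"])
    for p in (data_file, marker_file):
        if not os.path.exists(p):
            raise FileNotFoundError(f"companion file referenced by header not found: {p}")

    n_channels = int(common["NumberOfChannels"])
    rate = 1e6 / float(common["SamplingInterval"])  # interval is in microseconds
    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    fmt = binary.get("BinaryFormat", "IEEE_FLOAT_32")
    if fmt not in _BINARY_FORMATS:
        raise ValueError(f"unsupported BinaryFormat: {fmt}")
    dtype = _BINARY_FORMATS[fmt]

    labels: list[str] = []
    resolutions = np.ones(n_channels)
    units: list[str] = []
    for i in range(n_channels):
        entry = chans.get(f"Ch{i + 1}", f"Ch{i + 1},,1,µV")
        parts = entry.split(",")
        labels.append(parts[0])
        if len(parts) > 2 and parts[2]:
            resolutions[i] = float(parts[2])
        units.append(parts[3] if len(parts) > 3 and parts[3] else "µV")

    raw = np.fromfile(data_file, dtype=dtype)
    if raw.size % n_channels:
        raise ValueError(f"data file size not a multiple of channel count: {data_file}")
    n_samples = raw.size // n_channels
    if orientation == "MULTIPLEXED":
        data = raw.reshape(n_samples, n_channels).T.astype(float)
    elif orientation == "VECTORIZED":
        data = raw.reshape(n_channels, n_samples).astype(float)
    else:
        raise ValueError(f"unsupported DataOrientation: {orientation}")
    data *= resolutions[:, None]
    for i, u in enumerate(units):
        scale = {"µV": 1.0, "uV": 1.0, "mV": 1e3, "V": 1e6}.get(u)
        if scale is None:
            raise ValueError(f"unsupported unit {u!r} for channel {labels[i]}")
        if scale != 1.0:
            data[i] *= scale

    reference = "unknown"
    markers: list[Marker] = []
    with open(marker_file, encoding="utf-8") as fh:
        for name, entry in _parse_ini(fh.read()).get("Marker Infos", {}).items():
            if not name.startswith("Mk"):
                continue
            parts = entry.split(",")
            mtype, label = parts[0], parts[1]
            if mtype == "New Segment":
                continue
            sample = int(parts[2]) - 1  # 1-based on disk
            markers.append(
                Marker(label=label, sample=sample, kind=classify_marker_label(label, marker_kinds))
            )
    markers.sort(key=lambda m: (m.sample, m.label))
    return EEGRecording(
        data=data, rate=rate, labels=labels, markers=markers, reference=reference
    )


def write_brainvision(rec: EEGRecording, out_stem: str | os.PathLike) -> tuple[str, str, str]:
    """Write ``rec`` as ``<stem>.vhdr``/``.vmrk``/``.eeg`` (IEEE float 32,
    multiplexed). Returns the three paths."""
    out_stem = os.fspath(out_stem)
    base = os.path.basename(out_stem)
    vhdr, vmrk, eeg = (out_stem + ext for ext in (".vhdr", ".vmrk", ".eeg"))

    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by emriclean",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={base}.eeg",
        f"MarkerFile={base}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={1e6 / rec.rate:.6g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    header += [f"Ch{i + 1}={lab},,1,µV" for i, lab in enumerate(rec.labels)]
    with open(vhdr, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={base}.eeg",
        "",
        "[Marker Infos]",
        f"Mk1=New Segment,,1,1,{rec.n_channels}",
    ]
    for i, m in enumerate(rec.markers):
        bv_type = _KIND_TO_BV_TYPE[m.kind]
        mlines.append(f"Mk{i + 2}={bv_type},{m.label},{m.sample + 1},1,0")
    with open(vmrk, "w", encoding="utf-8") as fh:
        fh.write("\n".join(mlines) + "\n")

    rec.data.T.astype("<f4").tofile(eeg)
    return vhdr, vmrk, eeg


# ---------------------------------------------------------------------------
# Pulse-oximetry text format: first line "RATE=<S/s>", one sample per line
# ---------------------------------------------------------------------------

def read_pulseox(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.upper().startswith("RATE="):
            raise ValueError("pulse-ox file must start with a 'RATE=<S/s>' line")
        rate = float(first.split("=", 1)[1])
        values = np.array([float(line) for line in fh if line.strip()])
    return values, rate


def write_pulseox(path: str | os.PathLike, waveform: np.ndarray, rate: float) -> None:
    with open(path, "w") as fh:
        fh.write(f"RATE={rate:g}\n")
        np.savetxt(fh, np.asarray(waveform, dtype=float), fmt="%.6f")


# ---------------------------------------------------------------------------
# Volume triggers
# ---------------------------------------------------------------------------

def derive_volume_triggers(rec: EEGRecording, slices_per_volume: int) -> EEGRecording:
    """Add volume-kind markers at every ``n``-th slice trigger.

    The fMRI sequence emits one trigger per slice; the gradient-artifact
    template repeats per volume, so a volume marker is placed at the 1st
    slice of each complete volume (slice occurrences 1, n+1, 2n+1, ...).
    A trailing incomplete volume produces no marker. Idempotent: existing
    volume markers are replaced.
    """
    if slices_per_volume < 1:
        raise ValueError("slices_per_volume must be >= 1")
    slices = rec.marker_samples("slice")
    if slices.size == 0:
        raise ValueError("no slice triggers found")
    if slices.size < slices_per_volume:
        raise ValueError(
            f"need >= {slices_per_volume} slice triggers, found {slices.size}"
        )
    n_volumes = slices.size // slices_per_volume
    onsets = slices[: n_volumes * slices_per_volume : slices_per_volume]
    markers = [m for m in rec.markers if m.kind != "volume"]
    markers += [Marker(label="Volume", sample=int(s), kind="volume") for s in onsets]
    markers.sort(key=lambda m: (m.sample, m.label))
    return rec.copy(markers=markers)
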