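"""End-to-end artifact-reduction pipeline.

Stage order: volume triggers → gradient AAS/OBS at the native rate →
downsample to 250 S/s → bandpass (1–70 Hz rest, 0.1–70 Hz task) → notch
bank (slice frequency + harmonics, vibration, line) → cardiac detection
(pulse-ox preferred, then ICA, then ECG) → heartbeat-locked AAS → bad
interval detection → excision → extended Infomax ICA → feature
extraction → rule-based classification → full-length projection and
selective reconstruction. The corrected recording keeps bad intervals in
the data (the reconstruction is full length) but reports them for
downstream exclusion.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import core_io, template_subtraction as ts
from .cardiac_detection import (
    CardiacSeries,
    CardiacCycles,
    CardiacDetectionError,
    detect_cardiac_ica,
    detect_ecg_rpeaks,
    detect_pulseox_peaks,
)
from .core_io import EEGRecording, derive_volume_triggers
from .ic_classification import classify_all, compute_features
from .ica_engine import fit_infomax, project_full, reconstruct
from .interval_rejection import detect_bad_intervals, excise

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_files"]

VIBRATION_NOTCH_HZ = 26.0
LINE_NOTCH_HZ = 60.0


@dataclass
class RunConfig:
    tr: float = 2.0
    slices_per_volume: int = 39
    mode: str = "rest"  # rest: 1-70 Hz bandpass; task: 0.1-70 Hz
    target_rate: float = 250.0
    cardiac: str = "auto"  # {auto, pulseox, ica, ecg}
    vibration_notch: float = VIBRATION_NOTCH_HZ
    line_notch: float = LINE_NOTCH_HZ
    gradient_window: int = 30
    n_obs: int = 0  # plain AAS: with synchronized clocks the volume template
    # is exact, and residual PCA would mostly capture neural variance
    bcg_window: int = 21
    bcg_anchor_delay: float = 0.0
    bad_interval_threshold_db: float = 8.0
    seed: int = 97

    @property
    def band(self) -> tuple[float, float]:
        if self.mode == "rest":
            return (1.0, 70.0)
        if self.mode == "task":
            return (0.1, 70.0)
        raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class PipelineResult:
    corrected: EEGRecording
    filtered: EEGRecording  # after BCG AAS, before IC removal
    cycles: CardiacCycles | None
    bad_intervals: object
    decomposition: object
    labels: list
    removal: object
    report: dict = field(default_factory=dict)
    gradient_corrected: EEGRecording | None = None  # native rate, on request


def _pick_cardiac(
    cfg: RunConfig,
    rec: EEGRecording,
    pulseox: tuple[np.ndarray, float] | None,
    ecg: tuple[np.ndarray, float] | None,
) -> CardiacCycles:
    """Preference chain: pulse-ox if supplied, else ICA, ECG as fallback."""
    if cfg.cardiac in ("pulseox", "auto") and pulseox is not None:
        series = CardiacSeries(waveform=pulseox[0], rate=pulseox[1], source="pulseox")
        return detect_pulseox_peaks(series, rec.rate)
    if cfg.cardiac == "ecg":
        if ecg is None:
            raise CardiacDetectionError("ECG requested but no ECG series supplied")
        return detect_ecg_rpeaks(
            CardiacSeries(waveform=ecg[0], rate=ecg[1], source="ecg"), rec.rate
        )
    try:
        return detect_cardiac_ica(rec, seed=cfg.seed)
    except CardiacDetectionError:
        if ecg is not None:
            return detect_ecg_rpeaks(
                CardiacSeries(waveform=ecg[0], rate=ecg[1], source="ecg"), rec.rate
            )
        raise


STAGE_ORDER = [
    "volume_triggers",
    "gradient_correct",
    "downsample",
    "filters",
    "cardiac_detection",
    "bcg_correct",
    "bad_intervals",
    "excise",
    "ica",
    "project_full",
    "features",
    "classify",
    "reconstruct",
]


def run_pipeline(
    rec: EEGRecording,
    cfg: RunConfig | None = None,
    pulseox: tuple[np.ndarray, float] | None = None,
    ecg: tuple[np.ndarray, float] | None = None,
    dry_run: bool = False,
    keep_intermediates: bool = False,
) -> PipelineResult:
    """Run the full artifact-reduction chain on an in-memory recording.

    ``pulseox``/``ecg`` are (waveform, rate) tuples when available. With
    ``dry_run`` the planned stage order and parameters are reported without
    computing anything.
    """
    cfg = cfg or RunConfig()
    report: dict = {"parameters": asdict(cfg), "stages": {}}
    if dry_run:
        report["plan"] = list(STAGE_ORDER)
        return PipelineResult(
            corrected=rec, filtered=rec, cycles=None, bad_intervals=None,
            decomposition=None, labels=[], removal=None, report=report,
        )

    def _stage(name, fn, *args, **kw):
        t0 = time.perf_counter()
        out = fn(*args, **kw)
        report["stages"][name] = round(time.perf_counter() - t0, 3)
        return out

    rec = _stage("volume_triggers", derive_volume_triggers, rec, cfg.slices_per_volume)
    rec = _stage(
        "gradient_correct",
        ts.gradient_correct,
        rec,
        ts.TemplateConfig(
            window=cfg.gradient_window,
            n_obs=cfg.n_obs,
            template_highpass_hz=cfg.band[0],
        ),
    )
    gradient_corrected = rec if keep_intermediates else None
    rec = _stage("downsample", ts.downsample, rec, cfg.target_rate)
    notches = ts.slice_notches(cfg.slices_per_volume, cfg.tr, cfg.band[1])
    notches += [cfg.vibration_notch, cfg.line_notch]
    plan = ts.FilterPlan(band=cfg.band, notches=sorted(set(notches)))
    rec = _stage("filters", ts.apply_filters, rec, plan)
    report["notches_hz"] = plan.notches

    cycles = _stage("cardiac_detection", _pick_cardiac, cfg, rec, pulseox, ecg)
    report["cardiac"] = {
        "source": cycles.source,
        "hr_bpm": round(cycles.hr_bpm, 2),
        "n_beats": int(cycles.peaks.size),
        "confidence": round(cycles.confidence, 3),
    }
    rec = _stage(
        "bcg_correct",
        ts.bcg_correct,
        rec,
        cycles,
        ts.TemplateConfig(window=cfg.bcg_window, n_obs=0),
        cfg.bcg_anchor_delay,
    )

    bad = _stage(
        "bad_intervals",
        detect_bad_intervals,
        rec,
        threshold_db=cfg.bad_interval_threshold_db,
    )
    report["bad_intervals"] = {
        "n_spans": len(bad.spans),
        "total_seconds": round(bad.total_seconds, 2),
    }
    short, index_map = _stage("excise", excise, rec, bad)

    dec = _stage("ica", fit_infomax, short.data, seed=cfg.seed, labels=short.labels)
    _stage("project_full", project_full, dec, rec.data)
    feats = _stage("features", compute_features, dec, rec, cycles)
    labels, removal = _stage("classify", classify_all, feats)
    report["components"] = {
        str(l.component): l.label for l in labels if l.label != "neural"
    }
    report["n_removed"] = len(removal.ids)
    report["ica"] = {"seed": dec.seed, "n_iter": dec.n_iter, "converged": dec.converged}

    x_final = _stage("reconstruct", reconstruct, dec, removal)
    corrected = rec.copy(data=x_final)
    return PipelineResult(
        corrected=corrected,
        filtered=rec,
        cycles=cycles,
        bad_intervals=bad,
        decomposition=dec,
        labels=labels,
        removal=removal,
        report=report,
        gradient_corrected=gradient_corrected,
    )


def run_files(
    eeg_header: str,
    out_dir: str,
    cfg: RunConfig | None = None,
    pulseox_path: str | None = None,
) -> dict:
    """File-based wrapper: read BrainVision input, run, write outputs.

    Writes the corrected recording (BrainVision triplet), the bad-interval
    TSV, the classification JSON, and the run report JSON.
    """
    cfg = cfg or RunConfig()
    rec = core_io.read_brainvision(eeg_header)
    pulseox = core_io.read_pulseox(pulseox_path) if pulseox_path else None
    result = run_pipeline(rec, cfg, pulseox=pulseox)

    os.makedirs(out_dir, exist_ok=True)
    stem = os.path.join(out_dir, "corrected")
    corrected = result.corrected
    bad_markers = [
        core_io.Marker(label="Bad Interval", sample=int(a), kind="other")
        for a, _ in result.bad_intervals.spans
    ]
    corrected = corrected.copy(
        markers=sorted(
            list(corrected.markers) + bad_markers, key=lambda m: (m.sample, m.label)
        )
    )
    core_io.write_brainvision(corrected, stem)
    result.bad_intervals.to_tsv(os.path.join(out_dir, "bad_intervals.tsv"))
    np.savetxt(
        os.path.join(out_dir, "mixing_matrix.tsv"),
        result.decomposition.A,
        delimiter="\t",
        header="\t".join(result.decomposition.labels or result.corrected.labels),
        comments="",
    )
    with open(os.path.join(out_dir, "components.json"), "w") as fh:
        json.dump(
            [
                {"id": l.component, "label": l.label, "evidence": l.evidence}
                for l in result.labels
            ],
            fh,
            indent=1,
            default=float,
        )
    report_path = os.path.join(out_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(result.report, fh, indent=1, default=str)
    result.report["files"] = {
        "corrected": stem + ".vhdr",
        "report": report_path,
    }
    return result.report
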