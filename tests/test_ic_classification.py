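"""Component features and the artifact rules with the occipital-alpha guard."""

import numpy as np
import pytest

from emriclean.core_io import EEGRecording, default_montage
from emriclean.ic_classification import (
    SpectralFeatures,
    TemporalFeatures,
    TopoFeatures,
    alpha_guard,
    cardiac_locked_score,
    classify_all,
    compute_features,
    rule_bcg,
    rule_blink,
    rule_muscle,
    rule_saccade,
    rule_single_channel,
    spectral_features,
    topo_features,
)
from emriclean.ica_engine import ICADecomposition


MONTAGE = default_montage()
LABELS = list(MONTAGE.positions)


def _weights(values, floor=0.0):
    w = np.full(len(LABELS), floor)
    for lab, v in values.items():
        w[LABELS.index(lab)] = v
    return w


def _spec(band_means, peak_freq):
    means = {"delta": 0.0, "theta": 0.0, "alpha": 0.0, "beta": 0.0, "gamma": 0.0}
    means.update(band_means)
    return SpectralFeatures(
        freqs=np.linspace(0, 125, 100), psd=np.zeros(100),
        band_means=means, peak_freq=peak_freq,
    )


def _temp(kurtosis=3.0, ratio=1.0, locked=0.0, contribution=0.03):
    return TemporalFeatures(
        kurtosis=kurtosis,
        channel_projection_ratio=ratio,
        cardiac_locked_score=locked,
        contribution=contribution,
    )


class TestFeatures:
    def test_pure_alpha_component_spectrum(self):
        rng = np.random.default_rng(0)
        t = np.arange(15000) / 250.0
        src = np.sin(2 * np.pi * 10.0 * t) + 0.01 * rng.standard_normal(t.size)
        spec = spectral_features(src, 250.0)
        assert spec.peak_freq == pytest.approx(10.0, abs=0.25)
        assert all(
            spec.band_means["alpha"] > v
            for k, v in spec.band_means.items()
            if k != "alpha"
        )

    def test_gaussian_kurtosis_near_three(self):
        from scipy.stats import kurtosis

        rng = np.random.default_rng(1)
        k = kurtosis(rng.standard_normal(15000), fisher=False)
        assert 2.8 <= k <= 3.2

    def test_occipital_weights_overlap(self):
        topo = topo_features(_weights({"O1": 1.0, "O2": 1.0, "Oz": 1.0}), LABELS, MONTAGE)
        assert topo.occipital_overlap >= 0.9

    def test_compute_features_end_to_end(self):
        rng = np.random.default_rng(2)
        n, n_samp = len(LABELS), 5000
        A = np.linalg.qr(rng.standard_normal((n, n)))[0]
        S = rng.standard_normal((n, n_samp))
        dec = ICADecomposition(
            A=A, W=np.linalg.inv(A), S_short=S, seed=0, labels=LABELS, S_full=S
        )
        rec = EEGRecording(data=A @ S, rate=250.0, labels=LABELS)
        feats = compute_features(dec, rec)
        assert len(feats) == n
        contribs = [t.contribution for _, _, t in feats]
        assert sum(contribs) == pytest.approx(1.0, abs=0.05)

    def test_cardiac_locked_score_flat_noise_low_locked_high(self):
        rng = np.random.default_rng(3)
        rate = 250.0
        peaks = np.arange(0, 15000, 200)  # 75 bpm
        noise = rng.standard_normal(15000)
        assert cardiac_locked_score(noise, peaks, rate) < 0.3
        bump = np.zeros(15000)
        shape = np.sin(np.linspace(0, np.pi, 60)) ** 2
        for p in peaks[:-1]:
            bump[p + 20 : p + 80] += shape
        assert cardiac_locked_score(bump, peaks, rate) > 0.5


class TestAlphaGuard:
    def _occ_topo(self, overlap, polarity="unipolar"):
        return TopoFeatures(
            weights=np.zeros(31), grid=np.zeros((64, 64)), polarity=polarity,
            occipital_overlap=overlap, frontopolar_ratio=0.1, orbitofrontal_ratio=0.1,
            active_centroid=(0.0, -0.8), pos_lobe_centroid=None,
            neg_lobe_centroid=None, pos_peak_channel="Oz", neg_peak_channel=None,
        )

    def test_occipital_alpha_protected(self):
        assert alpha_guard(self._occ_topo(0.8), _spec({"alpha": 5.0}, 10.0))

    def test_overlap_below_unipolar_threshold_not_protected(self):
        assert not alpha_guard(self._occ_topo(0.3), _spec({"alpha": 5.0}, 10.0))

    def test_bipolar_needs_higher_overlap(self):
        spec = _spec({"alpha": 5.0}, 10.0)
        assert not alpha_guard(self._occ_topo(0.8, "bipolar"), spec)
        assert alpha_guard(self._occ_topo(0.95, "bipolar"), spec)

    def test_frontal_map_not_protected(self):
        assert not alpha_guard(self._occ_topo(0.0), _spec({"alpha": 5.0}, 10.0))

    def test_alpha_band_mean_dominance_suffices(self):
        spec = _spec({"alpha": 5.0, "delta": 2.0, "theta": 1.0, "beta": 1.0}, 3.0)
        assert alpha_guard(self._occ_topo(0.8), spec)


def _bipolar_hemispheric_topo():
    return TopoFeatures(
        weights=np.zeros(31), grid=np.zeros((64, 64)), polarity="bipolar",
        occipital_overlap=0.0, frontopolar_ratio=0.1, orbitofrontal_ratio=0.2,
        active_centroid=(0.0, 0.0), pos_lobe_centroid=(-0.6, 0.0),
        neg_lobe_centroid=(0.6, 0.0), pos_peak_channel="T7", neg_peak_channel="T8",
    )


class TestRules:
    def test_bcg_fires_on_locked_bipolar_low_frequency(self):
        spec = _spec({"delta": 5.0, "theta": 2.0, "alpha": 1.0}, 3.0)
        assert rule_bcg(_bipolar_hemispheric_topo(), spec, _temp(locked=0.6))

    def test_bcg_requires_cardiac_locking(self):
        spec = _spec({"delta": 5.0, "alpha": 1.0}, 3.0)
        assert not rule_bcg(_bipolar_hemispheric_topo(), spec, _temp(locked=0.1))

    def test_bcg_alpha_exemption(self):
        spec = _spec({"alpha": 5.0, "delta": 1.0}, 10.0)
        assert not rule_bcg(_bipolar_hemispheric_topo(), spec, _temp(locked=0.6))

    def test_bcg_needs_opposite_hemispheres(self):
        topo = _bipolar_hemispheric_topo()
        topo.pos_lobe_centroid = (0.3, 0.0)  # both lobes on the right
        spec = _spec({"delta": 5.0}, 3.0)
        assert not rule_bcg(topo, spec, _temp(locked=0.6))

    def test_blink_frontopolar_map_fires(self):
        topo = topo_features(
            _weights({"Fp1": 1.0, "Fp2": 1.0, "Fz": 0.2, "F3": 0.2}, floor=0.02),
            LABELS, MONTAGE,
        )
        assert rule_blink(topo, _temp(kurtosis=8.0))

    def test_blink_central_map_does_not_fire(self):
        topo = topo_features(_weights({"Cz": 1.0, "FC1": 0.4, "FC2": 0.4}), LABELS, MONTAGE)
        assert not rule_blink(topo, _temp(kurtosis=8.0))

    def test_blink_requires_2x_frontopolar_ratio(self):
        # every other channel at 2/3 puts the ratio at exactly 1.5
        topo = topo_features(
            _weights({"Fp1": 1.0, "Fp2": 1.0}, floor=2.0 / 3.0), LABELS, MONTAGE
        )
        assert topo.frontopolar_ratio == pytest.approx(1.5, abs=0.01)
        assert not rule_blink(topo, _temp(kurtosis=8.0))

    def test_saccade_orbitofrontal_dipole_fires(self):
        topo = topo_features(
            _weights({"F7": 1.0, "F8": -1.0, "Fp1": 0.2, "Fp2": -0.2}), LABELS, MONTAGE
        )
        assert rule_saccade(topo)

    def test_saccade_same_polarity_does_not_fire(self):
        topo = topo_features(_weights({"F7": 1.0, "F8": 1.0}), LABELS, MONTAGE)
        assert not rule_saccade(topo)

    def test_saccade_wrong_region_does_not_fire(self):
        topo = topo_features(_weights({"O1": 1.0, "O2": -1.0}), LABELS, MONTAGE)
        assert not rule_saccade(topo)

    def test_single_channel_thresholds(self):
        spec = _spec({"delta": 5.0}, 2.0)
        assert rule_single_channel(None, spec, _temp(kurtosis=6.2, ratio=8.0))
        assert not rule_single_channel(None, spec, _temp(kurtosis=3.9, ratio=8.0))
        alpha_spec = _spec({"alpha": 5.0}, 10.0)
        assert not rule_single_channel(None, alpha_spec, _temp(kurtosis=10.0, ratio=8.0))

    def test_muscle_gamma_dominant_fires(self):
        rng = np.random.default_rng(4)
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, 35.0, btype="high", fs=250.0, output="sos")
        spec = spectral_features(sosfiltfilt(sos, rng.standard_normal(15000)), 250.0)
        assert rule_muscle(spec)

    def test_muscle_alpha_sine_does_not_fire(self):
        t = np.arange(15000) / 250.0
        spec = spectral_features(np.sin(2 * np.pi * 10 * t), 250.0)
        assert not rule_muscle(spec)

    def test_muscle_narrowband_line_residue_fires(self):
        t = np.arange(15000) / 250.0
        rng = np.random.default_rng(5)
        src = np.sin(2 * np.pi * 60.0 * t) + 0.05 * rng.standard_normal(t.size)
        assert rule_muscle(spectral_features(src, 250.0))


class TestClassifyAll:
    def _features(self, topo, spec, temp):
        return (topo, spec, temp)

    def test_guard_precedes_bcg(self):
        """An occipital-alpha component that also looks bipolar-hemispheric
        stays neural."""
        topo = _bipolar_hemispheric_topo()
        topo.occipital_overlap = 0.95
        spec = _spec({"alpha": 5.0, "delta": 1.0}, 10.0)
        labels, removal = classify_all([self._features(topo, spec, _temp(locked=0.9))])
        assert labels[0].label == "neural"
        assert removal.ids == []

    def test_single_label_partition(self):
        feats = []
        # blink-like and bcg-like and neutral
        blink_topo = topo_features(
            _weights({"Fp1": 1.0, "Fp2": 0.9}, floor=0.02), LABELS, MONTAGE
        )
        feats.append((blink_topo, _spec({"delta": 2.0}, 2.0), _temp(kurtosis=9.0)))
        feats.append(
            (_bipolar_hemispheric_topo(), _spec({"delta": 5.0}, 3.0), _temp(locked=0.6))
        )
        neutral = topo_features(
            np.random.default_rng(0).normal(size=31) * 0.1 + 0.5, LABELS, MONTAGE
        )
        feats.append((neutral, _spec({"delta": 2.0, "alpha": 1.0}, 2.0), _temp()))
        labels, removal = classify_all(feats)
        assert [l.label for l in labels] == ["blink", "bcg", "neural"]
        assert removal.ids == [0, 1]

    def test_rules_pure_functions_of_features(self):
        topo = _bipolar_hemispheric_topo()
        spec = _spec({"delta": 5.0}, 3.0)
        temp = _temp(locked=0.6)
        a, _ = classify_all([(topo, spec, temp)])
        b, _ = classify_all([(topo, spec, temp)])
        assert [l.label for l in a] == [l.label for l in b]

    def test_contribution_floor_keeps_labels_but_not_removal(self):
        feats = [
            (_bipolar_hemispheric_topo(), _spec({"delta": 5.0}, 3.0),
             _temp(locked=0.6, contribution=0.001)),
        ]
        labels, removal = classify_all(feats, min_contribution=0.005)
        assert labels[0].label == "bcg"
        assert removal.ids == []
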