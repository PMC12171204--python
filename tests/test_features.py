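"""Feature operators against brute-force oracles, plus vector assembly."""

import numpy as np
import pytest

from bioharkit.features import (
    Spectrum,
    build_feature_vector,
    feature_matrix,
    mav,
    psd,
    spectral_flux,
    spectral_rolloff,
    waveform_length,
)
from bioharkit.io_windowing import SignalWindow


def _mav_loop(x):
    return sum(abs(v) for v in x) / len(x)


def _wl_loop(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


def _flux_loop(p, q):
    return sum((a - b) ** 2 for a, b in zip(p, q))


def _rolloff_loop(freqs, power, k):
    target = k * sum(power)
    acc = 0.0
    for f, p in zip(freqs, power):
        acc += p
        if acc >= target:
            return f
    return freqs[-1]


class TestTimeDomain:
    @pytest.mark.parametrize(
        "x, expected",
        [([1, -1, 1, -1], 1.0), ([0, 0, 0], 0.0), ([3, -4], 3.5)],
    )
    def test_mav_examples(self, x, expected):
        assert mav(np.array(x, dtype=float)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "x, expected", [([5, 5, 5], 0.0), ([0, 1, 0], 2.0)]
    )
    def test_wl_examples(self, x, expected):
        assert waveform_length(np.array(x, dtype=float)) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_match_loop_oracles(self, seed):
        x = np.random.default_rng(seed).standard_normal(100)
        assert mav(x) == pytest.approx(_mav_loop(x), abs=1e-12)
        assert waveform_length(x) == pytest.approx(_wl_loop(x), abs=1e-12)

    def test_scale_equivariance(self, rng):
        x = rng.standard_normal(64)
        for c in (-3.7, 0.5):
            assert mav(c * x) == pytest.approx(abs(c) * mav(x), abs=1e-9)
            assert waveform_length(c * x) == pytest.approx(
                abs(c) * waveform_length(x), abs=1e-9
            )

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            mav(np.array([]))
        with pytest.raises(ValueError):
            waveform_length(np.array([1.0]))


class TestPsd:
    def test_tone_peaks_at_its_bin(self):
        fs = 100.0
        t = np.arange(200) / fs
        s = psd(np.sin(2 * np.pi * 10 * t), fs)
        assert s.freqs_hz[np.argmax(s.power)] == pytest.approx(10.0)

    def test_zero_window(self):
        s = psd(np.zeros(64), 100.0)
        np.testing.assert_array_equal(s.power, 0.0)

    @pytest.mark.parametrize("n", [64, 127, 500])
    def test_parseval(self, n, rng):
        x = rng.standard_normal(n)
        s = psd(x, 100.0)
        energy = np.sum(x**2)
        assert np.sum(s.power) == pytest.approx(energy, rel=1e-6)


class TestRolloff:
    def test_single_bin(self):
        s = Spectrum(np.array([0.0, 12.0, 24.0]), np.array([0.0, 5.0, 0.0]))
        assert spectral_rolloff(s, 0.85) == 12.0

    def test_uniform_bins_match_cumsum_oracle(self):
        freqs = np.arange(100, dtype=float)
        power = np.ones(100)
        s = Spectrum(freqs, power)
        for k in (0.25, 0.5, 0.85, 0.999):
            assert spectral_rolloff(s, k) == _rolloff_loop(freqs, power, k)

    def test_k_one_returns_highest_nonzero_bin(self):
        power = np.array([1.0, 2.0, 3.0, 0.0, 0.0])
        s = Spectrum(np.arange(5, dtype=float), power)
        assert spectral_rolloff(s, 1.0) == 2.0

    def test_monotone_in_k(self, rng):
        power = rng.uniform(0, 1, 64)
        s = Spectrum(np.arange(64, dtype=float), power)
        ks = np.linspace(0.05, 1.0, 20)
        rolls = [spectral_rolloff(s, k) for k in ks]
        assert np.all(np.diff(rolls) >= 0)

    def test_zero_power_rejected(self):
        s = Spectrum(np.arange(4, dtype=float), np.zeros(4))
        with pytest.raises(ValueError):
            spectral_rolloff(s, 0.85)


class TestFlux:
    def test_identical_spectra_zero(self, rng):
        p = rng.uniform(0, 1, 16)
        s = Spectrum(np.arange(16, dtype=float), p)
        assert spectral_flux(s, s) == 0.0

    def test_hand_example(self):
        f = np.array([0.0, 1.0])
        assert spectral_flux(Spectrum(f, np.array([1.0, 0.0])),
                             Spectrum(f, np.array([0.0, 1.0]))) == 2.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        f = np.arange(64, dtype=float)
        p, q = rng.uniform(0, 1, 64), rng.uniform(0, 1, 64)
        assert spectral_flux(Spectrum(f, p), Spectrum(f, q)) == pytest.approx(
            _flux_loop(p, q), abs=1e-12
        )

    def test_scale_equivariance_squared(self, rng):
        f = np.arange(32, dtype=float)
        p, q = rng.uniform(0, 1, 32), rng.uniform(0, 1, 32)
        c = 2.5
        assert spectral_flux(Spectrum(f, c * p), Spectrum(f, c * q)) == pytest.approx(
            c**2 * spectral_flux(Spectrum(f, p), Spectrum(f, q)), rel=1e-9
        )

    def test_mismatched_grid_rejected(self):
        a = Spectrum(np.arange(8, dtype=float), np.ones(8))
        b = Spectrum(2 * np.arange(8, dtype=float), np.ones(8))
        with pytest.raises(ValueError):
            spectral_flux(a, b)


def _window(channels, roles, fs=100.0, n=500):
    return SignalWindow(
        subject_id="s1",
        start_index=0,
        length=n,
        channels=channels,
        label=1,
        label_purity=1.0,
        sampling_rate_hz=fs,
        channel_roles=roles,
    )


class TestBuildFeatureVector:
    def test_acc_only_window_has_only_acc_names(self, rng):
        w = _window(
            {f"acc_{a}": rng.standard_normal(500) for a in "xyz"},
            {f"acc_{a}": f"acc_{a}" for a in "xyz"},
        )
        fv = build_feature_vector(w)
        assert all(n.startswith("acc_") for n in fv.names)
        assert any("rolloff" in n for n in fv.names)
        assert not any("imf" in n or "synergy" in n for n in fv.names)

    def test_schema_stable_across_windows(self, rng):
        roles = {"ecg": "ecg", "emg1": "emg", "emg2": "emg", "acc_x": "acc_x"}
        vs = []
        for _ in range(2):
            w = _window({n: rng.standard_normal(500) for n in roles}, roles)
            vs.append(build_feature_vector(w))
        assert vs[0].names == vs[1].names

    def test_deterministic(self, rng):
        roles = {"emg1": "emg", "emg2": "emg"}
        chans = {n: rng.standard_normal(500) for n in roles}
        a = build_feature_vector(_window(chans, roles))
        b = build_feature_vector(_window(chans, roles))
        np.testing.assert_array_equal(a.values, b.values)

    def test_no_usable_channels_rejected(self, rng):
        w = _window({"ch": rng.standard_normal(500)}, {"ch": "other"})
        with pytest.raises(ValueError, match="usable"):
            build_feature_vector(w)

    def test_unknown_config_key_rejected(self, rng):
        w = _window({"acc_x": rng.standard_normal(500)}, {"acc_x": "acc_x"})
        with pytest.raises(KeyError):
            build_feature_vector(w, {"rolloff_kk": 0.9})


class TestFeatureMatrix:
    def test_full_cohort_matrix_finite(self, synthetic_features):
        X, y, subjects, names = synthetic_features
        assert np.all(np.isfinite(X))
        assert X.shape == (len(y), len(names))
        assert len(set(names)) == len(names)
        assert set(np.unique(y)) == {0, 1, 2, 3, 4, 5}
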