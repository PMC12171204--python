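"""Hybrid multidomain feature block.

Time-domain intensity/complexity features (mean absolute value, waveform
length), a one-sided periodogram with band-power summaries, and the
audio-style spectral shape features — rolloff (frequency below which a set
fraction, default 85%, of total power lies) and flux (sum of squared
differences between consecutive power spectra) — assembled into one
deterministic named vector per window.

The periodogram is rectangular-windowed and normalized so that total
one-sided power equals the time-domain energy sum(x^2) (Parseval), which
makes band powers directly interpretable as energy fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np

from bioharkit.decomposition import emd_features
from bioharkit.io_windowing import SignalWindow
from bioharkit.synergy import synergy_features

#: feature-extraction defaults; overridable per run via the ``features``
#: section of the pipeline config
DEFAULT_FEATURE_CONFIG: dict[str, Any] = {
    "rolloff_k": 0.85,
    "flux_segments": 4,
    "flux_normalize": False,
    "slow_bands_hz": [(0.5, 4.0), (4.0, 8.0), (8.0, 15.0), (15.0, 25.0)],
    "emd": {"n_imf_features": 3, "max_imfs": 5, "sd_threshold": 0.2},
    "synergy": {"k": 2, "seed": 0, "max_iter": 200},
    "use_emd": True,
    "use_synergy": True,
}


@dataclass
class Spectrum:
    """One-sided power spectrum on a strictly increasing grid from 0 Hz."""

    freqs_hz: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if len(self.freqs_hz) != len(self.power):
            raise ValueError("freqs and power must have equal length")
        if len(self.freqs_hz) and (self.freqs_hz[0] != 0.0 or np.any(np.diff(self.freqs_hz) <= 0)):
            raise ValueError("frequency grid must start at 0 and strictly increase")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class FeatureVector:
    """Named feature values for one window."""

    values: np.ndarray
    names: list[str]
    window_ref: tuple[str, int]
    label: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def mav(x: np.ndarray) -> float:
    """Mean absolute value ``(1/N) sum |x_i|`` — EMG contraction intensity."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty series")
    return float(np.mean(np.abs(x)))


def waveform_length(x: np.ndarray) -> float:
    """Waveform length ``sum |x_{i+1} - x_i|`` — temporal complexity."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("waveform length needs >= 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def psd(x: np.ndarray, sampling_rate_hz: float) -> Spectrum:
    """One-sided periodogram ``|FFT(x)|^2`` normalized to signal energy.

    ``P_k = |X_k|^2 / N`` with interior bins doubled, so
    ``sum(P) == sum(x^2)`` exactly (Parseval).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 4:
        raise ValueError("psd needs >= 4 samples")
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    n = len(x)
    spec = np.fft.rfft(x)
    power = (spec.real**2 + spec.imag**2) / n
    # double interior bins (DC and, for even n, Nyquist appear once)
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate_hz)
    return Spectrum(freqs_hz=freqs, power=power)


def spectral_rolloff(spectrum: Spectrum, k: float = 0.85) -> float:
    """Lowest frequency R with cumulative power through R >= k * total."""
    if not 0 < k <= 1:
        raise ValueError("k must be in (0, 1]")
    total = float(np.sum(spectrum.power))
    if total <= 0:
        raise ValueError("rolloff undefined for zero total power")
    if k == 1.0:
        nonzero = np.nonzero(spectrum.power)[0]
        return float(spectrum.freqs_hz[nonzero[-1]])
    cum = np.cumsum(spectrum.power)
    idx = int(np.searchsorted(cum, k * total))
    return float(spectrum.freqs_hz[min(idx, len(cum) - 1)])


def spectral_flux(spectrum_n: Spectrum, spectrum_prev: Spectrum) -> float:
    """``sum_f (P_n(f) - P_{n-1}(f))^2`` between spectra on one grid."""
    if len(spectrum_n.freqs_hz) != len(spectrum_prev.freqs_hz) or not np.array_equal(
        spectrum_n.freqs_hz, spectrum_prev.freqs_hz
    ):
        raise ValueError("spectra must share an identical frequency grid")
    diff = spectrum_n.power - spectrum_prev.power
    return float(np.sum(diff * diff))


def band_power_fractions(
    spectrum: Spectrum, bands_hz: list[tuple[float, float]]
) -> list[float]:
    """Fraction of total power inside each [lo, hi) band (hi-inclusive at top)."""
    total = float(np.sum(spectrum.power))
    if total <= 0:
        return [0.0] * len(bands_hz)
    out = []
    for lo, hi in bands_hz:
        mask = (spectrum.freqs_hz >= lo) & (spectrum.freqs_hz < hi)
        out.append(float(np.sum(spectrum.power[mask])) / total)
    return out


def _quartile_bands(nyquist: float) -> list[tuple[float, float]]:
    edges = np.linspace(0.0, nyquist, 5)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(4)]


def _flux_stats(x: np.ndarray, fs: float, n_segments: int, normalize: bool) -> tuple[float, float]:
    """Mean and max spectral flux between consecutive equal sub-segments."""
    seg_len = len(x) // n_segments
    if seg_len < 4 or n_segments < 2:
        return 0.0, 0.0
    spectra = []
    for i in range(n_segments):
        s = psd(x[i * seg_len:(i + 1) * seg_len], fs)
        if normalize:
            total = float(np.sum(s.power))
            if total > 0:
                s = Spectrum(s.freqs_hz, s.power / total)
        spectra.append(s)
    fluxes = [spectral_flux(spectra[i], spectra[i - 1]) for i in range(1, n_segments)]
    return float(np.mean(fluxes)), float(np.max(fluxes))


def _merge_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_FEATURE_CONFIG.items()}
    if config:
        for key, val in config.items():
            if key not in merged:
                raise KeyError(f"unknown feature config key {key!r}")
            if isinstance(merged[key], dict) and isinstance(val, Mapping):
                merged[key].update(val)
            else:
                merged[key] = val
    return merged


def build_feature_vector(
    window: SignalWindow, config: Mapping[str, Any] | None = None
) -> FeatureVector:
    """Assemble the per-window feature vector in fixed role order.

    Block order is ecg, emg (plus a shared synergy block when >= 2 EMG
    channels are present), then acc. ECG/EMG channels contribute MAV,
    waveform length, slow-band power fractions (ECG) or quartile-band
    fractions up to Nyquist (EMG), and EMD envelope/instantaneous-frequency
    moments. Accelerometer axes contribute MAV, band fractions, spectral
    rolloff, and sub-segment flux statistics. The name sequence depends only
    on the window's channel roles and the config, never on the data.
    """
    cfg = _merge_config(config)
    fs = window.sampling_rate_hz
    nyq = fs / 2.0
    names: list[str] = []
    values: list[float] = []

    def add(name: str, value: float) -> None:
        names.append(name)
        values.append(float(value))

    def add_ecg_emg_block(name: str, series: np.ndarray, role: str) -> None:
        add(f"{name}_mav", mav(series))
        add(f"{name}_wl", waveform_length(series))
        spectrum = psd(series, fs)
        bands = (
            [(lo, hi) for lo, hi in cfg["slow_bands_hz"] if lo < nyq]
            if role == "ecg"
            else _quartile_bands(nyq)
        )
        for (lo, hi), frac in zip(bands, band_power_fractions(spectrum, bands)):
            add(f"{name}_band_{lo:g}_{hi:g}", frac)
        if cfg["use_emd"]:
            emd_cfg = cfg["emd"]
            for key, val in emd_features(
                series,
                fs,
                n_imf_features=emd_cfg["n_imf_features"],
                max_imfs=emd_cfg["max_imfs"],
                sd_threshold=emd_cfg["sd_threshold"],
            ).items():
                add(f"{name}_{key}", val)

    ecg = window.channels and {
        n: s for n, s in window.channels.items() if window.channel_roles.get(n) == "ecg"
    }
    emg = {n: s for n, s in window.channels.items() if window.channel_roles.get(n) == "emg"}
    acc = {
        n: s
        for n, s in window.channels.items()
        if window.channel_roles.get(n) in {"acc_x", "acc_y", "acc_z"}
    }
    if not (ecg or emg or acc):
        raise ValueError("window has no channel with a usable role")

    for name, series in (ecg or {}).items():
        add_ecg_emg_block(name, series, "ecg")
    for name, series in emg.items():
        add_ecg_emg_block(name, series, "emg")
    if cfg["use_synergy"] and len(emg) >= 2:
        syn_cfg = cfg["synergy"]
        for key, val in synergy_features(
            emg, fs, k=syn_cfg["k"], seed=syn_cfg["seed"], max_iter=syn_cfg["max_iter"]
        ).items():
            add(key, val)
    for name, series in acc.items():
        add(f"{name}_mav", mav(series))
        spectrum = psd(series, fs)
        bands = [(lo, hi) for lo, hi in cfg["slow_bands_hz"] if lo < nyq]
        for (lo, hi), frac in zip(bands, band_power_fractions(spectrum, bands)):
            add(f"{name}_band_{lo:g}_{hi:g}", frac)
        total = float(np.sum(spectrum.power))
        add(f"{name}_rolloff", spectral_rolloff(spectrum, cfg["rolloff_k"]) if total > 0 else 0.0)
        flux_mean, flux_max = _flux_stats(
            series, fs, cfg["flux_segments"], cfg["flux_normalize"]
        )
        add(f"{name}_flux_mean", flux_mean)
        add(f"{name}_flux_max", flux_max)

    return FeatureVector(
        values=np.asarray(values),
        names=names,
        window_ref=(window.subject_id, window.start_index),
        label=window.label,
    )


def feature_matrix(
    windows: list[SignalWindow], config: Mapping[str, Any] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Stack per-window vectors into ``(X, y, subjects, names)``.

    Raises if windows disagree on the feature schema (they cannot, for a
    homogeneous recording set and one config).
    """
    if not windows:
        raise ValueError("no windows")
    vecs = [build_feature_vector(w, config) for w in windows]
    names = vecs[0].names
    for v in vecs[1:]:
        if v.names != names:
            raise ValueError("inconsistent feature schema across windows")
    X = np.vstack([v.values for v in vecs])
    y = np.asarray([v.label for v in vecs], dtype=np.int64)
    subjects = np.asarray([v.window_ref[0] for v in vecs], dtype=object)
    return X, y, subjects, names
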