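"""Seeded synthetic multimodal recordings with known ground truth.

The generator emulates the statistical structure the pipeline exploits,
not physiology:

* **ECG** — a train of template pulses (sum of three Gaussians, a
  P-QRS-T caricature) at intervals of ``60/bpm`` seconds with optional
  multiplicative jitter, plus white noise.
* **EMG** — two channels of band-limited noise amplitude-modulated by a
  known synergy structure ``W0 @ H-pattern`` (periodic burst activations),
  plus white noise.
* **Accelerometer** — a constant gravity offset, a class-dependent
  sinusoidal oscillation per axis, and Gaussian noise.

Activity classes differ in oscillation frequency/amplitude, burst rate and
intensity, and heart rate. Subjects carry random effects (amplitude scale
±15%, frequency ±10%) drawn from subject-keyed substreams of one root
seed, so every component is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import butter, sosfiltfilt

from bioharkit.io_windowing import MultimodalRecording

#: relative subject random effects (fractions)
SUBJECT_AMP_SPREAD = 0.15
SUBJECT_FREQ_SPREAD = 0.10

GRAVITY = 9.81


@dataclass
class ActivityProfile:
    """Latent parameters of one activity class."""

    label: int
    acc_osc_freq_hz: float
    acc_amplitude: tuple[float, float, float]
    emg_burst_rate_hz: float
    emg_burst_amplitude: float
    heart_rate_bpm: float
    heart_rate_jitter: float = 0.03  # fractional sd of beat interval
    synergy_W: np.ndarray | None = None  # 2 x 2 non-negative muscle weights

    def __post_init__(self) -> None:
        if self.acc_osc_freq_hz < 0 or self.emg_burst_rate_hz < 0:
            raise ValueError("frequencies must be non-negative")
        if any(a < 0 for a in self.acc_amplitude) or self.emg_burst_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart rate must be positive")
        if self.synergy_W is None:
            self.synergy_W = np.array([[1.0, 0.25], [0.25, 1.0]])


def default_profiles() -> list[ActivityProfile]:
    """Six activity classes spanning rest to vigorous locomotion."""
    spec = [
        # label, freq, (ax, ay, az), burst rate, burst amp, bpm, jitter
        (0, 0.2, (0.02, 0.016, 0.012), 0.4, 0.10, 60.0, 0.0),
        (1, 0.4, (0.05, 0.040, 0.030), 0.6, 0.15, 66.0, 0.02),
        (2, 1.2, (0.40, 0.320, 0.240), 1.2, 0.50, 90.0, 0.03),
        (3, 1.6, (0.70, 0.560, 0.420), 1.6, 0.80, 105.0, 0.03),
        (4, 2.5, (1.20, 0.960, 0.720), 2.5, 1.10, 130.0, 0.04),
        (5, 3.2, (2.00, 1.600, 1.200), 3.2, 1.50, 150.0, 0.04),
    ]
    profiles = []
    for label, f, amp, br, ba, bpm, jit in spec:
        W = np.array([[1.0, 0.2 + 0.1 * label], [0.2 + 0.08 * label, 1.0]])
        profiles.append(
            ActivityProfile(
                label=label,
                acc_osc_freq_hz=f,
                acc_amplitude=amp,
                emg_burst_rate_hz=br,
                emg_burst_amplitude=ba,
                heart_rate_bpm=bpm,
                heart_rate_jitter=jit,
                synergy_W=W,
            )
        )
    return profiles


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort."""

    n_subjects: int = 10
    classes: list[ActivityProfile] = field(default_factory=default_profiles)
    duration_per_class_s: float = 20.0
    sampling_rate_hz: float = 100.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"ecg": 0.02, "emg": 0.02, "acc": 0.05}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need at least 2 activity classes")
        labels = [p.label for p in self.classes]
        if len(set(labels)) != len(labels):
            raise ValueError("class labels must be distinct")
        if self.duration_per_class_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("durations and rates must be positive")
        if self.n_subjects < 1:
            raise ValueError("need at least 1 subject")
        nyq = self.sampling_rate_hz / 2.0
        if any(p.acc_osc_freq_hz >= nyq for p in self.classes):
            raise ValueError("oscillation frequency must be below Nyquist")


def _substream(seed: int, *keys: int) -> np.random.Generator:
    """Independent generator keyed by (seed, *keys)."""
    return np.random.default_rng([seed, *keys])


def _ecg_pulse(fs: float) -> np.ndarray:
    """P-QRS-T caricature: three Gaussians over a 0.6 s support."""
    t = np.arange(int(0.6 * fs)) / fs
    p = 0.12 * np.exp(-((t - 0.12) ** 2) / (2 * 0.025**2))
    qrs = 1.0 * np.exp(-((t - 0.26) ** 2) / (2 * 0.012**2))
    tw = 0.25 * np.exp(-((t - 0.45) ** 2) / (2 * 0.04**2))
    return p + qrs + tw


def _ecg_segment(
    n: int, fs: float, bpm: float, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    out = np.zeros(n)
    pulse = _ecg_pulse(fs)
    interval = 60.0 / bpm
    t = 0.05  # first beat offset, seconds
    while True:
        start = int(round(t * fs))
        if start >= n:
            break
        stop = min(start + len(pulse), n)
        out[start:stop] += pulse[: stop - start]
        step = interval * (1.0 + jitter * rng.standard_normal()) if jitter > 0 else interval
        t += max(step, 0.2)
    return out


def _bandlimited_noise(
    n: int, fs: float, rng: np.random.Generator, band: tuple[float, float] = (20.0, 45.0)
) -> np.ndarray:
    """Unit-variance noise band-limited to ``band`` (clipped below Nyquist)."""
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n + 200))[100:-100]
    sd = x.std()
    return x / sd if sd > 0 else x


def _activation_pattern(n: int, fs: float, rate_hz: float, amp: float) -> np.ndarray:
    """Two periodic, phase-offset non-negative activation rows (k=2)."""
    t = np.arange(n) / fs
    h1 = amp * np.clip(np.sin(2 * np.pi * rate_hz * t), 0.0, None)
    h2 = amp * np.clip(np.sin(2 * np.pi * rate_hz * t + np.pi), 0.0, None)
    return np.vstack([h1, h2]) + 0.05 * amp


def generate_recording(
    config: SyntheticConfig, subject_index: int
) -> tuple[MultimodalRecording, dict[str, Any]]:
    """One subject's recording (all classes back to back) plus ground truth."""
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError("subject_index out of range")
    fs = config.sampling_rate_hz
    n_seg = int(round(config.duration_per_class_s * fs))

    subj_rng = _substream(config.seed, subject_index, 0)
    amp_scale = 1.0 + SUBJECT_AMP_SPREAD * subj_rng.uniform(-1, 1)
    freq_scale = 1.0 + SUBJECT_FREQ_SPREAD * subj_rng.uniform(-1, 1)
    axis_phases = subj_rng.uniform(0, 2 * np.pi, size=3)

    ecg_parts, emg1_parts, emg2_parts = [], [], []
    acc_parts: list[np.ndarray] = []
    label_parts = []
    truth_segments = []

    for seg_idx, profile in enumerate(config.classes):
        rng = _substream(config.seed, subject_index, 1 + seg_idx)
        t = np.arange(n_seg) / fs

        bpm = profile.heart_rate_bpm * (2.0 - freq_scale)  # mild subject effect
        ecg = amp_scale * _ecg_segment(n_seg, fs, bpm, profile.heart_rate_jitter, rng)
        ecg += config.noise_sd["ecg"] * rng.standard_normal(n_seg)

        H = _activation_pattern(
            n_seg, fs, profile.emg_burst_rate_hz * freq_scale,
            profile.emg_burst_amplitude * amp_scale,
        )
        envelopes = profile.synergy_W @ H  # 2 x n
        carrier1 = _bandlimited_noise(n_seg, fs, rng)
        carrier2 = _bandlimited_noise(n_seg, fs, rng)
        emg1 = envelopes[0] * carrier1 + config.noise_sd["emg"] * rng.standard_normal(n_seg)
        emg2 = envelopes[1] * carrier2 + config.noise_sd["emg"] * rng.standard_normal(n_seg)

        freq = profile.acc_osc_freq_hz * freq_scale
        gravity = np.array([0.0, 0.0, GRAVITY])
        acc = np.empty((3, n_seg))
        for axis in range(3):
            osc = (
                amp_scale
                * profile.acc_amplitude[axis]
                * np.sin(2 * np.pi * freq * t + axis_phases[axis])
            )
            acc[axis] = gravity[axis] + osc + config.noise_sd["acc"] * rng.standard_normal(n_seg)

        ecg_parts.append(ecg)
        emg1_parts.append(emg1)
        emg2_parts.append(emg2)
        acc_parts.append(acc)
        label_parts.append(np.full(n_seg, profile.label, dtype=np.int64))
        truth_segments.append(
            {
                "label": profile.label,
                "bpm": bpm,
                "acc_freq_hz": freq,
                "acc_amplitude": [amp_scale * a for a in profile.acc_amplitude],
                "emg_burst_rate_hz": profile.emg_burst_rate_hz * freq_scale,
                "synergy_W": profile.synergy_W.tolist(),
                "synergy_H_mean": H.mean(axis=1).tolist(),
            }
        )

    acc_all = np.concatenate(acc_parts, axis=1)
    recording = MultimodalRecording(
        subject_id=f"S{subject_index:02d}",
        sampling_rate_hz=fs,
        channels={
            "ecg": np.concatenate(ecg_parts),
            "emg1": np.concatenate(emg1_parts),
            "emg2": np.concatenate(emg2_parts),
            "acc_x": acc_all[0],
            "acc_y": acc_all[1],
            "acc_z": acc_all[2],
        },
        labels=np.concatenate(label_parts),
        channel_roles={
            "ecg": "ecg",
            "emg1": "emg",
            "emg2": "emg",
            "acc_x": "acc_x",
            "acc_y": "acc_y",
            "acc_z": "acc_z",
        },
    )
    ground_truth = {
        "subject_index": subject_index,
        "amp_scale": amp_scale,
        "freq_scale": freq_scale,
        "segments": truth_segments,
    }
    return recording, ground_truth


def generate_dataset(config: SyntheticConfig) -> list[MultimodalRecording]:
    """Recordings for every subject in the cohort."""
    return [generate_recording(config, i)[0] for i in range(config.n_subjects)]


def generate_synergy_problem(
    m: int, n: int, k: int, noise_sd: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded NMF test problem: ``V = W0 @ H0 + non-negative noise``.

    Returns ``(V, W0, H0)`` with all entries non-negative.
    """
    if m < 2 or k < 1 or n < k:
        raise ValueError("need m >= 2 and n >= k >= 1")
    if k > min(m, n):
        raise ValueError("k must be <= min(m, n)")
    rng = np.random.default_rng(seed)
    W0 = rng.uniform(0.0, 1.0, size=(m, k))
    H0 = rng.uniform(0.0, 1.0, size=(k, n))
    V = W0 @ H0
    if noise_sd > 0:
        V = V + np.clip(noise_sd * rng.standard_normal(V.shape), 0.0, None)
    return V, W0, H0
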