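"""End-to-end wiring: condition recordings, window, extract features, and
run the subject-wise cross-validated classifier."""

from __future__ import annotations

import warnings
from typing import Any, Mapping

import numpy as np

from bioharkit import evaluation
from bioharkit.config import PipelineConfig, feature_config, merge_config
from bioharkit.features import feature_matrix
from bioharkit.filtering import FilterSpec, apply_bandpass, apply_butterworth_lowpass, apply_notch
from bioharkit.io_windowing import MultimodalRecording, SignalWindow, segment


def condition_recording(
    recording: MultimodalRecording, config: PipelineConfig
) -> MultimodalRecording:
    """Apply the role-appropriate conditioning chain to every channel.

    ECG/EMG: band-pass (edges clipped below Nyquist) then powerline notch;
    the notch is skipped with a warning when the notch frequency does not
    fit under Nyquist. Accelerometer axes: zero-phase Butterworth low-pass.
    Channels with role ``other`` pass through untouched.
    """
    fs = recording.sampling_rate_hz
    nyq = fs / 2.0
    fcfg = config["filters"]
    notch_freq = fcfg["notch"]["freq"]
    notch_ok = notch_freq < nyq * 0.999
    if not notch_ok:
        warnings.warn(
            f"notch at {notch_freq} Hz does not fit under Nyquist ({nyq} Hz); skipped",
            stacklevel=2,
        )

    out: dict[str, np.ndarray] = {}
    for name, series in recording.channels.items():
        role = recording.channel_roles.get(name, "other")
        if role in {"ecg", "emg"}:
            lo, hi = fcfg[role]["band"]
            hi = min(hi, 0.45 * fs)
            spec = FilterSpec(
                kind="bandpass", sampling_rate_hz=fs, f_low_hz=lo, f_high_hz=hi
            )
            filtered = apply_bandpass(series, spec)
            if notch_ok:
                nspec = FilterSpec(
                    kind="notch",
                    sampling_rate_hz=fs,
                    f_notch_hz=notch_freq,
                    quality_factor=fcfg["notch"]["q"],
                )
                filtered = apply_notch(filtered, nspec)
            out[name] = filtered
        elif role in {"acc_x", "acc_y", "acc_z"}:
            spec = FilterSpec(
                kind="butter_lowpass",
                sampling_rate_hz=fs,
                cutoff_hz=fcfg["acc"]["cutoff"],
                order=fcfg["acc"]["order"],
            )
            out[name] = apply_butterworth_lowpass(series, spec)
        else:
            out[name] = np.asarray(series, dtype=np.float64).copy()
    return MultimodalRecording(
        subject_id=recording.subject_id,
        sampling_rate_hz=fs,
        channels=out,
        labels=recording.labels.copy(),
        channel_roles=dict(recording.channel_roles),
    )


def windows_from_recordings(
    recordings: list[MultimodalRecording],
    config: PipelineConfig,
    condition: bool = True,
) -> list[SignalWindow]:
    """Condition (optionally) and segment every recording."""
    io_cfg = config["io"]
    windows: list[SignalWindow] = []
    for rec in recordings:
        prepared = condition_recording(rec, config) if condition else rec
        windows.extend(
            segment(
                prepared,
                window_length_s=io_cfg["window_length_s"],
                overlap_fraction=io_cfg["overlap_fraction"],
                purity_threshold=io_cfg["purity_threshold"],
                drop_labels=tuple(io_cfg["drop_labels"]),
            )
        )
    return windows


def features_from_recordings(
    recordings: list[MultimodalRecording],
    config: PipelineConfig | Mapping[str, Any] | None = None,
    condition: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Full feature table ``(X, y, subjects, names)`` for a recording set."""
    cfg = config if isinstance(config, dict) and "io" in config else merge_config(config)
    windows = windows_from_recordings(recordings, cfg, condition=condition)
    if not windows:
        raise ValueError("no usable windows after segmentation")
    return feature_matrix(windows, feature_config(cfg))


def evaluate_recordings(
    recordings: list[MultimodalRecording],
    config: PipelineConfig | Mapping[str, Any] | None = None,
    k: int | None = None,
    seed: int | None = None,
) -> evaluation.EvaluationReport:
    """Run the whole pipeline and return the cross-validation report.

    Feature extraction is per-window and fits no statistics, so it runs
    once; standardization, LDA, and the classifier are re-fit inside each
    fold on training subjects only.
    """
    cfg = config if isinstance(config, dict) and "io" in config else merge_config(config)
    X, y, subjects, _ = features_from_recordings(recordings, cfg)
    return evaluation.cross_validate(
        X,
        y,
        subjects,
        config={"lda": cfg["lda"], "classifier": cfg["classifier"]},
        k=k if k is not None else cfg["evaluation"]["folds"],
        seed=seed if seed is not None else cfg["seed"],
    )
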