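"""Muscle-synergy analysis of multichannel EMG by non-negative matrix
factorization.

The activation-envelope matrix V (muscles x time) is factored as V ~ W H
with W (muscles x synergies) holding the synergy vectors — per-muscle
weights of each coordinated activation pattern — and H (synergies x time)
the temporal activations. Fitting uses Lee–Seung multiplicative updates for
the Frobenius objective ||V - WH||^2, which decrease the objective
monotonically; reconstruction quality is summarized as VAF (variance
accounted for).

After fitting, columns of W are normalized to unit Euclidean norm with the
scale absorbed into H, so the product WH is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

_EPS = 1e-12


@dataclass
class SynergyModel:
    """Fitted non-negative factors with reconstruction diagnostics."""

    W: np.ndarray  # m x k, unit-norm columns
    H: np.ndarray  # k x n
    k: int
    reconstruction_vaf: float
    objective_trace: list[float] = field(default_factory=list)


def vaf(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Variance accounted for: ``1 - ||V - WH||_F^2 / ||V||_F^2``."""
    V = np.asarray(V, dtype=np.float64)
    total = float(np.sum(V * V))
    if total == 0.0:
        raise ValueError("VAF undefined for an all-zero matrix")
    resid = V - W @ H
    return 1.0 - float(np.sum(resid * resid)) / total


def _nmf_updates(
    V: np.ndarray, k: int, max_iter: int, tol: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    m, n = V.shape
    scale = np.sqrt(max(float(V.mean()), _EPS) / k)
    W = rng.uniform(0.0, 1.0, size=(m, k)) * scale + _EPS
    H = rng.uniform(0.0, 1.0, size=(k, n)) * scale + _EPS

    def objective() -> float:
        resid = V - W @ H
        return float(np.sum(resid * resid))

    trace = [objective()]
    for _ in range(max_iter):
        # H <- H * (W^T V) / (W^T W H)
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        # W <- W * (V H^T) / (W H H^T)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = objective()
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            break
    return W, H, trace


def fit_nmf(
    V: np.ndarray,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    n_restarts: int = 3,
) -> SynergyModel:
    """Factor a non-negative matrix by Lee–Seung multiplicative updates.

    Parameters
    ----------
    V
        m x n non-negative data matrix (m >= 2 muscles, n time samples).
    k
        Number of synergies, 1 <= k <= min(m, n).
    max_iter, tol
        Iteration cap and relative-improvement stopping threshold on the
        Frobenius objective.
    seed
        Root seed of the uniform random initializations (scaled by
        ``sqrt(mean(V)/k)``); the fit is deterministic given the seed.
    n_restarts
        Multiplicative updates only find local minima; the best of
        ``n_restarts`` independently initialized runs is kept.
    """
    V = np.asarray(V, dtype=np.float64)
    if V.ndim != 2:
        raise ValueError("V must be 2-d")
    if not np.all(np.isfinite(V)):
        raise ValueError("V must be finite")
    if np.any(V < 0):
        raise ValueError("V must be non-negative")
    m, n = V.shape
    if m < 2:
        raise ValueError("need at least 2 rows (muscles) for synergy analysis")
    if not 1 <= k <= min(m, n):
        raise ValueError(f"k must be in [1, min(m, n)] = [1, {min(m, n)}]")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    best: tuple[np.ndarray, np.ndarray, list[float]] | None = None
    for r in range(n_restarts):
        W, H, trace = _nmf_updates(V, k, max_iter, tol, np.random.default_rng([seed, r]))
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace)
    W, H, trace = best

    # normalize W columns; absorb scale into H so WH is preserved
    norms = np.linalg.norm(W, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    W = W / norms
    H = H * norms[:, None]

    return SynergyModel(
        W=W,
        H=H,
        k=k,
        reconstruction_vaf=vaf(V, W, H),
        objective_trace=trace,
    )


def select_rank(
    V: np.ndarray,
    k_max: int = 5,
    vaf_threshold: float = 0.90,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> int:
    """Smallest synergy count whose fitted VAF meets ``vaf_threshold``.

    Returns ``k_max`` if no candidate reaches the threshold.
    """
    V = np.asarray(V, dtype=np.float64)
    if k_max > min(V.shape):
        raise ValueError("k_max must be <= min(m, n)")
    for k in range(1, k_max + 1):
        model = fit_nmf(V, k, max_iter=max_iter, tol=tol, seed=seed)
        if model.reconstruction_vaf >= vaf_threshold:
            return k
    return k_max


def emg_envelopes(
    emg_channels: dict[str, np.ndarray],
    sampling_rate_hz: float,
    cutoff_hz: float = 4.0,
    order: int = 4,
) -> np.ndarray:
    """Stack rectified, low-passed EMG channels into the NMF data matrix V.

    Synergy analysis conventionally factorizes activation envelopes rather
    than raw interference EMG: each channel is full-wave rectified, smoothed
    by a zero-phase Butterworth low-pass, and clipped at zero.
    """
    if len(emg_channels) < 2:
        raise ValueError("synergy analysis needs >= 2 EMG channels")
    sos = butter(order, cutoff_hz, btype="lowpass", fs=sampling_rate_hz, output="sos")
    rows = []
    for series in emg_channels.values():
        env = sosfiltfilt(sos, np.abs(np.asarray(series, dtype=np.float64)))
        rows.append(np.clip(env, 0.0, None))
    return np.vstack(rows)


def synergy_features(
    emg_channels: dict[str, np.ndarray],
    sampling_rate_hz: float,
    k: int = 2,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> dict[str, float]:
    """Per-window synergy feature block: mean and peak of each activation row.

    Activation rows of H are sorted by descending mean so the feature order
    does not depend on the NMF permutation ambiguity.
    """
    V = emg_envelopes(emg_channels, sampling_rate_hz)
    k = min(k, V.shape[0], V.shape[1])
    if float(np.sum(V)) <= 0:
        return {
            key: 0.0
            for i in range(1, k + 1)
            for key in (f"synergy{i}_act_mean", f"synergy{i}_act_peak")
        }
    model = fit_nmf(V, k, max_iter=max_iter, tol=tol, seed=seed)
    order = np.argsort(-model.H.mean(axis=1))
    out: dict[str, float] = {}
    for rank, row in enumerate(order, start=1):
        out[f"synergy{rank}_act_mean"] = float(model.H[row].mean())
        out[f"synergy{rank}_act_peak"] = float(model.H[row].max())
    return out
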