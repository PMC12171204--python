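"""Empirical Mode Decomposition and Hilbert envelope / instantaneous frequency.

EMD splits a non-stationary signal into intrinsic mode functions (IMFs) by
iterative sifting: at each step the local mean — the average of cubic-spline
envelopes through the maxima and minima — is subtracted until the component
is locally symmetric. The residue is what remains after all IMFs are
removed, so

    x(t) = sum_n IMF_n(t) + r_N(t)

holds to machine precision by construction. Sifting stops per IMF on the
Cauchy standard-deviation criterion (default threshold 0.2, the customary
convention) or after a fixed iteration cap; decomposition stops when the
residue is monotonic, has too few extrema, or ``max_imfs`` is reached.

Envelope interpolation mirrors the outermost extrema across each boundary
before spline fitting, the standard treatment of EMD edge effects. Because
maxima and minima are handled symmetrically, the decomposition is odd:
``emd(-x)`` yields the negated IMFs of ``emd(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert


@dataclass
class IMFDecomposition:
    """Ordered IMFs plus residue for one signal."""

    source_length: int
    imfs: list[np.ndarray]
    residue: np.ndarray
    sifting_iterations: list[int] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Sum of IMFs plus residue."""
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


@dataclass
class HilbertAnalysis:
    """Amplitude envelope and instantaneous frequency of one component."""

    amplitude_envelope: np.ndarray
    instantaneous_frequency_hz: np.ndarray


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima.

    Flat plateaus register once, at their trailing edge. Symmetric in
    x -> -x (maxima of -x are exactly the minima of x).
    """
    dx = np.diff(x)
    # collapse exact zero slopes onto the preceding nonzero sign so plateaus
    # register a single extremum
    sign = np.sign(dx)
    nz = sign != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    # forward-fill zero signs
    idx = np.where(nz, np.arange(len(sign)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, sign[np.clip(idx, 0, None)], 0)
    change = np.diff(filled)
    maxima = np.where(change < 0)[0] + 1
    minima = np.where(change > 0)[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema with mirrored boundary points."""
    n = len(x)
    t = idx.astype(float)
    v = x[idx]
    k = min(2, len(idx))
    # reflect the first/last k extrema about the signal boundaries
    left_t = -t[:k][::-1]
    left_v = v[:k][::-1]
    right_t = 2.0 * (n - 1) - t[-k:][::-1]
    right_v = v[-k:][::-1]
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    # drop duplicate abscissae (extremum exactly at a boundary)
    keep = np.concatenate([[True], np.diff(tt) > 0])
    spline = CubicSpline(tt[keep], vv[keep])
    return spline(np.arange(n))


def _is_monotonic(x: np.ndarray) -> bool:
    dx = np.diff(x)
    return bool(np.all(dx >= 0) or np.all(dx <= 0))


def emd(
    signal: np.ndarray,
    max_imfs: int = 10,
    sd_threshold: float = 0.2,
    max_siftings: int = 50,
) -> IMFDecomposition:
    """Decompose ``signal`` into IMFs plus a residue (sifting EMD).

    Parameters
    ----------
    signal
        1-d array, length >= 8.
    max_imfs
        Upper bound on extracted IMFs; bounds runtime.
    sd_threshold
        Cauchy stopping criterion: sifting of one IMF ends when
        ``sum((h_prev - h)^2) / sum(h_prev^2)`` drops below this.
    max_siftings
        Hard cap on sifting iterations per IMF.

    A constant (or monotonic, or extremum-poor) input yields zero IMFs with
    the input itself as residue — not an error.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("signal must be 1-d with length >= 8")
    if max_imfs < 1:
        raise ValueError("max_imfs must be >= 1")

    imfs: list[np.ndarray] = []
    sift_counts: list[int] = []
    residue = x.copy()

    while len(imfs) < max_imfs:
        maxima, minima = _local_extrema(residue)
        if len(maxima) + len(minima) < 3 or len(maxima) < 2 or len(minima) < 2:
            break
        if _is_monotonic(residue):
            break
        h = residue.copy()
        n_sift = 0
        for _ in range(max_siftings):
            mx, mn = _local_extrema(h)
            if len(mx) < 2 or len(mn) < 2:
                break
            upper = _envelope(h, mx)
            lower = _envelope(h, mn)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            n_sift += 1
            denom = float(np.sum(h * h))
            if denom == 0.0:
                h = h_new
                break
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            if sd < sd_threshold:
                break
        # an IMF is oscillatory by definition: any global DC offset left by
        # sifting (possible for extremum-poor components) belongs to the
        # residue, so transfer it there
        h = h - np.mean(h)
        imfs.append(h)
        sift_counts.append(n_sift)
        residue = residue - h

    # residue recomputed by subtraction keeps the reconstruction identity exact
    residue = x - np.sum(imfs, axis=0) if imfs else x.copy()
    return IMFDecomposition(
        source_length=len(x),
        imfs=imfs,
        residue=residue,
        sifting_iterations=sift_counts,
    )


def hilbert_analysis(component: np.ndarray, sampling_rate_hz: float) -> HilbertAnalysis:
    """Amplitude envelope and instantaneous frequency via the analytic signal.

    The envelope is the analytic-signal magnitude (non-negative everywhere).
    Instantaneous frequency is the central-difference derivative of the
    unwrapped phase (one-sided at the endpoints, so the output keeps full
    length), scaled to Hz and clipped to [0, Nyquist].
    """
    x = np.asarray(component, dtype=np.float64)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("component must be 1-d with length >= 8")
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    analytic = hilbert(x)
    envelope = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    inst_freq = np.gradient(phase) * sampling_rate_hz / (2.0 * np.pi)
    inst_freq = np.clip(inst_freq, 0.0, sampling_rate_hz / 2.0)
    return HilbertAnalysis(amplitude_envelope=envelope, instantaneous_frequency_hz=inst_freq)


def emd_features(
    signal: np.ndarray,
    sampling_rate_hz: float,
    n_imf_features: int = 3,
    max_imfs: int = 10,
    sd_threshold: float = 0.2,
) -> dict[str, float]:
    """Per-window EMD feature block: envelope / instantaneous-frequency
    moments of the first ``n_imf_features`` IMFs.

    Missing IMFs (signal too simple) contribute zeros so the feature schema
    stays fixed across windows.
    """
    dec = emd(signal, max_imfs=max_imfs, sd_threshold=sd_threshold)
    out: dict[str, float] = {}
    for i in range(n_imf_features):
        if i < dec.n_imfs:
            ha = hilbert_analysis(dec.imfs[i], sampling_rate_hz)
            env, freq = ha.amplitude_envelope, ha.instantaneous_frequency_hz
            out[f"imf{i + 1}_env_mean"] = float(np.mean(env))
            out[f"imf{i + 1}_env_std"] = float(np.std(env))
            out[f"imf{i + 1}_if_mean"] = float(np.mean(freq))
            out[f"imf{i + 1}_if_std"] = float(np.std(freq))
        else:
            out[f"imf{i + 1}_env_mean"] = 0.0
            out[f"imf{i + 1}_env_std"] = 0.0
            out[f"imf{i + 1}_if_mean"] = 0.0
            out[f"imf{i + 1}_if_std"] = 0.0
    return out
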