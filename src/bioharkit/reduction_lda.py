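"""Supervised dimensionality reduction by Fisher linear discriminant analysis.

Finds projection directions w maximizing the Fisher ratio
``Q(w) = (w^T S_b w) / (w^T S_w w)`` — between-class scatter over
within-class scatter — as eigenvectors of ``S_w^{-1} S_b`` in decreasing
eigenvalue order. ``S_w`` is shrunk as ``S_w + lambda * tr(S_w)/d * I`` so
the inverse exists even with more features than windows. At most C-1
informative directions exist (rank of S_b), so ``n_components`` is clamped
there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


@dataclass
class LDAProjection:
    """Fitted discriminant directions and audit matrices."""

    directions: np.ndarray  # d x n_components, unit-norm columns
    eigenvalues: np.ndarray  # non-increasing Fisher ratios
    class_means: dict[int, np.ndarray]
    global_mean: np.ndarray
    n_components: int
    scatter_within: np.ndarray
    scatter_between: np.ndarray
    kept_features: np.ndarray = field(default=None)  # indices into original columns
    input_dim: int = 0  # original feature count at fit time


def _scatter_matrices(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray], np.ndarray]:
    global_mean = X.mean(axis=0)
    classes = np.unique(y)
    d = X.shape[1]
    s_w = np.zeros((d, d))
    s_b = np.zeros((d, d))
    class_means: dict[int, np.ndarray] = {}
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        class_means[int(c)] = mu
        centered = Xc - mu
        s_w += centered.T @ centered
        diff = (mu - global_mean)[:, None]
        s_b += len(Xc) * (diff @ diff.T)
    return s_w, s_b, class_means, global_mean


def fit_lda(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | None = None,
    shrinkage: float = 1e-4,
) -> LDAProjection:
    """Fit Fisher LDA on a windows x features matrix.

    Constant (zero-variance) feature columns are dropped with a warning
    before fitting; ``transform`` reapplies the same column selection.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-d with one label per row")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    if np.any(counts < 2):
        small = classes[counts < 2].tolist()
        raise ValueError(f"every class needs >= 2 samples; offending: {small}")

    variances = X.var(axis=0)
    kept = np.where(variances > 0)[0]
    if len(kept) < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - len(kept)} zero-variance feature column(s)",
            stacklevel=2,
        )
    if len(kept) == 0:
        raise ValueError("all features are constant")
    Xk = X[:, kept]
    d = Xk.shape[1]

    max_comp = min(len(classes) - 1, d)
    if n_components is None:
        n_components = max_comp
    elif n_components > max_comp:
        warnings.warn(
            f"n_components clamped from {n_components} to {max_comp}", stacklevel=2
        )
        n_components = max_comp
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    s_w, s_b, class_means, global_mean = _scatter_matrices(Xk, y)
    s_w_reg = s_w + shrinkage * np.trace(s_w) / d * np.eye(d)
    # symmetric-definite generalized eigenproblem S_b v = lambda S_w v
    eigvals, eigvecs = scipy.linalg.eigh(s_b, s_w_reg)
    order = np.argsort(eigvals)[::-1][:n_components]
    directions = eigvecs[:, order]
    directions = directions / np.linalg.norm(directions, axis=0)
    return LDAProjection(
        directions=directions,
        eigenvalues=np.maximum(eigvals[order], 0.0),
        class_means=class_means,
        global_mean=global_mean,
        n_components=n_components,
        scatter_within=s_w,
        scatter_between=s_b,
        kept_features=kept,
        input_dim=X.shape[1],
    )


def transform(X: np.ndarray, projection: LDAProjection) -> np.ndarray:
    """Project (globally centered) data onto the fitted directions."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != projection.input_dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the fitted "
            f"projection (expected {projection.input_dim})"
        )
    X = X[:, projection.kept_features]
    return (X - projection.global_mean) @ projection.directions


def fisher_ratio(w: np.ndarray, s_b: np.ndarray, s_w: np.ndarray) -> float:
    """``Q(w) = (w^T S_b w) / (w^T S_w w)`` for one direction."""
    w = np.asarray(w, dtype=np.float64)
    denom = float(w @ s_w @ w)
    if denom <= 0:
        raise ValueError("within-class quadratic form must be positive")
    return float(w @ s_b @ w) / denom
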