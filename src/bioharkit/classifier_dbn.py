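"""Deep belief network classifier: stacked RBMs with greedy unsupervised
pretraining (one-step contrastive divergence) and supervised softmax
fine-tuning.

The first RBM has Gaussian visible units (inputs are real-valued,
standardized features), deeper RBMs are Bernoulli over the previous
layer's hidden activation probabilities. After pretraining, the stack plus
a softmax output layer is fine-tuned end to end by mini-batch gradient
descent on the cross-entropy, with early stopping on a no-improvement
patience window. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RBMLayer:
    """One restricted Boltzmann machine layer."""

    weights: np.ndarray  # visible x hidden
    visible_bias: np.ndarray
    hidden_bias: np.ndarray
    visible_type: str  # gaussian | bernoulli
    reconstruction_errors: list[float] = field(default_factory=list)


@dataclass
class DBNModel:
    """Pretrained + fine-tuned network with softmax output."""

    layers: list[RBMLayer]
    softmax_weights: np.ndarray  # last hidden x classes
    softmax_bias: np.ndarray
    class_labels: np.ndarray
    training_log: dict[str, list[float]] = field(default_factory=dict)
    seed: int = 0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def train_rbm(
    data: np.ndarray,
    n_hidden: int,
    epochs: int = 30,
    learning_rate: float = 0.05,
    batch_size: int = 32,
    seed: int = 0,
    visible_type: str = "gaussian",
) -> RBMLayer:
    """Train one RBM by one-step contrastive divergence (CD-1).

    Gaussian visible units assume unit-variance standardized data; the
    reconstruction mean is then linear in the hidden sample. Mean-squared
    reconstruction error is logged once per epoch.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or not np.all(np.isfinite(data)):
        raise ValueError("data must be a finite 2-d array")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if visible_type not in {"gaussian", "bernoulli"}:
        raise ValueError("visible_type must be 'gaussian' or 'bernoulli'")

    rng = np.random.default_rng(seed)
    n, d = data.shape
    W = rng.normal(0.0, 0.01, size=(d, n_hidden))
    vb = np.zeros(d)
    hb = np.zeros(n_hidden)
    errors: list[float] = []

    for _ in range(epochs):
        perm = rng.permutation(n)
        epoch_err = 0.0
        for start in range(0, n, batch_size):
            v0 = data[perm[start:start + batch_size]]
            h0_prob = _sigmoid(v0 @ W + hb)
            h0_sample = (rng.random(h0_prob.shape) < h0_prob).astype(np.float64)
            if visible_type == "gaussian":
                v1 = h0_sample @ W.T + vb
            else:
                v1 = _sigmoid(h0_sample @ W.T + vb)
            h1_prob = _sigmoid(v1 @ W + hb)
            m = len(v0)
            W += learning_rate * (v0.T @ h0_prob - v1.T @ h1_prob) / m
            vb += learning_rate * (v0 - v1).mean(axis=0)
            hb += learning_rate * (h0_prob - h1_prob).mean(axis=0)
            epoch_err += float(np.sum((v0 - v1) ** 2))
        errors.append(epoch_err / n)

    return RBMLayer(
        weights=W,
        visible_bias=vb,
        hidden_bias=hb,
        visible_type=visible_type,
        reconstruction_errors=errors,
    )


def _forward_hidden(X: np.ndarray, layers: list[RBMLayer]) -> np.ndarray:
    h = X
    for layer in layers:
        h = _sigmoid(h @ layer.weights + layer.hidden_bias)
    return h


def fit_dbn(
    X: np.ndarray,
    y: np.ndarray,
    architecture: tuple[int, ...] = (64, 32),
    pretrain_epochs: int = 30,
    finetune_epochs: int = 100,
    pretrain_lr: float = 0.05,
    finetune_lr: float = 0.05,
    batch_size: int = 32,
    seed: int = 0,
    patience: int = 10,
    momentum: float = 0.9,
) -> DBNModel:
    """Greedy layer-wise pretraining followed by supervised fine-tuning.

    Fine-tuning backpropagates cross-entropy through the sigmoid stack and
    softmax head with momentum SGD (sigmoid stacks under plain small-step
    SGD barely move — the classic vanishing-gradient regime); the
    full-training-set cross-entropy is logged after every epoch and used
    for early stopping (no improvement for ``patience`` epochs).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-d with one label per row")
    classes, inverse, counts = np.unique(y, return_inverse=True, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if np.any(counts < 2):
        raise ValueError(f"every class needs >= 2 samples; offending: {classes[counts < 2]}")

    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=len(architecture) + 2)

    # greedy pretraining
    layers: list[RBMLayer] = []
    inp = X
    for i, n_hidden in enumerate(architecture):
        layer = train_rbm(
            inp,
            n_hidden,
            epochs=pretrain_epochs,
            learning_rate=pretrain_lr,
            batch_size=batch_size,
            seed=int(sub_seeds[i]),
            visible_type="gaussian" if i == 0 else "bernoulli",
        )
        layers.append(layer)
        inp = _sigmoid(inp @ layer.weights + layer.hidden_bias)

    n_classes = len(classes)
    n, _ = X.shape
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), inverse] = 1.0

    head_rng = np.random.default_rng(int(sub_seeds[-2]))
    Ws = [layer.weights.copy() for layer in layers]
    bs = [layer.hidden_bias.copy() for layer in layers]
    W_out = head_rng.normal(0.0, 0.01, size=(architecture[-1], n_classes))
    b_out = np.zeros(n_classes)

    def forward(batch: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        acts = [batch]
        h = batch
        for W, b in zip(Ws, bs):
            h = _sigmoid(h @ W + b)
            acts.append(h)
        return acts, _softmax(h @ W_out + b_out)

    def full_cross_entropy() -> float:
        _, probs = forward(X)
        return float(-np.mean(np.log(probs[np.arange(n), inverse] + 1e-12)))

    ft_rng = np.random.default_rng(int(sub_seeds[-1]))
    log_ce: list[float] = [full_cross_entropy()]
    best_ce = log_ce[0]
    best_params = None
    stale = 0
    vel_W = [np.zeros_like(w) for w in Ws]
    vel_b = [np.zeros_like(b) for b in bs]
    vel_W_out = np.zeros_like(W_out)
    vel_b_out = np.zeros_like(b_out)
    for _ in range(finetune_epochs):
        perm = ft_rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            acts, probs = forward(X[idx])
            m = len(idx)
            delta = (probs - onehot[idx]) / m
            back = delta @ W_out.T
            vel_W_out = momentum * vel_W_out - finetune_lr * (acts[-1].T @ delta)
            vel_b_out = momentum * vel_b_out - finetune_lr * delta.sum(axis=0)
            W_out += vel_W_out
            b_out += vel_b_out
            for li in range(len(Ws) - 1, -1, -1):
                a = acts[li + 1]
                back = back * a * (1.0 - a)
                grad_W = acts[li].T @ back
                grad_b = back.sum(axis=0)
                back = back @ Ws[li].T
                vel_W[li] = momentum * vel_W[li] - finetune_lr * grad_W
                vel_b[li] = momentum * vel_b[li] - finetune_lr * grad_b
                Ws[li] += vel_W[li]
                bs[li] += vel_b[li]
        ce = full_cross_entropy()
        log_ce.append(ce)
        if ce < best_ce - 1e-9:
            best_ce = ce
            best_params = ([w.copy() for w in Ws], [b.copy() for b in bs], W_out.copy(), b_out.copy())
            stale = 0
        else:
            stale += 1
            # the stack often sits on an initial plateau before the loss
            # drops; only allow early stopping once real progress has begun
            if stale >= patience and best_ce < 0.95 * log_ce[0]:
                break
    if best_params is not None:
        Ws, bs, W_out, b_out = best_params

    tuned_layers = [
        RBMLayer(
            weights=Ws[i],
            visible_bias=layers[i].visible_bias,
            hidden_bias=bs[i],
            visible_type=layers[i].visible_type,
            reconstruction_errors=layers[i].reconstruction_errors,
        )
        for i in range(len(layers))
    ]
    return DBNModel(
        layers=tuned_layers,
        softmax_weights=W_out,
        softmax_bias=b_out,
        class_labels=classes,
        training_log={
            "pretrain_reconstruction": [e for l in layers for e in l.reconstruction_errors],
            "finetune_cross_entropy": log_ce,
        },
        seed=seed,
    )


def predict_proba(model: DBNModel, X: np.ndarray) -> np.ndarray:
    """Class-probability matrix (rows sum to 1) for new windows."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    n_classes = len(model.class_labels)
    if X.shape[0] == 0:
        return np.zeros((0, n_classes))
    if X.shape[1] != model.layers[0].weights.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the model "
            f"(expected {model.layers[0].weights.shape[0]})"
        )
    h = _forward_hidden(X, model.layers)
    return _softmax(h @ model.softmax_weights + model.softmax_bias)


def predict(model: DBNModel, X: np.ndarray) -> np.ndarray:
    """Predicted class labels (argmax of :func:`predict_proba`)."""
    probs = predict_proba(model, X)
    return model.class_labels[np.argmax(probs, axis=1)]
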