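"""Fully connected binary classifier: forward pass, cross-entropy loss,
analytic gradients, and the plain gradient-descent update θ ← θ − η∇L(θ).

The model is deliberately minimal — a small multilayer perceptron with a
logistic-sigmoid output trained by minibatch SGD on mean binary cross-entropy.
No momentum, weight decay, or adaptive learning rates: the local update is
exactly one gradient-descent step per minibatch.  Parameters θ = ⟨W, b⟩ are
held as explicit per-layer arrays so a federation server can average them
elementwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: probabilities are clipped to [EPS, 1−EPS] before taking logs
EPS = 1e-7


@dataclass(frozen=True)
class NetworkArchitecture:
    """Layer widths and activations of the classifier.

    Default backbone: input → 32 → 16 → 1, ReLU hidden units, sigmoid output.
    """

    input_width: int
    hidden: tuple[int, ...] = (32, 16)
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.input_width < 1 or any(h < 1 for h in self.hidden):
            raise ValueError("all layer widths must be >= 1")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def widths(self) -> tuple[int, ...]:
        return (self.input_width, *self.hidden, 1)


@dataclass
class NetworkParams:
    """Ordered per-layer weight matrices and bias vectors (θ = ⟨W, b⟩)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("weights and biases must pair per layer")
        for W, b in zip(self.weights, self.biases):
            if W.shape[1] != b.shape[0]:
                raise ValueError("bias width must match weight output width")

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            [W.copy() for W in self.weights], [b.copy() for b in self.biases]
        )

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        return sum(W.size for W in self.weights) + sum(b.size for b in self.biases)

    def flat(self) -> np.ndarray:
        return np.concatenate(
            [a.ravel() for a in (*self.weights, *self.biases)]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": [W.tolist() for W in self.weights],
                "biases": [b.tolist() for b in self.biases],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkParams":
        doc = json.loads(text)
        return cls(
            [np.asarray(W, dtype=float) for W in doc["weights"]],
            [np.asarray(b, dtype=float) for b in doc["biases"]],
        )


@dataclass(frozen=True)
class TrainConfig:
    """Local optimisation hyperparameters: learning rate η, epochs E, batch B."""

    eta: float = 0.001
    epochs: int = 5
    batch_size: int = 10

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("learning rate must be nonnegative")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch size >= 1")

    def iterations(self, n_train: int) -> int:
        """Minibatch iterations per epoch, I = ceil(n/B)."""
        return -(-n_train // self.batch_size)


def init_params(arch: NetworkArchitecture, seed: int) -> NetworkParams:
    """Seeded init: W ~ N(0, 1/fan_in) per layer, biases zero."""
    rng = np.random.default_rng(seed)
    widths = arch.widths
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        weights.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in), (fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NetworkParams(weights, biases)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _hidden_act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(z, 0.0) if kind == "relu" else np.tanh(z)


def _forward_cached(
    params: NetworkParams, X: np.ndarray, activation: str
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Probabilities plus per-layer activations (input first) for backprop."""
    activations = [X]
    a = X
    last = params.n_layers - 1
    for i, (W, b) in enumerate(zip(params.weights, params.biases)):
        z = a @ W + b
        a = _sigmoid(z) if i == last else _hidden_act(z, activation)
        activations.append(a)
    return a[:, 0], activations


def forward(
    params: NetworkParams, X: np.ndarray, activation: str = "relu"
) -> np.ndarray:
    """Predicted severe-class probabilities for a batch (or single vector).

    Output is clipped into the open interval (0, 1).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.weights[0].shape[0]:
        raise ValueError(
            f"feature width {X.shape[1]} does not match input width "
            f"{params.weights[0].shape[0]}"
        )
    p, _ = _forward_cached(params, X, activation)
    return np.clip(p, EPS, 1.0 - EPS)


def bce_loss(labels: np.ndarray, probs: np.ndarray) -> float:
    """Mean binary cross-entropy, −mean[y·log p + (1−y)·log(1−p)]."""
    y = np.asarray(labels, dtype=float)
    p = np.clip(np.asarray(probs, dtype=float), EPS, 1.0 - EPS)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def _loss_and_gradient(
    params: NetworkParams, X: np.ndarray, y: np.ndarray, activation: str
) -> tuple[float, NetworkParams]:
    """Mean BCE loss and its exact gradient from a single forward pass."""
    n = X.shape[0]
    p, acts = _forward_cached(params, X, activation)
    loss = bce_loss(y, p)
    delta = ((p - y) / n)[:, None]  # (n, 1) gradient at the output pre-activation

    grad_W: list[np.ndarray] = [None] * params.n_layers  # type: ignore[list-item]
    grad_b: list[np.ndarray] = [None] * params.n_layers  # type: ignore[list-item]
    for i in range(params.n_layers - 1, -1, -1):
        a_prev = acts[i]
        grad_W[i] = a_prev.T @ delta
        grad_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = delta @ params.weights[i].T
            if activation == "relu":
                delta = delta * (acts[i] > 0)
            else:
                delta = delta * (1.0 - acts[i] ** 2)
    return loss, NetworkParams(grad_W, grad_b)


def gradient(
    params: NetworkParams,
    X: np.ndarray,
    y: np.ndarray,
    activation: str = "relu",
) -> NetworkParams:
    """Exact analytic gradient of the mean BCE loss, averaged over the batch.

    Uses the standard cancellation at the sigmoid output: ∂L/∂z_out = (p − y)/N.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise ValueError("empty batch")
    return _loss_and_gradient(params, X, y, activation)[1]


def sgd_step(params: NetworkParams, grad: NetworkParams, eta: float) -> NetworkParams:
    """One plain gradient-descent update, elementwise θ − η·∇L."""
    return NetworkParams(
        [W - eta * G for W, G in zip(params.weights, grad.weights)],
        [b - eta * g for b, g in zip(params.biases, grad.biases)],
    )


def run_epochs(
    params: NetworkParams,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
    epochs: int | None = None,
    activation: str = "relu",
) -> tuple[NetworkParams, list[float]]:
    """Minibatch SGD for a number of epochs; returns (params, per-epoch loss).

    One seeded shuffle per epoch; the last short batch is kept.  The reported
    loss per epoch is the mean of the pre-update minibatch losses.
    """
    n = len(y)
    if n == 0:
        raise ValueError("empty training set")
    epochs = cfg.epochs if epochs is None else epochs
    losses: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grad = _loss_and_gradient(params, X[idx], y[idx], activation)
            batch_losses.append(loss)
            params = sgd_step(params, grad, cfg.eta)
        losses.append(float(np.mean(batch_losses)))
    return params, losses
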