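"""Nonparametric regression of treatment on the fitted indices.

Two interchangeable scorers estimate the integrated propensity score
``E[A | S]`` on the index matrix ``S``:

* :func:`nw_mips` — multivariate Nadaraya-Watson regression with a product
  Gaussian kernel and a diagonal bandwidth (Scott-type rule by default).
  Simple and fast at small index dimension, but it degrades as candidate
  models are added (curse of dimensionality).
* :func:`train_ann` / :func:`predict_mips` — a small feed-forward network
  (d -> 4 -> 4 -> 1, tanh hidden units, sigmoid output) trained by
  full-batch gradient descent with momentum on the summed squared error.
  The sigmoid output keeps every estimated probability strictly inside
  (0, 1), and the architecture scales gracefully in the number of indices.

Training is deterministic given the seed: weights start uniform on
``(-init_scale, init_scale)`` and there is no stochastic batching, so two
runs with the same configuration produce bit-identical weight trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .candidates import IndexMatrix

__all__ = [
    "KernelConfig",
    "ANNConfig",
    "ANNModel",
    "PropensityVector",
    "scott_bandwidth",
    "nw_mips",
    "train_ann",
    "predict_mips",
]


@dataclass
class KernelConfig:
    """Bandwidth settings for the product-Gaussian kernel scorer.

    ``bandwidth_rule='scott'`` uses ``h_j = undersmooth * sd_j * n^(-1/(d+4))``;
    ``'manual'`` takes ``bandwidths`` as given. ``leave_one_out`` excludes the
    own observation from the kernel sums (the default keeps it, matching the
    full-sum definition of the estimator).
    """

    bandwidth_rule: str = "scott"
    bandwidths: np.ndarray | None = None
    undersmooth: float = 1.0
    leave_one_out: bool = False

    def __post_init__(self) -> None:
        if self.bandwidth_rule not in ("scott", "manual"):
            raise ValueError("bandwidth_rule must be 'scott' or 'manual'")
        if self.undersmooth <= 0:
            raise ValueError("undersmooth factor must be positive")
        if self.bandwidth_rule == "manual":
            if self.bandwidths is None:
                raise ValueError("manual rule requires explicit bandwidths")
            self.bandwidths = np.asarray(self.bandwidths, dtype=float)
            if np.any(self.bandwidths <= 0) or not np.all(np.isfinite(self.bandwidths)):
                raise ValueError("bandwidths must be finite and positive")


@dataclass
class ANNConfig:
    """Hyperparameters of the propensity network.

    Defaults follow the reference configuration: two hidden layers of four
    tanh units, sigmoid output, learning rate 0.001, momentum 0.5, seeded
    symmetric-uniform initialization. ``loss='sse'`` is the summed squared
    error (the LMS criterion classic trainers minimize); ``'mse'`` divides by
    n and ``'bce'`` is binary cross-entropy, both available for sensitivity
    analysis. Epochs default to 2000 full-batch passes — enough to learn the
    treatment-index relationship at the sample sizes this package targets
    while stopping short of the memorization regime in which individual
    subjects' scores are driven to the boundary (see the methods note).
    """

    hidden_units: tuple[int, ...] = (4, 4)
    learning_rate: float = 0.001
    momentum: float = 0.5
    epochs: int = 2000
    loss: str = "sse"
    init_scale: float = 0.3
    seed: int = 0
    output_activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if not (0 < self.learning_rate < 1):
            raise ValueError("learning_rate must be in (0, 1)")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("sse", "mse", "bce"):
            raise ValueError("loss must be 'sse', 'mse' or 'bce'")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be positive")
        if self.output_activation not in ("sigmoid", "linear"):
            raise ValueError("output_activation must be 'sigmoid' or 'linear'")
        self.hidden_units = tuple(int(h) for h in self.hidden_units)
        if any(h < 1 for h in self.hidden_units):
            raise ValueError("hidden layers need at least one unit")


@dataclass
class PropensityVector:
    """Estimated per-subject treatment probabilities plus range diagnostics."""

    scores: np.ndarray
    method: str  # "kernel" | "ann" | "parametric"
    out_of_range: int = 0
    clipped: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    def summary(self) -> dict:
        return {
            "method": self.method,
            "min": float(self.scores.min()),
            "max": float(self.scores.max()),
            "out_of_range": int(self.out_of_range),
            "clipped": bool(self.clipped),
        }


def _index_array(s) -> np.ndarray:
    if isinstance(s, IndexMatrix):
        return s.s
    return np.atleast_2d(np.asarray(s, dtype=float))


def scott_bandwidth(s, undersmooth: float = 1.0) -> np.ndarray:
    """Scott-type diagonal bandwidth ``h_j = undersmooth * sd_j * n^(-1/(d+4))``."""
    arr = _index_array(s)
    n, d = arr.shape
    if n < 2:
        raise ValueError("bandwidth selection needs at least two rows")
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = np.flatnonzero(sd <= 0).tolist()
        raise ValueError(f"zero-variance index column(s) {bad}; cannot set bandwidth")
    return undersmooth * sd * n ** (-1.0 / (d + 4))


def nw_mips(s, a: np.ndarray, cfg: KernelConfig | None = None) -> PropensityVector:
    """Nadaraya-Watson estimate of ``E[A | S]`` with a product Gaussian kernel.

    ``score_i = sum_j K_H(S_j - S_i) A_j / sum_j K_H(S_j - S_i)``, summing
    over all j including j = i unless ``cfg.leave_one_out``. With a strictly
    positive kernel the scores are convex combinations of the treatment
    indicators and therefore lie in [0, 1]; the ``out_of_range`` counter
    records any numerical excursions.
    """
    cfg = KernelConfig() if cfg is None else cfg
    arr = _index_array(s)
    a = np.asarray(a, dtype=float)
    n, d = arr.shape
    if n < 2:
        raise ValueError("kernel scoring needs at least two rows")
    if a.shape[0] != n:
        raise ValueError("index matrix and treatment vector lengths differ")
    if cfg.bandwidth_rule == "manual":
        h = cfg.bandwidths
        if len(h) != d:
            raise ValueError(f"need {d} bandwidths, got {len(h)}")
    else:
        h = scott_bandwidth(arr, cfg.undersmooth)
    u = arr / h
    sq = np.einsum("ij,ij->i", u, u)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (u @ u.T), 0.0)
    k = np.exp(-0.5 * d2)
    if cfg.leave_one_out:
        np.fill_diagonal(k, 0.0)
    denom = k.sum(axis=1)
    if np.any(denom == 0):
        rows = np.flatnonzero(denom == 0).tolist()
        raise ValueError(
            f"kernel weight sum underflowed to zero at row(s) {rows}; "
            "the bandwidth is too small for this sample"
        )
    scores = (k @ a) / denom
    # convex combination of 0/1 values: excursions within fp roundoff of the
    # bounds are arithmetic noise, not genuine out-of-range scores
    eps = 1e-12
    scores[(scores < 0) & (scores > -eps)] = 0.0
    scores[(scores > 1) & (scores < 1 + eps)] = 1.0
    oor = int(np.sum((scores < 0) | (scores > 1)))
    return PropensityVector(scores=scores, method="kernel", out_of_range=oor)


class ANNModel:
    """A trained feed-forward propensity network.

    Attributes
    ----------
    weights, biases : lists of ndarrays, one per layer.
    loss_trace : per-epoch value of the training criterion.
    config : the :class:`ANNConfig` used for training.
    """

    def __init__(self, weights, biases, config: ANNConfig, loss_trace: np.ndarray):
        self.weights = weights
        self.biases = biases
        self.config = config
        self.loss_trace = loss_trace

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def forward(self, s: np.ndarray) -> np.ndarray:
        h = np.atleast_2d(np.asarray(s, dtype=float))
        if h.shape[1] != self.weights[0].shape[0]:
            raise ValueError(
                f"input has {h.shape[1]} columns; network expects "
                f"{self.weights[0].shape[0]}"
            )
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.tanh(h @ w + b)
        z = h @ self.weights[-1] + self.biases[-1]
        if self.config.output_activation == "sigmoid":
            out = 1.0 / (1.0 + np.exp(-z))
        else:
            out = z
        return out.ravel()


def _init_net(d: int, cfg: ANNConfig):
    rng = np.random.default_rng(cfg.seed)
    sizes = [d, *cfg.hidden_units, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.uniform(-cfg.init_scale, cfg.init_scale, (fan_in, fan_out)))
        biases.append(rng.uniform(-cfg.init_scale, cfg.init_scale, fan_out))
    return weights, biases


def train_ann(s, a: np.ndarray, cfg: ANNConfig | None = None) -> ANNModel:
    """Train the propensity network by backpropagation.

    Full-batch gradient descent with momentum; the run is a pure function of
    the data and the configuration (identical seeds give identical weight
    trajectories). Raises if the loss goes non-finite, which signals an
    exploding update — reduce the learning rate.
    """
    cfg = ANNConfig() if cfg is None else cfg
    arr = _index_array(s)
    target = np.asarray(a, dtype=float).reshape(-1, 1)
    n, d = arr.shape
    if n != target.shape[0]:
        raise ValueError("index matrix and target lengths differ")
    if np.any(~np.isfinite(arr)) or np.any(~np.isfinite(target)):
        raise ValueError("training data contain non-finite values")

    weights, biases = _init_net(d, cfg)
    vel_w = [np.zeros_like(w) for w in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    sigmoid_out = cfg.output_activation == "sigmoid"
    lr, mom = cfg.learning_rate, cfg.momentum
    loss_trace = np.empty(cfg.epochs)

    for epoch in range(cfg.epochs):
        # forward
        acts = [arr]
        h = arr
        for w, b in zip(weights[:-1], biases[:-1]):
            h = np.tanh(h @ w + b)
            acts.append(h)
        z = h @ weights[-1] + biases[-1]
        out = 1.0 / (1.0 + np.exp(-z)) if sigmoid_out else z
        err = out - target

        if cfg.loss == "bce":
            eps = 1e-12
            loss = -np.sum(
                target * np.log(out + eps) + (1 - target) * np.log(1 - out + eps)
            )
            delta = err  # sigmoid + cross-entropy cancellation
        else:
            loss = float(np.sum(err**2))
            scale = 2.0 if cfg.loss == "sse" else 2.0 / n
            if cfg.loss == "mse":
                loss /= n
            delta = scale * err * (out * (1.0 - out) if sigmoid_out else 1.0)
        loss_trace[epoch] = loss
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training loss became non-finite at epoch {epoch}; "
                "reduce the learning rate"
            )

        # backward
        grads_w = [None] * len(weights)
        grads_b = [None] * len(biases)
        for layer in range(len(weights) - 1, -1, -1):
            grads_w[layer] = acts[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ weights[layer].T) * (1.0 - acts[layer] ** 2)
        for k in range(len(weights)):
            vel_w[k] = mom * vel_w[k] - lr * grads_w[k]
            vel_b[k] = mom * vel_b[k] - lr * grads_b[k]
            weights[k] += vel_w[k]
            biases[k] += vel_b[k]

    return ANNModel(weights, biases, cfg, loss_trace)


def predict_mips(model: ANNModel, s_new) -> PropensityVector:
    """Propensity scores for (possibly new) index rows.

    If ``s_new`` is an :class:`~mips.candidates.IndexMatrix` its stored
    standardization is assumed already applied. Sigmoid output guarantees
    scores strictly inside (0, 1); a guard clip at 1e-12 protects against
    floating-point saturation of the exponential.
    """
    arr = _index_array(s_new)
    raw = model.forward(arr)
    if model.config.output_activation == "sigmoid":
        raw = np.clip(raw, 1e-12, 1.0 - 1e-12)
        return PropensityVector(scores=raw, method="ann", out_of_range=0)
    return PropensityVector(scores=raw, method="ann", out_of_range=0)
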