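"""Single-hidden-layer feed-forward network trained by regularized
back-propagation.

The forward map for an individual with covariate row x is

    z_t = f(a_t + w1[t] . x)        t = 1..s   (hidden layer)
    yhat = g(b + w2 . z)                        (output neuron)

with f either tanh or the identity and g the identity. Training minimizes

    aMSE(yhat, y) + lambda * (||w1||^2 + ||w2||^2)

by full-batch gradient descent with momentum, where aMSE is the plain mean
squared error on the (normalized) phenotype scale and the decay term excludes
biases. Training stops at an iteration cap (default 1000) or when the
training aMSE falls to the tolerance (default 1e-3), whichever comes first;
when both trigger on the same iteration the threshold wins. Weights start at
i.i.d. uniform values in a small symmetric interval (default [-0.1, 0.1]), so
different seeds give the different initializations a repeated cross-validation
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import TrainingDivergedError, ValidationError

__all__ = [
    "Architecture",
    "NetworkWeights",
    "TrainingConfig",
    "TrainingTrace",
    "init_weights",
    "forward",
    "predict",
    "amse",
    "backprop_gradient",
    "train",
    "select_learning_rate",
]

ACTIVATIONS = ("tanh", "identity")


@dataclass(frozen=True)
class Architecture:
    n_inputs: int
    n_hidden: int
    hidden_activation: str = "tanh"
    output_activation: str = "identity"

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_hidden < 1:
            raise ValidationError("n_inputs and n_hidden must be >= 1")
        if self.hidden_activation not in ACTIVATIONS:
            raise ValidationError(f"hidden_activation must be one of {ACTIVATIONS}")
        if self.output_activation != "identity":
            raise ValidationError("only identity output activation is supported")


@dataclass
class NetworkWeights:
    """w1: (s, p) input->hidden; a: (s,) hidden biases; w2: (s,) hidden->output; b: output bias."""

    w1: np.ndarray
    a: np.ndarray
    w2: np.ndarray
    b: float

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        self.b = float(self.b)
        s, _ = self.w1.shape
        if self.a.shape != (s,) or self.w2.shape != (s,):
            raise ValidationError("bias/output weight shapes inconsistent with w1")

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.w1.copy(), self.a.copy(), self.w2.copy(), self.b)

    def is_finite(self) -> bool:
        return bool(
            np.isfinite(self.w1).all()
            and np.isfinite(self.a).all()
            and np.isfinite(self.w2).all()
            and np.isfinite(self.b)
        )


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.01
    max_iterations: int = 1000
    amse_tolerance: float = 1e-3
    init_range: tuple[float, float] = (-0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise ValidationError("momentum must lie in [0,1)")
        if self.weight_decay < 0:
            raise ValidationError("weight_decay must be nonnegative")
        if self.amse_tolerance <= 0:
            raise ValidationError("amse_tolerance must be positive")
        lo, hi = self.init_range
        if not (lo < hi):
            raise ValidationError("init_range must be a nonempty interval")


@dataclass
class TrainingTrace:
    amse_per_iteration: list[float] = field(default_factory=list)
    stop_reason: str = "max_iterations"  # or "amse_threshold"
    final_weights: NetworkWeights = None  # type: ignore[assignment]


def init_weights(arch: Architecture, config: TrainingConfig) -> NetworkWeights:
    """All weights and biases i.i.d. uniform on ``init_range``; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.init_range
    s, p = arch.n_hidden, arch.n_inputs
    return NetworkWeights(
        w1=rng.uniform(lo, hi, size=(s, p)),
        a=rng.uniform(lo, hi, size=s),
        w2=rng.uniform(lo, hi, size=s),
        b=float(rng.uniform(lo, hi)),
    )


def _hidden(weights: NetworkWeights, arch: Architecture, X: np.ndarray):
    """Pre-activations H and activations Z for a batch (rows = individuals)."""
    H = X @ weights.w1.T + weights.a
    Z = np.tanh(H) if arch.hidden_activation == "tanh" else H
    return H, Z


def forward(weights: NetworkWeights, arch: Architecture, x: np.ndarray) -> float:
    """Network output for a single covariate vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (arch.n_inputs,):
        raise ValidationError(f"expected covariate vector of length {arch.n_inputs}, got {x.shape}")
    _, z = _hidden(weights, arch, x[None, :])
    return float(z[0] @ weights.w2 + weights.b)


def predict(weights: NetworkWeights, arch: Architecture, X: np.ndarray) -> np.ndarray:
    """Row-wise forward pass; no refitting."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != arch.n_inputs:
        raise ValidationError(f"expected (n, {arch.n_inputs}) covariate matrix, got {X.shape}")
    _, Z = _hidden(weights, arch, X)
    return Z @ weights.w2 + weights.b


def amse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Averaged mean squared error between predicted and observed values."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1 or len(predicted) < 1:
        raise ValidationError("predicted and observed must be equal-length 1-D vectors")
    return float(np.mean((predicted - observed) ** 2))


def backprop_gradient(
    weights: NetworkWeights,
    arch: Architecture,
    X_batch: np.ndarray,
    y_batch: np.ndarray,
    weight_decay: float = 0.0,
) -> NetworkWeights:
    """Exact gradient of aMSE + weight_decay * (||w1||^2 + ||w2||^2).

    Biases are excluded from the decay term. Returned in weight shape.
    """
    X = np.asarray(X_batch, dtype=float)
    y = np.asarray(y_batch, dtype=float)
    if X.ndim != 2 or X.shape[1] != arch.n_inputs:
        raise ValidationError(f"expected (n, {arch.n_inputs}) batch, got {X.shape}")
    if y.shape != (X.shape[0],) or X.shape[0] < 1:
        raise ValidationError("batch covariates and responses are inconsistent or empty")
    n = X.shape[0]
    H, Z = _hidden(weights, arch, X)
    resid = Z @ weights.w2 + weights.b - y
    d_out = 2.0 * resid / n  # d aMSE / d yhat
    g_b = float(d_out.sum())
    g_w2 = Z.T @ d_out + 2.0 * weight_decay * weights.w2
    dZ = np.outer(d_out, weights.w2)
    dH = dZ * (1.0 - Z**2) if arch.hidden_activation == "tanh" else dZ
    g_a = dH.sum(axis=0)
    g_w1 = dH.T @ X + 2.0 * weight_decay * weights.w1
    return NetworkWeights(w1=g_w1, a=g_a, w2=g_w2, b=g_b)


def train(
    arch: Architecture,
    config: TrainingConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    initial_weights: NetworkWeights | None = None,
) -> TrainingTrace:
    """Full-batch gradient descent with momentum on the regularized objective.

    The trace records training aMSE after every update. Raises
    :class:`TrainingDivergedError` when the objective becomes non-finite.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if X.shape[0] < 1:
        raise ValidationError("training set is empty")
    w = (initial_weights or init_weights(arch, config)).copy()
    vel = NetworkWeights(
        w1=np.zeros_like(w.w1), a=np.zeros_like(w.a), w2=np.zeros_like(w.w2), b=0.0
    )
    trace = TrainingTrace(final_weights=w)
    lr, mom = config.learning_rate, config.momentum
    for it in range(config.max_iterations):
        g = backprop_gradient(w, arch, X, y, config.weight_decay)
        vel.w1 = mom * vel.w1 - lr * g.w1
        vel.a = mom * vel.a - lr * g.a
        vel.w2 = mom * vel.w2 - lr * g.w2
        vel.b = mom * vel.b - lr * g.b
        w.w1 += vel.w1
        w.a += vel.a
        w.w2 += vel.w2
        w.b = w.b + vel.b
        with np.errstate(over="ignore", invalid="ignore"):
            err = amse(predict(w, arch, X), y)
        if not (np.isfinite(err) and w.is_finite()):
            raise TrainingDivergedError(it + 1)
        trace.amse_per_iteration.append(err)
        if err <= config.amse_tolerance:
            trace.stop_reason = "amse_threshold"
            break
    else:
        trace.stop_reason = "max_iterations"
    trace.final_weights = w
    return trace


def select_learning_rate(
    arch: Architecture,
    config: TrainingConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    candidates: tuple[float, ...] = (
        0.3, 0.1, 0.05, 0.03, 0.02, 0.015, 0.01, 0.007, 0.005, 0.003, 0.002, 0.001
    ),
    probe_iterations: int | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> float:
    """Pick a learning rate by probe runs, mirroring the usual pre-processing
    step of tuning the optimizer before the production runs.

    Each candidate trains from the same initialization for the full training
    budget (or ``probe_iterations`` updates if given). Candidates that
    diverge, or whose training error ends the probe climbing away from its
    best value (slow momentum-driven oscillation), are discarded. Among the
    survivors the winner has the lowest final training aMSE, or — when a
    validation batch is supplied — the lowest validation aMSE, which guards
    against rates that merely interpolate the training batch. Ties go to the
    smaller rate. Deterministic given ``config.seed``.
    """
    best_lr, best_err = None, np.inf
    for lr in sorted(candidates, reverse=True):
        probe = replace(config, learning_rate=lr,
                        max_iterations=probe_iterations or config.max_iterations)
        try:
            tr = train(arch, probe, X_train, y_train)
        except TrainingDivergedError:
            continue
        if not tr.amse_per_iteration:
            continue
        err = tr.amse_per_iteration[-1]
        if err > 1.2 * min(tr.amse_per_iteration):
            continue  # oscillating upward: heading for divergence
        if X_val is not None:
            err = amse(predict(tr.final_weights, arch, X_val), y_val)
        if err <= best_err:
            best_lr, best_err = lr, err
    if best_lr is None:
        raise TrainingDivergedError(0)
    return best_lr
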