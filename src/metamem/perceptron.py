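"""A small feed-forward classifier with bipolar-logistic units, trained from scratch.

Architecture: p input units (z-scored measures), one hidden layer of h
units (default 2), one output unit.  Every unit applies the bipolar
logistic squashing function ``2 / (1 + exp(-x)) - 1``, which maps the
weighted input plus bias to (-1, 1); algebraically this is ``tanh(x/2)``,
which is how it is computed for numerical stability.

The network is trained to emit -1 for younger adults and +1 for older
adults by full-batch gradient descent on the sum of squared errors
(iterative error correction).  Because the targets are the asymptotes of
the activation, training stops on an error-change convergence criterion
rather than on reaching the targets exactly.  The trained network's
hidden-unit activations are the low-dimensional representation that the
clustering stage probes for participant subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from metamem.datamodel import FeatureMatrix

__all__ = [
    "NetworkParams",
    "TrainingConfig",
    "TrainingHistory",
    "activation",
    "init_network",
    "forward",
    "forward_batch",
    "train",
    "classify",
    "predict_targets",
    "hidden_activations",
    "sum_squared_error",
]


def activation(x):
    """Bipolar logistic: ``2 / (1 + e^-x) - 1``, computed as ``tanh(x / 2)``.

    Strictly increasing, odd, with range (-1, 1).
    """
    return np.tanh(np.asarray(x, dtype=float) / 2.0)


def _activation_deriv_from_value(a):
    # d/dx tanh(x/2) = (1 - tanh(x/2)^2) / 2, expressed via the activation value
    return (1.0 - a * a) / 2.0


@dataclass(frozen=True)
class NetworkParams:
    """Weights and biases of the p -> h -> 1 network."""

    input_to_hidden_weights: np.ndarray  # h x p
    hidden_biases: np.ndarray            # h
    hidden_to_output_weights: np.ndarray # h
    output_bias: float

    def __post_init__(self) -> None:
        w1 = np.asarray(self.input_to_hidden_weights, dtype=float)
        b1 = np.asarray(self.hidden_biases, dtype=float)
        w2 = np.asarray(self.hidden_to_output_weights, dtype=float)
        object.__setattr__(self, "input_to_hidden_weights", w1)
        object.__setattr__(self, "hidden_biases", b1)
        object.__setattr__(self, "hidden_to_output_weights", w2)
        if w1.ndim != 2:
            raise ValueError("input_to_hidden_weights must be h x p")
        h = w1.shape[0]
        if h < 1 or b1.shape != (h,) or w2.shape != (h,):
            raise ValueError("inconsistent network dimensions")
        if not (
            np.all(np.isfinite(w1))
            and np.all(np.isfinite(b1))
            and np.all(np.isfinite(w2))
            and np.isfinite(self.output_bias)
        ):
            raise ValueError("network parameters must be finite")

    @property
    def p(self) -> int:
        return self.input_to_hidden_weights.shape[1]

    @property
    def h(self) -> int:
        return self.input_to_hidden_weights.shape[0]

    def to_dict(self) -> dict:
        return {
            "p": self.p,
            "h": self.h,
            "input_to_hidden_weights": self.input_to_hidden_weights.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "hidden_to_output_weights": self.hidden_to_output_weights.tolist(),
            "output_bias": float(self.output_bias),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        return cls(
            input_to_hidden_weights=np.asarray(d["input_to_hidden_weights"], dtype=float),
            hidden_biases=np.asarray(d["hidden_biases"], dtype=float),
            hidden_to_output_weights=np.asarray(d["hidden_to_output_weights"], dtype=float),
            output_bias=float(d["output_bias"]),
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyperparameters.

    ``init_range`` is the half-width of the uniform initialization
    interval for every weight and bias.  ``learning_rate`` multiplies the
    *mean* (per-participant) gradient of the summed squared error, so its
    scale does not depend on cohort size.  Training stops when the total
    squared error changes by less than ``convergence_tol`` between
    epochs, or at ``max_epochs``.
    """

    seed: int = 0
    init_range: float = 0.005
    learning_rate: float = 0.05
    max_epochs: int = 20_000
    convergence_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.init_range <= 0:
            raise ValueError("init_range must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be at least 1")


@dataclass(frozen=True)
class TrainingHistory:
    """Per-epoch total squared error plus the stopping outcome."""

    errors: np.ndarray = field(default_factory=lambda: np.empty(0))
    final_epoch: int = 0
    converged: bool = False


def init_network(p: int, h: int, config: TrainingConfig) -> NetworkParams:
    """Draw every weight and bias uniformly from [-init_range, init_range).

    Reproducible under ``config.seed``.
    """
    if p < 1 or h < 1:
        raise ValueError("p and h must be at least 1")
    rng = np.random.default_rng(config.seed)
    r = config.init_range
    return NetworkParams(
        input_to_hidden_weights=rng.uniform(-r, r, size=(h, p)),
        hidden_biases=rng.uniform(-r, r, size=h),
        hidden_to_output_weights=rng.uniform(-r, r, size=h),
        output_bias=float(rng.uniform(-r, r)),
    )


def _as_matrix(features, require_zscored: bool) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        if require_zscored and features.scale != "zscored":
            raise ValueError("training requires a z-scored feature matrix")
        return features.values
    return np.asarray(features, dtype=float)


def forward(params: NetworkParams, x) -> tuple[np.ndarray, float]:
    """One input vector -> (hidden activations, output activation)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.p,):
        raise ValueError(f"input length {x.shape} does not match p = {params.p}")
    hidden = activation(params.input_to_hidden_weights @ x + params.hidden_biases)
    output = activation(params.hidden_to_output_weights @ hidden + params.output_bias)
    return hidden, float(output)


def forward_batch(params: NetworkParams, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All rows at once -> (n x h hidden activations, n outputs)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.p:
        raise ValueError(f"feature width {X.shape} does not match p = {params.p}")
    hidden = activation(X @ params.input_to_hidden_weights.T + params.hidden_biases)
    output = activation(hidden @ params.hidden_to_output_weights + params.output_bias)
    return hidden, output


def sum_squared_error(params: NetworkParams, X, targets) -> float:
    """Total squared error Sum (target - output)^2 over the rows of X."""
    _, output = forward_batch(params, _as_matrix(X, require_zscored=False))
    return float(np.sum((np.asarray(targets, dtype=float) - output) ** 2))


def gradients(
    params: NetworkParams, X: np.ndarray, targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Analytic gradient of the total squared error w.r.t. every parameter.

    Returns (dW1, db1, dw2, db2) in the same shapes as the parameters.
    Exposed separately so the finite-difference check in the test suite
    can exercise it directly.
    """
    hidden, output = forward_batch(params, X)
    # dE/d(pre-activation of output): -(t - y) * (1 - y^2)
    delta2 = -(targets - output) * (1.0 - output * output)
    dw2 = hidden.T @ delta2
    db2 = float(np.sum(delta2))
    delta1 = (delta2[:, None] * params.hidden_to_output_weights[None, :]) * (
        _activation_deriv_from_value(hidden)
    )
    dW1 = delta1.T @ X
    db1 = delta1.sum(axis=0)
    return dW1, db1, dw2, db2


def train(
    features,
    targets,
    config: TrainingConfig | None = None,
    params: NetworkParams | None = None,
    h: int = 2,
) -> tuple[NetworkParams, TrainingHistory]:
    """Fit the network by full-batch gradient descent on the squared error.

    ``features`` is a z-scored :class:`FeatureMatrix` (or a plain array
    assumed standardized); ``targets`` the +/-1 age coding.  A fresh
    network of ``h`` hidden units is initialized from ``config.seed``
    unless ``params`` is supplied.  Raises if the error becomes
    non-finite, reporting the epoch.
    """
    if config is None:
        config = TrainingConfig()
    X = _as_matrix(features, require_zscored=True)
    T = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if T.shape != (n,):
        raise ValueError(f"{n} rows but {T.shape} targets")
    if n == 0:
        raise ValueError("cannot train on an empty cohort")
    if params is None:
        params = init_network(X.shape[1], h, config)
    elif params.p != X.shape[1]:
        raise ValueError("params width does not match features")

    W1 = params.input_to_hidden_weights.copy()
    b1 = params.hidden_biases.copy()
    w2 = params.hidden_to_output_weights.copy()
    b2 = float(params.output_bias)
    lr = config.learning_rate / n  # learning rate applies to the mean gradient

    errors = np.empty(config.max_epochs)
    prev_error = np.inf
    converged = False
    epoch = 0
    for epoch in range(config.max_epochs):
        hidden = np.tanh((X @ W1.T + b1) / 2.0)
        output = np.tanh((hidden @ w2 + b2) / 2.0)
        residual = T - output
        error = float(residual @ residual)
        if not np.isfinite(error):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        errors[epoch] = error
        if abs(prev_error - error) < config.convergence_tol:
            converged = True
            break
        prev_error = error

        delta2 = -residual * (1.0 - output * output)
        dw2 = hidden.T @ delta2
        db2 = float(np.sum(delta2))
        delta1 = (delta2[:, None] * w2[None, :]) * ((1.0 - hidden * hidden) / 2.0)
        W1 -= lr * (delta1.T @ X)
        b1 -= lr * delta1.sum(axis=0)
        w2 -= lr * dw2
        b2 -= lr * db2

    fitted = NetworkParams(
        input_to_hidden_weights=W1,
        hidden_biases=b1,
        hidden_to_output_weights=w2,
        output_bias=b2,
    )
    history = TrainingHistory(
        errors=errors[: epoch + 1].copy(), final_epoch=epoch, converged=converged
    )
    return fitted, history


def classify(params: NetworkParams, x) -> str:
    """Label one input: "old" iff the output activation is positive.

    An output of exactly zero is labelled "young" so the rule is total.
    """
    _, output = forward(params, x)
    return "old" if output > 0.0 else "young"


def predict_targets(params: NetworkParams, X) -> np.ndarray:
    """Vectorized +/-1 predictions (+1 = old) for the rows of X."""
    _, output = forward_batch(params, _as_matrix(X, require_zscored=False))
    return np.where(output > 0.0, 1.0, -1.0)


def hidden_activations(params: NetworkParams, features) -> np.ndarray:
    """The n x h matrix of hidden-unit activations, row per participant."""
    X = _as_matrix(features, require_zscored=False)
    if X.shape[0] == 0:
        return np.empty((0, params.h))
    hidden, _ = forward_batch(params, X)
    return hidden
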