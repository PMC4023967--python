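"""Three-layer feed-forward regression network trained by Levenberg-Marquardt.

Architecture: an input layer (3-16 clinical features), one hidden layer of
tangent-sigmoid units (5, 10, 20 or 30 in the study grid), and a pure-linear
output layer for the three balance-control measures:

    y = W2 @ tanh(W1 @ x + b1) + b2

Inputs and targets are min-max normalized to [-1, 1]; the training MSE and
its stopping goals (0.1, 0.01, 0.001) live on that normalized scale, and
predictions are mapped back to real-world units (cm, cm, cm^2).

Training is damped Gauss-Newton: each epoch solves

    (J^T J + mu I) delta = J^T e

for the full parameter vector, accepts the step only if the MSE decreases
(mu /= 10), otherwise raises mu (* 10) and retries, and stops on the error
goal, the epoch cap, or damping overflow.  The Jacobian of the residuals is
computed analytically by backpropagation.  When the parameter count exceeds
the residual count the update is solved in the dual (residual-space) form,
which is algebraically identical and much cheaper for wide networks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import NormalizationError, TrainingError

__all__ = [
    "MinMaxNormalizer",
    "NetworkConfig",
    "NetworkModel",
    "TrainingTrace",
    "init_weights",
    "forward",
    "jacobian",
    "n_parameters",
    "train_lm",
    "predict",
    "input_importance",
    "save_model",
    "load_model",
    "make_teacher",
]

#: pre-activation clamp avoiding overflow in tanh's derivative bookkeeping
_PREACT_CLAMP = 40.0


# ---------------------------------------------------------------------------
# min-max normalization
# ---------------------------------------------------------------------------

@dataclass
class MinMaxNormalizer:
    """Per-column affine map onto [-1, 1] fitted from data extrema."""

    col_min: np.ndarray
    col_max: np.ndarray
    n_fit: int = 0  # number of rows the map was fitted on (leakage audit)

    @classmethod
    def fit(cls, X: np.ndarray, columns=None) -> "MinMaxNormalizer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lo, hi = X.min(axis=0), X.max(axis=0)
        degenerate = np.nonzero(hi - lo <= 0.0)[0]
        if degenerate.size:
            names = (
                [columns[i] for i in degenerate] if columns is not None
                else degenerate.tolist()
            )
            raise NormalizationError(f"constant column(s), cannot normalize: {names}")
        return cls(col_min=lo, col_max=hi, n_fit=X.shape[0])

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return 2.0 * (X - self.col_min) / (self.col_max - self.col_min) - 1.0

    def invert(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        return (Z + 1.0) / 2.0 * (self.col_max - self.col_min) + self.col_min


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Training configuration (study grid values documented per field)."""

    n_inputs: int
    n_hidden: int = 20       # study grid: 5, 10, 20 or 30
    n_outputs: int = 3
    error_goal: float = 0.001  # normalized MSE goal: 0.1, 0.01 or 0.001
    max_epochs: int = 500
    seed: int = 0
    mu0: float = 1e-3        # initial LM damping
    mu_increase: float = 10.0
    mu_decrease: float = 10.0
    mu_max: float = 1e10
    init: str = "nguyen-widrow"  # or "uniform"

    def __post_init__(self):
        if min(self.n_inputs, self.n_hidden, self.n_outputs) < 1:
            raise TrainingError("layer sizes must be positive")
        if self.error_goal <= 0.0 or self.max_epochs < 1:
            raise TrainingError("error_goal must be > 0 and max_epochs >= 1")


@dataclass
class NetworkModel:
    """Trained weights plus the normalization maps used during training."""

    W1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (n_outputs, n_hidden)
    b2: np.ndarray  # (n_outputs,)
    x_norm: MinMaxNormalizer | None = None
    y_norm: MinMaxNormalizer | None = None
    config: NetworkConfig | None = None


@dataclass
class TrainingTrace:
    """Per-epoch normalized MSE over accepted steps, and why training stopped."""

    mse: list = field(default_factory=list)
    epochs_used: int = 0
    stop_reason: str = ""  # 'goal' | 'max_epochs' | 'mu_overflow'
    final_mu: float = math.nan


def n_parameters(n_inputs: int, n_hidden: int, n_outputs: int) -> int:
    return n_hidden * (n_inputs + 1) + n_outputs * (n_hidden + 1)


def init_weights(config: NetworkConfig, rng: np.random.Generator) -> NetworkModel:
    """Seeded initialization; Nguyen-Widrow scaling of the hidden layer.

    Nguyen-Widrow spreads the hidden units' active regions evenly over the
    [-1, 1] input cube: random directions scaled to 0.7 * H^(1/I), biases
    spaced across the layer.
    """
    I, H, O = config.n_inputs, config.n_hidden, config.n_outputs
    if config.init == "uniform":
        W1 = rng.uniform(-0.5, 0.5, size=(H, I))
        b1 = rng.uniform(-0.5, 0.5, size=H)
    else:
        W1 = rng.uniform(-1.0, 1.0, size=(H, I))
        W1 /= np.linalg.norm(W1, axis=1, keepdims=True)
        magnitude = 0.7 * H ** (1.0 / I)
        W1 *= magnitude
        b1 = magnitude * np.linspace(-1.0, 1.0, H) * rng.choice([-1.0, 1.0], size=H)
    W2 = rng.uniform(-0.5, 0.5, size=(O, H))
    b2 = rng.uniform(-0.5, 0.5, size=O)
    return NetworkModel(W1=W1, b1=b1, W2=W2, b2=b2, config=config)


# ---------------------------------------------------------------------------
# forward pass and analytic Jacobian
# ---------------------------------------------------------------------------

def _hidden(model: NetworkModel, X: np.ndarray) -> np.ndarray:
    pre = np.clip(X @ model.W1.T + model.b1, -_PREACT_CLAMP, _PREACT_CLAMP)
    return np.tanh(pre)


def forward(model: NetworkModel, X: np.ndarray) -> np.ndarray:
    """Normalized-space forward pass; X is (n, n_inputs) or (n_inputs,)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.W1.shape[1]:
        raise TrainingError(
            f"input has {X.shape[1]} columns, model expects {model.W1.shape[1]}"
        )
    return _hidden(model, X) @ model.W2.T + model.b2


def _pack(model: NetworkModel) -> np.ndarray:
    return np.concatenate(
        [model.W1.ravel(), model.b1, model.W2.ravel(), model.b2]
    )


def _unpack(p: np.ndarray, I: int, H: int, O: int):
    i = 0
    W1 = p[i:i + H * I].reshape(H, I); i += H * I
    b1 = p[i:i + H]; i += H
    W2 = p[i:i + O * H].reshape(O, H); i += O * H
    b2 = p[i:i + O]
    return W1, b1, W2, b2


def jacobian(model: NetworkModel, X: np.ndarray) -> np.ndarray:
    """Jacobian of the network outputs w.r.t. all parameters.

    Rows are ordered sample-major then output ((n, o) -> n * n_outputs + o);
    columns follow the packing [W1, b1, W2, b2].  Because the residual is
    prediction minus target, this is also the residual Jacobian.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = X.shape[0]
    I, H, O = model.W1.shape[1], model.W1.shape[0], model.W2.shape[0]
    A = _hidden(model, X)          # (N, H)
    dA = 1.0 - A * A               # tanh'
    P = n_parameters(I, H, O)
    J = np.zeros((N * O, P))

    # d y_o / d W1[h, i] = W2[o, h] * (1 - a_h^2) * x_i
    g = model.W2[None, :, :] * dA[:, None, :]           # (N, O, H)
    J[:, : H * I] = np.einsum("noh,ni->nohi", g, X).reshape(N * O, H * I)
    J[:, H * I: H * I + H] = g.reshape(N * O, H)        # d/d b1
    off = H * I + H
    eye_o = np.eye(O)
    # d y_o / d W2[o', h] = delta(o, o') * a_h
    J[:, off: off + O * H] = np.einsum(
        "op,nh->nohp", eye_o, A
    ).transpose(0, 1, 3, 2).reshape(N * O, O * H)
    J[:, off + O * H:] = np.tile(eye_o, (N, 1))         # d/d b2
    return J


# ---------------------------------------------------------------------------
# Levenberg-Marquardt training
# ---------------------------------------------------------------------------

def _lm_step(J: np.ndarray, e: np.ndarray, mu: float) -> np.ndarray:
    """Solve (J^T J + mu I) delta = J^T e, in primal or dual form."""
    n_res, n_par = J.shape
    try:
        if n_par <= n_res:
            A = J.T @ J + mu * np.eye(n_par)
            return np.linalg.solve(A, J.T @ e)
        # dual identity: (J^T J + mu I)^-1 J^T = J^T (J J^T + mu I)^-1
        A = J @ J.T + mu * np.eye(n_res)
        return J.T @ np.linalg.solve(A, e)
    except np.linalg.LinAlgError as err:  # pragma: no cover - extreme inputs
        raise TrainingError(f"singular LM update at mu={mu:g}: {err}") from None


def train_lm(
    config: NetworkConfig,
    X: np.ndarray,
    Y: np.ndarray,
    x_columns=None,
    y_columns=None,
) -> tuple[NetworkModel, TrainingTrace]:
    """Train on raw-unit data; normalization is fitted here, on X and Y only.

    Returns the trained model (carrying its normalizers) and the training
    trace.  A sample count below one fifth of the parameter count is legal
    but the network is then heavily over-parameterized; training still runs
    (the study itself used 42 samples with up to ~600 parameters).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise TrainingError("non-finite values in training data")
    if X.shape[0] != Y.shape[0]:
        raise TrainingError("X and Y row counts differ")

    x_norm = MinMaxNormalizer.fit(X, x_columns)
    y_norm = MinMaxNormalizer.fit(Y, y_columns)
    Xn, Yn = x_norm.apply(X), y_norm.apply(Y)

    rng = np.random.default_rng(config.seed)
    model = init_weights(config, rng)
    model.x_norm, model.y_norm = x_norm, y_norm
    I, H, O = config.n_inputs, config.n_hidden, config.n_outputs
    p = _pack(model)
    trace = TrainingTrace()

    def set_params(vec):
        model.W1, model.b1, model.W2, model.b2 = _unpack(vec, I, H, O)

    set_params(p)
    resid = (forward(model, Xn) - Yn).ravel()
    mse = float(np.mean(resid**2))
    mu = config.mu0

    while trace.epochs_used < config.max_epochs and mse > config.error_goal:
        J = jacobian(model, Xn)
        accepted = False
        while mu <= config.mu_max:
            delta = _lm_step(J, resid, mu)
            candidate = p - delta
            set_params(candidate)
            new_resid = (forward(model, Xn) - Yn).ravel()
            new_mse = float(np.mean(new_resid**2))
            if new_mse < mse:
                p, resid, mse = candidate, new_resid, new_mse
                mu /= config.mu_decrease
                accepted = True
                break
            mu *= config.mu_increase
        if not accepted:
            set_params(p)
            trace.stop_reason = "mu_overflow"
            break
        trace.epochs_used += 1
        trace.mse.append(mse)

    set_params(p)
    trace.final_mu = mu
    if not trace.stop_reason:
        trace.stop_reason = "goal" if mse <= config.error_goal else "max_epochs"
    return model, trace


def predict(model: NetworkModel, X_raw: np.ndarray) -> np.ndarray:
    """Normalize, run the network, and return outputs in real-world units."""
    if model.x_norm is None or model.y_norm is None:
        raise TrainingError("model has no fitted normalizers; train it first")
    return model.y_norm.invert(forward(model, model.x_norm.apply(X_raw)))


def input_importance(model: NetworkModel, input_names=None):
    """Rank inputs by summed absolute hidden-layer weight.

    Returns ``(scores, order)``: one score per input and the input indices
    (or names) sorted by decreasing score, ties broken by original index.
    """
    scores = np.abs(model.W1).sum(axis=0)
    order = np.argsort(-scores, kind="stable")
    if input_names is not None:
        return scores, [input_names[i] for i in order]
    return scores, order.tolist()


# ---------------------------------------------------------------------------
# serialization and teacher networks
# ---------------------------------------------------------------------------

def _norm_to_dict(norm: MinMaxNormalizer | None):
    if norm is None:
        return None
    return {
        "col_min": norm.col_min.tolist(),
        "col_max": norm.col_max.tolist(),
        "n_fit": norm.n_fit,
    }


def _norm_from_dict(d):
    if d is None:
        return None
    return MinMaxNormalizer(
        col_min=np.asarray(d["col_min"], dtype=float),
        col_max=np.asarray(d["col_max"], dtype=float),
        n_fit=int(d["n_fit"]),
    )


def save_model(model: NetworkModel, path) -> None:
    """JSON serialization; floats round-trip bit-exactly via repr."""
    payload = {
        "W1": model.W1.tolist(), "b1": model.b1.tolist(),
        "W2": model.W2.tolist(), "b2": model.b2.tolist(),
        "x_norm": _norm_to_dict(model.x_norm),
        "y_norm": _norm_to_dict(model.y_norm),
        "config": None if model.config is None else vars(model.config),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> NetworkModel:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = payload.get("config")
    return NetworkModel(
        W1=np.asarray(payload["W1"], dtype=float),
        b1=np.asarray(payload["b1"], dtype=float),
        W2=np.asarray(payload["W2"], dtype=float),
        b2=np.asarray(payload["b2"], dtype=float),
        x_norm=_norm_from_dict(payload.get("x_norm")),
        y_norm=_norm_from_dict(payload.get("y_norm")),
        config=None if cfg is None else NetworkConfig(**cfg),
    )


def make_teacher(n_inputs: int, n_hidden: int, n_outputs: int,
                 seed: int = 0, weight_scale: float = 1.5) -> NetworkModel:
    """Random fixed network used as a data-generating ground truth in tests."""
    rng = np.random.default_rng(seed)
    return NetworkModel(
        W1=rng.normal(scale=weight_scale / math.sqrt(n_inputs), size=(n_hidden, n_inputs)),
        b1=rng.normal(scale=0.3, size=n_hidden),
        W2=rng.normal(scale=1.0 / math.sqrt(n_hidden), size=(n_outputs, n_hidden)),
        b2=rng.normal(scale=0.1, size=n_outputs),
    )
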