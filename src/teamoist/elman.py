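"""Elman recurrent network regression.

The network is a single-hidden-layer perceptron whose hidden activations
are copied into a context layer and fed back through recurrent weights w1:

    x(i) = alpha( w1 . xc(i) + w2 . T(i) + b_h ),   xc(i) = x(i-1)
    y(i) = g( w3 . x(i) + b_o )

with alpha = tanh and g = identity.  The inputs here are static feature
vectors, not sequences, so the context is reset to zero for every sample
and the recurrence is run K times (default 2) on the same input: this
keeps predictions independent of sample presentation order while leaving
the context weights w1 active.

Training is full-batch gradient descent on the mean squared error with the
gradient truncated at the context copy (one-step backpropagation through
time).  The `ElmanRegressor` estimator wraps the raw network with min-max
scaling of inputs and target learnt from the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "ElmanNet",
    "TrainConfig",
    "forward",
    "train_gd",
    "to_vector",
    "from_vector",
    "parameter_count",
    "ElmanRegressor",
]


def parameter_count(n_in: int, n_hidden: int, n_out: int = 1) -> int:
    """Total trainable parameters: w1 + w2 + w3 + hidden and output biases."""
    return n_hidden * n_hidden + n_hidden * n_in + n_out * n_hidden + n_hidden + n_out


@dataclass
class ElmanNet:
    """Weights and thresholds of an Elman network (n_out fixed at 1)."""

    w1: np.ndarray  # context -> hidden, (n_hidden, n_hidden)
    w2: np.ndarray  # input -> hidden, (n_hidden, n_in)
    w3: np.ndarray  # hidden -> output, (1, n_hidden)
    b_h: np.ndarray  # hidden thresholds, (n_hidden,)
    b_o: np.ndarray  # output threshold, (1,)

    def __post_init__(self) -> None:
        h = self.w1.shape[0]
        if self.w1.shape != (h, h) or self.w2.shape[0] != h \
                or self.w3.shape != (1, h) or self.b_h.shape != (h,) \
                or self.b_o.shape != (1,):
            raise ValueError("inconsistent weight shapes")

    @property
    def n_in(self) -> int:
        return self.w2.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[0]

    def copy(self) -> "ElmanNet":
        return ElmanNet(self.w1.copy(), self.w2.copy(), self.w3.copy(),
                        self.b_h.copy(), self.b_o.copy())

    @classmethod
    def random_init(cls, n_in: int, n_hidden: int, rng: np.random.Generator,
                    scale: float = 0.5) -> "ElmanNet":
        """Uniform(-scale, scale) initialization of all weights and biases.

        The input-to-hidden block is additionally divided by sqrt(n_in)
        (fan-in scaling) so the tanh layer does not saturate when the
        network is fed wide inputs such as full spectra.
        """
        u = lambda *shape: rng.uniform(-scale, scale, shape)
        return cls(u(n_hidden, n_hidden), u(n_hidden, n_in) / np.sqrt(n_in),
                   u(1, n_hidden), u(n_hidden), u(1))


@dataclass
class TrainConfig:
    """Gradient-descent hyperparameters for the Elman network."""

    epochs: int = 600
    learning_rate: float = 0.1
    recurrent_steps: int = 2  # K passes through the context loop per sample
    seed: int = 0
    tol: float = 0.0  # early stop when |ΔMSE| per epoch falls below tol

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.recurrent_steps < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")


def _hidden_states(net: ElmanNet, X: np.ndarray, k_steps: int):
    """Run the context loop; returns (last hidden, previous context)."""
    n = X.shape[0]
    drive = X @ net.w2.T + net.b_h  # constant across the K steps
    xc = np.zeros((n, net.n_hidden))
    prev = xc
    for _ in range(k_steps):
        prev = xc
        xc = np.tanh(xc @ net.w1.T + drive)
    return xc, prev


def forward(net: ElmanNet, X: np.ndarray, k_steps: int = 2) -> np.ndarray:
    """Predict outputs for one input vector or a matrix of rows.

    The context starts at zero for every sample, so the result does not
    depend on the order in which samples are presented.
    """
    X = np.asarray(X, dtype=float)
    one_d = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != net.n_in:
        raise ValueError(f"expected {net.n_in} inputs, got {X.shape[1]}")
    h, _ = _hidden_states(net, X, k_steps)
    y = (h @ net.w3.T + net.b_o).ravel()
    return float(y[0]) if one_d else y


def mse(net: ElmanNet, X: np.ndarray, y: np.ndarray, k_steps: int = 2) -> float:
    """Training-set mean squared error of the network as-is."""
    pred = forward(net, np.atleast_2d(X), k_steps)
    return float(np.mean((pred - np.asarray(y, dtype=float)) ** 2))


def train_gd(net: ElmanNet, X: np.ndarray, y: np.ndarray,
             cfg: TrainConfig = TrainConfig()) -> tuple[ElmanNet, np.ndarray]:
    """Full-batch gradient descent on MSE; returns (trained net, loss history).

    The gradient is truncated at the context copy: the hidden state from
    step K-1 is treated as a constant when differentiating step K.  The
    returned network is the best iterate seen (by training MSE), not
    necessarily the last one: a fixed-step descent from a sharp minimum can
    overshoot, and keeping the best iterate guarantees training never ends
    worse than its own starting point.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    net = net.copy()
    K, lr = cfg.recurrent_steps, cfg.learning_rate
    n = X.shape[0]
    history = []
    prev_loss = np.inf
    best_loss, best_net = np.inf, net.copy()
    for _ in range(cfg.epochs):
        h, h_prev = _hidden_states(net, X, K)
        resid = (h @ net.w3.T + net.b_o).ravel() - y
        loss = float(np.mean(resid**2))
        blown_up = history and loss > 1e9 * (history[0] + 1e-12)
        if not np.isfinite(loss) or blown_up:
            raise FloatingPointError(
                "training diverged; try a smaller learning rate"
            )
        history.append(loss)
        if loss < best_loss:
            best_loss, best_net = loss, net.copy()
        delta_o = (2.0 / n) * resid[:, None]  # dL/dy, (n, 1)
        g_w3 = delta_o.T @ h
        g_bo = delta_o.sum(axis=0)
        dh = (delta_o @ net.w3) * (1.0 - h**2)  # (n, n_hidden)
        g_w1 = dh.T @ h_prev
        g_w2 = dh.T @ X
        g_bh = dh.sum(axis=0)
        net.w1 -= lr * g_w1
        net.w2 -= lr * g_w2
        net.w3 -= lr * g_w3
        net.b_h -= lr * g_bh
        net.b_o -= lr * g_bo
        if cfg.tol > 0 and abs(prev_loss - loss) < cfg.tol:
            break
        prev_loss = loss
    final_loss = mse(net, X, y, K)
    if final_loss < best_loss:
        best_loss, best_net = final_loss, net
    history.append(final_loss)
    return best_net, np.asarray(history)


def fit_with_backoff(net0: ElmanNet, X: np.ndarray, y: np.ndarray,
                     cfg: TrainConfig, retries: int = 3,
                     shrink: float = 5.0) -> tuple[ElmanNet, np.ndarray]:
    """Run `train_gd`, shrinking the learning rate on divergence.

    Plain gradient descent can blow up when the step is too large for the
    local curvature (which grows with input width); each retry divides the
    learning rate by ``shrink``.  Raises after ``retries`` failures.
    """
    lr = cfg.learning_rate
    for attempt in range(retries + 1):
        try:
            trial = TrainConfig(cfg.epochs, lr, cfg.recurrent_steps,
                                cfg.seed, cfg.tol)
            return train_gd(net0, X, y, trial)
        except FloatingPointError:
            if attempt == retries:
                raise
            lr /= shrink
    raise AssertionError("unreachable")


def to_vector(net: ElmanNet) -> np.ndarray:
    """Flatten parameters in the fixed order w1, w2, w3, b_h, b_o (row-major)."""
    return np.concatenate([net.w1.ravel(), net.w2.ravel(), net.w3.ravel(),
                           net.b_h, net.b_o])


def from_vector(n_in: int, n_hidden: int, theta: np.ndarray) -> ElmanNet:
    """Rebuild a network from a flat parameter vector (inverse of to_vector)."""
    theta = np.asarray(theta, dtype=float)
    expected = parameter_count(n_in, n_hidden)
    if theta.shape != (expected,):
        raise ValueError(f"expected parameter vector of length {expected}, "
                         f"got {theta.shape}")
    sizes = [n_hidden * n_hidden, n_hidden * n_in, n_hidden, n_hidden, 1]
    parts = np.split(theta, np.cumsum(sizes)[:-1])
    # copy: np.split yields views of theta, and the net must own its weights
    return ElmanNet(parts[0].reshape(n_hidden, n_hidden).copy(),
                    parts[1].reshape(n_hidden, n_in).copy(),
                    parts[2].reshape(1, n_hidden).copy(),
                    parts[3].copy(), parts[4].copy())


class ElmanRegressor(RegressorMixin, BaseEstimator):
    """Elman network regressor with internal min-max scaling.

    Inputs and target are scaled to [0, 1] with training-set statistics
    before gradient training and predictions are mapped back, so the tanh
    hidden layer operates on a well-conditioned range regardless of the
    units of the features.

    Parameters
    ----------
    n_hidden : int, default 10
        Hidden (and context) layer width.
    epochs, learning_rate, recurrent_steps, tol :
        Passed to the gradient-descent trainer; see `TrainConfig`.
    init : None or array
        Optional flat parameter vector used as the starting point instead
        of random initialization (this is how the whale-optimized variant
        seeds training).
    random_state : int
        Seed for the random initialization.
    """

    def __init__(self, n_hidden=10, epochs=600, learning_rate=0.1,
                 recurrent_steps=2, tol=0.0, init=None, random_state=0):
        self.n_hidden = n_hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.recurrent_steps = recurrent_steps
        self.tol = tol
        self.init = init
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.x_scaler_ = MinMaxScaler().fit(X)
        self.y_scaler_ = MinMaxScaler().fit(y.reshape(-1, 1))
        Xs = self.x_scaler_.transform(X)
        ys = self.y_scaler_.transform(y.reshape(-1, 1)).ravel()
        rng = np.random.default_rng(self.random_state)
        if self.init is not None:
            net0 = from_vector(X.shape[1], self.n_hidden, np.asarray(self.init))
        else:
            net0 = ElmanNet.random_init(X.shape[1], self.n_hidden, rng)
        cfg = TrainConfig(self.epochs, self.learning_rate,
                          self.recurrent_steps, self.random_state, self.tol)
        self.net_, self.loss_history_ = fit_with_backoff(net0, Xs, ys, cfg)
        self.initial_mse_ = mse(net0, Xs, ys, self.recurrent_steps)
        self.train_mse_ = mse(self.net_, Xs, ys, self.recurrent_steps)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        Xs = self.x_scaler_.transform(X)
        ys = forward(self.net_, Xs, self.recurrent_steps)
        return self.y_scaler_.inverse_transform(
            np.atleast_1d(ys).reshape(-1, 1)
        ).ravel()
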