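"""Model zoo and evaluation metrics for the moisture-prediction pipeline.

`WOAElmanRegressor` is the headline model: the whale optimizer searches the
Elman network's flattened initial weights and thresholds over [-1, 1]^d,
scoring a candidate by the training-set MSE of the untrained network, and
the best candidate then seeds ordinary gradient training.  `make_plsr` and
`make_svr` provide the classical chemometrics baselines with
cross-validated hyperparameters.

Evaluation follows the standard chemometric triple on the prediction set:
the Pearson correlation Rp, the root mean square error of prediction
RMSEP, and the residual predictive deviation RPD = SD(y_true) / RMSEP,
with SD the sample standard deviation (n-1).  An RPD above 1.4 marks a
usable model, 1.8-2 a good one, above 2 an excellent one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted, check_X_y

from . import elman as _elman
from .elman import ElmanRegressor, TrainConfig, from_vector, parameter_count, train_gd
from .woa import WoaConfig, optimize

__all__ = ["EvalReport", "evaluate", "WOAElmanRegressor",
           "make_plsr", "make_svr", "train_woa_enn"]


@dataclass
class EvalReport:
    """Prediction-set performance of one model/fusion combination."""

    Rp: float
    RMSEP: float
    RPD: float
    n_test: int
    model: str = ""
    fusion: str = ""

    @property
    def quality(self) -> str:
        """Qualitative RPD band (reported, never enforced)."""
        if self.RPD > 2:
            return "excellent"
        if self.RPD >= 1.8:
            return "good"
        if self.RPD >= 1.4:
            return "applicable"
        return "not applicable"

    def row(self) -> dict:
        return {"model": self.model, "fusion": self.fusion, "Rp": self.Rp,
                "RMSEP": self.RMSEP, "RPD": self.RPD, "n_test": self.n_test}


def evaluate(y_true, y_pred, model: str = "", fusion: str = "") -> EvalReport:
    """Rp / RMSEP / RPD on a prediction set (moisture as fraction)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 3:
        raise ValueError("need equal-length y_true/y_pred with at least 3 samples")
    sd = float(np.std(y_true, ddof=1))
    if sd < 1e-15:
        raise ValueError("Rp undefined: y_true is constant")
    if float(np.std(y_pred)) < 1e-15:
        import warnings

        warnings.warn("constant predictions: Rp reported as 0")
        rp = 0.0
    else:
        rp = float(np.corrcoef(y_true, y_pred)[0, 1])
    rmsep = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    rpd = float(np.inf) if rmsep == 0 else sd / rmsep
    return EvalReport(rp, rmsep, rpd, int(y_true.size), model, fusion)


class WOAElmanRegressor(RegressorMixin, BaseEstimator):
    """Elman regressor whose initial weights/thresholds come from a whale search.

    The optimizer works over the box [-1, 1]^d (d = total parameter count,
    a tanh-friendly scale) in the same parametrization family the random
    initializer uses (input-to-hidden block fan-in scaled).  A candidate
    theta is scored by the training MSE of its network after a short
    gradient burst (``burst_epochs``, default 20): scoring the raw
    untrained MSE instead (``burst_epochs=0``) is cheaper but empirically
    selects basins that full training cannot improve on.  The best theta
    then initializes full-batch gradient training.  ``woa_iters=0`` skips
    the whale search entirely and reduces to the plain `ElmanRegressor`.

    Fitted attributes include both traces: ``woa_history_`` (best fitness
    per whale iteration) and ``loss_history_`` (gradient-training MSE per
    epoch), plus ``woa_init_mse_`` for the selected initialization.
    """

    def __init__(self, n_hidden=10, epochs=600, learning_rate=0.1,
                 recurrent_steps=2, tol=0.0, pop_size=30, woa_iters=100,
                 burst_epochs=20, spiral_b=1.0, random_state=0):
        self.n_hidden = n_hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.recurrent_steps = recurrent_steps
        self.tol = tol
        self.pop_size = pop_size
        self.woa_iters = woa_iters
        self.burst_epochs = burst_epochs
        self.spiral_b = spiral_b
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        base = ElmanRegressor(
            n_hidden=self.n_hidden, epochs=0, learning_rate=self.learning_rate,
            recurrent_steps=self.recurrent_steps, random_state=self.random_state,
        ).fit(X, y)  # borrows the scalers; epochs=0 leaves weights at init
        Xs = base.x_scaler_.transform(X)
        ys = base.y_scaler_.transform(y.reshape(-1, 1)).ravel()
        d = parameter_count(X.shape[1], self.n_hidden)
        fan_in = np.sqrt(X.shape[1])

        def decode(theta):
            # same parametrization family as the random initializer: the
            # input-to-hidden block is fan-in scaled so candidates in
            # [-1, 1]^d stay clear of tanh saturation and remain trainable
            net = from_vector(X.shape[1], self.n_hidden, theta)
            net.w2 /= fan_in
            return net

        burst_cfg = TrainConfig(max(self.burst_epochs, 1), self.learning_rate,
                                self.recurrent_steps)

        def fitness(theta):
            net = decode(theta)
            if self.burst_epochs > 0:
                try:
                    net, _ = train_gd(net, Xs, ys, burst_cfg)
                except FloatingPointError:
                    return 1e6  # untrainable candidate
            return _elman.mse(net, Xs, ys, self.recurrent_steps)

        if self.woa_iters > 0:
            cfg = WoaConfig(pop_size=self.pop_size, max_iters=self.woa_iters,
                            b=self.spiral_b, lo=-1.0, hi=1.0,
                            seed=self.random_state)
            result = optimize(fitness, d, cfg)
            net0 = decode(result.best_position)
        else:  # ablation: skip the whale search, plain random initialization
            result = None
            net0 = base.net_
        tcfg = TrainConfig(self.epochs, self.learning_rate,
                           self.recurrent_steps, self.random_state, self.tol)
        net, hist = _elman.fit_with_backoff(net0, Xs, ys, tcfg)
        self.net_ = net
        self.train_mse_ = _elman.mse(net, Xs, ys, self.recurrent_steps)
        self.x_scaler_, self.y_scaler_ = base.x_scaler_, base.y_scaler_
        self.woa_result_ = result
        self.woa_history_ = result.history if result is not None else np.array([])
        # MSE of the selected initialization before any gradient training;
        # the best-iterate rule in train_gd guarantees train_mse_ <= this
        self.woa_init_mse_ = _elman.mse(net0, Xs, ys, self.recurrent_steps)
        self.loss_history_ = hist
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        from sklearn.utils.validation import check_array

        X = check_array(X)
        Xs = self.x_scaler_.transform(X)
        ys = _elman.forward(self.net_, Xs, self.recurrent_steps)
        return self.y_scaler_.inverse_transform(
            np.atleast_1d(ys).reshape(-1, 1)
        ).ravel()


def train_woa_enn(X_train, y_train, elman_cfg: dict | None = None,
                  woa_cfg: dict | None = None) -> WOAElmanRegressor:
    """Convenience wrapper: fit a `WOAElmanRegressor` from plain config dicts."""
    params = dict(elman_cfg or {})
    woa = dict(woa_cfg or {})
    params.setdefault("pop_size", woa.get("pop_size", 30))
    params.setdefault("woa_iters", woa.get("max_iters", 100))
    params.setdefault("spiral_b", woa.get("b", 1.0))
    return WOAElmanRegressor(**params).fit(X_train, y_train)


def make_plsr(max_components: int = 10, cv: int = 5) -> GridSearchCV:
    """PLSR with the latent-variable count chosen by cross-validated RMSE."""
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    return GridSearchCV(
        PLSRegression(scale=False),
        {"n_components": list(range(1, max_components + 1))},
        scoring="neg_root_mean_squared_error",
        cv=KFold(n_splits=cv, shuffle=False),
        error_score="raise",
    )


#: declared epsilon-SVR hyperparameter grid (RBF kernel)
SVR_GRID = {
    "svr__C": [1.0, 10.0, 100.0],
    "svr__gamma": ["scale", 0.1, 1.0],
    "svr__epsilon": [0.001, 0.01, 0.1],
}


def make_svr(grid: dict | None = None, cv: int = 5) -> GridSearchCV:
    """RBF-kernel epsilon-SVR with (C, gamma, epsilon) grid search."""
    grid = SVR_GRID if grid is None else grid
    if not grid:
        raise ValueError("empty hyperparameter grid")
    pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
    return GridSearchCV(pipe, grid, scoring="neg_root_mean_squared_error",
                        cv=KFold(n_splits=cv, shuffle=False), error_score="raise")
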