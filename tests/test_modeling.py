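import numpy as np
import pytest

from teamoist.elman import ElmanRegressor, from_vector, parameter_count
from teamoist.modeling import (
    WOAElmanRegressor,
    evaluate,
    make_plsr,
    make_svr,
    train_woa_enn,
)


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([0.2, 0.4, 0.6, 0.5])
        rep = evaluate(y, y)
        assert rep.Rp == pytest.approx(1.0)
        assert rep.RMSEP == 0.0
        assert rep.RPD == np.inf

    def test_hand_computed_rmsep(self):
        rep = evaluate([0.1, 0.2, 0.4], [0.1, 0.2, 0.3])
        assert rep.RMSEP == pytest.approx(np.sqrt(0.01 / 3), abs=1e-12)

    def test_constant_shift_decouples_bias_from_correlation(self):
        y = np.array([0.1, 0.3, 0.6, 0.8])
        rep = evaluate(y, y + 0.05)
        assert rep.Rp == pytest.approx(1.0)
        assert rep.RMSEP == pytest.approx(0.05, abs=1e-12)

    def test_rpd_times_rmsep_equals_sd(self, rng):
        y = rng.uniform(0.1, 0.7, size=25)
        rep = evaluate(y, y + rng.normal(0, 0.02, size=25))
        assert rep.RPD * rep.RMSEP == pytest.approx(np.std(y, ddof=1),
                                                    abs=1e-12)

    def test_permutation_invariance(self, rng):
        y = rng.uniform(size=15)
        p = y + rng.normal(0, 0.05, size=15)
        perm = rng.permutation(15)
        a, b = evaluate(y, p), evaluate(y[perm], p[perm])
        assert a.Rp == pytest.approx(b.Rp, abs=1e-12)
        assert a.RMSEP == pytest.approx(b.RMSEP, abs=1e-12)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            evaluate([0.5, 0.5, 0.5], [0.4, 0.5, 0.6])

    def test_quality_bands(self):
        y = np.array([0.1, 0.3, 0.6, 0.8])
        assert evaluate(y, y).quality == "excellent"
        with pytest.warns(UserWarning, match="constant predictions"):
            rep = evaluate(y, np.full(4, y.mean()))
        assert rep.Rp == 0.0
        assert rep.quality == "not applicable"


class TestPlsr:
    def test_exact_linear_recovery(self, rng):
        X = rng.normal(size=(30, 5))
        y = X @ np.array([1.0, -2, 0.5, 3, 0.1])
        model = make_plsr(max_components=5).fit(X, y)
        rmse = np.sqrt(np.mean((np.asarray(model.predict(X)).ravel() - y) ** 2))
        assert rmse < 1e-8

    def test_one_component_univariate_equals_ols(self, rng):
        x = rng.normal(size=(40, 1))
        y = 2.5 * x[:, 0] + rng.normal(0, 0.1, size=40)
        model = make_plsr(max_components=1).fit(x, y)
        slope_ols = np.polyfit(x[:, 0], y, 1)[0]
        slope_pls = float(model.best_estimator_.coef_.ravel()[0])
        assert slope_pls == pytest.approx(slope_ols, abs=1e-10)

    def test_sample_order_invariance(self, rng):
        X = rng.normal(size=(25, 4))
        y = X @ np.array([1.0, 0.5, -1, 2]) + rng.normal(0, 0.05, 25)
        m = make_plsr(4).fit(X, y)
        perm = rng.permutation(25)
        m2 = make_plsr(4).fit(X[perm], y[perm])
        np.testing.assert_allclose(m.best_estimator_.coef_,
                                   m2.best_estimator_.coef_, atol=1e-8)


class TestSvr:
    def test_learns_smooth_nonlinearity(self, rng):
        x = np.linspace(0, 2, 100)[:, None]
        y = np.sin(3 * x[:, 0]) + rng.normal(0, 0.02, size=100)
        model = make_svr().fit(x, y)
        rmse = np.sqrt(np.mean((model.predict(x) - np.sin(3 * x[:, 0])) ** 2))
        assert rmse < 0.1

    def test_duplicate_rows_do_not_move_predictions(self, rng):
        # duplicating every row doubles the empirical loss term, so the
        # solution is invariant when C is halved to compensate
        X = rng.normal(size=(30, 2))
        y = X[:, 0] + rng.normal(0, 0.05, 30)
        probe = rng.normal(size=(5, 2))
        grid_a = {"svr__C": [10.0], "svr__gamma": [0.5],
                  "svr__epsilon": [0.01], "svr__tol": [1e-8]}
        grid_b = {"svr__C": [5.0], "svr__gamma": [0.5],
                  "svr__epsilon": [0.01], "svr__tol": [1e-8]}
        a = make_svr(grid=grid_a, cv=3).fit(X, y).predict(probe)
        b = make_svr(grid=grid_b, cv=3).fit(np.vstack([X, X]),
                                            np.concatenate([y, y])).predict(probe)
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_huge_epsilon_gives_flat_tube(self, rng):
        X = rng.normal(size=(40, 1))
        y = rng.uniform(size=40)
        model = make_svr(grid={"svr__C": [1.0], "svr__gamma": ["scale"],
                               "svr__epsilon": [10.0]}, cv=3).fit(X, y)
        preds = model.predict(X)
        assert preds.std() < 1e-6

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            make_svr(grid={})


@pytest.fixture(scope="module")
def toy_regression():
    rng = np.random.default_rng(42)
    X = rng.uniform(size=(80, 4))
    y = 0.6 * X[:, 0] - 0.3 * X[:, 1] + 0.2 * np.tanh(X[:, 2]) \
        + rng.normal(0, 0.01, size=80)
    return X, y


class TestWoaElman:
    def test_null_parameters_give_constant_predictor_fitness(self, toy_regression):
        X, y = toy_regression
        # a zero parameter vector predicts g(0) = 0 everywhere, so its MSE
        # equals the mean square of the (scaled) targets
        model = WOAElmanRegressor(woa_iters=1, pop_size=2, epochs=1,
                                  random_state=0).fit(X, y)
        net = from_vector(4, model.n_hidden, np.zeros(parameter_count(4, 10)))
        ys = model.y_scaler_.transform(y.reshape(-1, 1)).ravel()
        from teamoist.elman import mse

        Xs = model.x_scaler_.transform(X)
        assert mse(net, Xs, ys) == pytest.approx(np.mean(ys**2), abs=1e-12)

    def test_skipping_search_equals_plain_elman(self, toy_regression):
        X, y = toy_regression
        ablated = WOAElmanRegressor(woa_iters=0, epochs=80,
                                    random_state=3).fit(X, y)
        plain = ElmanRegressor(epochs=80, random_state=3).fit(X, y)
        np.testing.assert_allclose(ablated.predict(X), plain.predict(X),
                                   atol=1e-12)

    def test_training_never_worse_than_selected_init(self, toy_regression):
        X, y = toy_regression
        model = WOAElmanRegressor(woa_iters=10, pop_size=8, epochs=100,
                                  random_state=1).fit(X, y)
        assert model.train_mse_ <= model.woa_init_mse_ + 1e-15

    def test_woa_history_recorded_and_monotone(self, toy_regression):
        X, y = toy_regression
        model = WOAElmanRegressor(woa_iters=10, pop_size=8, epochs=20,
                                  random_state=0).fit(X, y)
        assert len(model.woa_history_) == 11
        assert np.all(np.diff(model.woa_history_) <= 0)

    def test_config_dict_wrapper(self, toy_regression):
        X, y = toy_regression
        model = train_woa_enn(X, y, elman_cfg={"epochs": 20, "random_state": 5},
                              woa_cfg={"pop_size": 6, "max_iters": 5})
        assert model.pop_size == 6 and model.woa_iters == 5
        assert hasattr(model, "net_")
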