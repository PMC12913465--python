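"""Splits, metrics, model fits, feature assembly, leakage guard."""

import numpy as np
import pandas as pd
import pytest

from heatspec import preprocessing as prep
from heatspec import regression_models as rm
from heatspec import trilateral_features as tf
from heatspec.errors import EmptyFeatureSetError, ValidationError


class TestSplit:
    def test_eighty_samples_split_sixty_twenty(self):
        train, test = rm.split_train_test(80, seed=0)
        assert train.size == 60 and test.size == 20

    def test_minimum_size_split(self):
        train, test = rm.split_train_test(8, seed=0)
        assert train.size == 6 and test.size == 2

    def test_too_small_rejected(self):
        with pytest.raises(ValidationError):
            rm.split_train_test(7)

    def test_deterministic_disjoint_exhaustive(self):
        a = rm.split_train_test(40, seed=7)
        b = rm.split_train_test(40, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        assert set(a[0]) | set(a[1]) == set(range(40))
        assert not set(a[0]) & set(a[1])


class TestMetrics:
    def test_r_squared_hand_value(self):
        assert rm.r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_r_squared_limits(self):
        assert rm.r_squared([1, 2, 3], [1, 2, 3]) == 1.0
        assert rm.r_squared([1, 2, 3], [2, 2, 2]) == 0.0
        assert np.isnan(rm.r_squared([2, 2], [1, 3]))

    def test_rmse_hand_value_and_homogeneity(self, rng):
        assert rm.rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))
        y, yh = rng.normal(size=20), rng.normal(size=20)
        assert rm.rmse(3 * y, 3 * yh) == pytest.approx(3 * rm.rmse(y, yh))

    def test_amplitude_of_variation(self):
        assert rm.amplitude_of_variation(40.0, 40.0) == 0.0
        assert rm.amplitude_of_variation(50.0, 40.0) == pytest.approx(25.0)
        assert rm.amplitude_of_variation(20.0, 40.0) == pytest.approx(-50.0)
        assert np.isnan(rm.amplitude_of_variation(1.0, 0.0))


class TestModels:
    def test_constant_target_predicts_constant_for_all_kinds(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.full(20, 7.5)
        for kind in rm.MODEL_KINDS:
            model = rm.fit_model(kind, X, y, seed=0)
            np.testing.assert_allclose(model.predict(X), 7.5)

    def test_plsr_recovers_exact_linear_relation(self, rng):
        x = rng.uniform(0, 1, 40)[:, None]
        y = 2.0 * x.ravel() + 1.0
        model = rm.fit_model("PLSR", x[:30], y[:30], seed=0)
        assert rm.rmse(y[30:], model.predict(x[30:])) < 1e-6

    def test_rfr_seeded_predictions_reproducible(self, rng):
        X = rng.normal(size=(30, 4))
        y = X[:, 0] + rng.normal(0, 0.1, 30)
        a = rm.fit_model("RFR", X, y, seed=3).predict(X)
        b = rm.fit_model("RFR", X, y, seed=3).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_svr_learns_monotone_signal(self, rng):
        x = rng.uniform(0, 1, 60)[:, None]
        y = 3.0 * x.ravel() + rng.normal(0, 0.05, 60)
        model = rm.fit_model("SVR", x[:45], y[:45], seed=0)
        assert rm.r_squared(y[45:], model.predict(x[45:])) > 0.8


def _context(rng, n=24, bands=40):
    wl = np.arange(500.0, 500.0 + bands)
    base = 0.1 + 0.4 / (1.0 + np.exp(-(wl - 520.0) / 5.0))
    X = base + rng.normal(0, 0.01, (n, bands))
    Xd = prep.derivative_matrix(X, 1.0)
    trilat = pd.DataFrame(
        {"Dr": X[:, 25] * 0.1, "SDr": X[:, 30], "Rg": X[:, 5],
         "lambda_r": np.full(n, 520.0)},
    )
    y = X[:, 30] * 10 + rng.normal(0, 0.05, n)
    return rm.FeatureContext(wl, X, Xd, trilat), y


class TestFeatureAssembly:
    def test_os1_has_ten_columns(self, rng):
        ctx, y = _context(rng)
        sel = rm.fit_selectors(ctx, y, spa_n_max=4, seed=0)
        assert rm.build_features(ctx, sel, "OS1").shape[1] == 10
        assert rm.build_features(ctx, sel, "FDS1").shape[1] == 10
        assert rm.build_features(ctx, sel, "NDVI").shape[1] == 1
        assert rm.build_features(ctx, sel, "OS2").shape[1] == sel.os2.n_selected

    def test_impossible_tp_threshold_raises(self, rng):
        ctx, y = _context(rng)
        sel = rm.fit_selectors(ctx, y, tp_threshold=1.1, spa_n_max=4, seed=0)
        with pytest.raises(EmptyFeatureSetError):
            rm.build_features(ctx, sel, "TP")

    def test_tp_filter_keeps_only_correlated_parameters(self, rng):
        ctx, y = _context(rng)
        # SDr is (up to noise) proportional to y; lambda_r is constant
        sel = rm.fit_selectors(ctx, y, tp_threshold=0.6, spa_n_max=4, seed=0)
        assert "SDr" in sel.tp_columns
        assert "lambda_r" not in sel.tp_columns
        F = rm.build_features(ctx, sel, "TP")
        assert F.shape[1] == len(sel.tp_columns)

    def test_selectors_depend_on_training_partition_only(self, rng):
        # leakage guard: shuffling unseen (test) targets cannot change
        # the fitted selectors
        ctx, y = _context(rng, n=32)
        train, test = rm.split_train_test(32, seed=0)
        y_shuffled = y.copy()
        y_shuffled[test] = rng.permutation(y[test])
        a = rm.fit_selectors(ctx.take(train), y[train], spa_n_max=4, seed=0)
        b = rm.fit_selectors(ctx.take(train), y_shuffled[train], spa_n_max=4,
                             seed=0)
        np.testing.assert_array_equal(a.os1_bands, b.os1_bands)
        assert a.os2.selected == b.os2.selected
        assert (a.ndvi_pair.lambda1, a.ndvi_pair.lambda2) == \
            (b.ndvi_pair.lambda1, b.ndvi_pair.lambda2)


class TestEvaluate:
    def test_report_fields_and_split_ratio(self, rng):
        ctx, y = _context(rng, n=24)
        train, test = rm.split_train_test(24, seed=1)
        sel = rm.fit_selectors(ctx.take(train), y[train], spa_n_max=4, seed=1)
        F_train = rm.build_features(ctx.take(train), sel, "NDVI")
        F_test = rm.build_features(ctx.take(test), sel, "NDVI")
        rep = rm.evaluate("PLSR", F_train, y[train], F_test, y[test],
                          indicator="SPAD", group="CK", stage="budding",
                          feature_set="NDVI", seed=1)
        assert rep.n_train == 18 and rep.n_test == 6
        assert rep.r2_train <= 1.0 and rep.rmse_test >= 0.0
        assert rep.as_dict()["feature_set"] == "NDVI"
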