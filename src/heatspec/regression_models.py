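"""Regression of physiological indicators on spectral feature sets.

Three model families mirror common practice in vegetation spectroscopy:

* SVR — epsilon-SVR with an RBF kernel (epsilon = 0.01); penalty C and
  kernel width are picked by a seeded internal 5-fold grid search.
* RFR — bagged regression trees, 200 trees, minimum leaf size 5.
* PLSR — partial least squares with the component count chosen by
  internal cross-validation, capped at min(10, features, n_train - 1).

Feature sets: OS1/FDS1 (top-10 correlation bands of the original /
first-derivative spectra), OS2/FDS2 (SPA-selected bands), TP
(trilateral parameters whose training-set |r| with the indicator
exceeds a 0.6 cut), and NDVI/FDNDVI (the single optimised two-band
index value).  Selectors are always fitted on the training partition
only so that test metrics stay leakage-free.

Scoring is R^2 = 1 - SSE/SST and RMSE = sqrt(mean squared error); the
test-set R^2 uses the test-set mean in the denominator (the train-mean
convention is available via the ``baseline_mean`` argument).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from . import band_selection as bsel
from . import vegetation_indices as vi
from .errors import EmptyFeatureSetError, ValidationError

MODEL_KINDS = ("SVR", "RFR", "PLSR")
FEATURE_SETS = ("OS1", "OS2", "FDS1", "FDS2", "TP", "NDVI", "FDNDVI")

SVR_C_GRID = (0.1, 1.0, 10.0, 100.0)
SVR_GAMMA_GRID = tuple(np.logspace(-3, 1, 5))


# ---------------------------------------------------------------- metrics

def r_squared(y, yhat, baseline_mean: float | None = None) -> float:
    """Coefficient of determination; NaN when y is constant."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    mean = y.mean() if baseline_mean is None else baseline_mean
    sst = float(np.sum((y - mean) ** 2))
    if sst == 0.0:
        return float("nan")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def rmse(y, yhat) -> float:
    """Root mean square error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def amplitude_of_variation(v_treatment: float, v_control: float) -> float:
    """Percent change of a treatment value relative to control.

    eta = (T - CK) / CK * 100; NaN (undefined) when CK is zero.
    """
    if v_control == 0:
        return float("nan")
    return (v_treatment - v_control) / v_control * 100.0


# ------------------------------------------------------------------ split

def split_train_test(n_samples: int, test_fraction: float = 0.25, seed: int = 0):
    """Seeded random 3:1 split; returns sorted (train, test) index arrays."""
    n_test = math.floor(n_samples * test_fraction)
    if n_test < 2:
        raise ValidationError(
            f"n={n_samples} too small for a {test_fraction:.0%} test partition"
        )
    perm = np.random.default_rng(seed).permutation(n_samples)
    test = np.sort(perm[:n_test])
    train = np.sort(perm[n_test:])
    return train, test


# ----------------------------------------------------------------- models

class ConstantPredictor:
    """Degenerate-target fallback: predicts the training mean."""

    def __init__(self, value: float):
        self.value = float(value)

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.value)


def fit_model(kind: str, X_train: np.ndarray, y_train: np.ndarray, seed: int = 0,
              svr_c_grid=SVR_C_GRID, svr_gamma_grid=SVR_GAMMA_GRID,
              rfr_trees: int = 200, rfr_min_leaf: int = 5,
              pls_max_components: int = 10):
    """Fit one model kind; returns a fitted predictor with ``.predict``."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if X_train.ndim != 2:
        raise ValidationError("X_train must be 2-D")
    if np.ptp(y_train) == 0.0:
        return ConstantPredictor(y_train[0])
    if kind == "SVR":
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("svr", SVR(kernel="rbf", epsilon=0.01)),
        ])
        grid = GridSearchCV(
            pipe,
            {"svr__C": list(svr_c_grid), "svr__gamma": list(svr_gamma_grid)},
            cv=KFold(n_splits=5, shuffle=True, random_state=seed),
            scoring="neg_root_mean_squared_error",
            n_jobs=1,
        )
        grid.fit(X_train, y_train)
        return grid.best_estimator_
    if kind == "RFR":
        model = RandomForestRegressor(
            n_estimators=rfr_trees,
            min_samples_leaf=rfr_min_leaf,
            random_state=seed,
            n_jobs=1,
        )
        model.fit(X_train, y_train)
        return model
    if kind == "PLSR":
        cap = min(pls_max_components, X_train.shape[1], X_train.shape[0] - 1)
        cap = max(cap, 1)
        best_k, best_rmse = 1, np.inf
        if cap > 1:
            kf = KFold(n_splits=min(5, X_train.shape[0]), shuffle=True,
                       random_state=seed)
            for k in range(1, cap + 1):
                errs = []
                for tr, te in kf.split(X_train):
                    k_eff = min(k, tr.size - 1, X_train.shape[1])
                    pls = Pipeline([
                        ("scale", StandardScaler()),
                        ("pls", PLSRegression(n_components=max(k_eff, 1),
                                              scale=False)),
                    ])
                    pls.fit(X_train[tr], y_train[tr])
                    errs.append(np.mean(
                        (y_train[te] - pls.predict(X_train[te]).ravel()) ** 2))
                score = float(np.sqrt(np.mean(errs)))
                if score < best_rmse:
                    best_k, best_rmse = k, score
        model = Pipeline([
            ("scale", StandardScaler()),
            ("pls", PLSRegression(n_components=best_k, scale=False)),
        ])
        model.fit(X_train, y_train)
        return _RavelWrapper(model)
    raise ValidationError(f"unknown model kind {kind!r}")


class _RavelWrapper:
    """Flattens PLSRegression's (n, 1) predictions to 1-D."""

    def __init__(self, model):
        self.model = model

    def predict(self, X):
        return np.asarray(self.model.predict(X)).ravel()


# --------------------------------------------------------------- features

@dataclass
class FeatureContext:
    """All per-sample spectral inputs a feature set can draw on."""

    wavelengths: np.ndarray
    X_orig: np.ndarray
    X_fd: np.ndarray
    trilateral: pd.DataFrame

    def take(self, idx) -> "FeatureContext":
        return FeatureContext(
            self.wavelengths,
            self.X_orig[idx],
            self.X_fd[idx],
            self.trilateral.iloc[idx],
        )


@dataclass
class FittedSelectors:
    """Train-partition-fitted selectors for all seven feature sets."""

    os1_bands: np.ndarray
    fds1_bands: np.ndarray
    os2: bsel.SPAResult
    fds2: bsel.SPAResult
    spa_wavelengths: np.ndarray
    tp_columns: tuple
    ndvi_pair: vi.BandPairResult
    fdndvi_pair: vi.BandPairResult
    tp_threshold: float = 0.6
    tp_correlations: dict = field(default_factory=dict)


def fit_selectors(
    ctx: FeatureContext,
    y: np.ndarray,
    tp_threshold: float = 0.6,
    top_k: int = 10,
    spa_n_max: int = 10,
    spa_stride: int = 1,
    index_stride: int = 1,
    cv_folds: int = 5,
    seed: int = 0,
) -> FittedSelectors:
    """Fit every selector on (what should be) the training partition."""
    y = np.asarray(y, dtype=float)
    corr_os = bsel.correlation_spectrum(ctx.X_orig, ctx.wavelengths, y)
    corr_fd = bsel.correlation_spectrum(ctx.X_fd, ctx.wavelengths, y)
    os1 = bsel.top_k_bands(corr_os, k=top_k)
    fds1 = bsel.top_k_bands(corr_fd, k=top_k)

    spa_wl = ctx.wavelengths[::spa_stride]
    n_max = min(spa_n_max, ctx.X_orig.shape[0] - 1, spa_wl.size)
    os2 = bsel.spa_optimize(ctx.X_orig[:, ::spa_stride], y, n_max,
                            cv_folds=cv_folds, seed=seed)
    fds2 = bsel.spa_optimize(ctx.X_fd[:, ::spa_stride], y, n_max,
                             cv_folds=cv_folds, seed=seed)

    tp_corr = {}
    tp_cols = []
    for col in ctx.trilateral.columns:
        vals = ctx.trilateral[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.ptp(vals) == 0.0:
            continue
        r = float(np.corrcoef(vals, y)[0, 1])
        tp_corr[col] = r
        if abs(r) > tp_threshold:
            tp_cols.append(col)

    ndvi = vi.optimize_band_pair(ctx.X_orig, ctx.wavelengths, y, "NDVI",
                                 stride=index_stride)
    fdndvi = vi.optimize_band_pair(ctx.X_fd, ctx.wavelengths, y, "FDNDVI",
                                   stride=index_stride)
    return FittedSelectors(
        os1_bands=os1, fds1_bands=fds1, os2=os2, fds2=fds2,
        spa_wavelengths=spa_wl, tp_columns=tuple(tp_cols),
        ndvi_pair=ndvi, fdndvi_pair=fdndvi,
        tp_threshold=tp_threshold, tp_correlations=tp_corr,
    )


def _columns_at(X: np.ndarray, wavelengths: np.ndarray, bands) -> np.ndarray:
    idx = [int(np.flatnonzero(np.isclose(wavelengths, b))[0]) for b in bands]
    return X[:, idx]


def build_features(
    ctx: FeatureContext, selectors: FittedSelectors, feature_set: str
) -> np.ndarray:
    """Design matrix for one feature set, using fitted selectors only."""
    if feature_set == "OS1":
        return _columns_at(ctx.X_orig, ctx.wavelengths, selectors.os1_bands)
    if feature_set == "FDS1":
        return _columns_at(ctx.X_fd, ctx.wavelengths, selectors.fds1_bands)
    if feature_set == "OS2":
        bands = selectors.spa_wavelengths[list(selectors.os2.selected)]
        return _columns_at(ctx.X_orig, ctx.wavelengths, bands)
    if feature_set == "FDS2":
        bands = selectors.spa_wavelengths[list(selectors.fds2.selected)]
        return _columns_at(ctx.X_fd, ctx.wavelengths, bands)
    if feature_set == "TP":
        if not selectors.tp_columns:
            raise EmptyFeatureSetError(
                f"no trilateral parameter exceeds |r| > "
                f"{selectors.tp_threshold}; lower the threshold"
            )
        return ctx.trilateral[list(selectors.tp_columns)].to_numpy(dtype=float)
    if feature_set == "NDVI":
        return vi.index_feature(ctx.X_orig, ctx.wavelengths,
                                selectors.ndvi_pair)[:, None]
    if feature_set == "FDNDVI":
        return vi.index_feature(ctx.X_fd, ctx.wavelengths,
                                selectors.fdndvi_pair)[:, None]
    raise ValidationError(f"unknown feature set {feature_set!r}")


# ----------------------------------------------------------------- report

@dataclass
class ModelReport:
    """One (model, indicator, group, feature set) evaluation cell."""

    model: str
    indicator: str
    group: str
    stage: str
    feature_set: str
    r2_train: float
    rmse_train: float
    r2_test: float
    rmse_test: float
    n_train: int
    n_test: int
    seed: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def evaluate(
    kind: str,
    X_train, y_train, X_test, y_test,
    indicator: str = "", group: str = "", stage: str = "",
    feature_set: str = "", seed: int = 0,
) -> ModelReport:
    """Fit one model and score train/test partitions."""
    model = fit_model(kind, X_train, y_train, seed=seed)
    pred_train = model.predict(X_train)
    pred_test = model.predict(X_test)
    return ModelReport(
        model=kind, indicator=indicator, group=group, stage=stage,
        feature_set=feature_set,
        r2_train=r_squared(y_train, pred_train),
        rmse_train=rmse(y_train, pred_train),
        r2_test=r_squared(y_test, pred_test),
        rmse_test=rmse(y_test, pred_test),
        n_train=int(len(y_train)), n_test=int(len(y_test)), seed=seed,
    )
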