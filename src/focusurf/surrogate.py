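"""Surrogate models of the simulation sweep and their evaluation metrics.

Four regressors map the three sweep inputs (x-element count, y-element
count, focal depth) to the three simulated responses (maximum pressure,
power deposition and temperature in the target layer): multiple linear
regression, a CART decision tree (20 leaf nodes), epsilon-insensitive SVR
with an RBF kernel fitted per target and stacked, and a 1000-tree random
forest. Features and targets are min-max scaled to [0, 1] with parameters
learned on the training split only; all reported metrics live on the
scaled target space.

Metrics pool the three scaled targets: MSE/RMSE and R^2 over all
(row, target) values, and information criteria from a Gaussian
log-likelihood with the per-row mean squared error as the variance
estimate,

    ln L = -(N/2) * (ln(2 pi MSE) + 1),
    AIC  = 2k - 2 ln L,
    BIC  = k ln(N) - 2 ln L,

with N the number of evaluation rows and k = 3 the number of input
features. Under this shared likelihood BIC - AIC = k (ln N - 2) for every
model, which is the relationship the criteria comparisons rely on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .sweep import FEATURES, TARGETS

log = logging.getLogger(__name__)

N_FEATURES = 3  # k in the information criteria

MODEL_KINDS = ("linear", "cart", "svr", "random_forest")

#: hyperparameter grids offered to grid_search (the default ModelSpec
#: settings belong to them; configurable through the scenario's surrogate block)
DEFAULT_GRIDS = {
    "cart": {"max_leaf_nodes": [5, 10, 20, 50]},
    "svr": {"C": [1, 5, 10, 100], "epsilon": [0.05, 0.1, 0.2],
            "gamma": ["scale", "auto"]},
    "random_forest": {"n_estimators": [100, 500, 1000]},
}


def split(table: pd.DataFrame, test_fraction: float = 0.2,
          seed: int = 42) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform random 80/20 row split (test size = ceil(fraction * N))."""
    if len(table) < 5:
        raise ValueError("need at least 5 rows to split")
    train, test = train_test_split(table, test_size=test_fraction,
                                   random_state=seed)
    return train.reset_index(drop=True), test.reset_index(drop=True)


@dataclass
class MinMaxScalerParams:
    """Per-column min/max learned on the training split.

    Applies x' = (x - min) / (max - min) without clipping, so values
    outside the training range map outside [0, 1].
    """

    columns: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, table: pd.DataFrame, columns: list[str]) -> "MinMaxScalerParams":
        mins = table[columns].min().to_numpy(float)
        maxs = table[columns].max().to_numpy(float)
        if np.any(maxs <= mins):
            bad = [c for c, lo, hi in zip(columns, mins, maxs) if hi <= lo]
            raise ValueError(f"constant column(s), cannot min-max scale: {bad}")
        return cls(columns=list(columns), mins=mins, maxs=maxs)

    def apply(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.columns].to_numpy(float)
        return (x - self.mins) / (self.maxs - self.mins)

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        return np.asarray(scaled, float) * (self.maxs - self.mins) + self.mins


@dataclass
class ModelSpec:
    """Model family plus hyperparameters."""

    kind: str
    cart_max_leaf_nodes: int = 20
    rf_n_estimators: int = 1000
    # per-target SVR settings (pressure, power, temperature order = TARGETS)
    svr_params: dict = dc_field(default_factory=lambda: {
        "max_pressure_pa": {"C": 5, "epsilon": 0.1, "gamma": "scale"},
        "max_power_w_m3": {"C": 100, "epsilon": 0.1, "gamma": "auto"},
        "max_temperature_c": {"C": 5, "epsilon": 0.1, "gamma": "scale"},
    })
    seed: int = 42

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")


class Predictor:
    """Fitted scaled-feature -> scaled-3-target mapping."""

    def __init__(self, spec: ModelSpec, estimators):
        self.spec = spec
        self._estimators = estimators  # one multi-output model, or per-target list

    def predict(self, x_scaled: np.ndarray) -> np.ndarray:
        x_scaled = np.asarray(x_scaled, float)
        if self.spec.kind == "svr":
            cols = [est.predict(x_scaled) for est in self._estimators]
            return np.column_stack(cols)  # stacked per-target outputs
        out = self._estimators.predict(x_scaled)
        return np.asarray(out, float)


def fit(spec: ModelSpec, x_train: np.ndarray, y_train: np.ndarray) -> Predictor:
    """Fit one model on scaled training data (y has the 3 target columns)."""
    x_train = np.asarray(x_train, float)
    y_train = np.asarray(y_train, float)
    if len(x_train) < 2 or np.allclose(y_train.std(axis=0), 0):
        raise ValueError("degenerate training set")
    if spec.kind == "linear":
        est = LinearRegression().fit(x_train, y_train)
    elif spec.kind == "cart":
        est = DecisionTreeRegressor(max_leaf_nodes=spec.cart_max_leaf_nodes,
                                    random_state=spec.seed).fit(x_train, y_train)
    elif spec.kind == "random_forest":
        est = RandomForestRegressor(n_estimators=spec.rf_n_estimators,
                                    bootstrap=True,
                                    random_state=spec.seed).fit(x_train, y_train)
    else:  # svr: one RBF machine per target, stacked at prediction time
        est = []
        for j, target in enumerate(TARGETS):
            p = spec.svr_params[target]
            est.append(SVR(kernel="rbf", C=p["C"], epsilon=p["epsilon"],
                           gamma=p["gamma"]).fit(x_train, y_train[:, j]))
    return Predictor(spec, est)


def grid_search(kind: str, x_train: np.ndarray, y_train: np.ndarray,
                grid: dict | None = None, folds: int = 5,
                seed: int = 42) -> dict:
    """5-fold CV grid search; ties resolved toward the simpler model.

    "Simpler" means earlier in the (ascending-complexity) grid ordering:
    fewer leaves/trees, smaller C. Returns the winning parameter dict plus
    its mean CV MSE under key ``"cv_mse"``.
    """
    if grid is None:
        grid = DEFAULT_GRIDS.get(kind)
    if not grid:
        raise ValueError(f"empty hyperparameter grid for {kind!r}")
    if kind == "linear":
        raise ValueError("linear regression has no hyperparameters to search")
    if kind == "cart":
        base = DecisionTreeRegressor(random_state=seed)
    elif kind == "random_forest":
        base = RandomForestRegressor(random_state=seed, bootstrap=True)
    else:
        base = SVR(kernel="rbf")
        y_train = np.asarray(y_train, float)
        if y_train.ndim == 2:
            if y_train.shape[1] != 1:
                raise ValueError("search SVR per target (pass one y column)")
            y_train = y_train[:, 0]
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(base, grid, scoring="neg_mean_squared_error", cv=cv)
    gs.fit(np.asarray(x_train, float), y_train)
    results = gs.cv_results_
    mses = -results["mean_test_score"]
    best = float(mses.min())
    # first (simplest) parameter set within numerical reach of the optimum
    idx = int(np.flatnonzero(mses <= best * (1 + 1e-12) + 1e-15)[0])
    params = dict(results["params"][idx])
    params["cv_mse"] = float(mses[idx])
    return params


def metrics(y_true_scaled: np.ndarray, y_pred_scaled: np.ndarray,
            k: int = N_FEATURES) -> dict:
    """Pooled RMSE, R^2, AIC and BIC over the scaled targets.

    N is the number of rows; errors are pooled across the 3 target
    columns for MSE/RMSE/R^2, and the Gaussian log-likelihood uses the
    pooled MSE (equal to the mean per-row MSE) as its variance.
    """
    yt = np.asarray(y_true_scaled, float)
    yp = np.asarray(y_pred_scaled, float)
    if yt.shape != yp.shape:
        raise ValueError("shape mismatch between truth and prediction")
    n_rows = yt.shape[0]
    resid2 = (yt - yp) ** 2
    mse = float(resid2.mean())
    rmse = math.sqrt(mse)
    ss_tot = float(((yt - yt.mean()) ** 2).sum())
    r2 = 1.0 - float(resid2.sum()) / ss_tot if ss_tot > 0 else float("nan")
    if mse > 0:
        loglik = -(n_rows / 2.0) * (math.log(2 * math.pi * mse) + 1.0)
        aic = 2 * k - 2 * loglik
        bic = k * math.log(n_rows) - 2 * loglik
    else:
        loglik = aic = bic = float("-inf") if mse == 0 else float("nan")
        aic = bic = float("-inf")
    return {"rmse": rmse, "r2": r2, "aic": aic, "bic": bic,
            "log_likelihood": loglik, "n": n_rows, "k": k}


def bic_from_aic(aic: float, n: int, k: int = N_FEATURES) -> float:
    """BIC implied by an AIC value under the shared Gaussian likelihood.

    Both criteria subtract the same 2 ln L, so
    BIC = AIC - 2k + k ln N = AIC + k (ln N - 2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    loglik = (2 * k - aic) / 2.0
    return k * math.log(n) - 2 * loglik


def test_split_size(n_total: int, test_fraction: float = 0.2) -> int:
    """Held-out row count under the ceiling rule, ceil(fraction * N)."""
    return math.ceil(test_fraction * n_total)


@dataclass
class ModelReport:
    """Per-model metric bundles on one or more named evaluation sets."""

    entries: dict  # {eval_set: {model_kind: metrics dict}}
    seed: int
    scaler_features: MinMaxScalerParams | None = None
    scaler_targets: MinMaxScalerParams | None = None

    def to_frame(self, eval_set: str = "test") -> pd.DataFrame:
        rows = []
        for kind in MODEL_KINDS:
            m = self.entries[eval_set][kind]
            rows.append({"model": kind, "RMSE": m["rmse"], "R2": m["r2"],
                         "AIC": m["aic"], "BIC": m["bic"]})
        return pd.DataFrame(rows)

    def best_model(self, eval_set: str = "test") -> str:
        ms = self.entries[eval_set]
        return max(ms, key=lambda kind: ms[kind]["r2"])


def evaluate_all(dataset: pd.DataFrame, seed: int = 42,
                 external: pd.DataFrame | None = None,
                 test_fraction: float = 0.2,
                 specs: dict[str, ModelSpec] | None = None
                 ) -> tuple[ModelReport, dict[str, Predictor]]:
    """Train all four models and report metrics on the held-out split.

    ``external`` rows (e.g. off-grid simulations) are scored with the same
    training-split scalers; rows whose (nx, ny, focus_mm) key appears in
    the dataset are rejected because they would leak training information.
    """
    if external is not None:
        keys = set(map(tuple, dataset[FEATURES].to_numpy().tolist()))
        ext_keys = set(map(tuple, external[FEATURES].to_numpy().tolist()))
        overlap = keys & ext_keys
        if overlap:
            raise ValueError(f"external rows overlap the dataset: {sorted(overlap)[:3]}")

    train, test = split(dataset, test_fraction=test_fraction, seed=seed)
    sx = MinMaxScalerParams.fit(train, FEATURES)
    sy = MinMaxScalerParams.fit(train, TARGETS)
    xtr, ytr = sx.apply(train), sy.apply(train)

    if specs is None:
        specs = {kind: ModelSpec(kind=kind, seed=seed) for kind in MODEL_KINDS}

    eval_sets = {"test": test}
    if external is not None:
        eval_sets["external"] = external

    predictors: dict[str, Predictor] = {}
    entries: dict[str, dict] = {name: {} for name in eval_sets}
    for kind in MODEL_KINDS:
        pred = fit(specs[kind], xtr, ytr)
        predictors[kind] = pred
        for name, table in eval_sets.items():
            m = metrics(sy.apply(table), pred.predict(sx.apply(table)))
            entries[name][kind] = m
            log.info("%s/%s: RMSE=%.4f R2=%.4f AIC=%.2f BIC=%.2f",
                     name, kind, m["rmse"], m["r2"], m["aic"], m["bic"])

    report = ModelReport(entries=entries, seed=seed,
                         scaler_features=sx, scaler_targets=sy)
    return report, predictors
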