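"""Boosted-tree regression of RSEI on urban-rural construction features.

Fits RSEI ~ (NDVI_nor, NDISI_nor, PB, PopD, BH) with an XGBoost gradient
boosted tree ensemble, tuned by seeded random search over a fixed
hyperparameter space with 5-fold cross-validation, and explains the fit with
exact tree-Shapley attributions and partial-dependence marginal-effect
curves.

The learner itself is library-backed (XGBoost); the module's own substance is
the sampling/tuning protocol, the attribution bookkeeping (efficiency checked
against the raw model margin), and the curve construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import KFold

from .raster_core import Raster
from .rsei import RSEIResult
from .spectral_indices import WaterMask

__all__ = [
    "FEATURE_NAMES",
    "FeatureState",
    "FeatureTable",
    "TuningSpace",
    "TrainedModel",
    "build_feature_table",
    "tune_hyperparameters",
    "train",
    "shap_importance",
    "marginal_effect_curve",
]

FEATURE_NAMES = ("ndvi_nor", "ndisi_nor", "pb", "popd", "bh")


@dataclass
class FeatureState:
    """The five per-pixel construction features; mutable scenario state.

    ndvi_nor and ndisi_nor lie in [0, 1], pb in [0, 100] percent, popd
    (persons per cell) and bh (metres) are nonnegative.
    """

    ndvi_nor: Raster
    ndisi_nor: Raster
    pb: Raster
    popd: Raster
    bh: Raster

    def __post_init__(self) -> None:
        grid = self.ndvi_nor.grid
        for name in FEATURE_NAMES:
            if getattr(self, name).grid != grid:
                raise ValueError("all five feature rasters must share one grid")
        self._check_ranges()

    def _check_ranges(self) -> None:
        for name, lo, hi in (
            ("ndvi_nor", 0.0, 1.0),
            ("ndisi_nor", 0.0, 1.0),
            ("pb", 0.0, 100.0),
            ("popd", 0.0, np.inf),
            ("bh", 0.0, np.inf),
        ):
            r: Raster = getattr(self, name)
            v = r.masked_values()
            if v.size and (v.min() < lo - 1e-9 or v.max() > hi + 1e-9):
                raise ValueError(f"feature {name} outside its range [{lo}, {hi}]")

    @property
    def grid(self):
        return self.ndvi_nor.grid

    @property
    def valid(self) -> np.ndarray:
        return np.logical_and.reduce(
            [getattr(self, n).valid for n in FEATURE_NAMES]
        )

    def copy(self) -> "FeatureState":
        return FeatureState(*(getattr(self, n).copy() for n in FEATURE_NAMES))

    def as_matrix(self, rows: np.ndarray) -> np.ndarray:
        """(len(rows), 5) feature matrix at the given flat cell indices."""
        return np.column_stack(
            [getattr(self, n).values.ravel()[rows] for n in FEATURE_NAMES]
        )


@dataclass
class FeatureTable:
    """Sampled training rows: 5 features + RSEI target, with provenance."""

    frame: pd.DataFrame  # columns FEATURE_NAMES + ['rsei']
    rows: np.ndarray  # flat cell indices sampled
    seed: int

    def __post_init__(self) -> None:
        expected = list(FEATURE_NAMES) + ["rsei"]
        if list(self.frame.columns) != expected:
            raise ValueError(f"feature table columns must be {expected}")
        if self.frame.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(FEATURE_NAMES)].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.frame["rsei"].to_numpy()


@dataclass(frozen=True)
class TuningSpace:
    """Closed search intervals per hyperparameter (integer-valued where noted)."""

    eta: tuple[float, float] = (0.0, 1.0)
    gamma: tuple[float, float] = (0.0, 20.0)
    max_depth: tuple[int, int] = (1, 20)
    min_child_weight: tuple[float, float] = (1.0, 10.0)
    subsample: tuple[float, float] = (0.5, 1.0)
    colsample_bytree: tuple[float, float] = (0.5, 1.0)
    nrounds: tuple[int, int] = (50, 300)

    INTEGER = ("max_depth", "nrounds")

    def sample(self, rng: np.random.Generator) -> dict:
        out = {}
        for name in (
            "eta", "gamma", "max_depth", "min_child_weight",
            "subsample", "colsample_bytree", "nrounds",
        ):
            lo, hi = getattr(self, name)
            v = rng.uniform(lo, hi)
            out[name] = int(round(v)) if name in self.INTEGER else float(v)
        return out

    def contains(self, hp: dict) -> bool:
        for name in (
            "eta", "gamma", "max_depth", "min_child_weight",
            "subsample", "colsample_bytree", "nrounds",
        ):
            lo, hi = getattr(self, name)
            if not (lo <= hp[name] <= hi):
                return False
        return True


@dataclass
class TrainedModel:
    """Fitted boosted-tree regressor with a deterministic predict contract."""

    booster: xgb.Booster
    hyperparameters: dict
    training_rmse: float
    cv_rmse: float | None = None
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def _dmatrix(self, X: np.ndarray) -> xgb.DMatrix:
        return xgb.DMatrix(np.asarray(X, dtype=float), feature_names=list(self.feature_names))

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Unclamped model margin (used for Shapley efficiency checks)."""
        return self.booster.predict(self._dmatrix(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """RSEI prediction, clamped to the index's [0, 1] range."""
        return np.clip(self.predict_raw(X), 0.0, 1.0)

    def save(self, path) -> None:
        self.booster.save_model(str(path))


def _booster_params(hp: dict, seed: int) -> tuple[dict, int]:
    params = {
        "eta": hp["eta"],
        "gamma": hp["gamma"],
        "max_depth": int(hp["max_depth"]),
        "min_child_weight": hp["min_child_weight"],
        "subsample": hp["subsample"],
        "colsample_bytree": hp["colsample_bytree"],
        "objective": "reg:squarederror",
        "seed": int(seed) % (2**31),
        "nthread": 1,
    }
    return params, int(hp["nrounds"])


def build_feature_table(
    fs: FeatureState,
    rsei: RSEIResult,
    water: WaterMask | None = None,
    n: int | None = None,
    seed: int = 0,
) -> FeatureTable:
    """Uniform seeded sample (without replacement) of usable cells.

    Usable cells are valid in all five features and the RSEI raster and not
    water.  ``n=None`` takes every usable cell.
    """
    if fs.grid != rsei.rsei.grid:
        raise ValueError("features and RSEI are on different grids")
    usable = fs.valid & rsei.rsei.valid
    if water is not None:
        usable &= ~water.is_water
    pool = np.flatnonzero(usable.ravel())
    if n is None:
        n = pool.size
    if n > pool.size:
        raise ValueError(f"requested {n} samples but only {pool.size} usable cells")
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(pool, size=n, replace=False))
    frame = pd.DataFrame(fs.as_matrix(rows), columns=list(FEATURE_NAMES))
    frame["rsei"] = rsei.rsei.values.ravel()[rows]
    return FeatureTable(frame, rows, seed)


def tune_hyperparameters(
    t: FeatureTable,
    space: TuningSpace | None = None,
    k: int = 5,
    budget: int = 60,
    seed: int = 0,
) -> tuple[dict, float]:
    """Seeded random search over the tuning space, scored by k-fold CV RMSE.

    Draws ``budget`` candidates uniformly from the space (integer parameters
    rounded), evaluates the mean held-out RMSE over k seeded folds, and
    returns the argmin candidate with its CV RMSE.
    """
    space = space or TuningSpace()
    if budget < 1:
        raise ValueError("budget must be at least 1")
    if len(t.frame) < 2 * k:
        raise ValueError(f"need at least {2 * k} rows for {k}-fold CV")
    rng = np.random.default_rng(seed)
    X, y = t.X, t.y
    best_hp, best_rmse = None, np.inf
    for _ in range(budget):
        hp = space.sample(rng)
        rmse = _cv_rmse(X, y, hp, k, seed)
        if rmse < best_rmse:
            best_hp, best_rmse = hp, rmse
    return best_hp, float(best_rmse)


def _cv_rmse(X: np.ndarray, y: np.ndarray, hp: dict, k: int, seed: int) -> float:
    params, nrounds = _booster_params(hp, seed)
    folds = KFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    errs = []
    for tr, te in folds.split(X):
        dtrain = xgb.DMatrix(X[tr], label=y[tr], feature_names=list(FEATURE_NAMES))
        dtest = xgb.DMatrix(X[te], feature_names=list(FEATURE_NAMES))
        booster = xgb.train(params, dtrain, num_boost_round=nrounds)
        pred = booster.predict(dtest)
        errs.append(np.sqrt(np.mean((pred - y[te]) ** 2)))
    return float(np.mean(errs))


def train(
    t: FeatureTable,
    hp: dict | None = None,
    space: TuningSpace | None = None,
    cv_rmse: float | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the boosted-tree ensemble on all rows of the feature table."""
    space = space or TuningSpace()
    if hp is None:
        hp = {
            "eta": 0.1, "gamma": 0.0, "max_depth": 6, "min_child_weight": 1.0,
            "subsample": 1.0, "colsample_bytree": 1.0, "nrounds": 200,
        }
    if not space.contains(hp):
        raise ValueError("hyperparameters outside the tuning space")
    y = t.y
    if np.ptp(y) == 0:
        warnings.warn("degenerate constant target; model will predict the constant")
    params, nrounds = _booster_params(hp, seed)
    dtrain = xgb.DMatrix(t.X, label=y, feature_names=list(FEATURE_NAMES))
    booster = xgb.train(params, dtrain, num_boost_round=nrounds)
    pred = booster.predict(dtrain)
    training_rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    return TrainedModel(booster, dict(hp), training_rmse, cv_rmse)


def shap_importance(
    m: TrainedModel, t: FeatureTable
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Exact tree-Shapley attributions and the mean-|value| importance ranking.

    Returns (ranking frame, per-row attributions (n, 5), per-row base values).
    Efficiency holds per row: base + sum(attributions) equals the raw model
    margin for that row.
    """
    dmat = xgb.DMatrix(t.X, feature_names=list(FEATURE_NAMES))
    contribs = m.booster.predict(dmat, pred_contribs=True)
    base = contribs[:, -1]
    attr = contribs[:, :-1]
    mean_abs = np.abs(attr).mean(axis=0)
    ranking = (
        pd.DataFrame({"feature": list(FEATURE_NAMES), "mean_abs_shap": mean_abs})
        .sort_values("mean_abs_shap", ascending=False)
        .reset_index(drop=True)
    )
    return ranking, attr, base


def marginal_effect_curve(
    m: TrainedModel,
    t: FeatureTable,
    feature: str,
    grid_points: int = 41,
    lo: float | None = None,
    hi: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marginal effect of one feature on predicted RSEI.

    Returns (partial-dependence curve, Shapley-dependence scatter).  The PD
    curve sets the feature to each grid value in every row and averages the
    clamped predictions; the scatter pairs each row's observed feature value
    with its Shapley attribution.
    """
    if feature not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature!r}")
    if grid_points < 2:
        raise ValueError("need at least 2 grid points")
    j = FEATURE_NAMES.index(feature)
    X = t.X
    if lo is None:
        lo = float(X[:, j].min())
    if hi is None:
        hi = float(X[:, j].max())
    grid = np.linspace(lo, hi, grid_points)
    pd_vals = np.empty(grid_points)
    Xmod = X.copy()
    for i, v in enumerate(grid):
        Xmod[:, j] = v
        pd_vals[i] = float(m.predict(Xmod).mean())
    curve = pd.DataFrame({feature: grid, "mean_predicted_rsei": pd_vals})
    _, attr, _ = shap_importance(m, t)
    scatter = pd.DataFrame({feature: X[:, j], "shap_value": attr[:, j]})
    return curve, scatter
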