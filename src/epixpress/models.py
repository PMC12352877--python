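"""Regression families behind one train/predict surface.

:class:`ExpressionRegressor` is a scikit-learn estimator wrapping the five
regression families benchmarked for expression prediction from flattened
bin-level signal: gradient-boosted trees (XGBoost, the reference family),
classic gradient boosting, linear least squares, support-vector regression,
and a one-hidden-layer multilayer perceptron.  All families minimize mean
squared error on the training genes; model selection uses validation Pearson
correlation (see :func:`grid_search`).

Fitting on a :class:`~epixpress.dataset.FlatDesignMatrix` records a
fingerprint (column count and column-map digest) that :meth:`predict`
enforces, so a model trained on one feature layout cannot silently consume
another.
"""

from __future__ import annotations

import itertools
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import FlatDesignMatrix

FAMILIES = (
    "gradient_boosted_trees",
    "classic_gradient_boosting",
    "linear_least_squares",
    "support_vector",
    "multilayer_perceptron",
)

#: Families exposing split-gain importances.
TREE_FAMILIES = ("gradient_boosted_trees", "classic_gradient_boosting")

# Defaults chosen for the 5,000-gene × 200-column study size; grid_search can
# refit any of them.
_DEFAULTS: dict[str, dict] = {
    "gradient_boosted_trees": dict(
        n_estimators=300, max_depth=4, learning_rate=0.1, subsample=1.0,
        tree_method="hist", objective="reg:squarederror", n_jobs=1, verbosity=0,
    ),
    "classic_gradient_boosting": dict(n_estimators=200, max_depth=3, learning_rate=0.1),
    "linear_least_squares": dict(),
    "support_vector": dict(kernel="rbf", C=1.0, epsilon=0.1),
    "multilayer_perceptron": dict(
        hidden_layer_sizes=(128,), early_stopping=True, max_iter=300,
        validation_fraction=0.1, n_iter_no_change=10,
    ),
}


def _build_estimator(family: str, hyperparams: Mapping | None, random_state: int):
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")
    params = dict(_DEFAULTS[family])
    params.update(hyperparams or {})
    if family == "gradient_boosted_trees":
        import xgboost as xgb

        est = xgb.XGBRegressor(random_state=random_state)
    elif family == "classic_gradient_boosting":
        from sklearn.ensemble import GradientBoostingRegressor

        est = GradientBoostingRegressor(random_state=random_state)
    elif family == "linear_least_squares":
        from sklearn.linear_model import LinearRegression

        est = LinearRegression()
    elif family == "support_vector":
        from sklearn.svm import SVR

        est = SVR()
    else:
        from sklearn.neural_network import MLPRegressor

        est = MLPRegressor(random_state=random_state)
    known = set(est.get_params())
    unknown = sorted(set(params) - known)
    if unknown:
        raise ValueError(f"unknown hyperparameters for {family}: {unknown}")
    est.set_params(**params)
    return est


class ExpressionRegressor(RegressorMixin, BaseEstimator):
    """Uniform fit/predict wrapper over the benchmarked regression families.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    hyperparams : dict, optional
        Overrides for the family's defaults; unknown names raise at fit time.
    random_state : int
        Single integer seed routed to every stochastic component of the family.
    """

    def __init__(
        self,
        family: str = "gradient_boosted_trees",
        hyperparams: dict | None = None,
        random_state: int = 0,
    ):
        self.family = family
        self.hyperparams = hyperparams
        self.random_state = random_state

    @staticmethod
    def _coerce(X) -> tuple[np.ndarray, str | None]:
        if isinstance(X, FlatDesignMatrix):
            return X.matrix, X.column_map.digest()
        return np.asarray(X, dtype=float), None

    def fit(self, X, y):
        matrix, digest = self._coerce(X)
        y = np.asarray(y, dtype=float).ravel()
        if matrix.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(y) != matrix.shape[0]:
            raise ValueError(
                f"X has {matrix.shape[0]} rows but y has {len(y)} values"
            )
        if len(y) == 0:
            raise ValueError("cannot fit on an empty gene set")
        if not (np.all(np.isfinite(matrix)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite (no missing values)")
        self.model_ = _build_estimator(self.family, self.hyperparams, self.random_state)
        self.model_.fit(matrix, y)
        self.n_features_in_ = matrix.shape[1]
        self.column_map_digest_ = digest
        self.n_training_genes_ = matrix.shape[0]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        matrix, digest = self._coerce(X)
        if matrix.shape[1] != self.n_features_in_:
            raise ValueError(
                f"column count mismatch: model expects {self.n_features_in_}, "
                f"got {matrix.shape[1]}"
            )
        if digest is not None and self.column_map_digest_ is not None:
            if digest != self.column_map_digest_:
                raise ValueError("column map differs from the one used in training")
        return np.asarray(self.model_.predict(matrix), dtype=float)

    @property
    def feature_importances_(self) -> np.ndarray:
        check_is_fitted(self, "model_")
        if self.family not in TREE_FAMILIES:
            raise AttributeError(
                f"family {self.family!r} does not expose split-gain importances"
            )
        return np.asarray(self.model_.feature_importances_, dtype=float)

    def fingerprint(self) -> dict:
        check_is_fitted(self, "model_")
        return {
            "family": self.family,
            "hyperparams": self.hyperparams or {},
            "random_state": self.random_state,
            "n_training_genes": self.n_training_genes_,
            "n_columns": self.n_features_in_,
            "column_map_digest": self.column_map_digest_,
        }


def fit(
    family: str, X, y, hyperparams: dict | None = None, random_state: int = 0
) -> ExpressionRegressor:
    """Functional wrapper: fit one family on (X, y)."""
    return ExpressionRegressor(
        family=family, hyperparams=hyperparams, random_state=random_state
    ).fit(X, y)


def save_model(model: ExpressionRegressor, path: str) -> None:
    """Serialize a fitted model plus a JSON sidecar with its spec/fingerprint."""
    import joblib

    joblib.dump(model, path)
    with open(str(path) + ".json", "w") as fh:
        json.dump(model.fingerprint(), fh, indent=2)


def load_model(path: str) -> ExpressionRegressor:
    import joblib

    return joblib.load(path)


def grid_search(
    family: str,
    grid: Mapping[str, Sequence],
    train: tuple,
    val: tuple,
    base_hyperparams: dict | None = None,
    random_state: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search maximizing validation Pearson correlation.

    Grid points are enumerated in deterministic lexicographic order (sorted
    hyperparameter names, values in the order given); ties keep the first
    maximizer.  Returns (best hyperparameter dict, table of all points with
    their validation PCC).
    """
    from scipy.stats import pearsonr

    if not grid:
        raise ValueError("hyperparameter grid is empty")
    X_tr, y_tr = train
    X_val, y_val = val
    keys = sorted(grid)
    rows, best, best_pcc = [], None, -np.inf
    for values in itertools.product(*(grid[k] for k in keys)):
        point = dict(zip(keys, values))
        hp = {**(base_hyperparams or {}), **point}
        model = ExpressionRegressor(family, hp, random_state).fit(X_tr, y_tr)
        yhat = model.predict(X_val)
        pcc = float(pearsonr(np.asarray(y_val, dtype=float).ravel(), yhat)[0])
        rows.append({**point, "val_pcc": pcc})
        if pcc > best_pcc:  # strict: ties keep the earlier point
            best, best_pcc = hp, pcc
    return best, pd.DataFrame(rows)
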