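"""AGE prediction models: feature selection, MLR, RBF-SVR and their hybrid.

The predictive core maps corrected corneal fluorescence intensity (plus
BMI and QC covariates) to serum AGE concentration (ug/mL).  Three models
are exposed through one scikit-learn style estimator:

* multiple linear regression (MLR), fitted by ordinary least squares on
  the raw selected features;
* epsilon-insensitive support vector regression with an RBF kernel
  (C = 10, gamma = 0.1, epsilon = 0.01), fitted on standardized features
  because a fixed kernel width is meaningless across arbitrary scales;
* their fixed convex combination ``y = w_mlr * MLR(x) + w_svr * SVR(x)``
  with default weights (0.7, 0.3).

Feature selection drops features with near-zero variance or weak Pearson
correlation with the serum reference (|r| < 0.3 by default), which also
serves as the collinearity control for the linear model.

:class:`HybridAGERegressor` follows the scikit-learn estimator contract
(``fit``/``predict``/``get_params``; fitted attributes carry a trailing
underscore) and composes with sklearn model selection.  The module-level
functions are thin wrappers kept for pipeline-style use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import train_test_split
from sklearn.svm import SVR
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import (
    CollinearFeaturesError,
    ConfigurationError,
    EmptySelectionError,
    InputError,
    SampleSizeError,
    SchemaVersionError,
)

__all__ = [
    "SelectionRule",
    "SvrHyperparams",
    "HybridAGERegressor",
    "HybridModelDocument",
    "select_features",
    "fit_mlr",
    "fit_svr",
    "predict_hybrid",
    "evaluate_models",
]

MODEL_SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class SelectionRule:
    """Variance floor + minimum |Pearson r| with the serum reference."""

    variance_floor: float = 1e-8
    min_abs_corr: float = 0.3

    def __post_init__(self) -> None:
        if self.variance_floor < 0:
            raise ConfigurationError("variance_floor must be >= 0")
        if not 0.0 <= self.min_abs_corr <= 1.0:
            raise ConfigurationError("min_abs_corr must lie in [0, 1]")


@dataclass(frozen=True)
class SvrHyperparams:
    C: float = 10.0
    gamma: float = 0.1
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0 or self.epsilon <= 0:
            raise ConfigurationError("C, gamma and epsilon must all be > 0")


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        return X.to_numpy(dtype=float), names
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if feature_names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    else:
        names = list(feature_names)
    return X, names


def select_features(
    X,
    y,
    rule: SelectionRule = SelectionRule(),
    feature_names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Indices of features passing the variance and correlation screens.

    A feature survives when its variance exceeds ``variance_floor`` AND
    its |Pearson r| with ``y`` is at least ``min_abs_corr``.  Raises
    :class:`EmptySelectionError` when nothing survives so the caller can
    relax the rule explicitly rather than fit an empty model.
    """
    X, names = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 3:
        raise InputError("feature selection needs at least 3 subjects")
    variances = X.var(axis=0)
    y_sd = y.std()
    selected = []
    for j in range(X.shape[1]):
        if variances[j] <= rule.variance_floor:
            continue
        if y_sd == 0:
            continue
        r = np.corrcoef(X[:, j], y)[0, 1]
        if abs(r) >= rule.min_abs_corr:
            selected.append(j)
    if not selected:
        raise EmptySelectionError(
            "every feature was excluded by the variance/correlation rule; "
            "relax variance_floor or min_abs_corr"
        )
    return np.asarray(selected, dtype=int)


def _check_collinearity(design: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming the dependent columns when the design is rank deficient."""
    from scipy.linalg import qr

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, _, pivots = qr(design, pivoting=True, mode="economic")
        dependent = sorted(pivots[rank:])
        labels = []
        for j in dependent:
            labels.append("intercept" if j == 0 else str(names[j - 1]))
        raise CollinearFeaturesError(labels)


def fit_mlr(
    X,
    y,
    feature_names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Ordinary least squares; returns ``[intercept, coef...]``.

    Residuals are orthogonal to the design columns (property of the OLS
    normal equations); rank deficiency raises
    :class:`CollinearFeaturesError` naming the implicated features.
    """
    X, names = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1] + 1:
        raise SampleSizeError(
            f"OLS needs more than p+1 = {X.shape[1] + 1} subjects, got {X.shape[0]}"
        )
    design = np.column_stack([np.ones(X.shape[0]), X])
    _check_collinearity(design, names)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta


def fit_svr(X, y, hp: SvrHyperparams = SvrHyperparams()) -> SVR:
    """Fit an epsilon-insensitive RBF SVR on already-standardized inputs."""
    X, _ = _as_matrix(X)
    return SVR(kernel="rbf", C=hp.C, gamma=hp.gamma, epsilon=hp.epsilon).fit(
        X, np.asarray(y, dtype=float)
    )


class HybridAGERegressor(RegressorMixin, BaseEstimator):
    """Weighted MLR + RBF-SVR ensemble predicting serum AGE concentration.

    Parameters
    ----------
    w_mlr, w_svr:
        Convex combination weights (must be >= 0 and sum to 1).  Defaults
        (0.7, 0.3) weight the linear component most heavily.
    C, gamma, epsilon:
        RBF-SVR hyperparameters.
    variance_floor, min_abs_corr:
        Feature screening rule; set ``select=False`` to keep all features.

    Attributes (after ``fit``)
    --------------------------
    selected_features_ : ndarray of int
        Column indices that survived screening.
    feature_names_in_ : list of str
        Names of all input columns.
    mlr_coef_ : ndarray
        ``[intercept, coef...]`` over the selected features (raw scale).
    scaler_mean_, scaler_scale_ : ndarray
        Per-feature standardization used for the SVR inputs.
    svr_ : sklearn.svm.SVR
        The fitted kernel machine.
    """

    def __init__(
        self,
        w_mlr: float = 0.7,
        w_svr: float = 0.3,
        C: float = 10.0,
        gamma: float = 0.1,
        epsilon: float = 0.01,
        variance_floor: float = 1e-8,
        min_abs_corr: float = 0.3,
        select: bool = True,
    ):
        self.w_mlr = w_mlr
        self.w_svr = w_svr
        self.C = C
        self.gamma = gamma
        self.epsilon = epsilon
        self.variance_floor = variance_floor
        self.min_abs_corr = min_abs_corr
        self.select = select

    def _validate_weights(self) -> None:
        if self.w_mlr < 0 or self.w_svr < 0:
            raise ConfigurationError("ensemble weights must be >= 0")
        if abs(self.w_mlr + self.w_svr - 1.0) > 1e-9:
            raise ConfigurationError("ensemble weights must sum to 1")

    def fit(self, X, y, feature_names: Optional[Sequence[str]] = None):
        self._validate_weights()
        X, names = _as_matrix(X, feature_names)
        X, y = check_X_y(X, y, y_numeric=True)
        self.feature_names_in_ = names
        self.n_features_in_ = X.shape[1]

        if self.select:
            rule = SelectionRule(self.variance_floor, self.min_abs_corr)
            self.selected_features_ = select_features(X, y, rule, names)
        else:
            self.selected_features_ = np.arange(X.shape[1])
        D = X[:, self.selected_features_]
        sel_names = [names[j] for j in self.selected_features_]

        self.mlr_coef_ = fit_mlr(D, y, sel_names)

        self.scaler_mean_ = D.mean(axis=0)
        scale = D.std(axis=0)
        scale[scale == 0.0] = 1.0
        self.scaler_scale_ = scale
        Z = (D - self.scaler_mean_) / self.scaler_scale_
        self.svr_ = fit_svr(Z, y, SvrHyperparams(self.C, self.gamma, self.epsilon))
        return self

    def _design(self, X) -> np.ndarray:
        check_is_fitted(self, "mlr_coef_")
        X, _ = _as_matrix(X, self.feature_names_in_)
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            missing = self.n_features_in_ - X.shape[1]
            raise InputError(
                f"expected {self.n_features_in_} features "
                f"({', '.join(self.feature_names_in_)}); got {X.shape[1]} "
                f"({abs(missing)} {'missing' if missing > 0 else 'extra'})"
            )
        return X[:, self.selected_features_]

    def predict_components(self, X) -> tuple[np.ndarray, np.ndarray]:
        """(MLR predictions, SVR predictions) for the two sub-models."""
        D = self._design(X)
        mlr = self.mlr_coef_[0] + D @ self.mlr_coef_[1:]
        svr = self.svr_.predict((D - self.scaler_mean_) / self.scaler_scale_)
        return mlr, svr

    def predict(self, X) -> np.ndarray:
        mlr, svr = self.predict_components(X)
        return self.w_mlr * mlr + self.w_svr * svr

    def to_document(self) -> "HybridModelDocument":
        """Serializable snapshot sufficient to reproduce predictions."""
        check_is_fitted(self, "mlr_coef_")
        svr = self.svr_
        return HybridModelDocument(
            schema_version=MODEL_SCHEMA_VERSION,
            feature_names=list(self.feature_names_in_),
            selected_features=[int(j) for j in self.selected_features_],
            w_mlr=float(self.w_mlr),
            w_svr=float(self.w_svr),
            mlr_coef=[float(v) for v in self.mlr_coef_],
            scaler_mean=[float(v) for v in self.scaler_mean_],
            scaler_scale=[float(v) for v in self.scaler_scale_],
            gamma=float(self.gamma),
            support_vectors=[[float(v) for v in row] for row in svr.support_vectors_],
            dual_coef=[float(v) for v in svr.dual_coef_.ravel()],
            svr_intercept=float(svr.intercept_[0]),
        )


def predict_hybrid(model: HybridAGERegressor, X) -> np.ndarray:
    """Thin wrapper over :meth:`HybridAGERegressor.predict`."""
    return model.predict(X)


@dataclass
class HybridModelDocument:
    """JSON-stable fitted-model document.

    Stores the OLS coefficients, the SVR support vectors/dual
    coefficients/intercept, the input standardization and the ensemble
    weights, so predictions round-trip bit-stably through JSON without
    refitting.  Readers reject unknown major schema versions.
    """

    feature_names: list
    selected_features: list
    w_mlr: float
    w_svr: float
    mlr_coef: list
    scaler_mean: list
    scaler_scale: list
    gamma: float
    support_vectors: list
    dual_coef: list
    svr_intercept: float
    schema_version: str = field(default=MODEL_SCHEMA_VERSION)

    def predict_components(self, X) -> tuple[np.ndarray, np.ndarray]:
        X, _ = _as_matrix(X, self.feature_names)
        if X.shape[1] != len(self.feature_names):
            raise InputError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        D = X[:, np.asarray(self.selected_features, dtype=int)]
        coef = np.asarray(self.mlr_coef)
        mlr = coef[0] + D @ coef[1:]
        Z = (D - np.asarray(self.scaler_mean)) / np.asarray(self.scaler_scale)
        sv = np.asarray(self.support_vectors)
        kernel = np.exp(-self.gamma * cdist(Z, sv, "sqeuclidean"))
        svr = kernel @ np.asarray(self.dual_coef) + self.svr_intercept
        return mlr, svr

    def predict(self, X) -> np.ndarray:
        mlr, svr = self.predict_components(X)
        return self.w_mlr * mlr + self.w_svr * svr

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "schema_version": self.schema_version,
            "feature_names": self.feature_names,
            "selected_features": self.selected_features,
            "weights": {"w_mlr": self.w_mlr, "w_svr": self.w_svr},
            "mlr": {"coef": self.mlr_coef},
            "standardization": {
                "mean": self.scaler_mean,
                "scale": self.scaler_scale,
            },
            "svr": {
                "gamma": self.gamma,
                "support_vectors": self.support_vectors,
                "dual_coef": self.dual_coef,
                "intercept": self.svr_intercept,
            },
        }
        return json.dumps(payload, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "HybridModelDocument":
        payload = json.loads(text)
        version = payload.get("schema_version", "0")
        if version.split(".")[0] != MODEL_SCHEMA_VERSION.split(".")[0]:
            raise SchemaVersionError(
                f"unsupported model schema version {version!r}"
            )
        return cls(
            schema_version=version,
            feature_names=payload["feature_names"],
            selected_features=payload["selected_features"],
            w_mlr=payload["weights"]["w_mlr"],
            w_svr=payload["weights"]["w_svr"],
            mlr_coef=payload["mlr"]["coef"],
            scaler_mean=payload["standardization"]["mean"],
            scaler_scale=payload["standardization"]["scale"],
            gamma=payload["svr"]["gamma"],
            support_vectors=payload["svr"]["support_vectors"],
            dual_coef=payload["svr"]["dual_coef"],
            svr_intercept=payload["svr"]["intercept"],
        )


def evaluate_models(
    X,
    y,
    feature_names: Optional[Sequence[str]] = None,
    test_size: float = 0.3,
    seed: int = 0,
    estimator: Optional[HybridAGERegressor] = None,
) -> dict:
    """Held-out error summary for MLR, SVR and the hybrid.

    Splits subjects train/validation (default 70/30, seeded), fits once,
    and reports per-model mean absolute relative error (percent) and bias
    (mean of reference minus prediction) on the held-out split.
    """
    X, names = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 10:
        raise SampleSizeError(
            f"model evaluation needs at least 10 subjects, got {X.shape[0]}"
        )
    est = estimator if estimator is not None else HybridAGERegressor()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, random_state=seed
    )
    est.fit(X_tr, y_tr, feature_names=names)
    mlr, svr = est.predict_components(X_te)
    hybrid = est.w_mlr * mlr + est.w_svr * svr

    def _summary(pred):
        rel = 100.0 * (pred - y_te) / y_te
        return {
            "mare_percent": float(np.mean(np.abs(rel))),
            "bias": float(np.mean(y_te - pred)),
        }

    return {
        "n_train": int(len(y_tr)),
        "n_test": int(len(y_te)),
        "selected_features": [names[j] for j in est.selected_features_],
        "mlr": _summary(mlr),
        "svr": _summary(svr),
        "hybrid": _summary(hybrid),
    }
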