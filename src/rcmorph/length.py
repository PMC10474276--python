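"""Predicting total scapula length from lateral scapular morphology.

A multivariable ordinary-least-squares regression relates the four lateral
morphometric measures (PD, PC, VB, HB; see :mod:`rcmorph.geometry`) to the
total sagittal scapula length.  All four predictors are retained in the
deployed model regardless of individual significance; a restricted PD+PC
model is available for sensitivity analysis via the ``predictors`` switch.

Because a clinical scan can never cover more than the whole scapula, a
prediction below the captured scapular extent is clamped to that extent and
flagged — coverage cannot exceed 100%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .geometry import LateralMorphometrics

__all__ = [
    "PREDICTOR_NAMES",
    "ScapulaLengthRegressor",
    "PredictedLength",
    "LengthEvaluation",
    "fit_length_model",
    "predict_length",
    "evaluate_length_model",
]

PREDICTOR_NAMES: tuple[str, ...] = ("PD_mm", "PC_mm2", "VB_mm", "HB_mm")


class ScapulaLengthRegressor(RegressorMixin, BaseEstimator):
    """OLS regression of total scapula length on lateral morphometrics.

    Parameters
    ----------
    predictors
        Names of the morphometric columns used, a subsequence of
        ``("PD_mm", "PC_mm2", "VB_mm", "HB_mm")``.  The default keeps all
        four; ``("PD_mm", "PC_mm2")`` gives the restricted sensitivity model.

    Attributes
    ----------
    intercept_ : float
        Fitted intercept (mm).
    coef_ : ndarray of shape (n_predictors,)
        Fitted coefficients, in ``predictors`` order.
    r_ : float
        Multiple correlation coefficient (square root of R²).
    f_pvalue_ : float
        p value of the overall regression F test.
    tvalues_, pvalues_, bse_ : ndarray of shape (n_predictors + 1,)
        Per-parameter t statistics, p values and standard errors
        (intercept first).
    shapiro_pvalues_ : dict
        Shapiro–Wilk normality p value for each predictor column and for
        the response (key ``"length_mm"``).
    n_train_ : int
        Number of training scans.
    """

    def __init__(self, predictors: Sequence[str] = PREDICTOR_NAMES):
        self.predictors = tuple(predictors)

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y) -> "ScapulaLengthRegressor":
        unknown = set(self.predictors) - set(PREDICTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown predictors {sorted(unknown)}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.predictors):
            raise ValueError(
                f"X must be (n_samples, {len(self.predictors)}) for predictors {self.predictors}"
            )
        n, k = X.shape
        if n < k + 2:
            raise ValueError(f"need at least {k + 2} training samples, got {n}")
        design = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("singular design matrix: predictors are collinear")
        res = sm.OLS(y, design).fit()
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.r_ = float(np.sqrt(max(res.rsquared, 0.0)))
        self.f_pvalue_ = float(res.f_pvalue)
        self.tvalues_ = np.asarray(res.tvalues, dtype=float)
        self.pvalues_ = np.asarray(res.pvalues, dtype=float)
        self.bse_ = np.asarray(res.bse, dtype=float)
        self.n_train_ = int(n)
        self.shapiro_pvalues_ = {
            name: float(stats.shapiro(X[:, j]).pvalue) for j, name in enumerate(self.predictors)
        }
        self.shapiro_pvalues_["length_mm"] = float(stats.shapiro(y).pvalue)
        return self

    def predict(self, X) -> np.ndarray:
        """Unclamped affine prediction (mm) for rows of morphometrics."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        check_is_fitted(self, "coef_")
        payload = {
            "predictors": list(self.predictors),
            "units": {"intercept": "mm", "PD_mm": "mm/mm", "PC_mm2": "mm/mm2",
                      "VB_mm": "mm/mm", "HB_mm": "mm/mm", "length": "mm"},
            "intercept_mm": self.intercept_,
            "coefficients": dict(zip(self.predictors, self.coef_.tolist())),
            "r": self.r_,
            "f_pvalue": self.f_pvalue_,
            "n_train": self.n_train_,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "ScapulaLengthRegressor":
        with open(path) as fh:
            payload = json.load(fh)
        model = cls(predictors=tuple(payload["predictors"]))
        model.intercept_ = float(payload["intercept_mm"])
        model.coef_ = np.array([payload["coefficients"][p] for p in model.predictors])
        model.r_ = float(payload.get("r", float("nan")))
        model.f_pvalue_ = float(payload.get("f_pvalue", float("nan")))
        model.n_train_ = int(payload.get("n_train", 0))
        return model

    def _morpho_row(self, m: LateralMorphometrics) -> np.ndarray:
        full = dict(zip(PREDICTOR_NAMES, m.as_array()))
        return np.array([full[p] for p in self.predictors])


@dataclass(frozen=True)
class PredictedLength:
    """A length prediction (mm) with its coverage-clamp flag."""

    length_mm: float
    clamped: bool


@dataclass(frozen=True)
class LengthEvaluation:
    """Held-out percent-error summary of a length model."""

    mape_pct: float
    sd_pct: float
    min_signed_pct: float
    max_signed_pct: float
    per_scan_signed_pct: np.ndarray


# -- functional wrappers ---------------------------------------------------


def fit_length_model(
    training: Sequence[tuple[LateralMorphometrics, float]],
    predictors: Sequence[str] = PREDICTOR_NAMES,
) -> ScapulaLengthRegressor:
    """Fit the length regression on (morphometrics, true length mm) pairs."""
    model = ScapulaLengthRegressor(predictors=predictors)
    X = np.vstack([model._morpho_row(m) for m, _ in training])
    y = np.array([length for _, length in training], dtype=float)
    return model.fit(X, y)


def predict_length(model: ScapulaLengthRegressor, m: LateralMorphometrics) -> PredictedLength:
    """Predict total scapula length, clamped to the captured extent.

    The linear prediction cannot be allowed to fall below the extent already
    captured in the scan (coverage would exceed 100%); such predictions are
    replaced by the captured extent and flagged.
    """
    raw = float(model.predict(model._morpho_row(m)[None, :])[0])
    if raw < m.captured_extent_mm:
        return PredictedLength(length_mm=m.captured_extent_mm, clamped=True)
    return PredictedLength(length_mm=raw, clamped=False)


def evaluate_length_model(
    model: ScapulaLengthRegressor,
    test: Sequence[tuple[LateralMorphometrics, float]],
) -> LengthEvaluation:
    """Signed-percent-error evaluation on held-out pairs.

    Per scan: ``(predicted − true) / true × 100``.  Predictions here are the
    raw regression output (no coverage clamp) so the evaluation reflects the
    model itself.
    """
    if len(test) == 0:
        raise ValueError("test set is empty")
    errors = []
    for m, true_length in test:
        if true_length <= 0:
            raise ValueError(f"true length must be positive, got {true_length}")
        pred = float(model.predict(model._morpho_row(m)[None, :])[0])
        errors.append((pred - true_length) / true_length * 100.0)
    errors = np.array(errors)
    abs_err = np.abs(errors)
    return LengthEvaluation(
        mape_pct=float(abs_err.mean()),
        sd_pct=float(abs_err.std(ddof=1)) if len(errors) > 1 else 0.0,
        min_signed_pct=float(errors.min()),
        max_signed_pct=float(errors.max()),
        per_scan_signed_pct=errors,
    )
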