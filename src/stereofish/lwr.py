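"""Allometric length-weight relationship W = a * L^b.

Fitted by ordinary least squares of log W on log L (the standard
fisheries practice): a = exp(intercept), b = slope.  b near 3 indicates
isometric growth; the intercept a reflects body shape/condition.  No
back-transform bias correction is applied by default; a log-normal
correction factor is available as an option.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._version import __version__

__all__ = ["LengthWeightRegressor", "fit_lwr", "predict_weight", "save_lwr", "load_lwr"]


class LengthWeightRegressor(BaseEstimator, RegressorMixin):
    """Power-law length-to-weight model, fit on the log-log scale.

    Parameters
    ----------
    bias_correction : bool, default False
        Multiply predictions by exp(sigma^2 / 2), the log-normal
        smearing factor, to target the conditional mean weight rather
        than the median.

    Attributes
    ----------
    a_ : float
        Allometric intercept (g * cm^-b).
    b_ : float
        Allometric exponent (dimensionless).
    r_squared_ : float
        Coefficient of determination on the log scale (the scale of the
        fit).
    n_ : int
        Sample count.
    sigma_ : float
        Residual standard deviation of log W.
    """

    def __init__(self, bias_correction: bool = False):
        self.bias_correction = bias_correction

    def fit(self, X, y=None) -> "LengthWeightRegressor":
        """Fit on lengths X (cm) and weights y (g); both strictly positive, n >= 3."""
        lengths = np.asarray(X, dtype=float).reshape(-1)
        weights = np.asarray(y, dtype=float).reshape(-1)
        if lengths.shape != weights.shape:
            raise ValueError("lengths and weights must have equal length")
        if lengths.size < 3:
            raise ValueError(f"need at least 3 fish to fit an LWR, got {lengths.size}")
        if np.any(lengths <= 0) or np.any(weights <= 0):
            raise ValueError("lengths and weights must be strictly positive")

        log_l = np.log(lengths)
        log_w = np.log(weights)
        design = np.column_stack([np.ones_like(log_l), log_l])
        coef, *_ = np.linalg.lstsq(design, log_w, rcond=None)
        intercept, slope = coef
        self.a_ = float(np.exp(intercept))
        self.b_ = float(slope)
        self.n_ = int(lengths.size)
        fitted = design @ coef
        resid = log_w - fitted
        ss_tot = float(np.sum((log_w - log_w.mean()) ** 2))
        self.r_squared_ = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        dof = max(lengths.size - 2, 1)
        self.sigma_ = float(np.sqrt(np.sum(resid**2) / dof))
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted weight a * L^b in grams; lengths must be positive."""
        check_is_fitted(self, "a_")
        sl = np.asarray(X, dtype=float)
        scalar = sl.ndim == 0
        sl = sl.reshape(-1)
        if np.any(sl <= 0):
            raise ValueError("standard length must be positive")
        w = self.a_ * sl**self.b_
        if self.bias_correction:
            w = w * np.exp(self.sigma_**2 / 2)
        return float(w[0]) if scalar else w


def fit_lwr(lengths_cm, weights_g, bias_correction: bool = False) -> LengthWeightRegressor:
    """Fit the allometric LWR by log-log least squares (thin wrapper)."""
    return LengthWeightRegressor(bias_correction=bias_correction).fit(lengths_cm, weights_g)


def predict_weight(model: LengthWeightRegressor, sl_cm) -> float | np.ndarray:
    """Weight (g) predicted at standard length sl_cm."""
    return model.predict(sl_cm)


def save_lwr(model: LengthWeightRegressor, path: str | Path) -> None:
    check_is_fitted(model, "a_")
    Path(path).write_text(
        json.dumps(
            {
                "a": model.a_,
                "b": model.b_,
                "r_squared_log": model.r_squared_,
                "n": model.n_,
                "sigma_log": model.sigma_,
                "bias_correction": model.bias_correction,
                "tool_version": __version__,
            },
            indent=2,
        )
    )


def load_lwr(path: str | Path) -> LengthWeightRegressor:
    d = json.loads(Path(path).read_text())
    model = LengthWeightRegressor(bias_correction=d.get("bias_correction", False))
    model.a_ = d["a"]
    model.b_ = d["b"]
    model.r_squared_ = d.get("r_squared_log")
    model.n_ = d.get("n", 0)
    model.sigma_ = d.get("sigma_log", 0.0)
    return model
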