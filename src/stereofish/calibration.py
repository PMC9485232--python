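"""Empirical translation -> micron/pixel scale calibration.

Builds calibration observations from annotated chessboard stereo frames
(each observation pairs the mean stereo translation of a landmark pair
with the physical scale implied by its known separation on the board),
then fits the scale as a polynomial in translation — a cubic by default,
with an optional ridge penalty on standardized polynomial features.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.utils.validation import check_is_fitted

from ._version import __version__
from .camera import PixelPoint, disparity

logger = logging.getLogger(__name__)

__all__ = [
    "ChessboardSpec",
    "CalibrationObservation",
    "ScaleCalibrator",
    "observations_from_chessboard",
    "fit_scale_model",
    "predict_scale",
    "r_squared",
    "save_scale_model",
    "load_scale_model",
    "MIN_TRANSLATION_PX",
]

# Minimum stereo translation (pixels) at which the parallax of a target is
# considered resolvable by the rig; smaller translations are discarded.
MIN_TRANSLATION_PX = 140.0


@dataclass(frozen=True)
class ChessboardSpec:
    """Physical chessboard used for calibration (27-mm squares, 270 x 190 mm board)."""

    square_size_mm: float = 27.0
    board_size_mm: tuple[float, float] = (270.0, 190.0)
    marked_corners: int = 15

    def __post_init__(self) -> None:
        if self.square_size_mm <= 0:
            raise ValueError("square_size_mm must be positive")


@dataclass(frozen=True)
class CalibrationObservation:
    """One landmark pair reduced to (translation, scale).

    ``translation`` is the mean stereo disparity of the pair's two
    endpoints; ``scale`` is the pair's known physical separation divided
    by its pixel separation in the reference frame (camera a).
    """

    translation: float
    scale: float
    session_id: str = ""
    pose_id: str = ""
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.translation <= 0:
            raise ValueError("translation must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def observations_from_chessboard(
    annotations: pd.DataFrame,
    spec: ChessboardSpec | None = None,
    reference_frame: str = "a",
) -> list[CalibrationObservation]:
    """Reduce a stereo landmark annotation table to calibration observations.

    Parameters
    ----------
    annotations
        Long-format table with columns ``session_id, pose_id, pair_id,
        endpoint (1|2), frame (a|b), u, v, squares_spanned``.  Each
        landmark pair must have both endpoints in both frames (4 rows).
    spec
        Chessboard geometry; ``squares_spanned * square_size_mm`` gives
        the physical separation of a pair.
    reference_frame
        Frame in which the pair's pixel separation is measured
        (``"a"``, the upper camera, by default; ``"mean"`` averages both
        frames).

    Returns
    -------
    One :class:`CalibrationObservation` per complete landmark pair:
    ``scale = squares * square_size * 1000 / pixel_distance`` (micron per
    pixel) and ``translation`` = mean of the two endpoints' disparities.
    Incomplete pairs are skipped with a warning; pairs with zero pixel
    separation are rejected.
    """
    spec = spec or ChessboardSpec()
    required = {"session_id", "pose_id", "pair_id", "endpoint", "frame", "u", "v", "squares_spanned"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")

    obs: list[CalibrationObservation] = []
    for (sid, pid, pair), grp in annotations.groupby(
        ["session_id", "pose_id", "pair_id"], sort=True
    ):
        pts: dict[tuple[int, str], PixelPoint] = {}
        for _, row in grp.iterrows():
            pts[(int(row["endpoint"]), str(row["frame"]))] = PixelPoint(row["u"], row["v"])
        needed = [(1, "a"), (1, "b"), (2, "a"), (2, "b")]
        if any(k not in pts for k in needed):
            logger.warning(
                "pair %s/%s/%s lacks a full stereo correspondence; skipped", sid, pid, pair
            )
            continue
        squares = float(grp["squares_spanned"].iloc[0])
        sep_mm = squares * spec.square_size_mm

        def frame_dist(frame: str) -> float:
            return disparity(pts[(1, frame)], pts[(2, frame)])

        if reference_frame == "mean":
            px_dist = (frame_dist("a") + frame_dist("b")) / 2
        else:
            px_dist = frame_dist(reference_frame)
        if px_dist <= 0:
            logger.warning("pair %s/%s/%s has zero pixel separation; rejected", sid, pid, pair)
            continue
        translation = (
            disparity(pts[(1, "a")], pts[(1, "b")]) + disparity(pts[(2, "a")], pts[(2, "b")])
        ) / 2
        obs.append(
            CalibrationObservation(
                translation=translation,
                scale=sep_mm * 1000.0 / px_dist,
                session_id=str(sid),
                pose_id=str(pid),
                pair_id=str(pair),
            )
        )
    return obs


class ScaleCalibrator(BaseEstimator, RegressorMixin):
    """Polynomial (ridge) regression of micron/pixel scale on stereo translation.

    The scale at which a target is imaged falls with its stereo
    translation (parallax); this estimator fits that empirical curve
    from chessboard observations with degree-``degree`` polynomial
    features.  ``alpha = 0`` gives the plain least-squares cubic;
    ``alpha > 0`` applies a ridge penalty on standardized features.

    Parameters
    ----------
    degree : int, default 3
        Polynomial degree in translation.
    alpha : float, default 0.0
        Ridge penalty on standardized polynomial features; 0 reproduces
        ordinary least squares.
    min_translation : float, default 140.0
        Lower bound of the validity range; queries below it are flagged
        as extrapolation.

    Attributes
    ----------
    coefficients_ : ndarray of shape (degree + 1,)
        Polynomial coefficients in raw translation units,
        lowest-order first.
    valid_range_ : tuple (min, max)
        Translation range over which the model is trusted.
    r_squared_ : float or None
        Training coefficient of determination (None when the response
        is constant and R^2 is undefined).
    n_obs_ : int
        Number of training observations.
    """

    def __init__(self, degree: int = 3, alpha: float = 0.0, min_translation: float = MIN_TRANSLATION_PX):
        self.degree = degree
        self.alpha = alpha
        self.min_translation = min_translation

    def fit(self, X, y=None) -> "ScaleCalibrator":
        """Fit on translations X (array-like, (n,) or (n, 1)) and scales y."""
        t = np.asarray(X, dtype=float).reshape(-1)
        s = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != s.shape:
            raise ValueError("translations and scales must have equal length")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        n_params = self.degree + 1
        if t.size < n_params + 1:
            raise ValueError(
                f"need more than {n_params} observations to fit degree {self.degree}, got {t.size}"
            )
        if np.ptp(t) == 0:
            raise np.linalg.LinAlgError("all translations identical: design matrix is rank deficient")

        if self.alpha == 0:
            reg = LinearRegression()
        else:
            reg = Ridge(alpha=self.alpha)
        self._pipeline_ = Pipeline(
            [
                ("poly", PolynomialFeatures(degree=self.degree, include_bias=False)),
                ("scale", StandardScaler()),
                ("reg", reg),
            ]
        ).fit(t[:, None], s)

        self.coefficients_ = self._raw_coefficients()
        self.valid_range_ = (max(float(t.min()), self.min_translation), float(t.max()))
        self.n_obs_ = int(t.size)
        pred = self._pipeline_.predict(t[:, None])
        self.r_squared_ = r_squared(s, pred)
        dof = max(t.size - n_params, 1)
        self.residual_sd_ = float(np.sqrt(np.sum((s - pred) ** 2) / dof))
        self._check_positive_on_grid()
        return self

    def _raw_coefficients(self) -> np.ndarray:
        """Translate the standardized-feature linear model back to raw
        polynomial coefficients, lowest-order first."""
        scaler: StandardScaler = self._pipeline_.named_steps["scale"]
        reg = self._pipeline_.named_steps["reg"]
        w = np.asarray(reg.coef_, dtype=float).reshape(-1) / scaler.scale_
        c = np.zeros(self.degree + 1)
        c[0] = float(reg.intercept_) - float(np.dot(w, scaler.mean_))
        c[1:] = w
        return c

    def _check_positive_on_grid(self, n_grid: int = 256) -> None:
        lo, hi = self.valid_range_
        if hi <= lo:
            return
        grid = np.linspace(lo, hi, n_grid)
        if np.any(np.polyval(self.coefficients_[::-1], grid) <= 0):
            warnings.warn(
                "fitted scale model is not strictly positive across its validity "
                "range; predictions may be unusable",
                RuntimeWarning,
            )

    def predict(self, X) -> np.ndarray:
        """Predicted micron/pixel scale at translation(s) X.

        Queries outside ``valid_range_`` are answered by polynomial
        extrapolation with a warning (field translations can slightly
        exceed the calibrated range).
        """
        check_is_fitted(self, "coefficients_")
        t = np.asarray(X, dtype=float)
        scalar = t.ndim == 0
        t = t.reshape(-1)
        lo, hi = self.valid_range_
        out_of_range = (t < lo) | (t > hi)
        if np.any(out_of_range):
            warnings.warn(
                f"{int(out_of_range.sum())} translation(s) outside calibrated range "
                f"[{lo:.1f}, {hi:.1f}] px; extrapolating",
                RuntimeWarning,
            )
        pred = np.polyval(self.coefficients_[::-1], t)
        return float(pred[0]) if scalar else pred

    def in_valid_range(self, translation) -> np.ndarray | bool:
        check_is_fitted(self, "coefficients_")
        t = np.asarray(translation, dtype=float)
        lo, hi = self.valid_range_
        return (t >= lo) & (t <= hi)

    def prediction_interval(self, X, level: float = 0.95):
        """Approximate pointwise prediction band from the residual variance.

        A normal-theory band pred +/- z * s_res; the exact construction
        used for the published confidence limits is unspecified, so this
        is documented as approximate.
        """
        from scipy import stats

        check_is_fitted(self, "residual_sd_")
        pred = np.atleast_1d(self.predict(X))
        z = stats.norm.ppf(0.5 + level / 2)
        return pred - z * self.residual_sd_, pred + z * self.residual_sd_


def fit_scale_model(
    observations: list[CalibrationObservation] | pd.DataFrame,
    degree: int = 3,
    alpha: float = 0.0,
    min_translation: float = MIN_TRANSLATION_PX,
) -> ScaleCalibrator:
    """Fit a :class:`ScaleCalibrator` from calibration observations."""
    if isinstance(observations, pd.DataFrame):
        t = observations["translation"].to_numpy(dtype=float)
        s = observations["scale"].to_numpy(dtype=float)
    else:
        t = np.array([o.translation for o in observations])
        s = np.array([o.scale for o in observations])
    return ScaleCalibrator(degree=degree, alpha=alpha, min_translation=min_translation).fit(t, s)


def predict_scale(model: ScaleCalibrator, translation) -> float | np.ndarray:
    """Micron/pixel scale predicted at a translation (thin wrapper)."""
    return model.predict(translation)


def r_squared(observed, predicted) -> float | None:
    """Coefficient of determination 1 - SS_res/SS_tot.

    Returns None when the observed response is constant (SS_tot = 0):
    R^2 is undefined there and reporting 0 would be misleading.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        return None
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# serialization


def save_scale_model(model: ScaleCalibrator, path: str | Path, rig_hash: str | None = None) -> None:
    check_is_fitted(model, "coefficients_")
    payload = {
        "degree": model.degree,
        "coefficients": list(model.coefficients_),  # lowest-order first
        "alpha": model.alpha,
        "valid_range": list(model.valid_range_),
        "r_squared": model.r_squared_,
        "n_obs": model.n_obs_,
        "residual_sd": getattr(model, "residual_sd_", None),
        "min_translation": model.min_translation,
        "rig_hash": rig_hash,
        "tool_version": __version__,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_scale_model(path: str | Path) -> ScaleCalibrator:
    d = json.loads(Path(path).read_text())
    model = ScaleCalibrator(
        degree=d["degree"], alpha=d["alpha"], min_translation=d.get("min_translation", MIN_TRANSLATION_PX)
    )
    model.coefficients_ = np.asarray(d["coefficients"], dtype=float)
    model.valid_range_ = tuple(d["valid_range"])
    model.r_squared_ = d["r_squared"]
    model.n_obs_ = d["n_obs"]
    if d.get("residual_sd") is not None:
        model.residual_sd_ = d["residual_sd"]
    model.rig_hash_ = d.get("rig_hash")
    return model
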