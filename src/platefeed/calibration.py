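"""Linear standard curves.

Two calibrations support the assay: in vivo fluorescence against algal
biomass density (F = l·W, through the origin by convention) and optical
absorbance at 800 nm against dry mass (intercept allowed).  Clearance
rates themselves depend only on fluorescence *ratios*, so the curves are
diagnostic — they matter only when results are requested in biomass units
or when linearity of the fluorometer response needs checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import PlatefeedError


@dataclass(frozen=True)
class StandardCurve:
    """Fitted linear calibration y = slope_l * x + intercept."""

    slope_l: float
    intercept: float
    r_squared: float
    n_points: int
    through_origin: bool
    residual_sd: float = float("nan")

    def predict(self, x):
        return self.slope_l * np.asarray(x, dtype=float) + self.intercept


def fit_standard_curve(x, y, through_origin: bool = True) -> StandardCurve:
    """Least-squares fit of a standard curve.

    Parameters
    ----------
    x, y
        Calibration points (predictor, response); at least two, with the
        predictor not constant.
    through_origin
        Force a zero intercept (the F = l·W form).  The reported R² is
        then the uncentred coefficient of determination.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise PlatefeedError("x and y must be 1-D arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise PlatefeedError("calibration points must be finite")
    if (x < 0).any():
        raise PlatefeedError("calibration predictor must be >= 0")
    if len(x) < 2:
        raise PlatefeedError(f"need at least 2 calibration points, got {len(x)}")
    if np.ptp(x) == 0:
        raise PlatefeedError("calibration predictor is constant; slope undefined")

    X = x[:, None] if through_origin else sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    if through_origin:
        slope, intercept = float(fit.params[0]), 0.0
    else:
        intercept, slope = float(fit.params[0]), float(fit.params[1])
    resid = y - (slope * x + intercept)
    dof = max(len(x) - (1 if through_origin else 2), 1)
    r2 = float(np.clip(fit.rsquared, 0.0, 1.0))
    return StandardCurve(
        slope_l=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=len(x),
        through_origin=through_origin,
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
    )


def check_linearity(curve: StandardCurve, min_r2: float = 0.95) -> dict:
    """Pass/fail linearity report; passes when R² >= min_r2 (inclusive)."""
    return {
        "passed": bool(curve.r_squared >= min_r2),
        "r_squared": curve.r_squared,
        "min_r2": float(min_r2),
        "n_points": curve.n_points,
        "residual_sd": curve.residual_sd,
    }


def fluorescence_to_biomass(F, curve: StandardCurve):
    """Invert the standard curve: W = (F - intercept) / l.

    Requires a positive slope; returns biomass in the curve's predictor
    units (mg dw L^-1 for the fluorescence-biomass curve).
    """
    if curve.slope_l <= 0:
        raise PlatefeedError(f"standard-curve slope must be > 0, got {curve.slope_l!r}")
    return (np.asarray(F, dtype=float) - curve.intercept) / curve.slope_l


def read_calibration_csv(path, kind: str | None = None) -> pd.DataFrame:
    """Read a calibration CSV with columns x, y and optional kind.

    ``kind`` filters to one of ``fluor_biomass`` / ``abs_drymass`` when the
    file holds both.
    """
    df = pd.read_csv(path)
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise PlatefeedError(f"calibration CSV missing column(s) {sorted(missing)}")
    if kind is not None:
        if "kind" not in df.columns:
            raise PlatefeedError("calibration CSV has no 'kind' column to filter on")
        df = df[df["kind"] == kind]
        if df.empty:
            raise PlatefeedError(f"no calibration points of kind {kind!r}")
    return df.reset_index(drop=True)
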