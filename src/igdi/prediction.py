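"""Univariate linear prediction of audience preference from the iGDI,
with leave-one-out cross-validation.

The model is y = b1 * iGDI + b0, fitted by ordinary least squares.  The
LOOCV report carries RMSE, MAPE, cross-validated R^2 (1 - SS_res/SS_tot
on held-out predictions, by default), shrinkage (fitted R^2 minus
cross-validated R^2) and the spread of the coefficients across the n
leave-one-out refits.  A negative fitted slope is the expected direction
(more divergence, lower preference); it is reported, never enforced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegeneratePredictorError


@dataclass
class PredictionModel:
    """OLS fit summary for y = b1 * x + b0."""

    b0: float
    b1: float
    r: float
    r2: float
    f_stat: float
    p_value: float
    n: int
    se_b1: float = float("nan")
    se_b0: float = float("nan")

    def predict(self, x) -> np.ndarray:
        return self.b0 + self.b1 * np.asarray(x, dtype=float)

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Analytic confidence interval for the slope (t, n-2 df)."""
        half = stats.t.ppf(0.5 + level / 2.0, self.n - 2) * self.se_b1
        return (self.b1 - half, self.b1 + half)


@dataclass
class CVReport:
    """Leave-one-out cross-validation summary.

    ``mape`` is None when any observed y is zero (percentage error
    undefined); a warning is issued in that case.
    """

    rmse: float
    mape: float | None
    r2_cv: float
    shrinkage: float
    coef_sd_b1: float
    coef_sd_b0: float
    predictions: np.ndarray = field(default_factory=lambda: np.empty(0))


def _check_xy(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("predictor x is constant")
    return x, y


def fit_linear(x, y) -> PredictionModel:
    """Least-squares fit of the univariate line, with r, R^2, F and p.

    F = R^2 (n-2) / (1 - R^2) on (1, n-2) degrees of freedom; the
    two-tailed p comes from the F distribution (equivalently the t test
    on the slope).
    """
    x, y = _check_xy(x, y, 3)
    n = x.size
    if np.ptp(y) == 0:  # flat response: slope 0, correlation defined as 0
        return PredictionModel(
            b0=float(y[0]), b1=0.0, r=0.0, r2=0.0, f_stat=0.0, p_value=1.0,
            n=n, se_b1=0.0, se_b0=0.0,
        )
    res = stats.linregress(x, y)
    r = float(res.rvalue)
    r2 = r * r
    if r2 >= 1.0 - 1e-15:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = r2 * (n - 2) / (1.0 - r2)
        p = float(stats.f.sf(f_stat, 1, n - 2))
    return PredictionModel(
        b0=float(res.intercept),
        b1=float(res.slope),
        r=r,
        r2=r2,
        f_stat=float(f_stat),
        p_value=p,
        n=n,
        se_b1=float(res.stderr),
        se_b0=float(res.intercept_stderr),
    )


def loocv(x, y, r2_cv_method: str = "holdout") -> CVReport:
    """Leave-one-out cross-validation of the univariate line.

    Each of the n refits excludes one point and predicts it; the report
    aggregates the held-out predictions.  ``r2_cv_method``:

    * ``"holdout"`` (default): 1 - SS_res(y_hat) / SS_tot(y);
    * ``"corr"``: squared Pearson correlation of y_hat with y.
    """
    x, y = _check_xy(x, y, 4)
    n = x.size
    preds = np.empty(n)
    coefs = np.empty((n, 2))  # (b1, b0) per refit
    for i in range(n):
        keep = np.arange(n) != i
        xi, yi = x[keep], y[keep]
        if np.ptp(xi) == 0:
            raise DegeneratePredictorError("predictor constant after leaving one out")
        b1, b0 = np.polyfit(xi, yi, 1)
        coefs[i] = (b1, b0)
        preds[i] = b0 + b1 * x[i]

    resid = y - preds
    rmse = float(np.sqrt(np.mean(resid**2)))
    if np.any(y == 0):
        warnings.warn("MAPE undefined: some observed y are zero", stacklevel=2)
        mape = None
    else:
        mape = float(100.0 * np.mean(np.abs(resid) / np.abs(y)))

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if r2_cv_method == "holdout":
        r2_cv = 1.0 - float(np.sum(resid**2)) / ss_tot
    elif r2_cv_method == "corr":
        r2_cv = float(np.corrcoef(preds, y)[0, 1] ** 2)
    else:
        raise ValueError(f"unknown r2_cv_method {r2_cv_method!r}")

    full = fit_linear(x, y)
    return CVReport(
        rmse=rmse,
        mape=mape,
        r2_cv=r2_cv,
        shrinkage=full.r2 - r2_cv,
        coef_sd_b1=float(np.std(coefs[:, 0], ddof=1)),
        coef_sd_b0=float(np.std(coefs[:, 1], ddof=1)),
        predictions=preds,
    )


def report_dict(model: PredictionModel, cv: CVReport) -> dict:
    """Flat JSON-serializable summary of a fit plus its CV report."""
    return {
        "b0": model.b0,
        "b1": model.b1,
        "r": model.r,
        "r2": model.r2,
        "f_stat": model.f_stat,
        "p_value": model.p_value,
        "n": model.n,
        "rmse": cv.rmse,
        "mape": cv.mape,
        "r2_cv": cv.r2_cv,
        "shrinkage": cv.shrinkage,
        "coef_sd_b1": cv.coef_sd_b1,
        "coef_sd_b0": cv.coef_sd_b0,
        "slope_negative": model.b1 < 0,
    }
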