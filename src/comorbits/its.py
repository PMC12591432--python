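"""Segmented (interrupted time series) regression engine.

The model for a monthly prevalence series Y observed at integer month
offsets around an index event is

    Y = b0 + b1*T + b2*D + b3*P + eps

with T the continuous time variable centered so the index month is T = 0,
D the interrupt indicator (0 before the index month, 1 from the index month
on), and P the time elapsed since the interruption (0 before the index, T
after).  b1 is the pre-index slope, b2 the level change at the index, and b3
the slope change; eps is zero-centered Gaussian error.  Slopes are in
percent per month; annualized rates downstream are 12x the monthly slopes.

The index month itself carries D = 1, P = 0, so b2 captures the index-month
level jump; ``include_index_month=False`` drops offset 0 from the fit
instead.

Estimation is ordinary least squares (statsmodels) with classical standard
errors; no autocorrelation correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["build_design", "SegmentedRegression", "ITSFit", "fit_its", "predict"]

COEF_NAMES = ("b0", "b1", "b2", "b3")


def build_design(offsets) -> pd.DataFrame:
    """Design rows (T, D, P) for sorted unique integer month offsets.

    T equals the offset (index month at T=0); D = 1 for offsets >= 0;
    P = T for offsets >= 0 and 0 before.
    """
    offsets = np.asarray(offsets)
    if offsets.size == 0:
        raise ValueError("offsets must be non-empty")
    t = offsets.astype(float)
    d = (t >= 0).astype(float)
    p = np.where(t >= 0, t, 0.0)
    return pd.DataFrame({"T": t, "D": d, "P": p}, index=np.asarray(offsets))


class SegmentedRegression(RegressorMixin, BaseEstimator):
    """OLS estimator of the four-coefficient segmented regression.

    Parameters
    ----------
    include_index_month:
        Whether offset 0 enters the fit (with D=1, P=0).  Default True.

    Attributes
    ----------
    coef_ : ndarray of shape (4,)
        ``(b0, b1, b2, b3)``; NaN when ``status_ == "fit_error"``.
    stderr_, pvalues_ : ndarray of shape (4,)
        Classical OLS standard errors and two-sided p-values.
    resid_sd_ : float
        Residual standard deviation (ddof = residual degrees of freedom).
    status_ : {"ok", "fit_error"}
        ``fit_error`` flags degenerate inputs (short or one-sided series,
        rank-deficient design, all-zero series, no residual degrees of
        freedom) instead of raising; mirrors the "*" convention in reports.
    """

    def __init__(self, include_index_month: bool = True):
        self.include_index_month = include_index_month

    def fit(self, offsets, y):
        offsets = np.asarray(offsets)
        y = np.asarray(y, dtype=float)
        if offsets.shape != y.shape or offsets.ndim != 1:
            raise ValueError("offsets and y must be 1-d arrays of equal length")
        if not self.include_index_month:
            keep = offsets != 0
            offsets, y = offsets[keep], y[keep]

        self.offsets_ = offsets
        self.coef_ = np.full(4, np.nan)
        self.stderr_ = np.full(4, np.nan)
        self.pvalues_ = np.full(4, np.nan)
        self.resid_sd_ = np.nan
        self.nobs_ = int(y.size)
        self.status_ = "fit_error"

        if y.size < 5:
            return self
        if (offsets < 0).sum() < 2 or (offsets >= 0).sum() < 2:
            return self
        if np.all(y == 0.0):
            return self

        X = sm.add_constant(build_design(offsets).to_numpy(), has_constant="add")
        if np.linalg.matrix_rank(X) < 4 or y.size - 4 < 1:
            return self

        res = sm.OLS(y, X).fit()
        if not np.all(np.isfinite(res.params)):
            return self
        self.coef_ = np.asarray(res.params, dtype=float)
        self.stderr_ = np.asarray(res.bse, dtype=float)
        self.pvalues_ = np.asarray(res.pvalues, dtype=float)
        self.resid_sd_ = float(np.sqrt(res.scale))
        self.status_ = "ok"
        return self

    def predict(self, offsets):
        if getattr(self, "status_", None) != "ok":
            raise ValueError("cannot predict from a fit_error model")
        X = build_design(np.asarray(offsets)).to_numpy()
        b = self.coef_
        return b[0] + X @ b[1:]


@dataclass(frozen=True)
class ITSFit:
    """Frozen result of one segmented-regression fit."""

    b0: float
    b1: float
    b2: float
    b3: float
    stderr: tuple[float, float, float, float]
    pvalues: tuple[float, float, float, float]
    resid_sd: float
    status: str
    condition_id: str = ""
    group: str = ""

    @property
    def coef(self) -> tuple[float, float, float, float]:
        return (self.b0, self.b1, self.b2, self.b3)


def fit_its(series, include_index_month: bool = True) -> ITSFit:
    """Fit the segmented regression to a :class:`~comorbits.trajectory.PrevalenceSeries`."""
    model = SegmentedRegression(include_index_month=include_index_month)
    model.fit(series.offsets, series.values)
    return ITSFit(
        b0=float(model.coef_[0]),
        b1=float(model.coef_[1]),
        b2=float(model.coef_[2]),
        b3=float(model.coef_[3]),
        stderr=tuple(float(v) for v in model.stderr_),
        pvalues=tuple(float(v) for v in model.pvalues_),
        resid_sd=float(model.resid_sd_),
        status=model.status_,
        condition_id=getattr(series, "condition_id", ""),
        group=getattr(series, "group", ""),
    )


def predict(fit: ITSFit, offset) -> float | np.ndarray:
    """Model prediction b0 + b1*T + b2*D + b3*P at one or more offsets."""
    if fit.status != "ok":
        raise ValueError("cannot predict from a fit_error fit")
    X = build_design(np.atleast_1d(np.asarray(offset))).to_numpy()
    out = fit.b0 + X @ np.array([fit.b1, fit.b2, fit.b3])
    return float(out[0]) if np.isscalar(offset) or np.ndim(offset) == 0 else out
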