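"""Post-hoc spatiotemporal trend regression on emergence dates.

Viterbi emergence dates (as day-of-year) are regressed on latitude or on
year with ordinary least squares; the models are compared with small-sample
corrected AIC (AICc).  Latitude and year are strongly collinear in telemetry
datasets of this kind, so no joint model is fitted; the collinearity is
reported as a Spearman rank-correlation diagnostic instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TrendFit",
    "fit_trend",
    "compare_trends",
    "predict_mean",
    "rank_correlation",
    "doy_to_date",
]

TREND_PREDICTORS = ("latitude", "year")


@dataclass
class TrendFit:
    """OLS fit of emergence DOY on a single predictor."""

    predictor: str
    result: sm.regression.linear_model.RegressionResultsWrapper
    n: int
    aicc: float

    @property
    def slope(self) -> float:
        return float(self.result.params[self.predictor])

    @property
    def slope_se(self) -> float:
        return float(self.result.bse[self.predictor])

    @property
    def slope_p(self) -> float:
        return float(self.result.pvalues[self.predictor])

    @property
    def intercept(self) -> float:
        return float(self.result.params["const"])


def _aicc_from_llf(llf: float, n: int, k: int) -> float:
    # k counts every estimated parameter, including the residual variance
    aic = -2.0 * llf + 2.0 * k
    if n - k - 1 <= 0:
        raise ValueError("n too small for AICc")
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_trend(emergence: pd.DataFrame, predictor: str) -> TrendFit:
    """OLS of emergence DOY on ``latitude`` or ``year``."""
    if predictor not in TREND_PREDICTORS:
        raise ValueError(f"predictor must be one of {TREND_PREDICTORS}")
    df = emergence.dropna(subset=["doy", predictor])
    n = len(df)
    if n < 3:
        raise ValueError("need at least 3 emergence rows")
    x = df[predictor].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor!r} is constant")
    X = sm.add_constant(pd.DataFrame({predictor: x}))
    res = sm.OLS(df["doy"].to_numpy(dtype=float), X).fit()
    k = 3  # intercept, slope, residual variance
    return TrendFit(predictor=predictor, result=res, n=n, aicc=_aicc_from_llf(res.llf, n, k))


def compare_trends(fits: list[TrendFit], emergence: pd.DataFrame | None = None) -> pd.DataFrame:
    """Rank trend fits by AICc; optionally report predictor collinearity.

    All fits must use the same rows.  When the emergence table is supplied,
    the Spearman rank correlation between latitude and year is attached as a
    collinearity diagnostic (``table.attrs['latitude_year_spearman']``).
    """
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError("fits must be computed on identical rows")
    table = pd.DataFrame(
        {
            "predictor": [f.predictor for f in fits],
            "slope": [f.slope for f in fits],
            "slope_se": [f.slope_se for f in fits],
            "p": [f.slope_p for f in fits],
            "AICc": [f.aicc for f in fits],
            "n": [f.n for f in fits],
        }
    )
    table["dAICc"] = table["AICc"] - table["AICc"].min()
    table = table.sort_values("dAICc").reset_index(drop=True)
    if emergence is not None and {"latitude", "year"} <= set(emergence.columns):
        rho, p = rank_correlation(emergence["latitude"], emergence["year"])
        table.attrs["latitude_year_spearman"] = (rho, p)
    return table


def predict_mean(fit: TrendFit, x0: float, level: float = 0.95) -> dict:
    """Predicted mean emergence DOY at a predictor value, with a t-based CI.

    The interval is for the conditional mean (the regression line), not for a
    new individual seal.
    """
    X0 = pd.DataFrame({"const": [1.0], fit.predictor: [float(x0)]})
    pred = fit.result.get_prediction(X0)
    frame = pred.summary_frame(alpha=1.0 - level)
    return {
        "doy": float(frame["mean"].iloc[0]),
        "lo": float(frame["mean_ci_lower"].iloc[0]),
        "hi": float(frame["mean_ci_upper"].iloc[0]),
    }


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties) and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in rank_correlation input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def doy_to_date(doy: float, year: int) -> pd.Timestamp:
    """Convert a (possibly fractional) day-of-year to a calendar date."""
    return pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=round(doy) - 1)
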