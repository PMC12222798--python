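"""Spheroid growth quantification and facilitation statistics.

Fluorescence intensities are mapped to cell abundances through a linear
standard curve; per-replicate growth rates come from least-squares fits of
log abundance against time (exponential growth model); facilitation is the
coculture-minus-monoculture growth-rate increase, pooled across cancer cell
lines with a mixed model that allows line-specific coculture responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mutualism import exponential_window, fit_loglinear_rate
from .stats import TestResult

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "fit_growth_rate",
    "facilitation_effect",
    "facilitation_lmm",
    "dose_trend",
]


@dataclass
class StandardCurve:
    """count = intercept + slope * intensity, with the inverse map applied to assays."""

    intercept: float
    slope: float

    def to_counts(self, intensities) -> np.ndarray:
        pred = self.intercept + self.slope * np.asarray(intensities, float)
        neg = pred < 0
        if neg.any():
            warnings.warn(f"{int(neg.sum())} predicted abundances < 0 floored at 0")
            pred = np.clip(pred, 0.0, None)
        return pred

    def to_intensity(self, counts) -> np.ndarray:
        return (np.asarray(counts, float) - self.intercept) / self.slope


def fit_standard_curve(intensities, counts) -> StandardCurve:
    """OLS calibration of known cell counts against fluorescence intensities."""
    x = np.asarray(intensities, float)
    y = np.asarray(counts, float)
    if x.size < 2:
        raise ValueError("standard curve needs >=2 calibration points")
    A = np.vstack([np.ones_like(x), x]).T
    (a, b), *_ = np.linalg.lstsq(A, y, rcond=None)
    if b == 0:
        raise ValueError("flat standard curve; intensities carry no abundance signal")
    return StandardCurve(intercept=float(a), slope=float(b))


def fit_growth_rate(times, abundances, window: bool = False) -> tuple[float, float]:
    """Exponential growth rate (cells/cell/hour) by log-linear least squares.

    Zero or negative abundances are excluded. With ``window=True`` the fit is
    restricted to the earliest contiguous exponential-phase run.
    """
    t = np.asarray(times, float)
    n = np.asarray(abundances, float)
    bad = n <= 0
    if bad.any():
        warnings.warn(f"excluded {int(bad.sum())} non-positive abundances from the rate fit")
    if window:
        idx = exponential_window(t, n)
        t, n = t[idx], n[idx]
    return fit_loglinear_rate(t, n)


def facilitation_effect(g_co: float, g_mono: float, partner_abundance: float) -> float:
    """Per-partner-cell growth-rate increase: (g_co - g_mono) / partner abundance."""
    if partner_abundance <= 0:
        raise ValueError("partner abundance must be > 0")
    return (g_co - g_mono) / partner_abundance


def facilitation_lmm(rates: pd.DataFrame, dose_interaction: bool = False) -> dict:
    """Pooled facilitation estimate across cell lines by a linear mixed model.

    ``rates`` needs columns ``rate`` (cells/cell/hour), ``coculture`` (0/1),
    ``cell_line``, and optionally ``dose``. Fixed effect: coculture (plus
    dose x coculture when requested); random intercept and coculture slope
    per cell line. A single cell line reduces to OLS. Inference is an LRT of
    the coculture effect against the no-facilitation null.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy import stats as sps

    df = rates.copy()
    df["coculture"] = df["coculture"].astype(float)
    terms = "coculture" + (" + coculture:dose" if dose_interaction else "")
    if df["cell_line"].nunique() < 2:
        y = df["rate"].to_numpy(float)
        X = sm.add_constant(df["coculture"].to_numpy(float))
        fit = sm.OLS(y, X).fit()
        return {"estimate": float(fit.params[1]), "se": float(fit.bse[1]),
                "test": TestResult(statistic=float(fit.tvalues[1] ** 2), df=1,
                                   p_value=float(fit.pvalues[1]), estimate=float(fit.params[1])),
                "collapsed": True}

    def _fit(formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = smf.mixedlm(formula, df, groups=df["cell_line"], re_formula="~coculture")
            return m.fit(reml=False, method="lbfgs", maxiter=300)

    full = _fit(f"rate ~ {terms}")
    nul = _fit("rate ~ 1" + (" + coculture:dose" if dose_interaction else ""))
    est = float(full.fe_params["coculture"])
    stat = max(0.0, 2.0 * (full.llf - nul.llf))
    out = {"estimate": est, "se": float(full.bse_fe["coculture"]),
           "test": TestResult(statistic=stat, df=1, p_value=float(sps.chi2.sf(stat, 1)),
                              estimate=est),
           "collapsed": False}
    if dose_interaction:
        out["dose_interaction"] = float(full.fe_params.get("coculture:dose", np.nan))
    return out


def dose_trend(rates: pd.DataFrame, n_knots: int = 3) -> pd.DataFrame:
    """Smooth trend of the coculture growth benefit over drug dose.

    Fits a low-rank cubic-spline of (rate_co - mean mono rate at dose) on
    dose and returns the fitted curve; descriptive companion to the Fig-5D
    style dose-facilitation analysis.
    """
    from .axes import _spline_basis

    co = rates[rates["coculture"] == 1]
    mono = rates[rates["coculture"] == 0].groupby("dose")["rate"].mean()
    delta = co["rate"].to_numpy(float) - co["dose"].map(mono).to_numpy(float)
    x = co["dose"].to_numpy(float)
    if np.unique(x).size < 3:
        grid = np.unique(x)
        fitted = np.array([delta[x == g].mean() for g in grid])
        return pd.DataFrame({"dose": grid, "facilitation": fitted})
    grid = np.linspace(x.min(), x.max(), 50)
    B_all = _spline_basis(np.r_[x, grid], n_knots=n_knots)
    X = np.column_stack([np.ones_like(x), B_all[: len(x), 1:]])
    beta, *_ = np.linalg.lstsq(X, delta, rcond=None)
    Xg = np.column_stack([np.ones_like(grid), B_all[len(x):, 1:]])
    return pd.DataFrame({"dose": grid, "facilitation": Xg @ beta})
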