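"""Crude-palm-oil price annualization, elasticity, and series comparison.

The elasticity of land conversion with respect to the commodity price is
the slope of an ordinary-least-squares fit of ``ln(area_t)`` on
``ln(price_t)`` over calendar years — a 1% price change is associated with
a beta% change in the converted area. Pairing is contemporaneous (lag 0)
by default, with an optional integer lag of the price series. Series
comparison against an external annual estimate reports Pearson's r on the
raw series and the slope of a regression through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z95 = 1.96


def annual_mean_price(monthly: pd.DataFrame) -> pd.Series:
    """Arithmetic mean price per calendar year.

    ``monthly`` has columns ``year`` and ``price`` (a ``month`` column may
    be present). Years with no retained months are simply absent.
    """
    if not {"year", "price"}.issubset(monthly.columns):
        raise ValueError("monthly frame needs columns 'year' and 'price'")
    clean = monthly.dropna(subset=["price"])
    return clean.groupby("year")["price"].mean()


@dataclass
class ElasticityResult:
    """Log-log OLS elasticity of an annual series on price."""

    beta: float
    se: float
    ci: tuple[float, float]
    intercept: float
    r: float            # Pearson correlation of the logged series
    p_value: float      # p-value of the slope
    n: int

    def covers(self, value: float) -> bool:
        return self.ci[0] <= value <= self.ci[1]


def _as_year_series(x, value_name: str) -> pd.Series:
    if isinstance(x, pd.DataFrame):
        cols = [c for c in x.columns if c != "year"]
        if "year" in x.columns:
            return x.set_index("year")[cols[0]]
        return x[cols[0]]
    return pd.Series(x)


def estimate_elasticity(area, price, lag: int = 0) -> ElasticityResult:
    """OLS of ``ln(area)`` on ``ln(price)`` over shared years.

    ``area`` and ``price`` are year-indexed Series (or frames with a
    ``year`` column). ``lag`` shifts the price series: ``lag=1`` pairs this
    year's area with last year's price. Non-positive values are rejected,
    naming the offending year.
    """
    a = _as_year_series(area, "area")
    p = _as_year_series(price, "price")
    if lag:
        p = p.copy()
        p.index = p.index + lag
    joined = pd.concat({"area": a, "price": p}, axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError(
            f"only {len(joined)} overlapping years; need at least 3")
    for col in ("area", "price"):
        bad = joined.index[joined[col] <= 0]
        if len(bad):
            raise ValueError(
                f"non-positive {col} in year(s) {list(bad)}")
    log_a = np.log(joined["area"].to_numpy(dtype=float))
    log_p = np.log(joined["price"].to_numpy(dtype=float))
    model = sm.OLS(log_a, sm.add_constant(log_p)).fit()
    beta = float(model.params[1])
    se = float(model.bse[1])
    if np.ptp(log_p) == 0:  # constant price: slope degenerate
        r = 0.0
    else:
        r = float(stats.pearsonr(log_p, log_a).statistic)
    return ElasticityResult(
        beta=beta, se=se, ci=(beta - Z95 * se, beta + Z95 * se),
        intercept=float(model.params[0]), r=r,
        p_value=float(model.pvalues[1]), n=len(joined))


@dataclass
class SeriesComparison:
    """Agreement between two annual series over their shared years."""

    r: float
    p_value: float
    slope_through_origin: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n: int


def compare_series(a, b) -> SeriesComparison:
    """Pearson r, zero-intercept slope of a on b, and per-series moments.

    The slope is ``sum(a*b) / sum(b*b)``, the least-squares regression of
    ``a`` on ``b`` constrained through the origin. Standard deviations use
    the sample (n-1) form.
    """
    sa = _as_year_series(a, "a")
    sb = _as_year_series(b, "b")
    joined = pd.concat({"a": sa, "b": sb}, axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError(
            f"only {len(joined)} shared years; need at least 3")
    x = joined["a"].to_numpy(dtype=float)
    y = joined["b"].to_numpy(dtype=float)
    pr = stats.pearsonr(x, y)
    return SeriesComparison(
        r=float(pr.statistic), p_value=float(pr.pvalue),
        slope_through_origin=float(np.sum(x * y) / np.sum(y * y)),
        mean_a=float(x.mean()), sd_a=float(x.std(ddof=1)),
        mean_b=float(y.mean()), sd_b=float(y.std(ddof=1)),
        n=len(joined))
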