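"""Rainfall-regime metrics, annual aggregation, linear trends and driver
correlations.

Frequency and intensity indicators per cell (or site) and year:

* ``F_rain`` — fraction of wet hours, 0 < P < local 90th percentile;
* ``I_rain`` — fraction of intensely raining hours, P > that percentile;

with the percentile fixed once per cell over the full record, computed over
rainy hours only (linear-interpolation convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rainfall_threshold", "annual_fractions", "linear_trend",
           "correlate_drivers"]

MIN_RAINY_HOURS = 100


def rainfall_threshold(p_hourly, min_rainy: int = MIN_RAINY_HOURS) -> float:
    """90th percentile of hourly rainfall over all rainy hours (P > 0),
    fixed over the whole record.  Cells with too few rainy hours are masked
    (raises)."""
    p = np.asarray(p_hourly, dtype=float)
    rainy = p[p > 0]
    if len(rainy) < min_rainy:
        raise ValueError(f"fewer than {min_rainy} rainy hours; cell masked")
    return float(np.percentile(rainy, 90.0))


def annual_fractions(p_hourly: pd.Series, p90: float) -> pd.DataFrame:
    """Yearly fractions of wet (0 < P < p90) and intense (P > p90) hours.

    Denominator is the number of non-gap hours in each year; hours exactly at
    the threshold or dry make up the remainder, so the three parts partition
    each year exactly.
    """
    p = p_hourly.dropna()
    years = p.index.year
    grouped = p.groupby(years)
    n = grouped.count()
    f_rain = grouped.apply(lambda s: ((s > 0) & (s < p90)).sum()) / n
    i_rain = grouped.apply(lambda s: (s > p90).sum()) / n
    out = pd.DataFrame({"F_rain": f_rain, "I_rain": i_rain, "n_hours": n})
    out.index.name = "year"
    return out


def linear_trend(annual, min_years: int = 5) -> dict:
    """OLS trend of an annual series: slope per year, two-sided p-value, and
    the percent change over the record relative to its mean.

    percent_change = slope * (n - 1) / mean * 100.  A constant series gets
    slope 0 and p = 1.
    """
    y = np.asarray(annual, dtype=float)
    y = y[np.isfinite(y)]
    n = len(y)
    if n < min_years:
        raise ValueError(f"trend needs >= {min_years} years, got {n}")
    if np.ptp(y) == 0:
        return {"slope": 0.0, "pvalue": 1.0, "percent_change": 0.0, "n": n}
    res = stats.linregress(np.arange(n, dtype=float), y)
    mean = y.mean()
    pct = res.slope * (n - 1) / mean * 100.0 if mean != 0 else np.nan
    return {"slope": float(res.slope), "pvalue": float(res.pvalue),
            "percent_change": float(pct), "n": n}


def correlate_drivers(series: dict[str, np.ndarray], min_years: int = 5) -> pd.DataFrame:
    """Pairwise Pearson correlations (with two-sided p) between aligned
    annual series, on the raw (non-detrended) values.

    Returns a tidy frame with columns a, b, r, pvalue; r is NaN where a
    series has zero variance.
    """
    names = list(series)
    arrs = {k: np.asarray(v, dtype=float) for k, v in series.items()}
    n = {len(a) for a in arrs.values()}
    if len(n) != 1:
        raise ValueError("annual series must be aligned (equal length)")
    if n.pop() < min_years:
        raise ValueError(f"need >= {min_years} years")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x, y = arrs[a], arrs[b]
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append((a, b, np.nan, np.nan))
            else:
                r, p = stats.pearsonr(x, y)
                rows.append((a, b, float(r), float(p)))
    return pd.DataFrame(rows, columns=["a", "b", "r", "pvalue"])
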