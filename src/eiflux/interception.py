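"""Hourly and event-level interception evaporation, and the event-level
driver analysis (rainfall amount/intensity, leaf area, wind).

The interception flux is the wet-model minus dry-model LE difference on
identical in-event forcing, converted from energy to water depth with the
temperature-dependent latent heat of vaporization.  Negative hourly
differences (measurement/model noise) are removed, not zeroed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .events import RainEvent
from .hybrid import CWSModel, HybridModel, predict_le
from .pm import latent_heat_of_vaporization

__all__ = [
    "energy_to_depth", "estimate_ei_hourly", "aggregate_event",
    "aggregate_events", "driver_analysis", "fit_rational", "fit_linear",
]


def energy_to_depth(le, ta):
    """Convert a latent heat flux (W m-2) to water depth per hour (mm h-1)."""
    return np.asarray(le, dtype=float) * 3600.0 / latent_heat_of_vaporization(ta)


def estimate_ei_hourly(hm_wet: HybridModel, hm_dry: HybridModel,
                       wet_table: pd.DataFrame,
                       cws_model: CWSModel | None = None,
                       descriptors: pd.DataFrame | None = None,
                       override_stats: dict | None = None) -> pd.DataFrame:
    """Hourly interception estimates for in-event hours.

    When ``cws_model`` is given, CWS is inferred from ``descriptors`` (which
    must carry the descriptor columns plus LAI and pft for the same hours)
    and installed as the wet model's extra predictor.  Returns one row per
    wet hour with the energy difference, the depth estimate and flags; hours
    with negative differences are flagged ``removed`` and their Ei is NaN.
    """
    table = wet_table.copy()
    if cws_model is not None:
        if descriptors is None:
            raise ValueError("descriptors required to infer CWS")
        desc = descriptors.reindex(table.index)
        missing = desc["cum_p_event"].isna()
        table = table[~missing.to_numpy()]
        desc = desc[~missing.to_numpy()]
        table["cws"] = cws_model.predict(desc)
    elif "cws" not in table.columns:
        raise ValueError("wet model needs CWS: pass cws_model or a cws column")
    le_wet = predict_le(hm_wet, table, override_stats=override_stats)
    le_dry = predict_le(hm_dry, table)
    diff = le_wet - le_dry
    depth = energy_to_depth(diff, table["Ta"].to_numpy())
    out = pd.DataFrame(
        {
            "le_wet_hat": le_wet, "le_dry_hat": le_dry, "ei_energy": diff,
            "ei_mm": np.where(diff >= 0, depth, np.nan),
            "P": table["P"].to_numpy(),
            "removed": diff < 0,
            "skipped": ~np.isfinite(diff),
        },
        index=table.index,
    )
    return out


def aggregate_event(ei_hours: pd.DataFrame, event: RainEvent,
                    index: pd.DatetimeIndex,
                    low_confidence_frac: float = 0.2) -> dict:
    """Event totals: Ei (mm), P (mm, all event hours incl. tail rain), ratio.

    Flags the event low-confidence when more than ``low_confidence_frac`` of
    its hours are absent from the hourly table (skipped or excluded).
    """
    hours = index[event.hours()]
    sub = ei_hours.reindex(hours)
    present = sub["ei_energy"].notna()
    ei = float(sub["ei_mm"].sum())
    p = event.total_p
    return {
        "event_start": hours[0], "n_hours": event.duration,
        "ei_mm": ei, "p_mm": p,
        "ratio": ei / p if p > 0 else np.nan,
        "low_confidence": bool(present.mean() < 1.0 - low_confidence_frac),
    }


def aggregate_events(ei_hours: pd.DataFrame, events: list[RainEvent],
                     index: pd.DatetimeIndex,
                     covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tidy table of per-event totals; optionally attach event-mean covariates
    (LAI, WS, ...) and per-event rain intensity metrics for driver analysis."""
    rows = []
    for ev in events:
        rec = aggregate_event(ei_hours, ev, index)
        hrs = index[ev.hours()]
        rainy = None
        if covariates is not None:
            cov = covariates.reindex(hrs)
            rainy = cov["P"] > 0
            rec["lai"] = float(cov["LAI"].mean())
            rec["ws"] = float(cov["WS"].mean())
            rec["max_hourly_p"] = float(cov["P"].max())
            rec["mean_hourly_p"] = float(cov["P"][rainy].mean()) if rainy.any() else 0.0
        rows.append(rec)
    return pd.DataFrame(rows)


def _rational(x, p, q):
    return p / (x + q)


def fit_rational(x, y):
    """Least-squares fit of ratio = p/(x + q); returns (p, q, r, pvalue)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    try:
        (p, q), _ = optimize.curve_fit(_rational, x, y, p0=[np.median(y) * (np.median(x) + 1.0), 1.0],
                                       maxfev=20000)
    except RuntimeError:
        return {"converged": False}
    r, pv = stats.pearsonr(x, y)
    return {"converged": True, "p": float(p), "q": float(q),
            "r": float(r), "pvalue": float(pv)}


def fit_linear(x, y):
    """OLS fit ratio = a + b x; returns intercept, slope, Pearson r, p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"converged": True, "a": float(np.mean(y)), "b": 0.0,
                "r": 0.0, "pvalue": 1.0}
    res = stats.linregress(x, y)
    return {"converged": True, "a": float(res.intercept), "b": float(res.slope),
            "r": float(res.rvalue), "pvalue": float(res.pvalue)}


#: driver -> (column, fit family); rainfall metrics use the rational form
DRIVERS = {
    "total_p": ("p_mm", "rational"),
    "max_hourly_p": ("max_hourly_p", "rational"),
    "mean_hourly_p": ("mean_hourly_p", "rational"),
    "lai": ("lai", "linear"),
    "ws": ("ws", "linear"),
}


def driver_analysis(events: pd.DataFrame, by_pft: bool = False,
                    min_events: int = 30) -> dict:
    """Fit the event-level Ei/P ratio against its candidate drivers.

    Rainfall amount/intensity metrics get the rational model p/(x + q);
    leaf area and wind speed get linear fits; Pearson correlations with
    two-sided p-values throughout.  Requires at least ``min_events`` events.
    """
    ok = events["ratio"].notna()
    ev = events[ok]
    if len(ev) < min_events:
        raise ValueError(f"driver analysis needs >= {min_events} events, got {len(ev)}")
    out = {}
    for name, (col, family) in DRIVERS.items():
        if col not in ev.columns:
            continue
        x, y = ev[col].to_numpy(), ev["ratio"].to_numpy()
        fin = np.isfinite(x) & np.isfinite(y)
        fit = fit_rational(x[fin], y[fin]) if family == "rational" else fit_linear(x[fin], y[fin])
        fit["family"] = family
        out[name] = fit
    if by_pft and "pft" in ev.columns:
        out["by_pft"] = {
            pft: driver_analysis(grp, by_pft=False, min_events=min_events)
            for pft, grp in ev.groupby("pft") if len(grp) >= min_events
        }
    return out
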