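"""Applying the trained models to gridded forcing.

Conventions: gridded forcing is an xarray Dataset with dims (time, lat, lon),
hourly variables Ta (degC), VPD (kPa), Rn, G (W m-2), WS (m s-1), P (mm h-1),
hourly LAI, plus static ``pft`` (string code per cell) and ``f_veg`` in [0,1].
Files use NetCDF3 through xarray's scipy engine.

Grid features are standardized with the statistics stored in the trained
models (site-derived); the latent CWS predictor alone is re-standardized with
mean/SD computed from grid cells around the training sites, because site- and
grid-derived CWS are quantitatively different and only the wet model sees it.
Sub-grid light rain (hours with 0 < P < 0.5 mm outside any event) gets an
interception ratio interpolated linearly between the vegetated fraction (the
P -> 0 limit, full interception over canopy) and the per-PFT ratio observed
near 0.6 mm at the sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import make_smoothing_spline

from .core import PFT8, SiteSeries, night_mask
from .events import detect_events, descriptor_frame, label_hours
from .hybrid import CWSModel, HybridModel
from .interception import estimate_ei_hourly
from .pm import aerodynamic_resistance
from .qc import IGBP_TO_PFT8, merge_pft

__all__ = [
    "NormalizationStats", "interpolate_lai", "dominant_pft",
    "light_rain_correction", "light_rain_ratio", "anchor_ratios", "tile_site_to_grid",
    "predict_grid_ei", "cws_window_stats",
]

LIGHT_RAIN_MAX = 0.5   # mm, below the event-start threshold
ANCHOR_P = 0.6         # mm, anchor of the light-rain interpolation
ANCHOR_BAND = (0.5, 0.7)

#: default canopy heights by functional type, m (reference height +10 m)
CANOPY_HEIGHT_BY_PFT = {
    "EBF": 30.0, "DBF": 20.0, "ENF": 15.0, "MF": 18.0,
    "SAV": 8.0, "SHU": 2.0, "GRA": 0.5, "CRO": 1.0,
}


@dataclass
class NormalizationStats:
    """Standardization statistics for grid prediction.

    Predictor stats live inside the trained models; this carries only the
    grid-window CWS replacement (mean, SD from cells around the sites).
    """

    cws_mean: float
    cws_sd: float

    def __post_init__(self):
        if self.cws_sd <= 0:
            raise ValueError("CWS SD must be positive")


def interpolate_lai(times, values, hourly_index: pd.DatetimeIndex,
                    lam: float | None = 1e-3) -> np.ndarray:
    """Interpolate 8-day LAI composites to hourly with a cubic smoothing
    spline, clipped at 0.

    ``times`` may be timestamps or day numbers; ``lam`` is the smoothing
    weight (small: near-interpolating; None lets GCV choose).
    """
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 4:
        raise ValueError("need at least 4 valid composite points")
    t = pd.DatetimeIndex(times) if not np.issubdtype(np.asarray(times).dtype, np.number) else None
    if t is not None:
        x = t.view("int64") / 8.64e13   # days
        xq = hourly_index.view("int64") / 8.64e13
    else:
        x = np.asarray(times, dtype=float)
        xq = np.asarray(hourly_index, dtype=float)
    spline = make_smoothing_spline(x[ok], values[ok], lam=lam)
    return np.clip(spline(xq), 0.0, None)


def dominant_pft(fractions: dict[str, float]) -> str | None:
    """Dominant functional type after merging IGBP classes; ties break by the
    fixed PFT order.  Returns None for an unvegetated (all-zero) cell."""
    if sum(fractions.values()) > 1.0 + 1e-9:
        raise ValueError("cover fractions exceed 1")
    merged = dict.fromkeys(PFT8, 0.0)
    for code, frac in fractions.items():
        if frac < 0:
            raise ValueError("negative cover fraction")
        if code in IGBP_TO_PFT8:
            merged[merge_pft(code)] += frac
    if max(merged.values()) <= 0:
        return None
    return max(PFT8, key=lambda p: (merged[p], -PFT8.index(p)))


def light_rain_ratio(p: float, pft: str, f_veg: float,
                     ratio_at_0p6: dict[str, float] | float) -> float:
    """Interception ratio for light rain: linear in P between f_veg at
    P = 0 (complete interception over the vegetated part) and the per-PFT
    event-derived ratio at the 0.6 mm anchor."""
    r06 = ratio_at_0p6[pft] if isinstance(ratio_at_0p6, dict) else float(ratio_at_0p6)
    return f_veg + (r06 - f_veg) * (p / ANCHOR_P)


def light_rain_correction(p: float, pft: str, f_veg: float,
                          ratio_at_0p6: dict[str, float] | float) -> float:
    """Interception (mm) for sub-threshold rain outside events:
    Ei = ratio(P) * P with the linearly interpolated ratio."""
    if not (0.0 < p < LIGHT_RAIN_MAX):
        raise ValueError(f"light-rain correction applies to 0 < P < {LIGHT_RAIN_MAX} mm")
    return light_rain_ratio(p, pft, f_veg, ratio_at_0p6) * p


def anchor_ratios(event_table: pd.DataFrame) -> dict[str, float]:
    """Per-PFT mean event Ei/P for events with mean hourly rain in the
    0.5-0.7 mm band (the sample-rich neighborhood of the 0.6 mm anchor)."""
    lo, hi = ANCHOR_BAND
    sel = event_table[
        event_table["mean_hourly_p"].between(lo, hi) & event_table["ratio"].notna()
    ]
    out = sel.groupby("pft")["ratio"].mean().to_dict()
    pooled = float(sel["ratio"].mean()) if len(sel) else 0.2
    return {p: out.get(p, pooled) for p in PFT8}


def cws_window_stats(cws_values) -> NormalizationStats:
    """CWS normalization from grid cells in the windows around the sites."""
    v = np.asarray(cws_values, dtype=float)
    v = v[np.isfinite(v)]
    return NormalizationStats(cws_mean=float(v.mean()), cws_sd=float(v.std()) or 1.0)


def tile_site_to_grid(site: SiteSeries, f_veg: float = 1.0,
                      nlat: int = 1, nlon: int = 1) -> xr.Dataset:
    """Build a gridded forcing Dataset by tiling one site's record."""
    df = site.data
    shape = (len(df), nlat, nlon)
    data = {}
    for v in ["Ta", "VPD", "Rn", "G", "WS", "P", "LAI"]:
        data[v] = (("time", "lat", "lon"),
                   np.broadcast_to(df[v].to_numpy()[:, None, None], shape).copy())
    ds = xr.Dataset(
        data,
        coords={
            "time": df.index,
            "lat": site.lat + 0.5 * np.arange(nlat),
            "lon": site.lon + 0.5 * np.arange(nlon),
        },
    )
    ds["pft"] = (("lat", "lon"), np.full((nlat, nlon), site.pft, dtype=object))
    ds["f_veg"] = (("lat", "lon"), np.full((nlat, nlon), float(f_veg)))
    return ds


def _cell_tables(grid: xr.Dataset, ilat: int, ilon: int):
    """Per-hour table + events + descriptors for one grid cell."""
    cell = grid.isel(lat=ilat, lon=ilon)
    pft = str(cell["pft"].item())
    lat = float(grid["lat"][ilat])
    index = pd.DatetimeIndex(grid["time"].to_numpy())
    night = night_mask(index, lat)
    P = cell["P"].to_numpy()
    canopy_h = CANOPY_HEIGHT_BY_PFT[pft]
    ra = aerodynamic_resistance(cell["WS"].to_numpy(), canopy_h + 10.0, canopy_h)
    table = pd.DataFrame(
        {
            "Ta": cell["Ta"].to_numpy(), "VPD": cell["VPD"].to_numpy(),
            "Rn": cell["Rn"].to_numpy(), "WS": cell["WS"].to_numpy(),
            "LAI": cell["LAI"].to_numpy(),
            "A": cell["Rn"].to_numpy() - cell["G"].to_numpy(),
            "ra": ra, "LE": np.nan, "P": P, "pft": pft,
        },
        index=index,
    )
    events = detect_events(P, night)
    desc = descriptor_frame(events, P, index)
    desc["LAI"] = table["LAI"].reindex(desc.index).to_numpy()
    desc["pft"] = pft
    return table, events, desc


def predict_grid_ei(hm_wet: HybridModel, hm_dry: HybridModel,
                    cws_model: CWSModel, grid: xr.Dataset,
                    stats: NormalizationStats | None = None,
                    ratio_at_0p6: dict[str, float] | float = 0.2) -> xr.DataArray:
    """Hourly interception maps (mm h-1) for a gridded forcing Dataset.

    Per cell: detect events from the cell's rainfall, infer CWS from the
    descriptors (standardized with the grid-window stats when given), run
    both hybrid models on wet hours, and apply the light-rain ratio to
    sub-threshold rain outside events; everything scales with the cell's
    vegetated fraction.
    """
    out = np.zeros(grid["P"].shape)
    index = pd.DatetimeIndex(grid["time"].to_numpy())
    override = None
    if stats is not None:
        override = {"cws": (stats.cws_mean, stats.cws_sd)}
    for ilat in range(grid.sizes["lat"]):
        for ilon in range(grid.sizes["lon"]):
            f_veg = float(grid["f_veg"][ilat, ilon])
            if f_veg <= 0 or grid["pft"][ilat, ilon].item() is None:
                continue
            table, events, desc = _cell_tables(grid, ilat, ilon)
            pft = str(grid["pft"][ilat, ilon].item())
            if events:
                wet_hours = np.concatenate([ev.hours() for ev in events])
                wet = table.iloc[np.sort(wet_hours)]
                ei = estimate_ei_hourly(hm_wet, hm_dry, wet, cws_model=cws_model,
                                        descriptors=desc, override_stats=override)
                vals = ei["ei_mm"].fillna(0.0)
                pos = index.get_indexer(vals.index)
                out[pos, ilat, ilon] = vals.to_numpy() * f_veg
            in_event = np.zeros(len(index), dtype=bool)
            for ev in events:
                in_event[ev.hours()] = True
            P = table["P"].to_numpy()
            light = (~in_event) & (P > 0) & (P < LIGHT_RAIN_MAX)
            for i in np.flatnonzero(light):
                out[i, ilat, ilon] = light_rain_correction(P[i], pft, f_veg,
                                                           ratio_at_0p6)
    return xr.DataArray(out, coords=grid["P"].coords, dims=grid["P"].dims,
                        name="Ei", attrs={"units": "mm h-1"})
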