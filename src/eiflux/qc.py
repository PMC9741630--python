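"""Tower-CSV ingest, quality filtering, PFT merging, LAI site-scaling,
half-hourly aggregation, the humidity/rain LE correction, and Bowen-ratio
energy-balance closure.

Quality-failing hours are *masked*, never deleted, so event detection always
sees the original hourly time axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .core import PFT8, SERIES_COLUMNS, SiteSeries

__all__ = [
    "QCReport", "read_site_csv", "aggregate_to_hourly", "apply_qc_filters",
    "merge_pft", "scale_site_lai", "LERModel", "fit_ler_model",
    "correct_le_humidity_rain", "bowen_closure",
]

#: IGBP land-cover codes mapped onto the eight retained functional types.
IGBP_TO_PFT8 = {
    "EBF": "EBF", "DBF": "DBF", "ENF": "ENF", "MF": "MF",
    "SAV": "SAV", "WSA": "SAV",
    "SHU": "SHU", "OSH": "SHU", "CSH": "SHU",
    "GRA": "GRA", "CRO": "CRO",
}

#: Offset admitting P = 0 in the log-transformed rain predictor, mm.
LOG_P_OFFSET = 0.01

# FLUXNET2015 FULLSET names accepted out of the box (internal -> CSV column)
DEFAULT_COLUMN_MAP = {
    "timestamp": "TIMESTAMP_START",
    "Ta": "TA_F", "RH": "RH", "VPD": "VPD_F", "Rn": "NETRAD",
    "G": "G_F_MDS", "H": "H_F_MDS", "LE": "LE_F_MDS", "WS": "WS_F",
    "P": "P_F", "qc": "LE_F_MDS_QC", "LAI": "LAI",
}

REQUIRED = ["timestamp", "Ta", "RH", "VPD", "Rn", "G", "H", "LE", "WS", "P"]


@dataclass
class QCReport:
    """Per-rule tally of removed records; removed + retained = input."""

    input_count: int
    removed: dict[str, int] = field(default_factory=dict)
    retained: int = 0

    def check(self):
        assert sum(self.removed.values()) + self.retained == self.input_count


def merge_pft(raw_pft: str) -> str:
    """Merge an IGBP code into the eight retained functional types.

    Woody savanna joins savanna; open/closed shrublands join shrublands.
    """
    try:
        return IGBP_TO_PFT8[raw_pft]
    except KeyError:
        raise ValueError(f"unsupported PFT {raw_pft!r} (e.g. wetlands are excluded)") from None


def read_site_csv(path, column_map: dict | None = None, *, vpd_unit: str | None = None,
                  **metadata) -> SiteSeries:
    """Read a tower CSV into a typed hourly/half-hourly series.

    ``column_map`` maps internal names (Ta, RH, VPD, ...) to CSV column
    names; unmapped internal names fall back to the FLUXNET2015 FULLSET
    vocabulary, then to the internal name itself.  VPD is converted
    hPa -> kPa when it comes from a FLUXNET column (``vpd_unit`` forces
    either unit); precipitation per time step is converted to mm h-1 on
    aggregation.  Half-hourly spacing is detected from the median step.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    # resolution order: explicit map, FLUXNET default, the internal name itself
    for k in list(cmap):
        if cmap[k] not in raw.columns and k in raw.columns:
            cmap[k] = k
    missing = [k for k in REQUIRED if cmap[k] not in raw.columns]
    if missing:
        raise KeyError(f"missing required column(s): {missing}")
    ts_raw = raw[cmap["timestamp"]].astype(str)
    if ts_raw.str.fullmatch(r"\d{12}").all():   # FLUXNET YYYYMMDDHHMM
        ts = pd.to_datetime(ts_raw, format="%Y%m%d%H%M", errors="coerce")
    else:
        ts = pd.to_datetime(ts_raw, format="mixed", errors="coerce")
    bad = ts.isna()
    if bad.any():
        raise ValueError(f"unparseable timestamps at rows {list(np.flatnonzero(bad))[:10]}")
    df = pd.DataFrame(index=pd.DatetimeIndex(ts.values))
    for name in SERIES_COLUMNS:
        col = cmap.get(name)
        if col is not None and col in raw.columns:
            df[name] = pd.to_numeric(raw[col], errors="coerce").to_numpy()
        else:
            df[name] = 0 if name == "qc" else np.nan
    if vpd_unit is None:
        vpd_unit = "kPa" if cmap["VPD"] == "VPD" else "hPa"
    if vpd_unit == "hPa":
        df["VPD"] = df["VPD"] / 10.0
    step = np.median(np.diff(df.index.view("int64"))) / 3.6e12
    half_hourly = bool(abs(step - 0.5) < 1e-6)
    series = SiteSeries(data=df, half_hourly=half_hourly,
                        **{k: v for k, v in metadata.items() if v is not None})
    return series


def aggregate_to_hourly(series: SiteSeries) -> SiteSeries:
    """Average states/fluxes and sum precipitation over half-hour pairs.

    An hour is valid only if both half-hours are valid; an odd trailing
    half-hour is dropped with a warning.
    """
    if not series.half_hourly:
        raise ValueError("series is not half-hourly")
    df = series.data
    if len(df) % 2 == 1:
        warnings.warn("odd trailing half-hour dropped", stacklevel=2)
        df = df.iloc[:-1]
    hour = df.index.floor("h")
    mean_cols = ["Ta", "RH", "VPD", "Rn", "G", "H", "LE", "WS", "LAI"]
    grouped = df.groupby(hour)
    out = grouped[mean_cols].mean()
    out["P"] = grouped["P"].sum()
    out["qc"] = grouped["qc"].max()
    # both-halves rule: any missing half poisons the hour's states/fluxes
    counts = grouped[mean_cols + ["P"]].count()
    incomplete = (counts < 2).any(axis=1)
    out.loc[incomplete, mean_cols + ["P"]] = np.nan
    out = out[[c for c in SERIES_COLUMNS]]
    new = series.copy()
    new.data = out
    new.half_hourly = False
    return new


def apply_qc_filters(series: SiteSeries, *, poor_quality_flag: int = 2) -> tuple[SiteSeries, QCReport]:
    """Mask hours with negative LE, poor-quality flags, or freezing air.

    The freezing rule (Ta < 0 degC) avoids confounding snowfall interception.
    ``poor_quality_flag`` is the lowest QC code treated as poor (gap-filled
    FLUXNET codes grow worse with magnitude).  Hours with missing required
    fields are masked under rule ``gap``.  Rules are tallied with precedence
    gap > negative_LE > poor_quality > freezing (an hour counts once).
    """
    out = series.copy()
    df = out.data
    n = len(df)
    gap = df[["Ta", "RH", "VPD", "Rn", "G", "H", "LE", "WS", "P"]].isna().any(axis=1)
    neg_le = (~gap) & (df["LE"] < 0)
    poor = (~gap) & (~neg_le) & (df["qc"] >= poor_quality_flag)
    freezing = (~gap) & (~neg_le) & (~poor) & (df["Ta"] < 0)
    excluded = gap | neg_le | poor | freezing
    df["excluded"] = excluded
    rule = np.full(n, "", dtype=object)
    rule[freezing.to_numpy()] = "freezing"
    rule[poor.to_numpy()] = "poor_quality"
    rule[neg_le.to_numpy()] = "negative_LE"
    rule[gap.to_numpy()] = "gap"
    df["qc_rule"] = rule
    report = QCReport(
        input_count=n,
        removed={
            "gap": int(gap.sum()), "negative_LE": int(neg_le.sum()),
            "poor_quality": int(poor.sum()), "freezing": int(freezing.sum()),
        },
        retained=int((~excluded).sum()),
    )
    report.check()
    return out, report


def scale_site_lai(grid_lai, site_max: float, grid_max: float):
    """Rescale grid-mean LAI to the site by the ratio of maxima."""
    if grid_max <= 0:
        raise ValueError("grid maximum LAI must be positive")
    if site_max is None or not np.isfinite(site_max):
        raise ValueError("site maximum LAI missing; supply the nearest "
                         "same-PFT site's scaling factor")
    return np.asarray(grid_lai, dtype=float) * (site_max / grid_max)


class LERModel:
    """Per-site regressor of the latent energy ratio LE/(Rn - G - H) on
    relative humidity and log-transformed hourly rainfall."""

    def __init__(self, seed: int = 0, hidden: int = 16, max_iter: int = 2000):
        # lbfgs: full-batch quasi-Newton, far better behaved than SGD variants
        # for this tiny single-layer net
        self.pipe = make_pipeline(
            StandardScaler(),
            MLPRegressor(hidden_layer_sizes=(hidden,), activation="relu",
                         solver="lbfgs", random_state=seed, max_iter=max_iter,
                         tol=1e-8),
        )

    def fit(self, rh, p, ler):
        X = np.column_stack([rh, np.log(np.asarray(p, dtype=float) + LOG_P_OFFSET)])
        self.pipe.fit(X, np.asarray(ler, dtype=float))
        return self

    def predict(self, rh, p):
        X = np.column_stack([np.asarray(rh, dtype=float),
                             np.log(np.asarray(p, dtype=float) + LOG_P_OFFSET)])
        return self.pipe.predict(X)


def fit_ler_model(series: SiteSeries, seed: int = 0) -> LERModel:
    """Fit the site's LER model on hours with positive available energy.

    All hours with Rn - G - H > 0 and valid LE enter the fit (wet and dry
    alike); hours with non-positive denominator are excluded from fitting
    only.
    """
    df = series.data
    denom = df["Rn"] - df["G"] - df["H"]
    ok = (denom > 0) & df["LE"].notna() & df["RH"].notna() & df["P"].notna()
    if "excluded" in df.columns:
        ok &= ~df["excluded"]
    if ok.sum() < 50:
        raise ValueError("too few hours with positive available energy to fit LER model")
    ler = (df["LE"] / denom)[ok]
    return LERModel(seed=seed).fit(df["RH"][ok], df["P"][ok], ler)


def correct_le_humidity_rain(series: SiteSeries, ler_model: LERModel) -> SiteSeries:
    """Rescale LE so its latent energy ratio sits at the reference level
    (RH = 50 %, no rain): LE_cor = LE * LER_ref / LER_pred(RH, P).

    Counteracts the systematic underestimation of eddy-covariance LE under
    rain and high humidity.  Hours where the predicted LER is non-positive
    are flagged (``ler_flagged``) and left uncorrected.
    """
    out = series.copy()
    df = out.data
    ler_pred = ler_model.predict(df["RH"].to_numpy(), df["P"].to_numpy())
    ler_ref = float(ler_model.predict([50.0], [0.0])[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = ler_ref / ler_pred
    bad = ~(ler_pred > 0) | ~np.isfinite(factor)
    factor = np.where(bad, 1.0, factor)
    df["LE_raw"] = df["LE"]
    df["LE"] = df["LE"] * factor
    df["ler_flagged"] = bad
    return out


def bowen_closure(series: SiteSeries) -> SiteSeries:
    """Close the surface energy balance while preserving the Bowen ratio:
    LE_cor = (Rn - G) * LE / (LE + H), H rescaled likewise.

    Hours with LE + H <= 0 are flagged (``bowen_flagged``) and left unchanged;
    afterwards LE + H = Rn - G exactly for every unflagged hour.
    """
    out = series.copy()
    df = out.data
    turb = df["LE"] + df["H"]
    ok = turb > 0
    scale = (df["Rn"] - df["G"]) / turb
    df.loc[ok, "LE"] = df.loc[ok, "LE"] * scale[ok]
    df.loc[ok, "H"] = df.loc[ok, "H"] * scale[ok]
    df["bowen_flagged"] = ~ok
    return out
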