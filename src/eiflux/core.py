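"""Shared containers: the hourly tower record and the synthetic ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The eight retained plant functional types, in the fixed order used for
#: one-hot encoding and deterministic tie-breaking.
PFT8 = ("EBF", "DBF", "ENF", "MF", "SAV", "SHU", "GRA", "CRO")

#: Columns every hourly tower record carries (qc: 0 = good, 1 = poor quality).
SERIES_COLUMNS = ["Ta", "RH", "VPD", "Rn", "G", "H", "LE", "WS", "P", "qc", "LAI"]


@dataclass
class SiteSeries:
    """An ordered hourly (or half-hourly) single-tower record.

    ``data`` is a DataFrame indexed by local solar timestamp with the columns
    in :data:`SERIES_COLUMNS` plus any derived ones (``night``, ``excluded``,
    ``qc_rule``).  Site metadata lives on the dataclass.
    """

    data: pd.DataFrame
    lat: float = 45.0
    lon: float = 0.0
    pft: str = "DBF"
    canopy_height: float = 20.0
    tower_height: float = 30.0
    ec_system: str = "OP"
    site_id: str = "SYN-0"
    half_hourly: bool = False

    def __post_init__(self):
        if self.pft not in PFT8:
            raise ValueError(f"unsupported PFT {self.pft!r}; expected one of {PFT8}")
        missing = [c for c in SERIES_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"series missing columns: {missing}")
        if not self.data.index.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def step_hours(self) -> float:
        dt = np.diff(self.data.index.view("int64"))
        return float(np.median(dt)) / 3.6e12

    def copy(self) -> "SiteSeries":
        out = SiteSeries.__new__(SiteSeries)
        out.__dict__.update(self.__dict__)
        out.data = self.data.copy()
        return out


@dataclass
class TruthSeries:
    """Known ground truth carried alongside a synthetic site.

    Fields are aligned with the site's hourly index: the dry-canopy latent
    heat baseline, the interception evaporation flux, and the canopy water
    bucket trajectory (store C bounded by capacity S).
    """

    le_dry_true: np.ndarray   # W m-2
    ei_true: np.ndarray       # mm h-1
    store: np.ndarray         # C, mm, at end of each hour
    capacity: np.ndarray      # S, mm
    index: pd.DatetimeIndex = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "LE_dry_true": self.le_dry_true,
                "Ei_true": self.ei_true,
                "C": self.store,
                "S": self.capacity,
            },
            index=self.index,
        )


def solar_elevation(index: pd.DatetimeIndex, lat: float) -> np.ndarray:
    """Sine of solar elevation for each timestamp at latitude ``lat`` (deg).

    Standard declination/hour-angle geometry; timestamps are local solar time.
    """
    doy = index.dayofyear.to_numpy()
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    decl = np.deg2rad(23.45) * np.sin(2 * np.pi * (284 + doy) / 365.0)
    ha = np.deg2rad(15.0 * (hour - 12.0))
    latr = np.deg2rad(lat)
    return np.sin(latr) * np.sin(decl) + np.cos(latr) * np.cos(decl) * np.cos(ha)


def night_mask(index: pd.DatetimeIndex, lat: float) -> np.ndarray:
    """Boolean night mask (solar elevation below the horizon)."""
    return solar_elevation(index, lat) < 0.0
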