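"""Physics-constrained hybrid models of latent heat flux.

Two feed-forward networks map environmental predictors to the log of the
Penman-Monteith surface resistance:

* the *dry* model (predictors Ta, VPD, Rn, WS, LAI, PFT) is trained only on
  hours outside rain events, so applied to in-event hours it yields the
  counterfactual LE that would occur in the absence of rainfall;
* the *wet* model adds canopy water storage (CWS) as a predictor and is
  trained on in-event hours.

Training targets are ln Rs obtained by the exact PM inversion of observed LE
(a bijection at fixed meteorological state, so matching ln Rs matches LE
through the forward operator); predictions run back through ``pm_forward``,
which guarantees non-negative LE and exact surface energy balance.

A third network regresses the CWS proxy (observed LE minus the dry baseline
on wet hours) on vegetation state and the eight rainfall descriptors, making
CWS available where it cannot be observed (prediction and upscaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPRegressor

from .core import PFT8, SiteSeries
from .pm import PMState, aerodynamic_resistance, pm_forward, pm_invert

__all__ = [
    "TrainConfig", "HybridModel", "CWSModel", "build_training_table",
    "train_hybrid", "predict_le", "derive_cws_proxy", "train_cws_net",
]

DRY_PREDICTORS = ["Ta", "VPD", "Rn", "WS", "LAI"]
WET_PREDICTORS = DRY_PREDICTORS + ["cws"]

#: numeric CWS-net predictors; the cyclic end-of-pulse time enters as sin/cos
CWS_DESCRIPTORS = [
    "cum_p_event", "mean_p_event", "max_p_event", "p_now",
    "cum_p_last_pulse", "max_p_last_pulse", "dry_hours_since_pulse",
]


@dataclass(frozen=True)
class TrainConfig:
    hidden_layers: tuple[int, ...] = (64, 64)
    max_iter: int = 300
    seed: int = 0
    rs_floor: float = 1.0      # s m-1, floor before the log transform
    min_samples_hybrid: int = 1000
    min_samples_cws: int = 500
    extrapolation_sd: float = 10.0


def _one_hot_pft(pft: pd.Series) -> np.ndarray:
    codes = pd.Categorical(pft, categories=PFT8)
    if codes.isna().any():
        raise ValueError("unknown PFT code in samples")
    return np.eye(len(PFT8))[codes.codes]


def build_training_table(series: SiteSeries, labels: pd.Series,
                         cws: pd.Series | None = None) -> pd.DataFrame:
    """Assemble one site's per-hour sample table for training/prediction.

    Carries the predictors, the PM state inputs (available energy, ra) and
    observed LE, plus the wet/dry/excluded label.  ``cws`` (W m-2) is merged
    on the timestamp index when given.
    """
    df = series.data
    ra = aerodynamic_resistance(df["WS"].to_numpy(), series.tower_height,
                                series.canopy_height)
    table = pd.DataFrame(
        {
            "Ta": df["Ta"], "VPD": df["VPD"], "Rn": df["Rn"], "WS": df["WS"],
            "LAI": df["LAI"], "A": df["Rn"] - df["G"], "ra": ra,
            "LE": df["LE"], "P": df["P"],
            "pft": series.pft, "site_id": series.site_id,
            "label": labels.reindex(df.index).to_numpy(),
        },
        index=df.index,
    )
    if cws is not None:
        table["cws"] = cws.reindex(df.index)
    return table


def _pm_state(table: pd.DataFrame) -> PMState:
    return PMState(ta=table["Ta"].to_numpy(), vpd=table["VPD"].to_numpy(),
                   available_energy=table["A"].to_numpy(),
                   ra=table["ra"].to_numpy())


@dataclass
class HybridModel:
    """A trained hybrid LE model: network over ln Rs + normalization stats.

    ``residual_quantiles`` hold the held-out ln Rs residual distribution used
    for the retransformation (smearing) correction: the network estimates the
    conditional mean of ln Rs, and LE is convex in ln Rs, so evaluating the
    forward operator at the point prediction alone would under-estimate mean
    LE; averaging over the residual distribution (Duan's smearing estimator)
    removes that bias.
    """

    flavor: str
    predictors: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    net: MLPRegressor
    seed: int
    metrics: dict[str, float] = field(default_factory=dict)
    residual_quantiles: np.ndarray | None = None

    def features(self, table: pd.DataFrame,
                 override_stats: dict[str, tuple[float, float]] | None = None,
                 warn_extrapolation: float | None = None) -> np.ndarray:
        cols = []
        for p in self.predictors:
            m, s = self.means[p], self.sds[p]
            if override_stats and p in override_stats:
                m, s = override_stats[p]
            z = (table[p].to_numpy(dtype=float) - m) / s
            if warn_extrapolation is not None and np.nanmax(np.abs(z)) > warn_extrapolation:
                warnings.warn(f"predictor {p} beyond +/-{warn_extrapolation} SD "
                              "of training stats; extrapolating", stacklevel=3)
            cols.append(z)
        return np.column_stack(cols + [_one_hot_pft(table["pft"])])


def train_hybrid(table: pd.DataFrame, flavor: str,
                 config: TrainConfig = TrainConfig()) -> HybridModel:
    """Train one flavor (dry or wet) of the hybrid model.

    Samples must all carry the requested label; the wet flavor requires a
    ``cws`` column.  Hours whose PM inversion is undefined are dropped from
    training.  Held-out (10 %) r2 and RMSE in LE space are recorded.
    """
    if flavor not in ("dry", "wet"):
        raise ValueError("flavor must be 'dry' or 'wet'")
    if "label" in table.columns:
        wrong = table["label"] != flavor
        if wrong.any():
            raise ValueError(f"{int(wrong.sum())} samples are not labeled {flavor!r}")
    predictors = WET_PREDICTORS if flavor == "wet" else DRY_PREDICTORS
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise ValueError(f"missing predictors for {flavor} model: {missing}")

    usable = table[table["LE"] > 0].copy()
    rs = pm_invert(usable["LE"].to_numpy(), _pm_state(usable))
    ok = np.isfinite(rs)
    usable = usable.iloc[ok]
    y = np.log(np.maximum(rs[ok], config.rs_floor))
    if len(usable) < config.min_samples_hybrid:
        raise ValueError(f"too few {flavor} samples: {len(usable)} < "
                         f"{config.min_samples_hybrid}")

    means = {p: float(usable[p].mean()) for p in predictors}
    sds = {p: float(usable[p].std()) or 1.0 for p in predictors}
    model = HybridModel(flavor=flavor, predictors=predictors, means=means,
                        sds=sds, net=None, seed=config.seed)
    X = model.features(usable)
    X_tr, X_te, y_tr, y_te, t_tr, t_te = train_test_split(
        X, y, np.arange(len(usable)), test_size=0.1, random_state=config.seed)
    net = MLPRegressor(hidden_layer_sizes=config.hidden_layers, activation="relu",
                       solver="adam", random_state=config.seed,
                       max_iter=config.max_iter, early_stopping=True,
                       validation_fraction=0.1, n_iter_no_change=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings are recorded via metrics
        net.fit(X_tr, y_tr)
    model.net = net
    if not np.isfinite(net.loss_):
        raise RuntimeError(f"{flavor} model diverged: loss={net.loss_}; "
                           f"n={len(X_tr)}, config={config}")
    held = usable.iloc[t_te]
    resid = y_te - net.predict(X_te)
    model.residual_quantiles = np.quantile(resid, np.linspace(0.02, 0.98, 25))
    le_hat = predict_le(model, held, extrapolation_sd=np.inf)
    fin = np.isfinite(le_hat)
    model.metrics = {
        "holdout_r2_le": float(r2_score(held["LE"].to_numpy()[fin], le_hat[fin])),
        "holdout_rmse_le": float(np.sqrt(np.mean(
            (held["LE"].to_numpy()[fin] - le_hat[fin]) ** 2))),
        "n_train": int(len(X_tr)),
    }
    return model


def predict_le(model: HybridModel, table: pd.DataFrame,
               override_stats: dict | None = None,
               extrapolation_sd: float = 10.0) -> np.ndarray:
    """LE (W m-2) from a trained model; non-negative by the resistor form.

    Applies the smearing retransformation: the forward operator is averaged
    over the model's held-out ln Rs residual quantiles rather than evaluated
    at the point prediction.  Features far outside the training distribution
    trigger an extrapolation warning but still predict.  NaN where the
    forward operator has no physical solution.
    """
    X = model.features(table, override_stats=override_stats,
                       warn_extrapolation=extrapolation_sd)
    lhat = model.net.predict(X)
    state = _pm_state(table)
    if model.residual_quantiles is None:
        return pm_forward(np.exp(np.clip(lhat, -5.0, 18.0)), state, on_invalid="nan")
    out = np.zeros_like(lhat)
    for r in model.residual_quantiles:
        out += pm_forward(np.exp(np.clip(lhat + r, -5.0, 18.0)), state,
                          on_invalid="nan")
    return out / len(model.residual_quantiles)


def derive_cws_proxy(le_obs: pd.Series, le_dry_hat: pd.Series,
                     labels: pd.Series | None = None) -> pd.Series:
    """CWS proxy (W m-2) on wet hours: observed LE minus the dry baseline.

    Negative values are returned as NaN (they are dropped from CWS training,
    reflecting measurement noise rather than negative storage).
    """
    if labels is not None:
        wrong = labels.reindex(le_obs.index) != "wet"
        if wrong.any():
            raise ValueError("CWS proxy is defined on wet hours only")
    proxy = le_obs - le_dry_hat.reindex(le_obs.index)
    return proxy.where(proxy >= 0)


@dataclass
class CWSModel:
    """Network inferring canopy water storage from vegetation state and the
    eight rainfall descriptors (W m-2, energy-equivalent units)."""

    means: dict[str, float]
    sds: dict[str, float]
    net: MLPRegressor
    seed: int
    metrics: dict[str, float] = field(default_factory=dict)

    numeric: tuple[str, ...] = tuple(CWS_DESCRIPTORS) + ("pulse_end_sin", "pulse_end_cos", "LAI")

    def _features(self, table: pd.DataFrame) -> np.ndarray:
        t = table.copy()
        ang = 2 * np.pi * t["last_pulse_end_time"] / 24.0
        t["pulse_end_sin"], t["pulse_end_cos"] = np.sin(ang), np.cos(ang)
        cols = [(t[p].to_numpy(dtype=float) - self.means[p]) / self.sds[p]
                for p in self.numeric]
        return np.column_stack(cols + [_one_hot_pft(t["pft"])])

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        out = self.net.predict(self._features(table))
        if not np.all(np.isfinite(out)):
            raise RuntimeError("non-finite CWS prediction")
        return out


def train_cws_net(table: pd.DataFrame, proxy: pd.Series,
                  config: TrainConfig = TrainConfig()) -> CWSModel:
    """Fit the CWS network on wet hours with a non-negative proxy.

    ``table`` holds the descriptors plus LAI and pft for the same hours as
    ``proxy``; NaN proxies (negative, removed) are skipped.
    """
    y = proxy.reindex(table.index)
    keep = y.notna()
    table, y = table[keep.to_numpy()], y[keep].to_numpy(dtype=float)
    if len(table) < config.min_samples_cws:
        raise ValueError(f"too few wet training hours: {len(table)}")
    if np.std(y) < 1e-9:
        warnings.warn("degenerate (constant) CWS proxy; fitting a constant",
                      stacklevel=2)
    t = table.copy()
    ang = 2 * np.pi * t["last_pulse_end_time"] / 24.0
    t["pulse_end_sin"], t["pulse_end_cos"] = np.sin(ang), np.cos(ang)
    numeric = tuple(CWS_DESCRIPTORS) + ("pulse_end_sin", "pulse_end_cos", "LAI")
    means = {p: float(t[p].mean()) for p in numeric}
    sds = {p: float(t[p].std()) or 1.0 for p in numeric}
    model = CWSModel(means=means, sds=sds, net=None, seed=config.seed)
    X = model._features(table)
    net = MLPRegressor(hidden_layer_sizes=config.hidden_layers, activation="relu",
                       solver="adam", random_state=config.seed,
                       max_iter=config.max_iter, early_stopping=True,
                       validation_fraction=0.1, n_iter_no_change=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net.fit(X, y)
    model.net = net
    model.metrics = {"train_r2": float(r2_score(y, net.predict(X))),
                     "n_train": int(len(y))}
    return model
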