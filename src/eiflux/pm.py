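"""Penman-Monteith physics: saturation-curve, aerodynamic resistance, and the
quadratic forward/inverse operators linking latent heat flux to surface resistance.

The forward operator solves the coupled surface energy balance

    H  = rho*cp*dT/ra
    LE = (rho*cp/gamma) * (VPD + Delta*dT + 0.5*k*dT^2) / (ra + Rs)
    A  = H + LE

for the surface-air temperature difference dT, retaining the *second-order*
(curvature) term k = d2 esat / dT2 of the saturation vapor pressure curve.
With k = 0 it reduces to the classical Penman-Monteith closed form.  The
inverse operator recovers the surface resistance Rs from an observed LE in
closed form; forward and inverse are exact algebraic inverses of each other
wherever the inversion is defined.

All functions are vectorized over numpy arrays and do no I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PMState",
    "esat_curve",
    "aerodynamic_resistance",
    "pm_forward",
    "pm_invert",
    "latent_heat_of_vaporization",
]

# Physical constants (SI unless noted)
CP = 1013.0          # specific heat of air, J kg-1 K-1
P_AIR = 101.325      # air pressure, kPa (no site pressure in the input schema)
R_DRY = 287.05       # gas constant of dry air, J kg-1 K-1
KARMAN = 0.41
WS_FLOOR = 0.5       # m s-1, floor applied to wind speed in ra

TA_MIN, TA_MAX = -40.0, 60.0


def latent_heat_of_vaporization(ta: np.ndarray | float) -> np.ndarray | float:
    """Latent heat of vaporization of water, J kg-1, linear in Ta (degC)."""
    return (2.501 - 0.002361 * np.asarray(ta, dtype=float)) * 1e6


def esat_curve(ta):
    """Saturation vapor pressure (Tetens), its slope and curvature.

    Parameters
    ----------
    ta : array-like
        Air temperature, degC, within [-40, 60].

    Returns
    -------
    esat : kPa
    delta : kPa K-1, first derivative d esat/dT
    k : kPa K-2, second derivative d2 esat/dT2
    """
    ta = np.asarray(ta, dtype=float)
    if np.any((ta < TA_MIN) | (ta > TA_MAX)):
        raise ValueError(f"air temperature outside [{TA_MIN}, {TA_MAX}] degC")
    denom = ta + 237.3
    esat = 0.6108 * np.exp(17.27 * ta / denom)
    # d/dT [17.27*T/(T+237.3)] = 17.27*237.3/(T+237.3)^2
    g1 = 17.27 * 237.3 / denom**2
    delta = esat * g1
    # second derivative: esat * (g1^2 + g1') with g1' = -2*17.27*237.3/(T+237.3)^3
    g1p = -2.0 * 17.27 * 237.3 / denom**3
    k = esat * (g1**2 + g1p)
    return esat, delta, k


def aerodynamic_resistance(ws, tower_height: float, canopy_height: float):
    """Neutral log-profile aerodynamic resistance, s m-1.

    d = 0.67 h, z0m = 0.123 h, z0h = 0.1 z0m; wind speed floored at 0.5 m s-1.
    """
    if not (tower_height > canopy_height > 0):
        raise ValueError("require tower_height > canopy_height > 0")
    d = 0.67 * canopy_height
    z0m = 0.123 * canopy_height
    z0h = 0.1 * z0m
    z = tower_height
    if z <= d:
        raise ValueError("measurement height below displacement height")
    ws = np.maximum(np.asarray(ws, dtype=float), WS_FLOOR)
    return np.log((z - d) / z0m) * np.log((z - d) / z0h) / (KARMAN**2 * ws)


@dataclass
class PMState:
    """All physical quantities entering the PM operators for a set of hours.

    Derived psychrometric fields are computed on construction from Ta.
    """

    ta: np.ndarray          # degC
    vpd: np.ndarray         # kPa
    available_energy: np.ndarray  # A = Rn - G, W m-2
    ra: np.ndarray          # s m-1
    pressure: float = P_AIR  # kPa

    esat: np.ndarray = field(init=False)
    delta: np.ndarray = field(init=False)
    curvature: np.ndarray = field(init=False)
    gamma: np.ndarray = field(init=False)
    rho: np.ndarray = field(init=False)
    lam: np.ndarray = field(init=False)

    def __post_init__(self):
        self.ta = np.asarray(self.ta, dtype=float)
        self.vpd = np.asarray(self.vpd, dtype=float)
        self.available_energy = np.asarray(self.available_energy, dtype=float)
        self.ra = np.asarray(self.ra, dtype=float)
        if np.any(self.ra <= 0):
            raise ValueError("aerodynamic resistance must be positive")
        self.esat, self.delta, self.curvature = esat_curve(self.ta)
        self.lam = latent_heat_of_vaporization(self.ta)
        self.gamma = CP * self.pressure / (0.622 * self.lam)
        self.rho = self.pressure * 1000.0 / (R_DRY * (self.ta + 273.15))


def pm_forward(rs, state: PMState, *, curvature: bool = True, on_invalid: str = "raise"):
    """Latent heat flux (W m-2) for a given surface resistance.

    Solves the quadratic energy-balance system for dT and returns
    LE = A - rho*cp*dT/ra.  The quadratic root is the one continuous with the
    classical (k = 0) Penman-Monteith solution.

    With ``curvature=False`` the saturation curve is linearized (k = 0) and the
    classical closed form is returned.

    Raises
    ------
    ValueError when the discriminant is negative (no physical solution;
    callers should skip the hour) unless ``on_invalid='nan'``.
    """
    rs = np.asarray(rs, dtype=float)
    if np.any(rs < 0):
        raise ValueError("surface resistance must be non-negative")
    a = state.rho * CP / state.ra
    b = state.rho * CP / (state.gamma * (state.ra + rs))
    A = state.available_energy
    if not curvature:
        dT = (A - b * state.vpd) / (a + b * state.delta)
        return A - a * dT
    k = state.curvature
    # (b k / 2) dT^2 + (a + b Delta) dT + (b VPD - A) = 0
    qa = 0.5 * b * k
    qb = a + b * state.delta
    qc = b * state.vpd - A
    disc = qb**2 - 4.0 * qa * qc
    if np.any(disc < 0):
        if on_invalid == "raise":
            raise ValueError("quadratic PM has no physical solution (negative discriminant)")
        disc = np.where(disc < 0, np.nan, disc)  # on_invalid == "nan": skip the hour
    # '+' root -> classical solution in the k->0 limit; where the curvature
    # vanishes the quadratic degenerates and the linear root is exact
    with np.errstate(invalid="ignore", divide="ignore"):
        dT_quad = (-qb + np.sqrt(disc)) / (2.0 * qa)
    dT_lin = -qc / qb
    dT = np.where(np.abs(qa) > 1e-300, dT_quad, dT_lin)
    return A - a * dT


def pm_invert(le, state: PMState):
    """Surface resistance (s m-1) implied by an observed latent heat flux.

    Closed form: dT from the sensible-heat branch, the surface saturation
    vapor pressure from the quadratic Tetens expansion, then the resistor
    equation solved for Rs.  Result is clipped at 0.

    Returns
    -------
    rs : ndarray
        Non-negative surface resistance; NaN where the inversion is
        undefined (es_surf <= ea, i.e. no positive vapor gradient).
    """
    le = np.asarray(le, dtype=float)
    if np.any(le <= 0):
        raise ValueError("pm_invert requires LE > 0")
    dT = (state.available_energy - le) * state.ra / (state.rho * CP)
    es_surf = state.esat + state.delta * dT + 0.5 * state.curvature * dT**2
    ea = state.esat - state.vpd
    grad = es_surf - ea
    rs = state.rho * CP * grad / (state.gamma * le) - state.ra
    rs = np.where(grad > 0, np.maximum(rs, 0.0), np.nan)
    return rs
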