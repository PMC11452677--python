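"""Single-channel land surface temperature retrieval from thermal radiance.

The heat indicator of the RSEI composite is LST retrieved with the
single-channel (SC) algorithm from at-sensor spectral radiance L of a single
thermal band (Landsat-8 TIRS band 10 constants by default):

    LST = gamma * [eps^-1 * (psi1 * L + psi2) + psi3] + delta
    gamma = T^2 / (b_gamma * L),   delta ~= T - T^2 / b_gamma
    T = K2 / ln(K1 / L + 1)                    (brightness temperature)
    psi1 = 1/tau,  psi2 = -L_down - L_up/tau

Two conventions for psi3 circulate: ``paper`` uses the upwelling radiance
L_up, ``standard`` (the original SC literature) uses the downwelling L_down.
Both are supported; with tau = 1, L_up = L_down = 0 and eps = 1 the retrieval
collapses to the brightness temperature exactly, which serves as the
closed-form sanity limit.

Atmospheric parameters are scene-level scalars supplied by the user; no
atmosphere model is computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_core import Raster
from .spectral_indices import IndicatorRaster, WaterMask

__all__ = [
    "ThermalBand",
    "ThermalConstants",
    "AtmosphericParams",
    "EmissivityRaster",
    "brightness_temperature",
    "atmospheric_functions",
    "gamma_delta",
    "retrieve_lst",
    "estimate_emissivity",
]


@dataclass
class ThermalBand:
    """At-sensor spectral radiance L (W/m^2/sr/um); L <= 0 cells are nodata."""

    radiance: Raster

    def __post_init__(self) -> None:
        r = self.radiance
        ok = r.valid & (r.values > 0)
        if not np.array_equal(ok, r.valid):
            self.radiance = Raster(r.grid, np.where(ok, r.values, np.nan), ok)


@dataclass(frozen=True)
class ThermalConstants:
    """Band-specific conversion constants (defaults: Landsat-8 TIRS band 10)."""

    k1: float = 774.89  # W/m^2/sr/um
    k2: float = 1321.08  # K
    b_gamma: float = 1324.0  # K

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.b_gamma) <= 0:
            raise ValueError("thermal constants must be strictly positive")


@dataclass(frozen=True)
class AtmosphericParams:
    """Scene-level transmissivity and up/downwelling radiances."""

    tau: float = 1.0
    l_up: float = 0.0
    l_down: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.tau <= 1):
            raise ValueError("tau must lie in (0, 1]")
        if self.l_up < 0 or self.l_down < 0:
            raise ValueError("atmospheric radiances must be nonnegative")


@dataclass
class EmissivityRaster:
    """Land-surface emissivity, 0 < eps <= 1 on valid cells."""

    raster: Raster

    def __post_init__(self) -> None:
        r = self.raster
        ok = r.valid & (r.values > 0) & (r.values <= 1)
        if not np.array_equal(ok, r.valid):
            self.raster = Raster(r.grid, np.where(ok, r.values, np.nan), ok)


def brightness_temperature(L: ThermalBand, c: ThermalConstants | None = None) -> Raster:
    """At-sensor brightness temperature T = K2 / ln(K1/L + 1), in kelvin."""
    c = c or ThermalConstants()
    r = L.radiance
    out = np.full(r.grid.shape, np.nan)
    ok = r.valid
    out[ok] = c.k2 / np.log(c.k1 / r.values[ok] + 1.0)
    return Raster(r.grid, out, ok.copy())


def atmospheric_functions(
    a: AtmosphericParams, convention: str = "paper"
) -> tuple[float, float, float]:
    """The three SC atmospheric functions (psi1, psi2, psi3).

    ``convention='paper'`` sets psi3 = L_up; ``'standard'`` sets psi3 = L_down.
    """
    if convention not in ("paper", "standard"):
        raise ValueError(f"unknown psi3 convention {convention!r}")
    psi1 = 1.0 / a.tau
    psi2 = -a.l_down - a.l_up / a.tau
    psi3 = a.l_up if convention == "paper" else a.l_down
    return psi1, psi2, psi3


def gamma_delta(
    T: Raster, L: ThermalBand, c: ThermalConstants | None = None
) -> tuple[Raster, Raster]:
    """Planck linearisation parameters; satisfies gamma*L + delta = T exactly."""
    c = c or ThermalConstants()
    ok = T.valid & L.radiance.valid
    g = np.full(T.grid.shape, np.nan)
    d = np.full(T.grid.shape, np.nan)
    t = T.values[ok]
    l = L.radiance.values[ok]
    g[ok] = t**2 / (c.b_gamma * l)
    d[ok] = t - t**2 / c.b_gamma
    return Raster(T.grid, g, ok.copy()), Raster(T.grid, d, ok.copy())


def retrieve_lst(
    L: ThermalBand,
    eps: EmissivityRaster,
    a: AtmosphericParams | None = None,
    c: ThermalConstants | None = None,
    psi3_convention: str = "paper",
) -> IndicatorRaster:
    """Single-channel LST in kelvin (kind='lst').

    Normalization of LST into [0, 1] for the indicator matrix happens later,
    in the RSEI construction stage.
    """
    a = a or AtmosphericParams()
    c = c or ThermalConstants()
    if eps.raster.grid != L.radiance.grid:
        raise ValueError("emissivity and radiance must share one grid")
    psi1, psi2, psi3 = atmospheric_functions(a, psi3_convention)
    T = brightness_temperature(L, c)
    gamma, delta = gamma_delta(T, L, c)
    ok = T.valid & eps.raster.valid
    out = np.full(T.grid.shape, np.nan)
    lv = L.radiance.values[ok]
    ev = eps.raster.values[ok]
    out[ok] = gamma.values[ok] * ((psi1 * lv + psi2) / ev + psi3) + delta.values[ok]
    return IndicatorRaster("lst", Raster(T.grid, out, ok))


def estimate_emissivity(
    ndvi_r: IndicatorRaster,
    water: WaterMask | None = None,
    eps_soil: float = 0.966,
    eps_veg: float = 0.986,
    eps_water: float = 0.991,
    t_low: float = 0.2,
    t_high: float = 0.5,
) -> EmissivityRaster:
    """NDVI-threshold emissivity: soil below t_low, vegetation above t_high,
    a linear blend between, and a fixed water value on water cells."""
    if ndvi_r.kind != "ndvi":
        raise ValueError("estimate_emissivity expects an NDVI indicator")
    if not t_low < t_high:
        raise ValueError("thresholds out of order: need t_low < t_high")
    r = ndvi_r.raster
    frac = np.clip((r.values - t_low) / (t_high - t_low), 0.0, 1.0)
    eps = eps_soil + frac * (eps_veg - eps_soil)
    if water is not None:
        eps = np.where(water.is_water, eps_water, eps)
    eps = np.where(r.valid, eps, np.nan)
    return EmissivityRaster(Raster(r.grid, eps, r.valid.copy()))
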