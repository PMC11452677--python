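"""Reflectance-derived ecological indicators.

Implements the four reflectance ingredients of the RSEI composite — NDVI
(greenness), tasseled-cap wetness, and the dryness pair NDISI/NDSI combined
into NDISSI — plus MNDWI and the water mask that removes open water before the
PCA stage.

Ratio indices are computed cell-wise with strict nodata propagation; a zero
denominator yields nodata rather than ±inf so the PCA sample stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_core import Raster, ReflectanceStack, normalize_minmax

__all__ = [
    "IndicatorRaster",
    "WaterMask",
    "ndvi",
    "tct_wetness",
    "mndwi",
    "ndsi",
    "ndisi",
    "ndissi",
    "water_mask",
    "TCT_WETNESS_COEFFS",
]

# Landsat-8 OLI tasseled-cap wetness coefficients (blue..swir2).
TCT_WETNESS_COEFFS = {
    "blue": 0.1511,
    "green": 0.1973,
    "red": 0.3283,
    "nir": 0.3407,
    "swir1": -0.7117,
    "swir2": -0.4559,
}

INDICATOR_KINDS = ("ndvi", "wetness", "mndwi", "ndisi", "ndsi", "ndissi", "lst")


@dataclass
class IndicatorRaster:
    """A named indicator layer; ratio-type kinds lie in [-1, 1] on valid cells."""

    kind: str
    raster: Raster

    def __post_init__(self) -> None:
        if self.kind not in INDICATOR_KINDS:
            raise ValueError(f"unknown indicator kind {self.kind!r}")


@dataclass
class WaterMask:
    """Boolean water raster derived from MNDWI by a strict > threshold rule."""

    raster: Raster
    threshold: float

    @property
    def is_water(self) -> np.ndarray:
        return self.raster.valid & (self.raster.values != 0)


def _ratio(
    num: np.ndarray, den: np.ndarray, valid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    ok = valid & (den != 0)
    out = np.full(num.shape, np.nan)
    out[ok] = num[ok] / den[ok]
    return out, ok


def ndvi(s: ReflectanceStack) -> IndicatorRaster:
    """Normalized difference vegetation index (NIR − Red)/(NIR + Red)."""
    out, ok = _ratio(s.nir.values - s.red.values, s.nir.values + s.red.values, s.valid)
    return IndicatorRaster("ndvi", Raster(s.grid, out, ok))


def tct_wetness(s: ReflectanceStack) -> IndicatorRaster:
    """Tasseled-cap wetness: fixed linear combination of the six OLI bands."""
    acc = np.zeros(s.grid.shape)
    for name, coef in TCT_WETNESS_COEFFS.items():
        acc = acc + coef * getattr(s, name).values
    return IndicatorRaster("wetness", Raster(s.grid, acc, s.valid.copy()))


def mndwi(s: ReflectanceStack) -> IndicatorRaster:
    """Modified NDWI, (Green − SWIR1)/(Green + SWIR1); the water-index band."""
    out, ok = _ratio(
        s.green.values - s.swir1.values, s.green.values + s.swir1.values, s.valid
    )
    return IndicatorRaster("mndwi", Raster(s.grid, out, ok))


def ndsi(s: ReflectanceStack) -> IndicatorRaster:
    """Normalized difference soil index, (SWIR1 − NIR)/(SWIR1 + NIR)."""
    out, ok = _ratio(
        s.swir1.values - s.nir.values, s.swir1.values + s.nir.values, s.valid
    )
    return IndicatorRaster("ndsi", Raster(s.grid, out, ok))


def ndisi(
    s: ReflectanceStack,
    tir: Raster,
    wi: IndicatorRaster,
    scale: str = "tir_only",
) -> IndicatorRaster:
    """Normalized difference impervious surface index.

    NDISI = (TIR − m)/(TIR + m) with m = (WI + NIR + SWIR1)/3, where WI is the
    MNDWI layer.  ``scale`` controls how inputs are made commensurate:

    - ``tir_only`` (default): the thermal band is min-max normalized to [0, 1]
      so it matches the reflectance scale; WI and reflectance enter as-is.
    - ``all_bands``: TIR, WI, NIR and SWIR1 are each min-max normalized.
    - ``none``: all inputs enter untouched.

    The output is clipped to [-1, 1]: a negative WI (MNDWI < 0 over land) can
    push the raw ratio marginally outside the ratio-index range.
    """
    if wi.kind != "mndwi":
        raise ValueError("ndisi expects the MNDWI layer as its water-index band")
    if scale not in ("tir_only", "all_bands", "none"):
        raise ValueError(f"unknown ndisi scale mode {scale!r}")
    if tir.grid != s.grid:
        raise ValueError("thermal band must be resampled to the scene grid first")

    valid = s.valid & tir.valid & wi.raster.valid

    def maybe_norm(r: Raster) -> np.ndarray:
        nr, _ = normalize_minmax(r, valid)
        return nr.values

    tir_v = tir.values
    wi_v = wi.raster.values
    nir_v = s.nir.values
    swir1_v = s.swir1.values
    if scale == "tir_only":
        tir_v = maybe_norm(tir)
    elif scale == "all_bands":
        tir_v = maybe_norm(tir)
        wi_v = maybe_norm(wi.raster)
        nir_v = maybe_norm(s.nir)
        swir1_v = maybe_norm(s.swir1)
    m = (wi_v + nir_v + swir1_v) / 3.0
    out, ok = _ratio(tir_v - m, tir_v + m, valid)
    out = np.clip(out, -1.0, 1.0)
    return IndicatorRaster("ndisi", Raster(s.grid, out, ok))


def ndissi(
    ndisi_r: IndicatorRaster,
    ndsi_r: IndicatorRaster,
    water: WaterMask | None = None,
) -> IndicatorRaster:
    """Composite dryness index: mean of min-max normalized NDISI and NDSI.

    Normalization ranges are taken over valid non-water cells so that masked
    water cannot set the scale; water cells are nodata in the output.
    """
    if ndisi_r.raster.grid != ndsi_r.raster.grid:
        raise ValueError("NDISI and NDSI must share one grid")
    domain = ndisi_r.raster.valid & ndsi_r.raster.valid
    if water is not None:
        domain &= ~water.is_water
    a, _ = normalize_minmax(ndisi_r.raster, domain)
    b, _ = normalize_minmax(ndsi_r.raster, domain)
    out = (a.values + b.values) / 2.0
    return IndicatorRaster("ndissi", Raster(ndisi_r.raster.grid, out, domain))


def water_mask(mndwi_r: IndicatorRaster, threshold: float = 0.1) -> WaterMask:
    """Water where MNDWI strictly exceeds the threshold (default 0.1)."""
    if mndwi_r.kind != "mndwi":
        raise ValueError("water_mask expects an MNDWI indicator")
    r = mndwi_r.raster
    water = r.valid & (r.values > threshold)
    return WaterMask(Raster(r.grid, water.astype(float), r.valid.copy()), threshold)
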