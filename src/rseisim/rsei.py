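"""RSEI construction by covariance PCA, level classification and summaries.

The remote-sensing ecological index is built in two steps:

    RSEI0 = 1 - PC1[f(greenness, wetness, heat, dryness)]
    RSEI  = min-max rescaling of RSEI0 to [0, 1]

where PC1 is the first principal component of the covariance matrix of the
four indicators, each first min-max normalized to [0, 1] over valid non-water
cells.  The eigenvector sign returned by a solver is arbitrary, so PC1 is
oriented by forcing the greenness loading negative (the stable empirical
pattern: greenness and wetness load against PC1, heat and dryness with it);
with the subsequent 1 - score flip, greener/wetter cells end up with higher
RSEI.

RSEI is then cut into five equal-width quality levels (interval 0.2,
level 1 = worst), with area/percent accounting, change detection between two
level rasters, and zonal means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_core import (
    NormalizationParams,
    Raster,
    SceneGrid,
    area_km2,
    normalize_minmax,
)
from .spectral_indices import IndicatorRaster, WaterMask

__all__ = [
    "IndicatorMatrix",
    "PCAResult",
    "RSEIResult",
    "LevelRaster",
    "INDICATOR_ORDER",
    "LEVEL_BOUNDS",
    "build_indicator_matrix",
    "pca_pc1",
    "orient_pc1",
    "compute_rsei",
    "percent_eigenvalues",
    "classify_levels",
    "level_stats",
    "level_change",
    "zonal_mean",
]

INDICATOR_ORDER = ("greenness", "wetness", "heat", "dryness")
# level k covers [LEVEL_BOUNDS[k-1], LEVEL_BOUNDS[k]); the top interval is
# closed at 1.0
LEVEL_BOUNDS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class IndicatorMatrix:
    """Valid non-water cells x 4 normalized indicator columns (fixed order)."""

    data: np.ndarray  # (n, 4) in [0, 1]
    rows: np.ndarray  # flat cell indices into the grid
    grid: "SceneGrid"
    norm_params: tuple[NormalizationParams, ...]

    @property
    def n(self) -> int:
        return self.data.shape[0]


@dataclass
class PCAResult:
    """Eigendecomposition bookkeeping of the 4x4 indicator covariance matrix.

    ``loadings[k]`` is the unit-norm eigenvector of component k; eigenvalues
    are sorted descending and ``percent`` gives each component's share of the
    total variance (sums to 100).
    """

    loadings: np.ndarray  # (4, 4), row k = component k
    eigenvalues: np.ndarray  # (4,), descending
    percent: np.ndarray  # (4,), sums to 100
    oriented: bool = False


@dataclass
class RSEIResult:
    rsei: Raster  # in [0, 1]; nodata on water/invalid cells
    pca: PCAResult
    oriented: bool


@dataclass
class LevelRaster:
    levels: Raster  # integer codes 1..5
    boundaries: tuple[float, ...] = LEVEL_BOUNDS


def build_indicator_matrix(
    ndvi: IndicatorRaster,
    wetness: IndicatorRaster,
    lst: IndicatorRaster,
    ndissi: IndicatorRaster,
    water: WaterMask | None = None,
) -> IndicatorMatrix:
    """Assemble the (greenness, wetness, heat, dryness) sample matrix.

    Rows are cells valid in all four indicators and not water; each column is
    min-max normalized to [0, 1] over exactly those rows.
    """
    layers = (ndvi.raster, wetness.raster, lst.raster, ndissi.raster)
    grid = layers[0].grid
    for r in layers[1:]:
        if r.grid != grid:
            raise ValueError("indicator rasters are on different grids")
    domain = np.logical_and.reduce([r.valid for r in layers])
    if water is not None:
        domain &= ~water.is_water
    rows = np.flatnonzero(domain.ravel())
    if rows.size < 5:
        raise ValueError(f"only {rows.size} usable cells; need at least 5")
    cols = []
    params = []
    for r in layers:
        nr, p = normalize_minmax(r, domain)
        cols.append(nr.values.ravel()[rows])
        params.append(p)
    return IndicatorMatrix(np.column_stack(cols), rows, grid, tuple(params))


def percent_eigenvalues(eigenvalues: np.ndarray) -> np.ndarray:
    """Each eigenvalue's percent share of the total, percent_k = 100*l_k/sum(l)."""
    ev = np.asarray(eigenvalues, dtype=float)
    total = ev.sum()
    if total <= 0:
        raise ValueError("eigenvalues must have a positive sum")
    return 100.0 * ev / total


def pca_pc1(m: IndicatorMatrix) -> PCAResult:
    """Covariance-matrix PCA of the mean-centered indicator columns.

    Columns are already commensurate (all in [0, 1]) so no variance scaling is
    applied; components are ordered by descending eigenvalue.
    """
    if m.n < 5:
        raise ValueError("need at least 5 rows for PCA")
    X = m.data - m.data.mean(axis=0)
    cov = X.T @ X / (m.n - 1)
    if np.trace(cov) <= 0:
        raise ValueError("zero total variance; PCA undefined")
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    loadings = eigvecs[:, order].T  # row k = component k
    return PCAResult(loadings, eigvals, percent_eigenvalues(eigvals), oriented=False)


def orient_pc1(p: PCAResult) -> PCAResult:
    """Resolve the arbitrary eigenvector sign: PC1 greenness loading <= 0.

    Falls back to the wetness loading when greenness is exactly zero.
    """
    pc1 = p.loadings[0]
    pivot = pc1[0] if pc1[0] != 0 else pc1[1]
    if pivot == 0:
        raise ValueError("cannot orient PC1: greenness and wetness loadings are zero")
    loadings = p.loadings.copy()
    if pivot > 0:
        loadings[0] = -loadings[0]
    return PCAResult(loadings, p.eigenvalues.copy(), p.percent.copy(), oriented=True)


def compute_rsei(m: IndicatorMatrix, p: PCAResult) -> RSEIResult:
    """Project onto oriented PC1, flip (RSEI0 = 1 - score), rescale to [0, 1]."""
    if not p.oriented:
        raise ValueError("PCA result must be oriented before computing RSEI")
    score = (m.data - m.data.mean(axis=0)) @ p.loadings[0]
    rsei0 = 1.0 - score
    lo, hi = rsei0.min(), rsei0.max()
    if hi == lo:
        raise ValueError("degenerate RSEI0 range")
    rsei = (rsei0 - lo) / (hi - lo)
    out = np.full(m.grid.shape, np.nan)
    out.ravel()[m.rows] = rsei
    valid = np.zeros(m.grid.shape, dtype=bool)
    valid.ravel()[m.rows] = True
    return RSEIResult(Raster(m.grid, out, valid), p, oriented=True)


def classify_levels(r: RSEIResult) -> LevelRaster:
    """Five equal 0.2-wide quality levels; lower-closed, top closed at 1.0."""
    v = r.rsei.values
    codes = np.full(r.rsei.grid.shape, np.nan)
    ok = r.rsei.valid
    codes[ok] = np.digitize(v[ok], LEVEL_BOUNDS[1:-1], right=False) + 1
    codes[ok & (v == 1.0)] = 5
    return LevelRaster(Raster(r.rsei.grid, codes, ok.copy()))


def level_stats(lv: LevelRaster) -> pd.DataFrame:
    """Per-level area (km²) and percent of total classified area."""
    r = lv.levels
    if not r.valid.any():
        raise ValueError("empty level raster")
    rows = []
    for level in range(1, 6):
        mask = Raster(r.grid, (r.valid & (r.values == level)).astype(float),
                      np.ones(r.grid.shape, bool))
        rows.append({"level": level, "area_km2": area_km2(mask)})
    df = pd.DataFrame(rows)
    total = df["area_km2"].sum()
    df["percent"] = 100.0 * df["area_km2"] / total
    return df


def level_change(before: LevelRaster, after: LevelRaster) -> Raster:
    """Per-cell level difference after − before (range −4..4)."""
    if before.levels.grid != after.levels.grid:
        raise ValueError("level rasters are on different grids")
    ok = before.levels.valid & after.levels.valid
    out = np.full(before.levels.grid.shape, np.nan)
    out[ok] = after.levels.values[ok] - before.levels.values[ok]
    return Raster(before.levels.grid, out, ok)


def zonal_mean(r: RSEIResult, zones: Raster) -> pd.DataFrame:
    """Mean RSEI per integer zone label; zones with no valid cells are skipped."""
    if zones.grid != r.rsei.grid:
        raise ValueError("zone raster is on a different grid")
    ok = r.rsei.valid & zones.valid
    labels = np.unique(zones.values[zones.valid]).astype(int)
    rows = []
    for z in labels:
        sel = ok & (zones.values == z)
        if not sel.any():
            warnings.warn(f"zone {z} has no valid RSEI cells; omitted")
            continue
        rows.append({"zone": int(z), "mean_rsei": float(r.rsei.values[sel].mean()),
                     "n_cells": int(sel.sum())})
    return pd.DataFrame(rows)
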