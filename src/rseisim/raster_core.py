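"""Grid-aligned raster data model and the basic raster algebra shared by every stage.

A :class:`SceneGrid` describes a north-up, square-cell grid in a projected CRS
(metres); a :class:`Raster` couples one value per cell with a validity mask.
Nodata propagation is strict: any operation that consumes an invalid cell
produces an invalid cell, so the sample set entering the PCA stays identical
across all four ecological indicators.

Conventions: cell centres carry the geometry, row 0 is the northern edge, and
``origin_x``/``origin_y`` anchor the *top-left corner* of cell (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SceneGrid",
    "Raster",
    "ReflectanceStack",
    "NormalizationParams",
    "normalize_minmax",
    "resample_to_grid",
    "aggregate_fraction",
    "area_km2",
    "read_geotiff",
    "write_geotiff",
    "read_reflectance_stack",
    "write_rasters_multiband",
]

BAND_ORDER = ("blue", "green", "red", "nir", "swir1", "swir2")


@dataclass(frozen=True)
class SceneGrid:
    """Square-cell analysis grid in a projected CRS.

    ``cell_size`` is in metres per cell edge.  Two rasters are combinable only
    if their grids compare equal.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_label: str = "EPSG:32650"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre, each shaped (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)


@dataclass
class Raster:
    """One value per grid cell plus a validity mask (False = nodata).

    Values at invalid cells are stored as NaN and must never be consumed.
    """

    grid: SceneGrid
    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.grid.shape:
                raise ValueError("valid mask shape does not match grid")
        # normalise storage: NaN wherever invalid
        self.values = np.where(self.valid, self.values, np.nan)
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("non-finite values inside the valid mask")

    @classmethod
    def full(cls, grid: SceneGrid, fill: float) -> "Raster":
        return cls(grid, np.full(grid.shape, float(fill)))

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.valid.copy())

    def same_grid(self, other: "Raster") -> bool:
        return self.grid == other.grid

    def masked_values(self) -> np.ndarray:
        """1-D array of the valid cell values."""
        return self.values[self.valid]


def _require_same_grid(*rasters: Raster) -> None:
    g0 = rasters[0].grid
    for r in rasters[1:]:
        if r.grid != g0:
            raise ValueError("rasters are on different grids and cannot be combined")


@dataclass
class ReflectanceStack:
    """Six aligned surface-reflectance bands (dimensionless, clipped to [0, 1]).

    All bands share one grid and one joint validity mask: a cell invalid in any
    band is invalid in all.
    """

    grid: SceneGrid
    blue: Raster
    green: Raster
    red: Raster
    nir: Raster
    swir1: Raster
    swir2: Raster

    def __post_init__(self) -> None:
        bands = self.bands()
        _require_same_grid(*bands)
        if bands[0].grid != self.grid:
            raise ValueError("band grid does not match stack grid")
        joint = np.logical_and.reduce([b.valid for b in bands])
        for name in BAND_ORDER:
            b: Raster = getattr(self, name)
            clipped = np.clip(b.values, 0.0, 1.0)
            setattr(self, name, Raster(self.grid, clipped, joint))

    def bands(self) -> list[Raster]:
        return [getattr(self, name) for name in BAND_ORDER]

    @property
    def valid(self) -> np.ndarray:
        return self.blue.valid


@dataclass(frozen=True)
class NormalizationParams:
    """The (min, max) pair of an affine min-max rescaling, stored for re-use."""

    i_min: float
    i_max: float

    def __post_init__(self) -> None:
        if self.i_max < self.i_min:
            raise ValueError("i_max must be >= i_min")

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.i_min) / (self.i_max - self.i_min)


def normalize_minmax(
    r: Raster, mask: Raster | np.ndarray | None = None
) -> tuple[Raster, NormalizationParams]:
    """Min-max rescale a raster to [0, 1] over its valid (optionally masked) cells.

    The minimum and maximum are taken over cells that are valid *and* inside
    ``mask`` (where given); cells outside the mask become nodata in the output.
    """
    domain = r.valid.copy()
    if mask is not None:
        m = mask.values.astype(bool) if isinstance(mask, Raster) else np.asarray(mask, bool)
        if isinstance(mask, Raster):
            m = m & mask.valid
        domain &= m
    if not domain.any():
        raise ValueError("empty valid set: nothing to normalize")
    vals = r.values[domain]
    i_min, i_max = float(vals.min()), float(vals.max())
    if i_max == i_min:
        raise ValueError("degenerate normalization range (all values equal)")
    params = NormalizationParams(i_min, i_max)
    out = np.full(r.grid.shape, np.nan)
    out[domain] = params.apply(r.values[domain])
    return Raster(r.grid, out, domain), params


def resample_to_grid(r: Raster, target: SceneGrid, method: str = "nearest") -> Raster:
    """Resample onto another grid of the same CRS (nearest or bilinear).

    Bilinear is for continuous fields only; any invalid source neighbour makes
    the interpolated cell nodata (strict propagation, via NaN arithmetic).
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    if r.grid.crs_label != target.crs_label:
        raise ValueError(
            f"CRS mismatch: {r.grid.crs_label!r} vs {target.crs_label!r}"
        )
    if r.grid == target:
        return r.copy()
    tx, ty = target.cell_centers()
    # fractional source indices of the target cell centres
    src_col = (tx - r.grid.origin_x) / r.grid.cell_size - 0.5
    src_row = (r.grid.origin_y - ty) / r.grid.cell_size - 0.5
    if method == "nearest":
        ci = np.rint(src_col).astype(int)
        ri = np.rint(src_row).astype(int)
        inside = (ri >= 0) & (ri < r.grid.n_rows) & (ci >= 0) & (ci < r.grid.n_cols)
        out = np.full(target.shape, np.nan)
        valid = np.zeros(target.shape, dtype=bool)
        rr, cc = ri[inside], ci[inside]
        out[inside] = r.values[rr, cc]
        valid[inside] = r.valid[rr, cc]
        out[~valid] = np.nan
        return Raster(target, out, valid)
    out = ndimage.map_coordinates(
        r.values, [src_row, src_col], order=1, mode="constant", cval=np.nan
    )
    valid = np.isfinite(out)
    return Raster(target, out, valid)


def aggregate_fraction(fine_binary: Raster, target: SceneGrid) -> Raster:
    """Percent coverage of a fine binary raster inside each coarse target cell.

    Used to turn a fine (e.g. 2.5 m) rooftop mask into a percent-of-cell layer
    on the analysis grid.  The fine cell size must divide the target cell size
    exactly and the fine grid must tile the target grid.
    """
    fg = fine_binary.grid
    if fg.crs_label != target.crs_label:
        raise ValueError("CRS mismatch between fine raster and target grid")
    ratio = target.cell_size / fg.cell_size
    f = int(round(ratio))
    if abs(ratio - f) > 1e-9 or f < 1:
        raise ValueError(
            f"fine cell size {fg.cell_size} does not divide target cell size {target.cell_size}"
        )
    if fg.n_rows != target.n_rows * f or fg.n_cols != target.n_cols * f:
        raise ValueError("fine grid does not tile the target grid")
    if abs(fg.origin_x - target.origin_x) > 1e-6 or abs(fg.origin_y - target.origin_y) > 1e-6:
        raise ValueError("fine and target grid origins differ")
    ones = np.where(fine_binary.valid, fine_binary.values != 0, False)
    vals = ones.reshape(target.n_rows, f, target.n_cols, f)
    valid = fine_binary.valid.reshape(target.n_rows, f, target.n_cols, f)
    n_one = vals.sum(axis=(1, 3), dtype=float)
    n_valid = valid.sum(axis=(1, 3), dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = 100.0 * n_one / n_valid
    out_valid = n_valid > 0
    frac[~out_valid] = np.nan
    return Raster(target, frac, out_valid)


def area_km2(mask: Raster) -> float:
    """Total area in km² of the true (and valid) cells of a boolean raster."""
    n_true = int(np.count_nonzero(mask.valid & (mask.values != 0)))
    return n_true * mask.grid.cell_size**2 / 1e6


# ---------------------------------------------------------------------------
# GeoTIFF input/output (tifffile with the standard geo tags)
# ---------------------------------------------------------------------------

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_ASCII = 34737
_TAG_GDAL_NODATA = 42113
_NODATA = -9999.0


def _geo_extratags(grid: SceneGrid) -> list[tuple]:
    return [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
        (_TAG_GEO_ASCII, "s", 0, grid.crs_label + "|"),
        (_TAG_GDAL_NODATA, "s", 0, str(_NODATA)),
    ]


def write_geotiff(r: Raster, path) -> None:
    """Write a single-band float32 GeoTIFF with explicit nodata tagging."""
    import tifffile

    data = np.where(r.valid, r.values, _NODATA).astype(np.float32)
    tifffile.imwrite(str(path), data, extratags=_geo_extratags(r.grid))


def write_rasters_multiband(rasters: list[Raster], path) -> None:
    """Write aligned rasters as one multi-band float32 GeoTIFF."""
    import tifffile

    _require_same_grid(*rasters)
    data = np.stack(
        [np.where(r.valid, r.values, _NODATA).astype(np.float32) for r in rasters]
    )
    tifffile.imwrite(
        str(path), data, photometric="minisblack", extratags=_geo_extratags(rasters[0].grid)
    )


def _grid_from_page(page, shape: tuple[int, int]) -> tuple[SceneGrid, float]:
    tags = page.tags
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise ValueError("GeoTIFF is missing georeferencing tags")
    scale = tags[_TAG_MODEL_PIXEL_SCALE].value
    tie = tags[_TAG_MODEL_TIEPOINT].value
    crs = "unknown"
    if _TAG_GEO_ASCII in tags:
        crs = str(tags[_TAG_GEO_ASCII].value).rstrip("|")
    nodata = _NODATA
    if _TAG_GDAL_NODATA in tags:
        nodata = float(tags[_TAG_GDAL_NODATA].value)
    grid = SceneGrid(
        n_rows=shape[0],
        n_cols=shape[1],
        cell_size=float(scale[0]),
        origin_x=float(tie[3]),
        origin_y=float(tie[4]),
        crs_label=crs,
    )
    return grid, nodata


def read_geotiff(path) -> Raster:
    """Read a single-band GeoTIFF into a Raster (nodata tag -> invalid cells)."""
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray().astype(float)
        if data.ndim != 2:
            raise ValueError(f"expected a single-band raster, got shape {data.shape}")
        grid, nodata = _grid_from_page(tif.pages[0], data.shape)
    valid = np.isfinite(data) & (data != nodata)
    data[~valid] = np.nan
    return Raster(grid, data, valid)


def read_reflectance_stack(path) -> ReflectanceStack:
    """Read a six-band GeoTIFF (blue..swir2 in order) into a ReflectanceStack."""
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray().astype(float)
        if data.ndim != 3 or data.shape[0] != len(BAND_ORDER):
            raise ValueError(
                f"expected {len(BAND_ORDER)} bands (blue, green, red, nir, swir1, swir2), "
                f"got shape {data.shape}"
            )
        grid, nodata = _grid_from_page(tif.pages[0], data.shape[1:])
    bands = {}
    for i, name in enumerate(BAND_ORDER):
        layer = data[i]
        valid = np.isfinite(layer) & (layer != nodata)
        layer = np.where(valid, layer, np.nan)
        bands[name] = Raster(grid, layer, valid)
    return ReflectanceStack(grid=grid, **bands)
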