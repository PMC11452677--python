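"""Seeded generator of Landsat-like scenes with known ground truth.

Emulates the statistical structure the analysis assumes, with no download:
a spatially clustered land-cover map over five classes (water,
vegetation/cropland, bare soil, impervious construction land, built-up
settlement), per-class reflectance and thermal-radiance spectra with Gaussian
within-class noise, clustered construction layers (rooftop percent,
population density, building height) concentrated on settlement cells, and
synthetic regression targets with a known feature-response function
(linear, U-shaped or inverted-U) for parameter-recovery tests.

The default class spectra encode the qualitative orderings the composite
index relies on — vegetation is greener and wetter, built/bare surfaces are
hotter and drier — so that on a generated scene the class-mean RSEI ordering
vegetation > bare soil > impervious holds by construction.

All randomness flows from one root seed through named substreams, so every
layer is bit-reproducible under (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster_core import BAND_ORDER, Raster, ReflectanceStack, SceneGrid
from .regression import FeatureState
from .thermal_lst import ThermalBand

__all__ = [
    "CLASS_ORDER",
    "SceneConfig",
    "GroundTruth",
    "ResponseSpec",
    "generate_scene",
    "generate_construction_layers",
    "generate_feature_fields",
    "generate_regression_target",
    "default_scene_config",
]

CLASS_ORDER = ("water", "vegetation", "bare_soil", "impervious", "settlement")

# Per-class mean surface reflectance (blue, green, red, nir, swir1, swir2).
# Orderings by construction: vegetation has high NIR/low red (high NDVI) and
# low SWIR (wet); bare soil and built surfaces have SWIR1 > NIR (dry, NDSI>0);
# water has green > SWIR1 (MNDWI > 0).
DEFAULT_SPECTRA: dict[str, tuple[float, ...]] = {
    "water": (0.06, 0.05, 0.03, 0.02, 0.01, 0.01),
    "vegetation": (0.03, 0.06, 0.04, 0.45, 0.18, 0.08),
    "bare_soil": (0.10, 0.14, 0.18, 0.24, 0.32, 0.28),
    "impervious": (0.16, 0.18, 0.20, 0.22, 0.34, 0.30),
    "settlement": (0.13, 0.15, 0.17, 0.21, 0.28, 0.24),
}

# Thermal at-sensor radiance means (W/m^2/sr/um); hotter surfaces emit more.
DEFAULT_RADIANCE: dict[str, float] = {
    "water": 8.2,
    "vegetation": 8.6,
    "bare_soil": 9.6,
    "impervious": 10.4,
    "settlement": 10.0,
}

DEFAULT_FRACTIONS: dict[str, float] = {
    "water": 0.10,
    "vegetation": 0.45,
    "bare_soil": 0.15,
    "impervious": 0.12,
    "settlement": 0.18,
}


@dataclass(frozen=True)
class SceneConfig:
    """Full parameterisation of a synthetic scene."""

    grid: SceneGrid
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    class_spectra: dict = field(default_factory=lambda: dict(DEFAULT_SPECTRA))
    class_radiance: dict = field(default_factory=lambda: dict(DEFAULT_RADIANCE))
    reflectance_sd: float = 0.015
    radiance_sd: float = 0.15
    clustering: float = 4.0  # spatial correlation length, cells
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.get(c, 0.0) for c in CLASS_ORDER)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if any(self.class_fractions.get(c, 0.0) < 0 for c in CLASS_ORDER):
            raise ValueError("class fractions must be nonnegative")


@dataclass
class ResponseSpec:
    """Generative feature→target response used for recovery tests.

    kinds: ``linear`` (a + b·x), ``u`` (ymin + c·(x−x0)²) and ``inverted_u``
    (ymax − c·(x−x0)²), each driven by a single named feature.
    """

    kind: str
    feature: str = "ndvi_nor"
    x0: float = 0.5
    a: float = 0.3
    b: float = 0.4
    c: float = 1.2

    def __call__(self, X: dict[str, np.ndarray]) -> np.ndarray:
        x = X[self.feature]
        if self.kind == "linear":
            return self.a + self.b * x
        if self.kind == "u":
            return self.a + self.c * (x - self.x0) ** 2
        if self.kind == "inverted_u":
            return self.a - self.c * (x - self.x0) ** 2
        raise ValueError(f"unknown response kind {self.kind!r}")


@dataclass
class GroundTruth:
    """What the generator knows: the class map and any generative response."""

    class_map: Raster  # integer codes, index into CLASS_ORDER
    response: ResponseSpec | None = None

    def class_mask(self, name: str) -> np.ndarray:
        code = CLASS_ORDER.index(name)
        return self.class_map.valid & (self.class_map.values == code)


def default_scene_config(
    n_rows: int = 120, n_cols: int = 120, cell_size: float = 30.0, seed: int = 0
) -> SceneConfig:
    grid = SceneGrid(n_rows, n_cols, cell_size)
    return SceneConfig(grid=grid, seed=seed)


def _substream(seed: int, label: str) -> np.random.Generator:
    # named substreams off one root seed keep layers independent but reproducible
    tag = int.from_bytes(label.encode(), "little") % (2**32)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), tag]))


def _smooth_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    return noise


def generate_scene(cfg: SceneConfig) -> tuple[ReflectanceStack, ThermalBand, GroundTruth]:
    """Generate an aligned six-band reflectance stack, thermal band and truth.

    The class map thresholds one smoothed seeded noise field at the quantiles
    of the configured fractions, which calibrates realized class fractions to
    the configured ones while keeping classes spatially contiguous.
    """
    grid = cfg.grid
    rng_map = _substream(cfg.seed, "class_map")
    fld = _smooth_field(grid.shape, cfg.clustering, rng_map)
    fracs = np.array([cfg.class_fractions.get(c, 0.0) for c in CLASS_ORDER])
    cum = np.cumsum(fracs)[:-1]
    cuts = np.quantile(fld, cum)
    class_map = np.digitize(fld, cuts).astype(float)
    gt = GroundTruth(Raster(grid, class_map, np.ones(grid.shape, bool)))

    rng_refl = _substream(cfg.seed, "reflectance")
    bands = {}
    for bi, name in enumerate(BAND_ORDER):
        mean = np.zeros(grid.shape)
        for ci, cname in enumerate(CLASS_ORDER):
            mean[class_map == ci] = cfg.class_spectra[cname][bi]
        vals = np.clip(mean + cfg.reflectance_sd * rng_refl.standard_normal(grid.shape), 0.0, 1.0)
        bands[name] = Raster(grid, vals)
    stack = ReflectanceStack(grid=grid, **bands)

    rng_rad = _substream(cfg.seed, "radiance")
    mean = np.zeros(grid.shape)
    for ci, cname in enumerate(CLASS_ORDER):
        mean[class_map == ci] = cfg.class_radiance[cname]
    rad = np.clip(mean + cfg.radiance_sd * rng_rad.standard_normal(grid.shape), 0.1, None)
    thermal = ThermalBand(Raster(grid, rad))
    return stack, thermal, gt


def generate_construction_layers(
    gt: GroundTruth, cfg: SceneConfig, seed: int | None = None
) -> tuple[Raster, Raster, Raster]:
    """Rooftop percent (PB), population density (PopD) and building height (BH).

    Settlement cells get clustered rooftop fractions, lognormal population
    counts and low-rise lognormal heights — small-scale concentration within
    settlements, large-scale dispersion outside — while non-settlement cells
    are zero (PB exactly; PopD/BH mostly, with sparse low population on
    impervious cells).
    """
    seed = cfg.seed if seed is None else seed
    grid = gt.class_map.grid
    settle = gt.class_mask("settlement")
    imperv = gt.class_mask("impervious")

    rng = _substream(seed, "construction")
    pb = np.zeros(grid.shape)
    pb_field = 55.0 + 15.0 * _smooth_field(grid.shape, cfg.clustering / 2, rng)
    pb[settle] = np.clip(pb_field[settle], 5.0, 95.0)

    popd = np.zeros(grid.shape)
    popd[settle] = rng.lognormal(mean=3.3, sigma=0.6, size=int(settle.sum()))
    sparse = imperv & (rng.random(grid.shape) < 0.15)
    popd[sparse] = rng.lognormal(mean=1.0, sigma=0.5, size=int(sparse.sum()))

    bh = np.zeros(grid.shape)
    bh[settle] = rng.lognormal(mean=1.8, sigma=0.35, size=int(settle.sum()))  # ~6 m

    ones = np.ones(grid.shape, bool)
    return (
        Raster(grid, pb, ones.copy()),
        Raster(grid, popd, ones.copy()),
        Raster(grid, bh, ones.copy()),
    )


def generate_feature_fields(
    grid: SceneGrid, seed: int = 0, clustering: float = 3.0
) -> FeatureState:
    """Construction-feature rasters with broad, smooth coverage of their ranges.

    Unlike the class-driven layers, these fields spread NDVI_nor/NDISI_nor
    quasi-uniformly over [0, 1], which is what response-surface recovery tests
    need (a class-clustered scene leaves coverage gaps between class modes).
    """
    rng = _substream(seed, "feature_fields")

    def unit_field() -> np.ndarray:
        f = _smooth_field(grid.shape, clustering, rng)
        ranks = f.ravel().argsort().argsort().astype(float)
        return (ranks / (ranks.size - 1)).reshape(grid.shape)  # rank-uniform in [0,1]

    ndvi = unit_field()
    ndisi = unit_field()
    pb = 100.0 * unit_field()
    popd = 120.0 * unit_field() ** 2
    bh = 25.0 * unit_field() ** 2
    ones = np.ones(grid.shape, bool)
    return FeatureState(
        Raster(grid, ndvi, ones.copy()),
        Raster(grid, ndisi, ones.copy()),
        Raster(grid, pb, ones.copy()),
        Raster(grid, popd, ones.copy()),
        Raster(grid, bh, ones.copy()),
    )


def generate_regression_target(
    fs: FeatureState,
    response: ResponseSpec,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[Raster, GroundTruth]:
    """Target raster clamp01(response(features) + Gaussian noise), with truth."""
    rng = _substream(seed, "target_noise")
    grid = fs.grid
    X = {name: getattr(fs, name).values for name in
         ("ndvi_nor", "ndisi_nor", "pb", "popd", "bh")}
    clean = response(X)
    noisy = clean + noise_sd * rng.standard_normal(grid.shape)
    target = np.clip(noisy, 0.0, 1.0)
    valid = fs.valid
    target = np.where(valid, target, np.nan)
    gt = GroundTruth(Raster(grid, np.zeros(grid.shape), np.ones(grid.shape, bool)),
                     response=response)
    return Raster(grid, target, valid), gt
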