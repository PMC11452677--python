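"""Buffer-ring multi-scenario simulation of urban-rural construction.

The engine extracts the built/bare core region A1 by thresholding the
normalized dryness composite (Otsu threshold by default), grows disjoint
concentric buffer rings A2-A4 at 200/400/600 m via a Euclidean distance
transform, and then perturbs the five construction features cumulatively:
scenario S_k activates region A_k and applies one 5% step to every active
region, so after S_k a region activated at step j has received k-j+1 steps
(NDVI_nor decreased, the other four increased).

Feature clamps: NDVI_nor >= 0, NDISI_nor <= 1, PB <= 100.  When a buffer ring
is newly activated and a cell has both PopD = 0 and BH = 0, the minimum
nonzero value of that layer within the ring (scene-wide fallback) is
substituted so multiplicative growth can act on it.

Each scenario's RSEI surface is predicted with the trained regression model;
the headline summary is the mean predicted RSEI per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster_core import Raster
from .regression import FEATURE_NAMES, FeatureState, TrainedModel

__all__ = [
    "RegionPartition",
    "ScenarioSpec",
    "ScenarioResult",
    "extract_a1",
    "buffer_rings",
    "perturb_once",
    "zero_substitute",
    "run_scenarios",
    "scenario_means",
]


@dataclass
class RegionPartition:
    """Core region A1 plus pairwise-disjoint buffer rings A2..A{n+1}.

    Ring k holds exactly the cells whose centre-to-centre Euclidean distance
    to the nearest A1 cell lies in (d_{k-1}, d_k].
    """

    a1: Raster  # boolean
    rings: list[Raster]  # boolean, ordered outward
    distances: tuple[float, ...]

    def regions(self) -> list[np.ndarray]:
        """Boolean arrays [A1, A2, ...] in activation order."""
        out = [self.a1.valid & (self.a1.values != 0)]
        out += [r.valid & (r.values != 0) for r in self.rings]
        return out


@dataclass(frozen=True)
class ScenarioSpec:
    """Perturbation protocol: step size, scenario count and change mode."""

    step_fraction: float = 0.05
    n_scenarios: int = 4
    mode: str = "multiplicative"
    distances: tuple[float, ...] = (200.0, 400.0, 600.0)

    def __post_init__(self) -> None:
        if not (0 < self.step_fraction < 1):
            raise ValueError("step_fraction must lie in (0, 1)")
        if self.mode not in ("multiplicative", "additive"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if self.n_scenarios != len(self.distances) + 1:
            raise ValueError("n_scenarios must equal ring count + 1")


@dataclass
class ScenarioResult:
    """One scenario's feature snapshot, predicted RSEI and its mean."""

    label: str
    features: FeatureState
    predicted_rsei: Raster
    mean_rsei: float


def extract_a1(ndissi_nor: Raster, threshold: float | str = "otsu") -> Raster:
    """Built/bare core: cells with normalized dryness >= threshold.

    ``threshold='otsu'`` derives the cut from the valid-cell histogram.
    """
    vals = ndissi_nor.masked_values()
    if vals.size == 0:
        raise ValueError("no valid cells to threshold")
    if threshold == "otsu":
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(vals))
    core = ndissi_nor.valid & (ndissi_nor.values >= float(threshold))
    if not core.any():
        raise ValueError("no core region: threshold excludes every cell")
    return Raster(ndissi_nor.grid, core.astype(float), np.ones(ndissi_nor.grid.shape, bool))


def buffer_rings(a1: Raster, distances: tuple[float, ...] = (200.0, 400.0, 600.0)) -> RegionPartition:
    """Disjoint distance rings around A1 from a Euclidean distance transform."""
    d = tuple(float(x) for x in distances)
    if any(b <= a for a, b in zip((0.0,) + d, d)):
        raise ValueError("distances must be strictly increasing and positive")
    core = a1.valid & (a1.values != 0)
    if not core.any():
        raise ValueError("A1 is empty")
    cell = a1.grid.cell_size
    dist = ndimage.distance_transform_edt(~core, sampling=(cell, cell))
    rings = []
    lower = 0.0
    ones = np.ones(a1.grid.shape, bool)
    for upper in d:
        ring = (dist > lower) & (dist <= upper) & ~core
        rings.append(Raster(a1.grid, ring.astype(float), ones.copy()))
        lower = upper
    return RegionPartition(a1.copy(), rings, d)


def perturb_once(fs: FeatureState, region: np.ndarray | Raster, spec: ScenarioSpec) -> FeatureState:
    """One 5% construction step inside ``region``; identity elsewhere.

    NDVI_nor decreases, NDISI_nor/PB/PopD/BH increase.  Multiplicative mode
    scales by (1 -/+ step); additive mode shifts by step x full range (1.0 for
    the unit-range indices, 100 for PB, and the scene maximum for PopD/BH).
    Clamps (NDVI_nor >= 0, NDISI_nor <= 1, PB <= 100) are applied after.
    """
    reg = region.valid & (region.values != 0) if isinstance(region, Raster) else np.asarray(region, bool)
    out = fs.copy()
    s = spec.step_fraction

    def scale_range(r: Raster) -> float:
        v = r.masked_values()
        return float(v.max()) if v.size else 1.0

    ranges = {"ndvi_nor": 1.0, "ndisi_nor": 1.0, "pb": 100.0,
              "popd": scale_range(fs.popd), "bh": scale_range(fs.bh)}
    for name in FEATURE_NAMES:
        r: Raster = getattr(out, name)
        sign = -1.0 if name == "ndvi_nor" else 1.0
        v = r.values.copy()
        sel = reg & r.valid
        if spec.mode == "multiplicative":
            v[sel] = v[sel] * (1.0 + sign * s)
        else:
            v[sel] = v[sel] + sign * s * ranges[name]
        setattr(out, name, Raster(r.grid, v, r.valid.copy()))
    _clamp(out)
    return out


def _clamp(fs: FeatureState) -> None:
    for name, lo, hi in (
        ("ndvi_nor", 0.0, 1.0),
        ("ndisi_nor", 0.0, 1.0),
        ("pb", 0.0, 100.0),
        ("popd", 0.0, np.inf),
        ("bh", 0.0, np.inf),
    ):
        r: Raster = getattr(fs, name)
        v = np.clip(r.values, lo, hi)
        setattr(fs, name, Raster(r.grid, v, r.valid.copy()))


def zero_substitute(fs: FeatureState, new_ring: np.ndarray | Raster) -> FeatureState:
    """Seed PopD/BH in a newly activated ring where both are exactly zero.

    Substitutes the minimum nonzero value of each layer within the ring
    (falling back to the scene-wide nonzero minimum when the ring has none);
    cells where only one of the two is zero are left untouched.
    """
    ring = new_ring.valid & (new_ring.values != 0) if isinstance(new_ring, Raster) else np.asarray(new_ring, bool)
    out = fs.copy()
    both_zero = ring & out.popd.valid & out.bh.valid \
        & (out.popd.values == 0) & (out.bh.values == 0)
    if not both_zero.any():
        return out
    for name in ("popd", "bh"):
        r: Raster = getattr(out, name)
        ring_vals = r.values[ring & r.valid]
        nz = ring_vals[ring_vals > 0]
        if nz.size == 0:
            all_vals = r.masked_values()
            nz = all_vals[all_vals > 0]
        if nz.size == 0:
            raise ValueError(f"no nonzero {name} values anywhere; cannot substitute")
        v = r.values.copy()
        v[both_zero] = float(nz.min())
        setattr(out, name, Raster(r.grid, v, r.valid.copy()))
    return out


def _predict_state(fs: FeatureState, model: TrainedModel) -> tuple[Raster, float]:
    valid = fs.valid
    rows = np.flatnonzero(valid.ravel())
    pred = model.predict(fs.as_matrix(rows))
    out = np.full(fs.grid.shape, np.nan)
    out.ravel()[rows] = pred
    return Raster(fs.grid, out, valid), float(pred.mean())


def run_scenarios(
    fs0: FeatureState,
    part: RegionPartition,
    model: TrainedModel,
    spec: ScenarioSpec | None = None,
) -> list[ScenarioResult]:
    """Run the cumulative scenario ladder S0..S_n.

    S0 is the observed baseline.  At scenario k the k-th region (A1 first,
    then each ring outward) is activated — newly activated buffer rings get
    the PopD/BH zero-substitution — and one perturbation step is applied to
    the union of all active regions.  Predictions outside every region are
    therefore identical across scenarios.
    """
    spec = spec or ScenarioSpec(distances=part.distances)
    regions = part.regions()
    if spec.n_scenarios != len(regions):
        raise ValueError("scenario count does not match the region partition")
    results = []
    pred, mean = _predict_state(fs0, model)
    results.append(ScenarioResult("S0", fs0.copy(), pred, mean))
    fs = fs0.copy()
    active = np.zeros(fs.grid.shape, dtype=bool)
    for k, region in enumerate(regions, start=1):
        if k > 1:  # newly activated buffer ring
            fs = zero_substitute(fs, region)
        active |= region
        fs = perturb_once(fs, active, spec)
        pred, mean = _predict_state(fs, model)
        results.append(ScenarioResult(f"S{k}", fs.copy(), pred, mean))
    return results


def scenario_means(results: list[ScenarioResult]) -> pd.DataFrame:
    """Table of mean predicted RSEI per scenario, S0 first."""
    if not results:
        raise ValueError("no scenario results")
    return pd.DataFrame(
        {"scenario": [r.label for r in results],
         "mean_rsei": [r.mean_rsei for r in results]}
    )
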