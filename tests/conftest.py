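import numpy as np
import pytest

from rseisim import rsei as rsei_mod
from rseisim import spectral_indices as si
from rseisim import synthetic
from rseisim import thermal_lst as tl
from rseisim.raster_core import Raster, SceneGrid


def make_raster(values, cell_size=30.0, valid=None, **grid_kw):
    values = np.asarray(values, dtype=float)
    grid = SceneGrid(values.shape[0], values.shape[1], cell_size, **grid_kw)
    return Raster(grid, values, valid)


@pytest.fixture(scope="session")
def scene():
    """One deterministic 120x120 synthetic scene shared across tests."""
    cfg = synthetic.default_scene_config(seed=1)
    stack, thermal, gt = synthetic.generate_scene(cfg)
    return {"cfg": cfg, "stack": stack, "thermal": thermal, "gt": gt}


@pytest.fixture(scope="session")
def indicators(scene):
    """The four RSEI indicators plus the water mask on the shared scene."""
    stack, thermal = scene["stack"], scene["thermal"]
    ndvi = si.ndvi(stack)
    wet = si.tct_wetness(stack)
    mndwi = si.mndwi(stack)
    ndsi = si.ndsi(stack)
    water = si.water_mask(mndwi)
    ndisi = si.ndisi(stack, thermal.radiance, mndwi)
    ndissi = si.ndissi(ndisi, ndsi, water)
    eps = tl.estimate_emissivity(ndvi, water)
    lst = tl.retrieve_lst(thermal, eps, tl.AtmosphericParams(0.85, 1.2, 2.0))
    return {"ndvi": ndvi, "wetness": wet, "mndwi": mndwi, "ndsi": ndsi,
            "ndisi": ndisi, "ndissi": ndissi, "water": water, "lst": lst}


@pytest.fixture(scope="session")
def rsei_result(indicators):
    m = rsei_mod.build_indicator_matrix(
        indicators["ndvi"], indicators["wetness"], indicators["lst"],
        indicators["ndissi"], indicators["water"])
    pca = rsei_mod.orient_pc1(rsei_mod.pca_pc1(m))
    return m, pca, rsei_mod.compute_rsei(m, pca)
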