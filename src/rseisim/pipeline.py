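"""End-to-end orchestration: indices -> LST -> RSEI -> regression -> scenarios.

``run_pipeline`` executes the full analysis from a single validated config
dict (typically loaded from YAML), writes every stage product under an output
directory, and records a run manifest with the effective configuration and a
SHA-256 hash of every output file, so that a rerun with identical config and
seeds is verifiable as identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import raster_core, regression, rsei, scenario, spectral_indices, synthetic, thermal_lst

log = logging.getLogger("rseisim")

DEFAULT_CONFIG: dict = {
    "scene": {"n_rows": 120, "n_cols": 120, "cell_size": 30.0, "seed": 0},
    "water_threshold": 0.1,
    "ndisi_scale": "tir_only",
    "atmosphere": {"tau": 0.85, "l_up": 1.2, "l_down": 2.0},
    "thermal_constants": {"k1": 774.89, "k2": 1321.08, "b_gamma": 1324.0},
    "sc_psi3": "paper",
    "regression": {"n_samples": 5000, "seed": 0, "cv_folds": 5, "budget": 12,
                   "tune": False},
    "scenario": {"a1_threshold": "otsu", "distances": [200.0, 400.0, 600.0],
                 "step": 0.05, "mode": "multiplicative", "n_scenarios": 4},
    "output_dir": "rseisim_run",
}

_REQUIRED_SECTIONS = ("scene", "atmosphere", "thermal_constants", "regression", "scenario")


def validate_config(cfg: dict) -> dict:
    """Merge a user config over the defaults and sanity-check it."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (cfg or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    for section in _REQUIRED_SECTIONS:
        if section not in merged:
            raise ValueError(f"config missing section {section!r}")
    sc = merged["scenario"]
    if sc["n_scenarios"] != len(sc["distances"]) + 1:
        raise ValueError("scenario.n_scenarios must equal len(distances) + 1")
    if not (0 < sc["step"] < 1):
        raise ValueError("scenario.step must lie in (0, 1)")
    a = merged["atmosphere"]
    thermal_lst.AtmosphericParams(a["tau"], a["l_up"], a["l_down"])  # validates
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: dict | None = None) -> dict:
    """Run every stage on a generated scene and return the manifest dict."""
    cfg = validate_config(cfg or {})
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "outputs": {}, "summary": {}}

    def save(r, name):
        path = out_dir / name
        raster_core.write_geotiff(r, path)
        manifest["outputs"][name] = _sha256(path)

    # --- synthetic inputs -------------------------------------------------
    sc = cfg["scene"]
    scene_cfg = synthetic.SceneConfig(
        grid=raster_core.SceneGrid(sc["n_rows"], sc["n_cols"], sc["cell_size"]),
        seed=sc["seed"],
    )
    stack, thermal, gt = synthetic.generate_scene(scene_cfg)
    log.info("scene generated: %dx%d cells", sc["n_rows"], sc["n_cols"])

    # --- spectral indices -------------------------------------------------
    ndvi = spectral_indices.ndvi(stack)
    wet = spectral_indices.tct_wetness(stack)
    mndwi = spectral_indices.mndwi(stack)
    ndsi = spectral_indices.ndsi(stack)
    water = spectral_indices.water_mask(mndwi, cfg["water_threshold"])
    ndisi = spectral_indices.ndisi(stack, thermal.radiance, mndwi, cfg["ndisi_scale"])
    ndissi = spectral_indices.ndissi(ndisi, ndsi, water)
    for ind, name in ((ndvi, "ndvi"), (wet, "wetness"), (mndwi, "mndwi"),
                      (ndsi, "ndsi"), (ndisi, "ndisi"), (ndissi, "ndissi")):
        save(ind.raster, f"{name}.tif")
    n_water = int(water.is_water.sum())
    log.info("water mask: %d cells (%.1f%%)", n_water, 100 * n_water / water.raster.values.size)

    # --- LST --------------------------------------------------------------
    tc = cfg["thermal_constants"]
    a = cfg["atmosphere"]
    consts = thermal_lst.ThermalConstants(tc["k1"], tc["k2"], tc["b_gamma"])
    atmos = thermal_lst.AtmosphericParams(a["tau"], a["l_up"], a["l_down"])
    eps = thermal_lst.estimate_emissivity(ndvi, water)
    lst = thermal_lst.retrieve_lst(thermal, eps, atmos, consts, cfg["sc_psi3"])
    save(lst.raster, "lst.tif")

    # --- RSEI -------------------------------------------------------------
    matrix = rsei.build_indicator_matrix(ndvi, wet, lst, ndissi, water)
    pca = rsei.orient_pc1(rsei.pca_pc1(matrix))
    result = rsei.compute_rsei(matrix, pca)
    save(result.rsei, "rsei.tif")
    levels = rsei.classify_levels(result)
    save(levels.levels, "rsei_levels.tif")
    stats = rsei.level_stats(levels)
    stats.to_csv(out_dir / "level_stats.csv", index=False)
    manifest["outputs"]["level_stats.csv"] = _sha256(out_dir / "level_stats.csv")
    manifest["summary"]["pca"] = {
        "loadings_pc1": [float(x) for x in pca.loadings[0]],
        "eigenvalues": [float(x) for x in pca.eigenvalues],
        "percent": [float(x) for x in pca.percent],
    }
    manifest["summary"]["mean_rsei"] = float(np.mean(result.rsei.masked_values()))

    # --- regression -------------------------------------------------------
    rg = cfg["regression"]
    pb, popd, bh = synthetic.generate_construction_layers(gt, scene_cfg)
    ndvi_nor, _ = raster_core.normalize_minmax(ndvi.raster, ~water.is_water & ndvi.raster.valid)
    ndisi_nor, _ = raster_core.normalize_minmax(ndisi.raster, ~water.is_water & ndisi.raster.valid)
    fs = regression.FeatureState(ndvi_nor, ndisi_nor, pb, popd, bh)
    n = min(rg["n_samples"], int((fs.valid & result.rsei.valid).sum()))
    table = regression.build_feature_table(fs, result, water, n=n, seed=rg["seed"])
    if rg.get("tune"):
        hp, cv = regression.tune_hyperparameters(
            table, k=rg["cv_folds"], budget=rg["budget"], seed=rg["seed"])
    else:
        hp, cv = None, None
    model = regression.train(table, hp, cv_rmse=cv, seed=rg["seed"])
    model.save(out_dir / "model.json")
    manifest["outputs"]["model.json"] = _sha256(out_dir / "model.json")
    ranking, _, _ = regression.shap_importance(model, table)
    ranking.to_csv(out_dir / "shap_importance.csv", index=False)
    manifest["outputs"]["shap_importance.csv"] = _sha256(out_dir / "shap_importance.csv")
    curves = {}
    for feat in ("ndvi_nor", "ndisi_nor"):
        curve, _ = regression.marginal_effect_curve(model, table, feat)
        curve.to_csv(out_dir / f"pd_{feat}.csv", index=False)
        manifest["outputs"][f"pd_{feat}.csv"] = _sha256(out_dir / f"pd_{feat}.csv")
        curves[feat] = curve
    manifest["summary"]["regression"] = {
        "n_samples": int(len(table.frame)),
        "training_rmse": model.training_rmse,
        "cv_rmse": model.cv_rmse,
        "hyperparameters": model.hyperparameters,
        "importance": ranking.to_dict(orient="records"),
    }

    # --- scenarios --------------------------------------------------------
    scn = cfg["scenario"]
    a1 = scenario.extract_a1(ndissi.raster, scn["a1_threshold"])
    part = scenario.buffer_rings(a1, tuple(scn["distances"]))
    spec = scenario.ScenarioSpec(scn["step"], scn["n_scenarios"],
                                 scn["mode"], tuple(scn["distances"]))
    results = scenario.run_scenarios(fs, part, model, spec)
    means = scenario.scenario_means(results)
    means.to_csv(out_dir / "scenario_means.csv", index=False)
    manifest["outputs"]["scenario_means.csv"] = _sha256(out_dir / "scenario_means.csv")
    for res in results:
        save(res.predicted_rsei, f"rsei_pred_{res.label}.tif")
    manifest["summary"]["scenario_means"] = dict(
        zip(means["scenario"], [float(x) for x in means["mean_rsei"]])
    )

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def report(run_dir) -> str:
    """Human-readable summary of a completed (or partial) run."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        return f"no manifest found under {run_dir}\n"
    manifest = json.loads(manifest_path.read_text())
    lines = ["rseisim run report", "=" * 40]
    summ = manifest.get("summary", {})
    if "pca" in summ:
        pca = summ["pca"]
        lines.append("\nPC1 loadings (greenness, wetness, heat, dryness):")
        lines.append("  " + "  ".join(f"{x:+.3f}" for x in pca["loadings_pc1"]))
        lines.append("Eigenvalues: " + "  ".join(f"{x:.4f}" for x in pca["eigenvalues"]))
        lines.append("Percent variance: " + "  ".join(f"{x:.2f}" for x in pca["percent"])
                     + f"  (sum {sum(pca['percent']):.2f})")
    if "mean_rsei" in summ:
        lines.append(f"\nScene mean RSEI: {summ['mean_rsei']:.3f}")
    stats_path = run_dir / "level_stats.csv"
    if stats_path.exists():
        stats = pd.read_csv(stats_path)
        lines.append("\nRSEI level statistics:")
        lines.append(stats.to_string(index=False))
    if "regression" in summ:
        rg = summ["regression"]
        lines.append(f"\nRegression: n={rg['n_samples']}, training RMSE {rg['training_rmse']:.4f}")
        lines.append("SHAP importance ranking: "
                     + ", ".join(r["feature"] for r in rg["importance"]))
    if "scenario_means" in summ:
        lines.append("\nScenario mean predicted RSEI:")
        for k, v in summ["scenario_means"].items():
            lines.append(f"  {k}: {v:.3f}")
    missing = [n for n in manifest.get("outputs", {}) if not (run_dir / n).exists()]
    if missing:
        lines.append("\nWARNING: missing outputs: " + ", ".join(missing))
    return "\n".join(lines) + "\n"
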