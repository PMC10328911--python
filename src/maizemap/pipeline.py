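"""End-to-end workflow: simulate -> composite -> train -> predict ->
postprocess -> evaluate.

Two entry styles are provided.  :func:`run_experiment` executes the whole
chain in memory and returns every intermediate product — the form used by
tests and the acceptance script.  The ``stage_*`` functions read and write
the on-disk conventions (GeoTIFF + CSV) and are what the CLI drives; each
returns the paths it produced and appends a structured JSON line (stage,
timestamps, seed, input/output SHA-256 prefixes) to ``run_log.jsonl``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .calendar import BANDS, PERIOD_NAMES
from .classifier import (NODATA_BYTE, MaizeClassifier, build_model,
                         predict_binary, train)
from .compositing import (CompositeFeatures, SceneStack, append_indices,
                          drop_cloudy_scenes, max_value_composite,
                          replace_cloudy_bands, sample_sequences)
from .config import RunConfig
from .evaluation import (accuracy_metrics, area_by_region, binarize_matrix,
                         confusion_matrix, r_squared)
from .geotiff import Raster, read_raster, validate_binary_map, write_raster
from .postprocess import apply_cropland_mask, remove_speckle
from .simulate import (CLASSES, MAIZE_ID, default_profiles,
                       simulate_reference_areas, simulate_samples,
                       simulate_scene_stack)


class MissingInputError(FileNotFoundError):
    """A stage's required input artifact is absent."""


# --------------------------------------------------------------------------
# in-memory experiment
# --------------------------------------------------------------------------

def extract_labeled_features(composite: CompositeFeatures,
                             samples: pd.DataFrame):
    """(X, y, keep) for the sample table; rows with an invalid compositing
    period are dropped (returned in ``keep`` as a boolean mask)."""
    rows = samples["row"].to_numpy()
    cols = samples["col"].to_numpy()
    keep = composite.all_periods_valid[rows, cols]
    x = sample_sequences(composite, rows[keep], cols[keep])
    y = np.array([CLASSES.index(c) for c in samples["class"][keep]])
    return x, y, keep


def model_input_composite(composite: CompositeFeatures,
                          cfg: RunConfig) -> tuple[CompositeFeatures, int]:
    """Composite as the classifier sees it and its channel count
    (6 bands, or 9 with the spectral-index ablation enabled)."""
    if cfg.compositing.use_indices:
        return append_indices(composite), 9
    return composite, 6


def run_experiment(cfg: RunConfig) -> dict:
    """Run the full pipeline in memory; returns a dict of all products.

    Keys: ``profiles, stack, truth, cropland, regions, samples, reference,
    composite, model, history, raw_map, clean_map, matrix4, matrix2,
    metrics4, metrics2, areas, r2``.
    """
    cfg.validate()
    scenario = dataclasses.replace(cfg.scenario, seed=cfg.seed)
    profiles = default_profiles(cfg.seed)
    stack, truth, cropland, regions = simulate_scene_stack(scenario, profiles)
    samples = simulate_samples(scenario, truth, cfg.sampling.n_per_class,
                               cfg.sampling.train_fraction)
    reference = simulate_reference_areas(truth, regions,
                                         cfg.reference.error_sd, cfg.seed,
                                         scenario.year)

    stack = drop_cloudy_scenes(stack, cfg.compositing.max_cloud_fraction)
    stack = replace_cloudy_bands(stack)
    composite = max_value_composite(stack)

    feat_comp, n_bands = model_input_composite(composite, cfg)
    ccfg = dataclasses.replace(cfg.classifier, seed=cfg.seed, n_bands=n_bands)
    model = build_model(ccfg)
    train_tab = samples[samples["split"] == "train"]
    x_train, y_train, _ = extract_labeled_features(feat_comp, train_tab)
    history = train(model, x_train, y_train)

    raw_map = predict_binary(model, feat_comp, maize_class=MAIZE_ID)
    masked = apply_cropland_mask(raw_map, cropland)
    clean_map = remove_speckle(masked, cfg.postprocess.min_patch_px)

    test_tab = samples[samples["split"] == "test"]
    x_test, y_test, keep = extract_labeled_features(feat_comp, test_tab)
    probs = model.predict_proba(x_test)
    pred4 = [CLASSES[i] for i in probs.argmax(axis=1)]
    truth4 = [CLASSES[i] for i in y_test]
    matrix4 = confusion_matrix(truth4, pred4, CLASSES)
    matrix2 = binarize_matrix(matrix4, "maize")
    areas = area_by_region(clean_map, regions, year=scenario.year)
    merged = areas.merge(reference, on=["region", "year"])
    r2 = r_squared(merged["mapped_area_ha"], merged["area_ha"])
    return {
        "profiles": profiles, "stack": stack, "truth": truth,
        "cropland": cropland, "regions": regions, "samples": samples,
        "reference": reference, "composite": composite, "model": model,
        "history": history, "raw_map": raw_map, "clean_map": clean_map,
        "matrix4": matrix4, "matrix2": matrix2,
        "metrics4": accuracy_metrics(matrix4),
        "metrics2": accuracy_metrics(matrix2),
        "areas": merged, "r2": r2,
    }


# --------------------------------------------------------------------------
# on-disk stages (CLI)
# --------------------------------------------------------------------------

def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _log(outdir: Path, stage: str, t0: float, inputs: list[Path],
         outputs: list[Path], seed: int) -> None:
    rec = {
        "stage": stage, "seed": seed,
        "started": t0, "finished": time.time(),
        "inputs": {p.name: _sha(p) for p in inputs if p.exists()},
        "outputs": {p.name: _sha(p) for p in outputs if p.exists()},
    }
    with open(outdir / "run_log.jsonl", "a") as fh:
        fh.write(json.dumps(rec) + "\n")


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise MissingInputError(f"missing {what}: {path} (run the producing stage first)")
    return path


def _scene_path(outdir: Path, doy: int) -> Path:
    return outdir / f"scene_d{doy:03d}.tif"


def stage_simulate(cfg: RunConfig, outdir: Path) -> list[Path]:
    t0 = time.time()
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = dataclasses.replace(cfg.scenario, seed=cfg.seed)
    profiles = default_profiles(cfg.seed)
    stack, truth, cropland, regions = simulate_scene_stack(scenario, profiles)
    samples = simulate_samples(scenario, truth, cfg.sampling.n_per_class,
                               cfg.sampling.train_fraction)
    reference = simulate_reference_areas(truth, regions,
                                         cfg.reference.error_sd, cfg.seed,
                                         scenario.year)
    outputs = []
    for ti, doy in enumerate(stack.dates):
        p = _scene_path(outdir, doy)
        write_raster(p, Raster(stack.data[ti], nodata=-9999.0, band_names=BANDS))
        q = outdir / f"cloud_d{doy:03d}.tif"
        write_raster(q, Raster(stack.cloud[ti].astype(np.uint8), band_names=BANDS))
        outputs += [p, q]
    for name, arr in (("truth", truth), ("cropland_mask", cropland),
                      ("regions", regions)):
        p = outdir / f"{name}.tif"
        write_raster(p, Raster(arr.astype(np.uint8)))
        outputs.append(p)
    samples.to_csv(outdir / "samples.csv", index=False)
    reference.to_csv(outdir / "reference_areas.csv", index=False)
    outputs += [outdir / "samples.csv", outdir / "reference_areas.csv"]
    _log(outdir, "simulate", t0, [], outputs, cfg.seed)
    return outputs


def load_scene_stack(outdir: Path) -> SceneStack:
    scene_files = sorted(outdir.glob("scene_d*.tif"))
    if not scene_files:
        raise MissingInputError(f"no scene rasters under {outdir}")
    dates, data, cloud = [], [], []
    for p in scene_files:
        doy = int(p.stem.split("_d")[1])
        dates.append(doy)
        data.append(read_raster(p).data)
        cloud.append(read_raster(_require(outdir / f"cloud_d{doy:03d}.tif",
                                          "cloud flags")).data.astype(bool))
    return SceneStack(dates=dates, data=np.stack(data), cloud=np.stack(cloud))


def stage_composite(cfg: RunConfig, outdir: Path) -> list[Path]:
    t0 = time.time()
    stack = load_scene_stack(outdir)
    inputs = sorted(outdir.glob("scene_d*.tif"))
    stack = drop_cloudy_scenes(stack, cfg.compositing.max_cloud_fraction)
    stack = replace_cloudy_bands(stack)
    composite = max_value_composite(stack)
    names = tuple(f"{p}_{b}" for p in PERIOD_NAMES for b in BANDS)
    flat = composite.values.reshape(-1, *composite.grid_shape)  # period-major
    p1 = outdir / "composite.tif"
    arr = np.where(np.isfinite(flat), flat, -9999.0).astype(np.float32)
    write_raster(p1, Raster(arr, nodata=-9999.0, band_names=names))
    p2 = outdir / "composite_valid.tif"
    write_raster(p2, Raster(composite.valid.astype(np.uint8),
                            band_names=PERIOD_NAMES))
    _log(outdir, "composite", t0, inputs, [p1, p2], cfg.seed)
    return [p1, p2]


def load_composite(outdir: Path) -> CompositeFeatures:
    r = read_raster(_require(outdir / "composite.tif", "composite raster"))
    v = read_raster(_require(outdir / "composite_valid.tif", "composite validity"))
    vals = r.data.astype(np.float32)
    vals[vals == -9999.0] = np.nan
    n_p = v.data.shape[0]
    h, w = vals.shape[-2:]
    return CompositeFeatures(values=vals.reshape(n_p, -1, h, w),
                             valid=v.data.astype(bool))


def stage_train(cfg: RunConfig, outdir: Path) -> list[Path]:
    t0 = time.time()
    composite = load_composite(outdir)
    samples = pd.read_csv(_require(outdir / "samples.csv", "sample table"))
    _check_columns(samples, ["row", "col", "year", "class", "split"],
                   outdir / "samples.csv")
    feat_comp, n_bands = model_input_composite(composite, cfg)
    ccfg = dataclasses.replace(cfg.classifier, seed=cfg.seed, n_bands=n_bands)
    model = build_model(ccfg)
    x, y, _ = extract_labeled_features(feat_comp, samples[samples["split"] == "train"])
    train(model, x, y, log_path=outdir / "training_log.csv")
    model.save(outdir / "checkpoint.npz")
    outs = [outdir / "checkpoint.npz", outdir / "training_log.csv"]
    _log(outdir, "train", t0,
         [outdir / "composite.tif", outdir / "samples.csv"], outs, cfg.seed)
    return outs


def stage_predict(cfg: RunConfig, outdir: Path) -> list[Path]:
    t0 = time.time()
    model = MaizeClassifier.load(_require(outdir / "checkpoint.npz", "checkpoint"))
    composite, _ = model_input_composite(load_composite(outdir), cfg)
    raw = predict_binary(model, composite, maize_class=MAIZE_ID)
    p = outdir / "maize_map_raw.tif"
    write_raster(p, Raster(raw, nodata=NODATA_BYTE))
    _log(outdir, "predict", t0, [outdir / "checkpoint.npz"], [p], cfg.seed)
    return [p]


def stage_postprocess(cfg: RunConfig, outdir: Path) -> list[Path]:
    t0 = time.time()
    raw = read_raster(_require(outdir / "maize_map_raw.tif", "raw maize map"))
    mask = read_raster(_require(outdir / "cropland_mask.tif", "cropland mask"))
    cleaned = remove_speckle(apply_cropland_mask(raw.data, mask.data),
                             cfg.postprocess.min_patch_px)
    p = outdir / "maize_map.tif"
    out = Raster(cleaned, nodata=NODATA_BYTE)
    validate_binary_map(out, p)
    write_raster(p, out)
    _log(outdir, "postprocess", t0,
         [outdir / "maize_map_raw.tif", outdir / "cropland_mask.tif"], [p], cfg.seed)
    return [p]


def stage_evaluate(cfg: RunConfig, outdir: Path) -> list[Path]:
    t0 = time.time()
    map_r = read_raster(_require(outdir / "maize_map.tif", "maize map"))
    validate_binary_map(map_r, outdir / "maize_map.tif")
    samples = pd.read_csv(_require(outdir / "samples.csv", "sample table"))
    _check_columns(samples, ["row", "col", "year", "class", "split"],
                   outdir / "samples.csv")
    regions = read_raster(_require(outdir / "regions.tif", "region raster")).data
    reference = pd.read_csv(_require(outdir / "reference_areas.csv",
                                     "reference area table"))
    _check_columns(reference, ["region", "year", "area_ha"],
                   outdir / "reference_areas.csv")

    test = samples[samples["split"] == "test"]
    vals = map_r.data[test["row"].to_numpy(), test["col"].to_numpy()]
    ok = vals != NODATA_BYTE
    truth2 = np.where(test["class"][ok] == "maize", "maize", "non-maize")
    pred2 = np.where(vals[ok] == 1, "maize", "non-maize")
    matrix2 = binarize_matrix(confusion_matrix(truth2, pred2,
                                               ("maize", "non-maize")), "maize")
    metrics = accuracy_metrics(matrix2)
    metrics.insert(0, "year", cfg.scenario.year)
    areas = area_by_region(map_r.data, regions, year=cfg.scenario.year)
    merged = areas.merge(reference, on=["region", "year"])
    r2 = r_squared(merged["mapped_area_ha"], merged["area_ha"])

    p_m = outdir / "accuracy.csv"
    metrics.to_csv(p_m, index=False)
    p_a = outdir / "areas.csv"
    merged.to_csv(p_a, index=False)
    p_s = outdir / "summary.txt"
    oa = metrics.loc[metrics["class"] == "__overall__", "oa"].iloc[0]
    mrow = metrics.loc[metrics["class"] == "maize"].iloc[0]
    p_s.write_text(
        f"binary confusion matrix (rows=truth, cols=prediction):\n"
        f"{matrix2.to_frame()}\n\n"
        f"maize UA={mrow.ua:.3f} PA={mrow.pa:.3f} F1={mrow.f1:.3f} OA={oa:.3f}\n"
        f"area consistency over {len(merged)} regions: R^2={r2:.4f}\n"
    )
    _log(outdir, "evaluate", t0, [outdir / "maize_map.tif"], [p_m, p_a, p_s], cfg.seed)
    return [p_m, p_a, p_s]


STAGES = {
    "simulate": stage_simulate,
    "composite": stage_composite,
    "train": stage_train,
    "predict": stage_predict,
    "postprocess": stage_postprocess,
    "evaluate": stage_evaluate,
}


def run_all(cfg: RunConfig, outdir: Path) -> list[Path]:
    outputs = []
    for stage in STAGES.values():
        outputs += stage(cfg, outdir)
    return outputs


def _check_columns(frame: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
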