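"""End-to-end orchestration of the invasion-risk analysis.

One configuration drives the whole chain:

    clean -> thin -> prep (organic, focal density, resample) -> prune
    -> background -> k-fold fit/evaluate -> ensemble predict -> importance
    -> store KDE -> normalize -> combine -> zonal summary

Inputs come either from files (occurrences, rasters, stores, polygons) or
from a ``simulate`` block driving the synthetic generators.  All randomness
derives from one global seed: each stage gets ``(seed XOR crc32(stage))
mod 2^31``, so stages have independent, reproducible streams and reruns are
bit-identical.  A JSON manifest records the config echo, per-stage seeds,
record counts and timings.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from pathlib import Path

import pandas as pd
import yaml

from . import kde as kde_mod
from . import maxent, occurrences as occ_mod, rasters, risk as risk_mod, synthetic

logger = logging.getLogger("invasionrisk")

DEFAULTS = {
    "min_year": 2000,
    "max_uncertainty_m": 10_000.0,
    "organic_threshold": 50.0,
    "density_radius_m": 500.0,
    "correlation_threshold": 0.7,
    "correlation_sample_n": 10_000,
    "background_n": 10_000,
    "k_folds": 10,
    "lam_multiplier": 1.0,
    "hotspot_threshold": 0.5,
    "bandwidth_m": None,
    "feature_classes": None,   # None -> presence-count schedule
    "n_hinge_knots": 5,
    "importance_repeats": 3,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(sh)


def load_config(path) -> dict:
    with open(str(path)) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def run(config: dict, outdir) -> Path:
    """Execute the full analysis; returns the output directory.

    ``config`` holds either an ``inputs`` block (paths to occurrences .csv,
    predictor .asc rasters, stores .csv, polygons .geojson, plus optional
    ``organic_percent`` raster name) or a ``simulate`` block with generator
    parameters; a ``params`` block overrides the documented defaults; and a
    top-level ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    seed = int(config.get("seed", 0))
    params = {**DEFAULTS, **(config.get("params") or {})}
    manifest: dict = {"config": config, "seeds": {}, "stages": {}}

    def record(stage: str, t0: float, **counts) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **counts}
        logger.info("stage=%s %s", stage,
                    " ".join(f"{k}={v}" for k, v in counts.items()))

    def seeded(stage: str) -> int:
        s = stage_seed(seed, stage)
        manifest["seeds"][stage] = s
        return s

    def fail(stage: str, message: str):
        manifest["failed_stage"] = stage
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise PipelineError(stage, message)

    # -- inputs -----------------------------------------------------------
    t0 = time.time()
    if "simulate" in config:
        sim = dict(config["simulate"] or {})
        stack, truth = synthetic.make_landscape(
            seed=seeded("simulate"),
            rows=int(sim.get("rows", 50)), cols=int(sim.get("cols", 50)),
            n_predictors=int(sim.get("n_predictors", 4)),
            autocorrelation_range=int(sim.get("autocorrelation_range", 5)),
            organic_band=bool(sim.get("organic_band", True)),
        )
        raw_occ = synthetic.sample_occurrences(
            truth, stack, n_presence=int(sim.get("n_presence", 400)),
            seed=seeded("sample_occurrences"))
        stores = synthetic.sample_stores(
            n_points=int(sim.get("n_stores", 100)),
            n_clusters=int(sim.get("n_store_clusters", 5)),
            cluster_sd=float(sim.get("store_cluster_sd", 0.05)),
            grid=stack.header, seed=seeded("sample_stores"))
        zones = synthetic.make_protected_areas(
            stack.header, n_polygons=int(sim.get("n_polygons", 4)),
            seed=seeded("make_protected_areas"))
        organic_name = "organic_pct" if bool(sim.get("organic_band", True)) else None
        truth_doc = {"predictors": truth.predictor_names,
                     "coefficients": truth.true_coefficients.tolist()}
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth_doc, fh, indent=1)
    elif "inputs" in config:
        inp = config["inputs"]
        for key in ("occurrences", "rasters", "stores", "polygons"):
            if key not in inp:
                fail("inputs", f"missing input block entry '{key}'")
        missing = [p for p in ([inp["occurrences"], inp["stores"], inp["polygons"]]
                               + list(inp["rasters"]))
                   if not Path(p).exists()]
        if missing:
            fail("inputs", f"missing input path(s): {missing}")
        stack = rasters.RasterStack()
        for p in inp["rasters"]:
            stack.add(rasters.read_ascii_grid(p))
        raw_occ = occ_mod.read_occurrences(inp["occurrences"])
        stores = synthetic.read_points(inp["stores"])
        zones = risk_mod.read_protected_areas(inp["polygons"])
        organic_name = inp.get("organic_percent")
    else:
        fail("inputs", "config needs either a 'simulate' or an 'inputs' block")
    record("inputs", t0, n_occurrences=len(raw_occ), n_stores=len(stores),
           n_layers=len(stack.names), n_polygons=len(zones))

    # -- occurrence cleaning and thinning ---------------------------------
    t0 = time.time()
    cleaned = occ_mod.clean_records(raw_occ, min_year=int(params["min_year"]),
                                    max_uncertainty_m=float(params["max_uncertainty_m"]))
    record("clean", t0, n_in=len(raw_occ), n_out=len(cleaned))
    t0 = time.time()
    thinned = occ_mod.thin_to_grid(cleaned, stack.header, seed=seeded("thin"))
    occ_mod.write_occurrences(thinned, outdir / "occurrences_thinned.csv")
    record("thin", t0, n_in=len(cleaned), n_out=len(thinned))
    if len(thinned) < max(2, int(params["k_folds"])):
        fail("thin", f"only {len(thinned)} occurrences survive cleaning/thinning")

    # -- predictor preprocessing ------------------------------------------
    t0 = time.time()
    if organic_name is not None:
        organic = rasters.organic_layer(stack[organic_name],
                                        threshold=float(params["organic_threshold"]))
        density = rasters.focal_density(organic,
                                        radius_m=float(params["density_radius_m"]))
        density.name = "organic_density"
        layers = {n: r for n, r in stack.layers.items() if n != organic_name}
        layers[density.name] = density
        stack = rasters.RasterStack(layers)
        rasters.write_ascii_grid(density, outdir / "organic_density.asc")
    record("prep", t0, n_layers=len(stack.names))

    t0 = time.time()
    retained, corr = rasters.correlation_prune(
        stack, threshold=float(params["correlation_threshold"]),
        sample_n=int(params["correlation_sample_n"]), seed=seeded("prune"))
    corr.to_csv(outdir / "correlation_matrix.csv")
    stack = stack.subset(retained)
    record("prune", t0, n_retained=len(retained), retained=",".join(retained))

    # -- model fitting and evaluation -------------------------------------
    t0 = time.time()
    background = maxent.sample_background(stack, n=int(params["background_n"]),
                                          seed=seeded("background"),
                                          presences=thinned)
    presence_table = (background[background["is_presence"] == 1]
                      .drop(columns="is_presence").reset_index(drop=True))
    if len(presence_table) < int(params["k_folds"]):
        fail("background", f"only {len(presence_table)} presences with full "
                           "predictor data")
    record("background", t0, n_background=len(background),
           n_presence=len(presence_table))

    t0 = time.time()
    classes = params["feature_classes"] or maxent.default_classes(len(presence_table))
    features_kw = {"classes": tuple(classes),
                   "n_hinge_knots": int(params["n_hinge_knots"])}
    report, models = maxent.kfold_evaluate(
        presence_table, background, features_kw=features_kw,
        k=int(params["k_folds"]), seed=seeded("kfold"),
        lam_multiplier=float(params["lam_multiplier"]))
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump({"fold_aucs": report.fold_aucs, "mean_auc": report.mean_auc,
                   "sd_auc": report.sd_auc, "fold_sizes": report.fold_sizes},
                  fh, indent=1)
    record("evaluate", t0, k=len(report.fold_aucs),
           mean_auc=round(report.mean_auc, 4), sd_auc=round(report.sd_auc, 4))

    t0 = time.time()
    mean_r, sd_r = maxent.ensemble_predict(models, stack)
    rasters.write_ascii_grid(mean_r, outdir / "suitability_mean.asc")
    rasters.write_ascii_grid(sd_r, outdir / "suitability_sd.asc")
    record("predict", t0)

    t0 = time.time()
    joint = pd.concat([presence_table, background], ignore_index=True)
    fs, joint_mat = maxent.build_features(joint, **features_kw)
    f_pres = joint_mat[: len(presence_table)]
    f_bg = joint_mat[len(presence_table):]
    lam = maxent.default_lambdas(fs, f_pres,
                                 multiplier=float(params["lam_multiplier"]))
    full_model = maxent.fit(f_pres, f_bg, fs, lam=lam)
    full_model.to_json(outdir / "model.json")
    imp = maxent.permutation_importance(full_model, presence_table, background,
                                        seed=seeded("importance"),
                                        n_repeats=int(params["importance_repeats"]))
    imp.to_frame().to_csv(outdir / "importance.csv", index=False)
    record("importance", t0, baseline_auc=round(imp.baseline_auc, 4))

    # -- introduction pressure and risk ------------------------------------
    t0 = time.time()
    density_r = kde_mod.kernel_density(stores, stack.header,
                                       bandwidth_m=params["bandwidth_m"])
    pressure = kde_mod.minmax_normalize(density_r)
    pressure.name = "introduction_pressure"
    rasters.write_ascii_grid(pressure, outdir / "introduction_pressure.asc")
    record("kde", t0, n_stores=len(stores))

    t0 = time.time()
    risk_surface = risk_mod.combine(mean_r, pressure)
    rasters.write_ascii_grid(risk_surface, outdir / "invasion_risk.asc")
    summary = risk_mod.zonal_summary(risk_surface, zones,
                                     hotspot_threshold=float(params["hotspot_threshold"]))
    summary.to_csv(outdir / "risk_report.csv", index=False)
    risk_mod.write_protected_areas(zones, outdir / "protected_areas.geojson")
    record("risk", t0, n_polygons=len(zones))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    logger.info("run complete: %s", outdir)
    return outdir
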