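"""Stage orchestration: each stage reads declared inputs, writes declared
outputs under the working directory, and appends a manifest entry (config
hash, stage seed, output checksums). Stages fail fast with the name of the
stage to run first when an upstream artifact is missing."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import landscape as lsc
from . import saltbridge as sbs
from .attribution import (global_shap_summary, log_odds_fn, model_importance,
                          sample_background, shapley_matrix)
from .config import PipelineConfig, config_hash, stage_seed
from .embedding import pca_project, spib_embed
from .features import (DESCRIPTOR_COLUMNS, FeatureMatrix, build_feature_matrix,
                       standardize)
from .structures import read_pdb_ensemble
from .synthetic import (energy_table, generate_study, toy_motif,
                        write_pdb_ensemble)

logger = logging.getLogger(__name__)

STAGES = ["generate", "extract", "embed", "landscape", "classify", "explain",
          "stats", "report"]

_REQUIRES = {
    "generate": [],
    "extract": ["ensembles/manifest.json"],
    "embed": ["features.csv"],
    "landscape": ["latent.csv"],
    "classify": ["features.csv"],
    "explain": ["features.csv", "cv_results.json"],
    "stats": ["features.csv"],
    "report": ["cv_results.json", "variant_scores.csv", "shap_global.csv"],
}


class MissingStageOutput(FileNotFoundError):
    pass


def _check_inputs(stage: str, workdir: Path) -> None:
    hints = {"ensembles/manifest.json": "generate", "features.csv": "extract",
             "latent.csv": "embed", "cv_results.json": "classify",
             "variant_scores.csv": "classify", "shap_global.csv": "explain"}
    for rel in _REQUIRES[stage]:
        if not (workdir / rel).exists():
            raise MissingStageOutput(
                f"stage '{stage}' needs {rel}; run '{hints[rel]}' first")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _record_manifest(cfg: PipelineConfig, stage: str, outputs: list[Path],
                     t0: float, extra: dict | None = None) -> None:
    path = cfg.workdir / "run_manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {"stages": {}}
    manifest["config_hash"] = config_hash(cfg)
    manifest["stages"][stage] = {
        "seed": stage_seed(cfg.rng_seed, stage) if stage != "report" else None,
        "outputs": {str(p.relative_to(cfg.workdir)): _checksum(p) for p in outputs},
        "wall_seconds": round(time.time() - t0, 3),
        **(extra or {}),
    }
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _motif(cfg: PipelineConfig):
    return cfg.motif if cfg.motif is not None else toy_motif(cfg.generator.topology)


def _load_features(cfg: PipelineConfig) -> FeatureMatrix:
    return FeatureMatrix(pd.read_csv(cfg.workdir / "features.csv"))


def run_stage(stage: str, cfg: PipelineConfig) -> list[Path]:
    """Run one named stage; returns the paths it wrote."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    cfg.workdir.mkdir(parents=True, exist_ok=True)
    _check_inputs(stage, cfg.workdir)
    t0 = time.time()
    outputs = globals()[f"_stage_{stage}"](cfg)
    _record_manifest(cfg, stage, outputs, t0)
    logger.info("stage %s: %d outputs in %.1fs", stage, len(outputs), time.time() - t0)
    return outputs


def run_all(cfg: PipelineConfig) -> None:
    for stage in STAGES:
        run_stage(stage, cfg)


# --------------------------------------------------------------------------


def _stage_generate(cfg: PipelineConfig) -> list[Path]:
    conformers, targets = generate_study(cfg.generator)
    ens_dir = cfg.workdir / "ensembles"
    write_pdb_ensemble(conformers, energy_table(targets), ens_dir)
    targets.to_csv(cfg.workdir / "planted_targets.csv", index=False)
    labels = pd.DataFrame(
        [{"variant": vid, "class": cls, "label": int(cls == "pathogenic")}
         for vid, cls in cfg.generator.variants])
    labels.to_csv(cfg.workdir / "labels.csv", index=False)
    return [ens_dir / "manifest.json", ens_dir / "energies.csv",
            cfg.workdir / "planted_targets.csv", cfg.workdir / "labels.csv"]


def _stage_extract(cfg: PipelineConfig) -> list[Path]:
    ens_dir = cfg.workdir / "ensembles"
    conformers = read_pdb_ensemble(ens_dir)
    energies = pd.read_csv(ens_dir / "energies.csv")
    labels = pd.read_csv(cfg.workdir / "labels.csv")
    fm = build_feature_matrix(conformers, _motif(cfg), energies,
                              dict(zip(labels["variant"], labels["label"])))
    out = cfg.workdir / "features.csv"
    fm.data.to_csv(out, index=False, float_format="%.8f")
    return [out]


def _stage_embed(cfg: PipelineConfig) -> list[Path]:
    fm = _load_features(cfg)
    fm_std, scaler = standardize(fm)
    pca = pca_project(fm_std.X, k=cfg.pca_components)
    emb = spib_embed(fm_std, cfg.spib)
    latent = fm.data[["variant", "label", "depth", "seed", "frame"]].copy()
    latent["sigma1"] = emb.coords[:, 0]
    latent["sigma2"] = emb.coords[:, 1]
    latent["state"] = emb.state_labels
    for k in range(cfg.pca_components):
        latent[f"pc{k + 1}"] = pca.scores[:, k]
    latent.to_csv(cfg.workdir / "latent.csv", index=False, float_format="%.8f")
    emb.training_log.to_csv(cfg.workdir / "training_log.csv", index=False,
                            float_format="%.8f")
    summary = {
        "pca_explained_variance_ratio": pca.explained_variance_ratio.tolist(),
        "spib_n_states": emb.n_states,
        "scaler_mean": scaler.mean.tolist(),
        "scaler_sd": scaler.sd.tolist(),
    }
    (cfg.workdir / "embedding_summary.json").write_text(
        json.dumps(summary, indent=1))
    return [cfg.workdir / "latent.csv", cfg.workdir / "training_log.csv",
            cfg.workdir / "embedding_summary.json"]


def _stage_landscape(cfg: PipelineConfig) -> list[Path]:
    latent = pd.read_csv(cfg.workdir / "latent.csv")
    coords = latent[["sigma1", "sigma2"]].to_numpy()
    grid = lsc.kde_density(coords, bandwidth=cfg.landscape_bandwidth,
                           grid_cells=cfg.landscape_grid_cells,
                           temperature=cfg.landscape_temperature)
    lsc.boltzmann_invert(grid)
    grid.to_frame().to_csv(cfg.workdir / "landscape.csv", index=False,
                           float_format="%.8g")
    basins = lsc.find_basins(coords, cfg.hdbscan_min_cluster_size,
                             cfg.hdbscan_min_samples)
    dens = lsc.point_density(coords, bandwidth=grid.bandwidth)
    lsc.pick_representatives(basins, coords, density=dens)
    bdf = latent[["variant", "depth", "seed", "frame"]].copy()
    bdf["cluster"] = basins.labels
    rep_idx = set(basins.representatives.values())
    bdf["representative"] = [i in rep_idx for i in range(len(bdf))]
    bdf.to_csv(cfg.workdir / "basins.csv", index=False)
    return [cfg.workdir / "landscape.csv", cfg.workdir / "basins.csv"]


def _stage_classify(cfg: PipelineConfig) -> list[Path]:
    fm = _load_features(cfg)
    folds = clf.lomo_split(fm)
    seed = stage_seed(cfg.rng_seed, "classify")
    results = {}
    oof_frame = fm.data[["variant", "label", "depth", "seed", "frame"]].copy()
    for name in cfg.models:
        res = clf.fit_and_predict(folds, fm, name, rng_seed=seed,
                                  n_bootstrap=cfg.n_bootstrap)
        results[name] = {"auroc": res.auroc, "ci_lo": res.ci[0],
                         "ci_hi": res.ci[1], "n_bootstrap": res.n_bootstrap}
        oof_frame[f"prob_{name}"] = res.oof_probs
    best = max(results, key=lambda m: results[m]["auroc"])
    probs = oof_frame[f"prob_{best}"].to_numpy()
    scores = clf.aggregate_all_variants(fm, probs, rng_seed=seed,
                                        n_bootstrap=cfg.n_bootstrap)
    report = clf.calibration_report(probs, fm.y, n_bins=cfg.calibration_bins,
                                    threshold=cfg.decision_threshold)
    (cfg.workdir / "cv_results.json").write_text(json.dumps(
        {"models": results, "best_model": best, "rng_seed": seed}, indent=1))
    oof_frame.to_csv(cfg.workdir / "oof_probs.csv", index=False,
                     float_format="%.8f")
    scores.to_csv(cfg.workdir / "variant_scores.csv", index=False,
                  float_format="%.6f")
    (cfg.workdir / "calibration.json").write_text(json.dumps({
        "brier": report.brier, "ece": report.ece,
        "balanced_accuracy": report.balanced_accuracy, "mcc": report.mcc,
        "auroc": report.auroc, "aupr": report.aupr,
        "threshold": report.threshold, "model": best}, indent=1))
    report.reliability_frame().to_csv(cfg.workdir / "reliability_curve.csv",
                                      index=False, float_format="%.6f")
    return [cfg.workdir / p for p in ("cv_results.json", "oof_probs.csv",
                                      "variant_scores.csv", "calibration.json",
                                      "reliability_curve.csv")]


def _stage_explain(cfg: PipelineConfig) -> list[Path]:
    fm = _load_features(cfg)
    seed = stage_seed(cfg.rng_seed, "explain")
    best = json.loads((cfg.workdir / "cv_results.json").read_text())["best_model"]
    model = clf.make_model(best, rng_seed=seed)
    model.fit(fm.X, fm.y)
    background = sample_background(fm.X, size=cfg.background_size, rng_seed=seed)
    # explain a seeded subsample of frames (exact enumeration per frame)
    rng = np.random.default_rng(seed)
    n_explain = min(fm.n, 512)
    idx = np.sort(rng.choice(fm.n, size=n_explain, replace=False))
    phis, _ = shapley_matrix(log_odds_fn(model), fm.X[idx], background)
    frames = fm.data.iloc[idx][["variant", "depth", "seed", "frame"]].reset_index(drop=True)
    shap_frames = pd.concat(
        [frames, pd.DataFrame(phis, columns=DESCRIPTOR_COLUMNS)], axis=1)
    shap_frames.to_csv(cfg.workdir / "shap_frames.csv", index=False,
                       float_format="%.8f")
    summary = global_shap_summary(phis, DESCRIPTOR_COLUMNS, rng_seed=seed,
                                  n_bootstrap=cfg.n_bootstrap)
    summary.to_csv(cfg.workdir / "shap_global.csv", index=False,
                   float_format="%.8f")
    imp_rows = []
    for name in ("lr", "rf"):
        m = clf.make_model(name, rng_seed=seed)
        m.fit(fm.X, fm.y)
        for feat, val in zip(DESCRIPTOR_COLUMNS, model_importance(m)):
            imp_rows.append({"model": name, "feature": feat, "importance": val})
    pd.DataFrame(imp_rows).to_csv(cfg.workdir / "importance.csv", index=False,
                                  float_format="%.8f")
    return [cfg.workdir / p for p in ("shap_frames.csv", "shap_global.csv",
                                      "importance.csv")]


def _stage_stats(cfg: PipelineConfig) -> list[Path]:
    fm = _load_features(cfg)
    wt = next((vid for vid, c in cfg.generator.variants if c == "WT"),
              sorted(fm.data["variant"].unique())[0])
    summary = sbs.distance_summary(fm.data, lo=cfg.stats_lo, hi=cfg.stats_hi)
    tests = sbs.variant_vs_wt_tests(fm.data, wt, lo=cfg.stats_lo, hi=cfg.stats_hi)
    summary.to_csv(cfg.workdir / "saltbridge_summary.csv", index=False,
                   float_format="%.6f")
    (cfg.workdir / "tests.json").write_text(
        tests.to_json(orient="records", indent=1))
    return [cfg.workdir / "saltbridge_summary.csv", cfg.workdir / "tests.json"]


def _stage_report(cfg: PipelineConfig) -> list[Path]:
    cv = json.loads((cfg.workdir / "cv_results.json").read_text())
    model_table = pd.DataFrame(
        [{"model": m, **vals} for m, vals in cv["models"].items()])
    scores = pd.read_csv(cfg.workdir / "variant_scores.csv")
    if cfg.baseline_scores is not None and Path(cfg.baseline_scores).exists():
        baselines = pd.read_csv(cfg.baseline_scores)
        scores = scores.merge(baselines, on="variant", how="left")
    shap_global = pd.read_csv(cfg.workdir / "shap_global.csv")
    model_table.to_csv(cfg.workdir / "report_models.csv", index=False,
                       float_format="%.6f")
    scores.to_csv(cfg.workdir / "report_variants.csv", index=False,
                  float_format="%.6f")
    shap_global.to_csv(cfg.workdir / "report_attribution.csv", index=False,
                       float_format="%.6f")
    return [cfg.workdir / p for p in ("report_models.csv", "report_variants.csv",
                                      "report_attribution.csv")]
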