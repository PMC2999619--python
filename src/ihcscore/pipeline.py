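"""End-to-end orchestration: simulate -> classify -> quantify -> score ->
threshold -> stats, with a machine-readable run manifest.

Every stage writes plain CSV/JSON artifacts into the output directory; the
manifest records the seed, per-stage record counts and package versions so a
run can be audited and reproduced.  Any stage failure aborts the run with
the stage name in the raised error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import classify_tissue, train_classifier
from .io import dump_json, write_image, write_mask
from .scoring import ThresholdConfig, aggregate_cohort, dichotomize, quant_to_record
from .stain import OD_MAX, PositivityThresholds, quantify_compartments
from .stats import (
    build_table1,
    cox_fit,
    km_estimate,
    logrank_test,
    spearman_rho,
)
from .synthetic.cohort import COVARIATE_LEVELS, CohortSimConfig, generate_cohort
from .synthetic.images import StainParams, generate_core_image
from .tree import select_model_cv

log = logging.getLogger("ihcscore.pipeline")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (defaults give a small smoke run)."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    n_patients: int = 10
    image_size: int = 128
    tissue_poor_rate: float = 0.0  # chance a core is rendered nearly tumour-free
    n_training_cores: int = 3
    classifier_window: int = 5
    min_tumour_px: int = 500
    positivity: PositivityThresholds = field(default_factory=PositivityThresholds)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    tree_k: int = 10
    tree_max_depth: int = 3
    tree_min_node_size: int = 20
    write_images: bool = True

    @staticmethod
    def from_dict(raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "positivity" in raw:
            raw["positivity"] = PositivityThresholds(**raw["positivity"])
        if "thresholds" in raw:
            raw["thresholds"] = ThresholdConfig(**raw["thresholds"])
        if "cohort" in raw:
            raw["cohort"] = CohortSimConfig(**raw["cohort"])
        return PipelineConfig(**raw)


def _core_stain_params(row, rng, tissue_poor_rate: float) -> StainParams:
    """Staining parameters of one rendered core, driven by its measured scores."""
    poor = rng.random() < tissue_poor_rate
    return StainParams(
        fraction_positive_nuclei=float(row.nuclear_pct),
        fraction_positive_cytoplasm=float(row.cyt_pct),
        nuclear_dab_od=float(row.nuclear_intensity) * OD_MAX,
        cytoplasmic_dab_od=float(row.cyt_intensity) * OD_MAX,
        tumour_area_fraction=0.02 if poor else 0.45,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "version": __version__, "stages": {}}
    rng = np.random.default_rng(config.seed)

    # --- stage: simulate cohort ------------------------------------------
    stage = "simulate-cohort"
    log.info("stage=%s", stage)
    cohort_cfg = config.cohort
    cohort_cfg.n_patients = config.n_patients
    cohort_cfg.seed = int(rng.integers(2**31))
    patients, cores = generate_cohort(cohort_cfg)
    patients.to_csv(out / "patients_true.csv", index=False)
    cores.to_csv(out / "cores_true.csv", index=False)
    manifest["stages"][stage] = {"patients": len(patients), "cores": len(cores)}

    # --- stage: simulate + classify + quantify images ---------------------
    stage = "images"
    log.info("stage=%s", stage)
    train_imgs, train_truth = [], []
    for i in range(config.n_training_cores):
        img, gt = generate_core_image(StainParams(), config.image_size,
                                      config.image_size, seed=int(rng.integers(2**31)))
        train_imgs.append(img)
        train_truth.append(gt)
    model = train_classifier(train_imgs, train_truth, window=config.classifier_window,
                             seed=config.seed)

    records = []
    image_dir = out / "cores"
    if config.write_images:
        image_dir.mkdir(exist_ok=True)
    for row in cores.itertuples():
        params = _core_stain_params(row, rng, config.tissue_poor_rate)
        img, gt = generate_core_image(params, config.image_size, config.image_size,
                                      seed=int(rng.integers(2**31)))
        tissue = classify_tissue(img, model)
        quant = quantify_compartments(img, tissue.labels, thresholds=config.positivity,
                                      min_tumour_px=config.min_tumour_px)
        records.append(quant_to_record(row.patient_id, int(row.replicate), quant))
        if config.write_images:
            stem = f"{row.patient_id}_r{row.replicate}"
            write_image(image_dir / f"{stem}.png", img)
            write_mask(image_dir / f"{stem}_labels.png", tissue.labels)
    measured = pd.DataFrame(records)
    measured.to_csv(out / "cores_measured.csv", index=False)
    manifest["stages"][stage] = {"cores": len(measured),
                                 "training_cores": config.n_training_cores}

    # --- stage: score ------------------------------------------------------
    stage = "score"
    log.info("stage=%s", stage)
    agg = aggregate_cohort(measured)
    agg["snas_group"] = [dichotomize(s, config.thresholds.snas_threshold)
                         if ok else None
                         for s, ok in zip(agg["snas"], agg["evaluable"])]
    agg["cnr_group"] = [dichotomize(c, config.thresholds.cnr_threshold)
                        if ok else None
                        for c, ok in zip(agg["cnr"], agg["evaluable"])]
    cohort = patients.drop(columns=["snas", "cytoplasmic_autoscore", "cnr"]).merge(
        agg, on="patient_id", validate="1:1")
    cohort.to_csv(out / "patients_scored.csv", index=False)
    n_eval = int(cohort["evaluable"].sum())
    manifest["stages"][stage] = {
        "patients": len(cohort),
        "evaluable": n_eval,
        "non_evaluable": len(cohort) - n_eval,
        "evaluable_pct": round(100.0 * n_eval / len(cohort), 1),
    }

    evaluable = cohort[cohort["evaluable"]].reset_index(drop=True)

    # --- stage: threshold (CV survival tree) ------------------------------
    stage = "threshold"
    log.info("stage=%s", stage)
    if len(evaluable) >= 50 and evaluable["bcss_event"].any():
        cv = select_model_cv(evaluable, k=config.tree_k, seed=config.seed,
                             max_depth=config.tree_max_depth,
                             min_node_size=config.tree_min_node_size)
        dump_json(out / "tree.json", cv.selected_model.to_dict())
        cv.fold_table().to_csv(out / "cv_folds.csv", index=False)
        manifest["stages"][stage] = {
            "selected_predictor": cv.selected_predictor,
            "selected_threshold": cv.selected_threshold,
            "n": len(evaluable),
        }
    else:
        log.warning("stage=%s skipped: n=%d too small for cross-validation",
                    stage, len(evaluable))
        manifest["stages"][stage] = {"skipped": True, "n": len(evaluable)}

    # --- stage: stats ------------------------------------------------------
    stage = "stats"
    log.info("stage=%s", stage)
    stats_report: dict = {"n": len(evaluable)}
    strat_ok = (evaluable["cnr_group"].nunique() == 2)
    if strat_ok:
        t1 = build_table1(evaluable, "cnr_group", dict(COVARIATE_LEVELS))
        t1.to_csv(out / "table1_cnr.csv", index=False)
        stats_report["table1"] = "table1_cnr.csv"
    n_events = int(evaluable["bcss_event"].sum())
    if strat_ok and n_events >= 10:
        evaluable = evaluable.assign(cnr_high=evaluable["cnr_group"] == "high")
        uni = cox_fit(evaluable, ["cnr_high"], outcome="bcss")["cnr_high"]
        est = uni.estimates.iloc[0]
        stats_report["cox_univariate_cnr_bcss"] = {
            "hazard_ratio": est.hazard_ratio, "ci_low": est.ci_low,
            "ci_high": est.ci_high, "p": est.p,
        }
        chi2, p = logrank_test(evaluable["bcss_time"], evaluable["bcss_event"],
                               evaluable["cnr_group"])
        stats_report["logrank_cnr_bcss"] = {"chi_square": chi2, "p": p}
        curves = km_estimate(evaluable["bcss_time"], evaluable["bcss_event"],
                             evaluable["cnr_group"])
        pd.concat([c.to_frame() for c in curves.values()]).to_csv(
            out / "km_cnr_bcss.csv", index=False)
    rep1 = measured[measured["replicate"] == 1].set_index("patient_id")
    rep2 = measured[measured["replicate"] == 2].set_index("patient_id")
    common = rep1.index.intersection(rep2.index)
    if len(common) >= 5:
        rho = spearman_rho(rep1.loc[common, "nuclear_autoscore"],
                           rep2.loc[common, "nuclear_autoscore"])
        stats_report["duplicate_rho_nuclear_autoscore"] = {"rho": rho.rho, "p": rho.p}
    dump_json(out / "stats.json", stats_report)
    manifest["stages"][stage] = {"n": len(evaluable), "events": n_events}

    dump_json(out / "manifest.json", manifest)
    return manifest
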