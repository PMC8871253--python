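"""End-to-end orchestration: simulate -> extract -> train -> ensemble ->
Boruta -> group statistics, with file artifacts and a machine-readable
run summary.

Every stage reads only files written by earlier stages (or in-memory
equivalents when ``run_all`` is called with ``write_images=False``),
and every artifact is stamped with the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boruta import run_boruta
from .eml import build_eml_report, roc_points
from .features import RadiomicsExtractor, default_manifest
from .models import AutoScaler, FeatureScreener, ZOO_MODELS, split, train_zoo
from .stats import smile_table
from .synthdata import CohortSpec, generate_cohort, write_cohort

log = logging.getLogger("lvradiomics")

__all__ = ["RunConfig", "run_all", "ensemble_replicate", "SUMMARY_SCHEMA_VERSION"]

SUMMARY_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    seed: int = 0
    n_htn: int = 83
    n_nc: int = 75
    image_size: int = 160
    effect: bool = True  # False -> null cohort (no injected class effect)
    split_ratio: float = 0.7
    corr_min: float = 1e-5
    corr_max: float = 0.95
    identical_frac: float = 0.90
    models: tuple[str, ...] = ZOO_MODELS
    cv_folds: int = 10
    tuning_budget: int = 0
    accuracy_gate: float = 0.60
    gate_metric: str = "cv_accuracy"
    boruta_n_iter: int = 200
    boruta_rule: str = "binomial"
    boruta_alpha: float = 0.01
    boruta_trees: int = 100
    fdr_level: float = 0.05
    fc_cutoff: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def cohort_spec(self) -> CohortSpec:
        maker = CohortSpec.calibrated if self.effect else CohortSpec.null
        return maker(n_htn=self.n_htn, n_nc=self.n_nc, seed=self.seed,
                     image_size=self.image_size)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def ensemble_replicate(config: RunConfig) -> dict:
    """One in-memory replicate of the classification arm.

    Runs cohort generation, feature extraction, split, screening,
    autoscaling, the model zoo and the ensemble evaluation (no Boruta,
    no group statistics, no file artifacts) and returns the headline
    ensemble metrics.  Used for replicate studies where only the
    ensemble's operating characteristics are of interest.
    """
    cohort = generate_cohort(config.cohort_spec())
    clinical = pd.DataFrame([dataclasses.asdict(rec) for _, _, rec in cohort])
    extractor = RadiomicsExtractor(default_manifest()).fit()
    features = extractor.transform(
        [(img, roi) for img, roi, _ in cohort],
        subject_ids=[rec.subject_id for _, _, rec in cohort],
    )
    table = features.copy()
    table["label"] = (clinical.set_index("subject_id").loc[features.index, "group"]
                      == "HTN").astype(int).to_numpy()
    train, test = split(table, ratio=config.split_ratio, seed=config.seed)
    feat_cols = list(features.columns)
    screener = FeatureScreener(config.corr_min, config.corr_max,
                               config.identical_frac).fit(train[feat_cols],
                                                          train["label"])
    scaler = AutoScaler().fit(screener.transform(train))
    results = train_zoo(scaler.transform(screener.transform(train)),
                        train["label"].to_numpy(),
                        scaler.transform(screener.transform(test)),
                        test["label"].to_numpy(), models=config.models,
                        cv_folds=config.cv_folds,
                        tuning_budget=config.tuning_budget, seed=config.seed)
    septum_test = (clinical.set_index("subject_id")
                   .loc[test.index, "septum_width"].to_numpy())
    report = build_eml_report(results, test["label"].to_numpy(),
                              septum_test=septum_test,
                              threshold=config.accuracy_gate,
                              metric=config.gate_metric)
    return {
        "auc": report.auc, "auc_se": report.auc_se,
        "r": report.correlation["r"], "r2": report.correlation["r2"],
        "accuracy": report.metrics["accuracy"], "cutoff": report.cutoff,
        "n_selected": len(report.selected_models),
        "train_table": (scaler.transform(screener.transform(train)),
                        train["label"].to_numpy()),
    }


def run_all(config: RunConfig, outdir: str | Path, write_images: bool = True) -> dict:
    """Execute the full analysis; returns (and writes) the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.digest(), "seed": config.seed,
             "package_version": __version__, "schema_version": SUMMARY_SCHEMA_VERSION}

    def _stage(name):
        log.info("stage: %s", name)

    try:
        _stage("simulate")
        cohort = generate_cohort(config.cohort_spec())
        if write_images:
            write_cohort(cohort, outdir / "cohort")
        clinical = pd.DataFrame([dataclasses.asdict(rec) for _, _, rec in cohort])

        _stage("extract")
        manifest = default_manifest()
        extractor = RadiomicsExtractor(manifest).fit()
        features = extractor.transform(
            [(img, roi) for img, roi, _ in cohort],
            subject_ids=[rec.subject_id for _, _, rec in cohort],
        )
        features.to_csv(outdir / "features.csv")
        with open(outdir / "manifest.json", "w") as fh:
            fh.write(manifest.to_json())

        _stage("train")
        table = features.copy()
        table["label"] = (clinical.set_index("subject_id").loc[features.index, "group"]
                          == "HTN").astype(int).to_numpy()
        train, test = split(table, ratio=config.split_ratio, seed=config.seed)
        screener = FeatureScreener(config.corr_min, config.corr_max,
                                   config.identical_frac)
        screener.fit(train[manifest.names], train["label"])
        screener.report_.to_frame().to_csv(outdir / "screening.csv", index=False)
        scaler = AutoScaler().fit(screener.transform(train))
        Xtr = scaler.transform(screener.transform(train))
        Xte = scaler.transform(screener.transform(test))
        results = train_zoo(Xtr, train["label"].to_numpy(), Xte,
                            test["label"].to_numpy(), models=config.models,
                            cv_folds=config.cv_folds,
                            tuning_budget=config.tuning_budget, seed=config.seed)
        (outdir / "models").mkdir(exist_ok=True)
        for r in results:
            with open(outdir / "models" / f"{r.model_name}.json", "w") as fh:
                json.dump({**stamp, **r.to_dict()}, fh, sort_keys=True, default=_jsonable)

        _stage("eml")
        septum_test = (clinical.set_index("subject_id")
                       .loc[test.index, "septum_width"].to_numpy())
        report = build_eml_report(results, test["label"].to_numpy(),
                                  septum_test=septum_test,
                                  threshold=config.accuracy_gate,
                                  metric=config.gate_metric)
        with open(outdir / "eml_report.json", "w") as fh:
            json.dump({**stamp, **report.to_dict()}, fh, sort_keys=True, default=_jsonable)
        pd.DataFrame({"subject_id": test.index, "label": report.labels,
                      "score": report.scores}).to_csv(outdir / "eml_scores.csv",
                                                      index=False)
        pts = roc_points(report.scores, report.labels)
        pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(outdir / "roc.csv", index=False)

        _stage("boruta")
        boruta_report = run_boruta(Xtr, train["label"].to_numpy(),
                                   n_iter=config.boruta_n_iter, seed=config.seed,
                                   rule=config.boruta_rule, alpha=config.boruta_alpha,
                                   n_estimators=config.boruta_trees)
        with open(outdir / "boruta_report.json", "w") as fh:
            json.dump({**stamp, **boruta_report.to_dict()}, fh, sort_keys=True)
        pd.Series(boruta_report.confirmed, name="feature").to_csv(
            outdir / "boruta_confirmed.csv", index=False)

        _stage("stats")
        comparison = smile_table(features, table["label"].to_numpy(),
                                 fdr_level=config.fdr_level,
                                 fc_cutoff=config.fc_cutoff)
        comparison.to_csv(outdir / "group_comparison.csv")
        comparison[["log2_fc", "neg_log10_p_fdr", "flagged"]].to_csv(
            outdir / "smile_coordinates.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    summary = {
        **stamp,
        "n_subjects": len(cohort),
        "n_features": len(manifest),
        "n_retained": len(screener.retained_),
        "model_cv_accuracy": {r.model_name: r.cv_accuracy for r in results},
        "model_test_accuracy": {r.model_name: r.test_metrics.get("accuracy")
                                for r in results if r.status == "ok"},
        "ensemble": {
            "selected_models": report.selected_models,
            "auc": report.auc, "auc_se": report.auc_se, "auc_p": report.auc_p,
            "cutoff": report.cutoff, "metrics": report.metrics,
            "group_means": report.group_means,
            "correlation": report.correlation,
        },
        "n_smile_flagged": int(comparison["flagged"].sum()),
        "n_boruta_confirmed": len(boruta_report.confirmed),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1, default=_jsonable)
    return summary
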