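"""End-to-end orchestration: simulate -> preprocess -> per-site
classification -> biomechanics -> mixed-model validation.

A single :class:`RunConfig` (YAML-serializable) drives the whole run;
every stage derives its own random seed deterministically from the
master seed, so two runs with the same configuration produce identical
outputs.  Completed stages are skipped on re-runs when their
configuration hash and outputs are unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomech import analyze_test
from .classify import (ClassifierSpec, assign_prediction_groups,
                       run_site_experiment)
from .evaluate import permutation_importance
from .preprocess import PreprocessConfig, preprocess_pipeline
from .synthdata import (Cohort, CohortConfig, GroundTruthMechanics,
                        ProtocolConfig, SpectralFeatureModel, generate_cohort)
from .validate import build_comparison_tables

logger = logging.getLogger(__name__)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


@dataclass
class RunConfig:
    """Everything one run needs; round-trips through YAML."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    features: SpectralFeatureModel = field(default_factory=SpectralFeatureModel)
    mechanics: GroundTruthMechanics = field(default_factory=GroundTruthMechanics)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    classifier1: ClassifierSpec = field(
        default_factory=lambda: ClassifierSpec(task="classifier1"))
    classifier2: ClassifierSpec = field(
        default_factory=lambda: ClassifierSpec(task="classifier2"))
    k_wavelengths: int = 30
    n_repeats: int = 3
    min_spacing_nm: float | None = None
    n_permutations: int = 20
    run_importance: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return _to_plain(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for name, sub_cls in (
                ("cohort", CohortConfig), ("features", SpectralFeatureModel),
                ("mechanics", GroundTruthMechanics), ("protocol", ProtocolConfig),
                ("preprocess", PreprocessConfig),
                ("classifier1", ClassifierSpec), ("classifier2", ClassifierSpec)):
            if name in d:
                sub = d.pop(name)
                if name == "preprocess" and "trim_windows" in sub:
                    sub["trim_windows"] = tuple(tuple(w) for w in sub["trim_windows"])
                kwargs[name] = sub_cls(**_tupled(sub))
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _stage_seeds(master: int, names) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31)
            for n, c in zip(names, children)}


def _stage_done(outdir: Path, stage: str, token: str, outputs: list[str]) -> bool:
    marker = outdir / f".{stage}.hash"
    return (marker.exists() and marker.read_text() == token
            and all((outdir / o).exists() for o in outputs))


def _mark_stage(outdir: Path, stage: str, token: str) -> None:
    (outdir / f".{stage}.hash").write_text(token)


def simulate_stage(config: RunConfig, seed: int) -> Cohort:
    cohort_cfg = dataclasses.replace(config.cohort, seed=seed)
    return generate_cohort(cohort_cfg, config.features, config.mechanics,
                           config.protocol)


def classification_stage(cohort: Cohort, config: RunConfig, seeds: dict,
                         outdir: Path) -> tuple[pd.DataFrame, dict]:
    records = preprocess_pipeline(cohort.records, config.preprocess)
    proc = dataclasses.replace(cohort, records=records)

    summary_rows, importance_frames, all_preds = [], [], {"classifier1": [],
                                                          "classifier2": []}
    for site in config.cohort.sites:
        X, wl, meta = proc.spectra_matrix(site)
        for task, spec in (("classifier1", config.classifier1),
                           ("classifier2", config.classifier2)):
            logger.info("site %s / %s", site, task)
            results = run_site_experiment(
                X, wl, meta, spec, k_wavelengths=config.k_wavelengths,
                n_repeats=config.n_repeats, seed=seeds[f"{site}:{task}"],
                min_spacing_nm=config.min_spacing_nm)
            for res in results:
                row = {"site": site, "classifier": task, "repeat": res.repeat_index,
                       "kernel": res.trained.best_params["kernel"],
                       "cv_score": res.trained.best_cv_score,
                       "accuracy": res.report["accuracy_standard"],
                       "balanced_accuracy": res.report["balanced_accuracy"],
                       "sensitivity": res.report["sensitivity"],
                       "specificity": res.report["specificity"],
                       "auc": res.report["auc"],
                       "accuracy_full_spectrum":
                           res.report_full["accuracy_standard"]
                           if res.report_full else None}
                summary_rows.append(row)
                all_preds[task].append(res.test_predictions.assign(site=site))
                if config.run_importance and res.repeat_index == 0:
                    te = res.test_predictions
                    if config.min_spacing_nm:
                        from .select import decimate_indices
                        Xd = X[:, decimate_indices(wl, config.min_spacing_nm)]
                    else:
                        Xd = X
                    # test rows, in meta order, restricted to the selected columns
                    te_mask = meta["sample_id"].isin(set(te["sample_id"])).to_numpy()
                    X_te = Xd[np.ix_(te_mask, res.selection.selected_indices)]
                    imp = permutation_importance(
                        res.trained.pipeline, X_te, te["y_true"].to_numpy(),
                        res.selection.selected_wavelengths,
                        n_permutations=config.n_permutations,
                        seed=seeds[f"{site}:{task}"])
                    importance_frames.append(imp.assign(site=site, classifier=task))

    summary = pd.DataFrame(summary_rows).sort_values(
        ["site", "classifier", "repeat"]).reset_index(drop=True)
    summary.to_csv(outdir / "summary.csv", index=False)
    if importance_frames:
        pd.concat(importance_frames, ignore_index=True).to_csv(
            outdir / "importance.csv", index=False)

    predictions = {}
    for task, frames in all_preds.items():
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(outdir / f"predictions_{task}.csv", index=False)
        predictions[task] = assign_prediction_groups(df)
        predictions[task].to_csv(outdir / f"prediction_groups_{task}.csv",
                                 index=False)
    return summary, predictions


def biomech_stage(cohort: Cohort, outdir: Path) -> pd.DataFrame:
    rows = []
    for sample_id in cohort.manifest["sample_id"]:
        test = cohort.mechanical_test(sample_id)
        rows.append(analyze_test(test).as_dict())
    moduli = pd.DataFrame(rows)
    moduli.to_csv(outdir / "moduli.csv", index=False)
    return moduli


def validate_stage(moduli: pd.DataFrame, cohort: Cohort, predictions: dict,
                   outdir: Path) -> pd.DataFrame:
    groupings = ["oarsi_classifier1", "oarsi_classifier2", "three_group"]
    if predictions:
        groupings += ["prediction_classifier1", "prediction_classifier2"]
    contrasts = build_comparison_tables(
        moduli.rename(columns={}), cohort.manifest, predictions,
        groupings=tuple(groupings))
    contrasts.to_csv(outdir / "contrasts.csv", index=False)
    return contrasts


def run_all(config: RunConfig, outdir) -> Path:
    """Execute every stage into ``outdir``; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    token = f"{config.hash()}:{config.seed}"
    names = ["simulate", "biomech"] + [
        f"{s}:{t}" for s in config.cohort.sites
        for t in ("classifier1", "classifier2")]
    seeds = _stage_seeds(config.seed, names)

    config.to_yaml(outdir / "config.yaml")
    cohort = simulate_stage(config, seeds["simulate"])
    cohort.manifest.to_csv(outdir / "manifest.csv", index=False)

    class_outputs = ["summary.csv", "predictions_classifier1.csv",
                     "predictions_classifier2.csv"]
    if _stage_done(outdir, "classify", token, class_outputs):
        logger.info("classification stage up to date; skipping")
        summary = pd.read_csv(outdir / "summary.csv")
        predictions = {
            t: pd.read_csv(outdir / f"prediction_groups_{t}.csv")
            for t in ("classifier1", "classifier2")}
    else:
        summary, predictions = classification_stage(cohort, config, seeds, outdir)
        _mark_stage(outdir, "classify", token)

    if _stage_done(outdir, "biomech", token, ["moduli.csv"]):
        moduli = pd.read_csv(outdir / "moduli.csv")
    else:
        moduli = biomech_stage(cohort, outdir)
        _mark_stage(outdir, "biomech", token)

    if not _stage_done(outdir, "validate", token, ["contrasts.csv"]):
        validate_stage(moduli, cohort, predictions, outdir)
        _mark_stage(outdir, "validate", token)

    provenance = {"config_hash": config.hash(), "seed": config.seed,
                  "stage_seeds": seeds, "cartispec_version": __version__}
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1,
                                                       sort_keys=True))
    return outdir
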