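"""End-to-end experiment orchestration.

Stages: generate synthetic spectra → airPLS baseline correction → three-way
augmentation → dataset assembly and stratified 80/20 split → random-forest
channel ranking and top-K selection → CNN (+ SVM/RF/KNN baselines) training →
mixture-identification evaluation.  Every stage draws its seed from the
master seed, so a run is reproducible end to end.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .augment import assemble_binary, expand_dataset, split_dataset
from .config import ExperimentConfig, stage_seed
from .evaluate import MetricsReport, build_test_set, evaluate_pipeline, report_table
from .features import FeatureMask, rank_importance, select_top
from .io import SpectrumSet
from .models import TrainedModel, random_search, train, train_baseline
from .preprocess import correct_set, normalize_matrix
from .synth import generate_blank, generate_mixture, generate_pure

__all__ = ["run_experiment", "ReportBundle", "StageError"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ReportBundle:
    config: ExperimentConfig
    mask: FeatureMask
    models: dict[str, TrainedModel]
    validation_accuracy: dict[str, float]
    reports: list[MetricsReport]
    report: pd.DataFrame
    search_log: list[dict] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)
    train_set: tuple | None = None
    val_set: tuple | None = None


def _stage(name: str, timings: dict):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            timings[name] = dt
            if exc is not None:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2f s", name, dt)

    return _Ctx()


def generate_raw(cfg: ExperimentConfig, seed: int) -> dict[str, SpectrumSet]:
    """Pure-analyte sets (n_per_concentration × each concentration) plus blanks."""
    sets: dict[str, SpectrumSet] = {}
    for j, (name, lib) in enumerate(sorted(cfg.libraries.items())):
        parts = [
            generate_pure(lib, c, cfg.grid, cfg.n_per_concentration, cfg.noise,
                          seed + 1000 * j + i)
            for i, c in enumerate(cfg.concentrations)
        ]
        sets[name] = SpectrumSet.concat(parts)
    n_blank = cfg.n_per_concentration * len(cfg.concentrations)
    sets["substrate"] = generate_blank(cfg.grid, n_blank, cfg.noise, seed + 999_001)
    return sets


def _mixture_positives(cfg: ExperimentConfig, condition: str, seed: int) -> SpectrumSet:
    ratios = cfg.mixture_conditions[condition]
    components = [(cfg.libraries[name], frac) for name, frac in ratios.items()]
    return generate_mixture(components, cfg.mixture_concentration, cfg.grid,
                            cfg.test_n_pos, cfg.noise, seed)


def run_experiment(cfg: ExperimentConfig, outdir: str | Path | None = None) -> ReportBundle:
    """Execute the full pipeline; optionally persist the report bundle."""
    timings: dict[str, float] = {}
    ms = cfg.master_seed

    with _stage("generate", timings):
        raw = generate_raw(cfg, stage_seed(ms, "generate"))

    with _stage("preprocess", timings):
        corrected = {name: correct_set(ss, cfg.preprocess) for name, ss in raw.items()}

    with _stage("augment", timings):
        from dataclasses import replace

        augmented = {
            name: expand_dataset(ss, replace(cfg.augment,
                                             seed=stage_seed(ms, f"augment:{name}")))
            for name, ss in corrected.items()
        }

    with _stage("assemble", timings):
        negatives = [augmented[n] for n in ("CBZ", "TBZ", "phosmet", "substrate")
                     if n in augmented]
        dataset = assemble_binary(augmented["thiram"], negatives, cfg.n_pos,
                                  cfg.n_per_neg, stage_seed(ms, "assemble"))
        from dataclasses import replace as _replace

        train_ds, val_ds = split_dataset(
            dataset, _replace(cfg.split, seed=stage_seed(ms, "split")))

    with _stage("select_features", timings):
        from dataclasses import replace as _replace

        forest = _replace(cfg.forest, seed=stage_seed(ms, "forest"))
        ranking = rank_importance(train_ds.X, train_ds.labels, forest)
        Xtr_sel, mask = select_top(train_ds.X, ranking, cfg.top_k)

    search_log: list[dict] = []
    hp = cfg.hyperparams
    if cfg.tune:
        with _stage("tune", timings):
            hp, search_log = random_search(
                cfg.search_space, Xtr_sel, train_ds.labels,
                budget=cfg.tune_budget, folds=cfg.tune_folds,
                seed=stage_seed(ms, "tune"), cfg=cfg.cnn, base=cfg.hyperparams)

    with _stage("train", timings):
        ytr, yva = train_ds.labels, val_ds.labels
        cnn_tm = train(None, (Xtr_sel, ytr), (mask.apply(val_ds.X), yva), hp,
                       seed=stage_seed(ms, "train"), cfg=cfg.cnn, mask=mask)
        models = {"RF-1D-CNN": cnn_tm}
        norm = cfg.normalization_baselines
        for kind in ("svm", "rf", "knn"):
            use_norm = norm if kind in ("svm", "knn") else "none"
            Xb = normalize_matrix(train_ds.X, use_norm)
            models[kind.upper()] = train_baseline(
                kind, Xb, ytr, seed=stage_seed(ms, f"baseline:{kind}"),
                normalization=use_norm)

    with _stage("validate", timings):
        val_acc = {name: tm.accuracy(val_ds.X, yva) for name, tm in models.items()}

    reports: list[MetricsReport] = []
    with _stage("evaluate", timings):
        neg_names = cfg.negative_names()
        for ci, condition in enumerate(cfg.mixture_conditions):
            seed_c = stage_seed(ms, f"test:{condition}")
            positives = correct_set(
                _mixture_positives(cfg, condition, seed_c), cfg.preprocess)
            negs = []
            for nj, name in enumerate(neg_names):
                if name == "substrate":
                    ss = generate_blank(cfg.grid, cfg.test_n_per_neg, cfg.noise,
                                        seed_c + 100 + nj)
                else:
                    ss = generate_pure(cfg.libraries[name], cfg.mixture_concentration,
                                       cfg.grid, cfg.test_n_per_neg, cfg.noise,
                                       seed_c + 100 + nj)
                negs.append(correct_set(ss, cfg.preprocess))
            test = build_test_set(positives, negs, cfg.test_n_pos,
                                  cfg.test_n_per_neg, seed_c + 7)
            for name, tm in models.items():
                reports.append(
                    evaluate_pipeline(tm, test, model_name=name, condition=condition,
                                      n_channels=cfg.grid.n))

    bundle = ReportBundle(
        config=cfg, mask=mask, models=models, validation_accuracy=val_acc,
        reports=reports, report=report_table(reports), search_log=search_log,
        timings=timings,
        train_set=(Xtr_sel, ytr), val_set=(mask.apply(val_ds.X), yva),
    )
    if outdir is not None:
        _persist(bundle, Path(outdir))
    return bundle


def _persist(bundle: ReportBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.report.to_csv(outdir / "report.tsv", sep="\t", index=False)
    bundle.mask.save(outdir / "feature_mask.json", grid=bundle.config.grid)
    if bundle.search_log:
        pd.DataFrame(bundle.search_log).to_csv(outdir / "search_log.tsv",
                                               sep="\t", index=False)
    record = {
        "config_hash": bundle.config.config_hash(),
        "master_seed": bundle.config.master_seed,
        "stage_seeds": {s: stage_seed(bundle.config.master_seed, s)
                        for s in ("generate", "assemble", "split", "forest", "train")},
        "validation_accuracy": bundle.validation_accuracy,
        "timings_s": {k: round(v, 3) for k, v in bundle.timings.items()},
        "version": __version__,
        "numpy": np.__version__,
    }
    (outdir / "run_record.json").write_text(json.dumps(record, indent=2))
    (outdir / "config.json").write_text(
        json.dumps(bundle.config.to_dict(), indent=2, default=float))
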