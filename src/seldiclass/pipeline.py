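"""End-to-end orchestration: acquire spectra, normalize, select, train, score.

One call to :func:`run_pipeline` executes the whole diagnostic workflow —
simulate or load a cohort, optionally normalize to total ion current,
rank m/z features or search for a discriminatory subset, split 80/20,
train the chosen classifier on the training half and evaluate it on the
held-out half — and leaves behind a reproducible paper trail: ranking
table, subset report, model document, predictions, evaluation report, the
fully resolved configuration and a manifest with a SHA-256 digest and
wall-clock time for every artifact.

By default feature selection sees only the training samples; the test
half never influences which m/z values are chosen.  The
``select_on_all`` escape hatch disables the guard (and is loudly logged)
for protocols that selected features on the full cohort before splitting.
Every stochastic stage (simulation, split, search, weight init) has its
own explicit seed, so identical configuration implies byte-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, evaluate, features, simulate, spectra
from .errors import ConfigError, DataError
from .spectra import SpectraSet

logger = logging.getLogger("seldiclass.pipeline")

NORMALIZATIONS = ("none", "tic")
SELECTIONS = ("top-k-by-t", "subset-search")
CLASSIFIERS = ("mlp", "lda")


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    outdir: Path
    source: str = "simulate"  # "simulate" | "load"
    sim: simulate.SimConfig | None = None
    spectra_path: str | None = None  # wide-matrix CSV (source == "load")
    labels_path: str | None = None
    normalization: str = "none"
    selection: str = "top-k-by-t"
    k: int = 5
    classifier: str = "mlp"
    fraction: float = 0.8
    stratify: bool = False
    select_on_all: bool = False
    split_seed: int = 1
    search_seed: int = 2
    train_seed: int = 3
    train: classify.TrainConfig = field(default_factory=classify.TrainConfig)
    search_population: int = 50
    search_elite: int = 10
    search_mutation: float = 0.1
    search_max_iterations: int = 100

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if self.source not in ("simulate", "load"):
            raise ConfigError(f"unknown source {self.source!r}")
        if self.normalization not in NORMALIZATIONS:
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if self.selection not in SELECTIONS:
            raise ConfigError(f"unknown selection {self.selection!r}")
        if self.classifier not in CLASSIFIERS:
            raise ConfigError(f"unknown classifier {self.classifier!r}")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if not (0.0 < self.fraction < 1.0):
            raise ConfigError("fraction must be in (0, 1)")
        if self.source == "simulate" and self.sim is None:
            self.sim = simulate.default_paper_like_config()
        if self.source == "load" and (self.spectra_path is None or self.labels_path is None):
            raise ConfigError("source 'load' requires spectra_path and labels_path")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["outdir"] = str(self.outdir)
        return out


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain dict (e.g. a parsed YAML file)."""
    raw = dict(raw)
    if "sim" in raw and isinstance(raw["sim"], dict):
        sim = dict(raw["sim"])
        for key in ("shared_peaks", "marker_peaks"):
            if key in sim:
                sim[key] = tuple(
                    simulate.PeakSpec(**p) if isinstance(p, dict) else p
                    for p in sim[key]
                )
        raw["sim"] = simulate.SimConfig(**sim)
    if "train" in raw and isinstance(raw["train"], dict):
        raw["train"] = classify.TrainConfig(**raw["train"])
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"bad pipeline config: {exc}") from exc


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_tic(sset: SpectraSet) -> SpectraSet:
    """Scale every spectrum so its total ion current equals the cohort
    median total.  Idempotent; a zero-total spectrum is an error."""
    totals = np.array([s.intensities.sum() for s in sset.spectra])
    for spec, total in zip(sset.spectra, totals):
        if total <= 0:
            raise DataError(f"sample {spec.sample_id!r} has zero total intensity")
    target = float(np.median(totals))
    scaled = [
        spectra.Spectrum(s.sample_id, s.intensities * (target / total))
        for s, total in zip(sset.spectra, totals)
    ]
    return SpectraSet(sset.grid, scaled, dict(sset.labels))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_predictions(path: Path, ids, true_labels, pred_labels, scores) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id,true,predicted,score\n")
        for sid, t, p, s in zip(ids, true_labels, pred_labels, scores):
            fh.write(f"{sid},{t},{p},{float(s)!r}\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``outdir/manifest.json``).  The manifest carries the resolved config,
    per-artifact SHA-256 digests, per-stage wall-clock seconds, the
    selected feature indices and the held-out performance metrics."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, dict] = {}
    timings: dict[str, float] = {}
    manifest: dict = {"config": config.to_dict(), "artifacts": artifacts, "timings_s": timings}
    stage = "setup"

    def record(name: str, path: Path, stage_name: str) -> None:
        artifacts[name] = {
            "path": str(path),
            "sha256": _sha256(path),
            "stage": stage_name,
        }
        logger.info("artifact %s -> %s (sha256 %s)", name, path, artifacts[name]["sha256"][:12])

    try:
        # -- acquire -----------------------------------------------------
        stage = "acquire"
        t0 = time.perf_counter()
        if config.source == "simulate":
            sset, _truth = simulate.generate(config.sim)
            logger.info("simulated cohort: %s", sset.class_counts())
        else:
            labels = spectra.read_labels_manifest(config.labels_path)
            sset = spectra.read_wide_matrix(config.spectra_path, labels)
            logger.info("loaded cohort from %s: %s", config.spectra_path, sset.class_counts())
        timings[stage] = time.perf_counter() - t0

        # -- normalize ---------------------------------------------------
        stage = "normalize"
        t0 = time.perf_counter()
        if config.normalization == "tic":
            sset = normalize_tic(sset)
            logger.info("applied total-ion-current normalization")
        timings[stage] = time.perf_counter() - t0

        # -- split -------------------------------------------------------
        stage = "split"
        t0 = time.perf_counter()
        plan = evaluate.split(
            sset.sample_ids,
            fraction=config.fraction,
            seed=config.split_seed,
            stratify_labels=sset.labels if config.stratify else None,
        )
        logger.info(
            "split seed %d: %d training / %d test samples",
            config.split_seed, len(plan.train_ids), len(plan.test_ids),
        )
        train_set = sset.subset(plan.train_ids)
        test_set = sset.subset(plan.test_ids)
        timings[stage] = time.perf_counter() - t0

        # -- feature selection (training half only, unless overridden) ---
        stage = "select"
        t0 = time.perf_counter()
        selection_set = sset if config.select_on_all else train_set
        if config.select_on_all:
            logger.warning(
                "select_on_all=True: feature selection sees the TEST samples; "
                "held-out metrics are no longer leakage-free"
            )
        ranking = features.rank_features(selection_set)
        ranking_path = outdir / "ranking.csv"
        ranking.to_frame().to_csv(ranking_path, index=False)
        record("ranking", ranking_path, stage)
        if config.selection == "top-k-by-t":
            indices = tuple(int(i) for i in ranking.top(config.k))
            rating = features.rate_subset(selection_set, indices)
            subset = features.FeatureSubset(tuple(sorted(indices)), rating)
            log = [rating]
        else:
            search_cfg = features.SearchConfig(
                k=config.k,
                population_size=config.search_population,
                n_elite=config.search_elite,
                mutation_rate=config.search_mutation,
                max_iterations=config.search_max_iterations,
                seed=config.search_seed,
            )
            subset, log = features.search_subsets(selection_set, search_cfg)
        subset_path = outdir / "subset.json"
        subset_path.write_text(
            json.dumps(
                {
                    "indices": list(subset.indices),
                    "mz": [float(sset.grid.values[i]) for i in subset.indices],
                    "rating": subset.rating,
                    "iterations": len(log),
                    "best_rating_log": log,
                },
                indent=2,
            )
            + "\n"
        )
        record("subset", subset_path, stage)
        indices = subset.indices
        mz_selected = tuple(float(sset.grid.values[i]) for i in indices)
        logger.info("selected m/z features: %s", [round(v, 2) for v in mz_selected])
        timings[stage] = time.perf_counter() - t0

        # -- train -------------------------------------------------------
        stage = "train"
        t0 = time.perf_counter()
        x_train = train_set.intensity_matrix()[:, list(indices)]
        y_train = train_set.label_array()
        if config.classifier == "mlp":
            train_cfg = dataclasses.replace(config.train, seed=config.train_seed)
            model, _losses = classify.train_mlp(
                x_train, y_train, train_cfg,
                feature_indices=indices, feature_mz=mz_selected,
            )
        else:
            model = classify.train_lda(
                x_train, y_train,
                feature_indices=indices, feature_mz=mz_selected,
            )
        model_path = outdir / "model.txt"
        classify.save_model(model_path, model)
        record("model", model_path, stage)
        timings[stage] = time.perf_counter() - t0

        # -- predict -----------------------------------------------------
        stage = "predict"
        t0 = time.perf_counter()
        x_test = test_set.intensity_matrix()[:, list(indices)]
        pred_labels, scores = classify.predict(model, x_test)
        predictions_path = outdir / "predictions.csv"
        _write_predictions(
            predictions_path, test_set.sample_ids, test_set.label_array(),
            pred_labels, scores,
        )
        record("predictions", predictions_path, stage)
        timings[stage] = time.perf_counter() - t0

        # -- evaluate ----------------------------------------------------
        stage = "evaluate"
        t0 = time.perf_counter()
        report = evaluate.confusion(list(test_set.label_array()), list(pred_labels))
        evaluation_path = outdir / "evaluation.csv"
        report.to_frame().to_csv(evaluation_path, index=False)
        record("evaluation", evaluation_path, stage)
        timings[stage] = time.perf_counter() - t0

        # -- manifest ----------------------------------------------------
        stage = "finalize"
        config_path = outdir / "resolved_config.yaml"
        config_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
        record("resolved_config", config_path, stage)
        manifest["status"] = "ok"
        manifest["selected_indices"] = list(indices)
        manifest["selected_mz"] = list(mz_selected)
        manifest["subset_rating"] = subset.rating
        manifest["n_train"] = len(plan.train_ids)
        manifest["n_test"] = len(plan.test_ids)
        manifest["metrics"] = json.loads(
            report.to_frame().iloc[0].to_json()
        )
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        for art in artifacts.values():
            art["partial_run"] = True
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        logger.error("stage %r failed: %s", stage, exc)
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
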