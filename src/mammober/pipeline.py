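"""End-to-end orchestration: data -> augment -> features -> search -> stats.

``run_pipeline`` wires the stages together with a leakage-free protocol:
the image set is split 70:30 stratified by class; augmentation is applied
to the training split only; the optimizer's objective is k-fold
cross-validated accuracy inside the training split; the best decoded
configuration is retrained on the whole training split and scored exactly
once on the untouched 30%. A global seed fans out to per-stage child seeds
through ``numpy.random.SeedSequence`` so each stage is independently
reproducible, and re-running an identical config reproduces every numeric
artifact byte for byte.

``replicate_runs`` repeats the optimize-and-score cycle for the four
competing models (baseline CNN at the first grid point, random-search CNN
with an evaluation budget equal to the unique evaluations ABER spent,
classic-BER CNN, ABER CNN) and emits the ``model,replicate,accuracy`` CSV
consumed by :func:`mammober.stats.comparison_report`.

Two budget presets are provided: ``desk_scale`` (small synthetic set,
population 10, 20 iterations, 3 restarts — minutes on one CPU) and
``paper_scale`` (population 30, 500 iterations, 30 restarts, 5 folds).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import ber
from .augment import AugmentationConfig, augment_set
from .cnn import (FitnessEvaluator, TrainProtocol, build_model, predict,
                  train, vectors_to_maps)
from .features import BackboneConfig, extract_features, write_features
from .metrics import METRIC_ORDER, confusion, metrics
from .space import decode, default_space
from .synthetic import SyntheticConfig, generate_dataset, read_dataset

__all__ = ["PipelineConfig", "desk_scale", "paper_scale", "run_pipeline",
           "replicate_runs", "MODELS"]

MODELS = ("baseline-CNN", "classic-BER-CNN", "ABER-CNN", "random-search-CNN")


@dataclass(frozen=True)
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    data_dir: str | None = None  # overrides synthetic generation when set
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    optimizer: ber.OptimizerConfig = field(default_factory=ber.OptimizerConfig)
    protocol: TrainProtocol = field(default_factory=TrainProtocol)
    out_dir: str = "runs/out"
    seed: int = 0

    def config_hash(self) -> str:
        payload = {
            "synthetic": asdict(self.synthetic),
            "data_dir": self.data_dir,
            "augmentation": asdict(self.augmentation),
            "backbone": {
                k: v for k, v in asdict(self.backbone).items() if k != "adapter"
            },
            "optimizer": asdict(self.optimizer),
            "protocol": asdict(self.protocol),
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def desk_scale(seed: int = 0, out_dir: str = "runs/desk") -> PipelineConfig:
    """Reduced-budget preset: completes in minutes on one CPU core."""
    return PipelineConfig(
        synthetic=SyntheticConfig(n_per_class=24, image_size=32, seed=seed),
        backbone=BackboneConfig(channels_per_stage=(8, 16, 64)),
        optimizer=ber.OptimizerConfig(
            population_size=10, max_iterations=20, n_runs=3, seed=seed
        ),
        protocol=TrainProtocol(epochs=3, cv_folds=2, seed=seed),
        out_dir=out_dir,
        seed=seed,
    )


def paper_scale(seed: int = 0, out_dir: str = "runs/paper") -> PipelineConfig:
    """Published run protocol: population 30, 500 iterations, 30 restarts."""
    return PipelineConfig(
        synthetic=SyntheticConfig(seed=seed),
        optimizer=ber.OptimizerConfig(
            population_size=30, max_iterations=500, n_runs=30, seed=seed
        ),
        protocol=TrainProtocol(epochs=10, cv_folds=5, seed=seed),
        out_dir=out_dir,
        seed=seed,
    )


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage child seeds, each below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def _prepare_data(config: PipelineConfig):
    """Split, augment the training side, extract features.

    Returns (x_train maps, y_train, x_test maps, y_test) with features
    standardized by training-set statistics.
    """
    data_seed, split_seed = _child_seeds(config.seed, 5)[:2]
    if config.data_dir is not None:
        images = read_dataset(config.data_dir)
    else:
        images = generate_dataset(replace(config.synthetic, seed=data_seed))
    labels = [img.label for img in images]
    idx = np.arange(len(images))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=config.protocol.train_fraction,
        stratify=labels,
        random_state=split_seed % (2 ** 31),
    )
    train_imgs = augment_set([images[i] for i in train_idx], config.augmentation)
    test_imgs = [images[i] for i in test_idx]

    fm_train = extract_features(train_imgs, config.backbone)
    fm_test = extract_features(test_imgs, config.backbone)
    y_train = np.array([img.label == "malignant" for img in train_imgs], dtype=int)
    y_test = np.array([img.label == "malignant" for img in test_imgs], dtype=int)

    mu = fm_train.values.mean(axis=0)
    sd = fm_train.values.std(axis=0) + 1e-8
    x_train = vectors_to_maps((fm_train.values - mu) / sd)
    x_test = vectors_to_maps((fm_test.values - mu) / sd)
    return x_train, y_train, x_test, y_test, fm_train, fm_test


def _score_config(position, x_train, y_train, x_test, y_test, protocol):
    """Retrain the decoded config on the full training split, score held-out."""
    cfg = decode(position)
    model = build_model(cfg, x_train.shape[1:], seed=protocol.seed)
    trained = train(model, x_train, y_train, protocol)
    y_pred = predict(trained, x_test)
    to_label = np.array(["benign", "malignant"])
    cm = confusion(to_label[y_test].tolist(), to_label[y_pred].tolist())
    return cfg, cm, metrics(cm)


def run_pipeline(config: PipelineConfig, save_features: bool = False) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 5)
    x_train, y_train, x_test, y_test, fm_train, fm_test = _prepare_data(config)
    if save_features:
        write_features(fm_train, out / "features_train.csv")
        write_features(fm_test, out / "features_test.csv")

    evaluator = FitnessEvaluator(x_train, y_train, protocol=config.protocol)
    opt_cfg = replace(config.optimizer, seed=seeds[2])
    best, histories = ber.multi_run(evaluator, opt_cfg, default_space().dimension)

    hist_rows = []
    for r, hist in enumerate(histories):
        for t, f in enumerate(hist, start=1):
            ne, nx = ber.group_sizes(t, opt_cfg.max_iterations,
                                     opt_cfg.population_size, opt_cfg)
            hist_rows.append(
                {"restart": r, "iteration": t, "best_fitness": f,
                 "n_explore": ne, "n_exploit": nx}
            )
    pd.DataFrame(hist_rows).to_csv(out / "history.csv", index=False)

    best_cfg, cm, mets = _score_config(
        best.position, x_train, y_train, x_test, y_test, config.protocol
    )
    pd.DataFrame([mets])[list(METRIC_ORDER)].to_csv(
        out / "heldout_metrics.csv", index=False
    )

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {
            "data": seeds[0], "split": seeds[1], "optimizer": seeds[2],
        },
        "n_train": int(len(y_train)), "n_test": int(len(y_test)),
        "unique_fitness_evaluations": evaluator.n_evaluations,
        "best_fitness": best.fitness,
        "best_cv_accuracy": 1.0 - best.fitness,
        "best_config": best_cfg.as_dict(),
        "best_position": [float(v) for v in best.position],
        "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "heldout_metrics": mets,
        "fitness_warnings": evaluator.warnings,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _accuracy_of(position, bundle, protocol) -> float:
    x_train, y_train, x_test, y_test = bundle
    _, _, mets = _score_config(position, x_train, y_train, x_test, y_test, protocol)
    return mets["accuracy"]


def replicate_runs(
    config: PipelineConfig,
    n_runs: int,
    out_csv: str | Path | None = None,
    models: tuple[str, ...] = MODELS,
) -> pd.DataFrame:
    """Held-out accuracy per (model, replicate); feeds the stats suite.

    Each replicate re-seeds the whole pipeline (fresh data draw, split and
    search), emulating independent repetitions of the study.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    unknown = set(models) - set(MODELS)
    if unknown:
        raise ValueError(f"unknown model(s): {sorted(unknown)}")
    dim = default_space().dimension
    rows = []
    for r in range(n_runs):
        rep_seed = _child_seeds(config.seed, n_runs + 1)[r + 1] % (2 ** 31)
        rep_cfg = replace(config, seed=rep_seed)
        x_train, y_train, x_test, y_test, _, _ = _prepare_data(rep_cfg)
        bundle = (x_train, y_train, x_test, y_test)
        protocol = replace(config.protocol, seed=rep_seed % (2 ** 31))
        seeds = _child_seeds(rep_seed, 4)

        aber_evals = None
        for model_name in models:
            if model_name == "baseline-CNN":
                # first point of the search grid: position at the origin
                acc = _accuracy_of(np.zeros(dim), bundle, protocol)
            elif model_name == "ABER-CNN":
                evaluator = FitnessEvaluator(x_train, y_train, protocol=protocol)
                opt = replace(config.optimizer, seed=seeds[0], classic_mode=False)
                best, _ = ber.multi_run(evaluator, opt, dim)
                aber_evals = evaluator.n_evaluations
                acc = _accuracy_of(best.position, bundle, protocol)
            elif model_name == "classic-BER-CNN":
                evaluator = FitnessEvaluator(x_train, y_train, protocol=protocol)
                opt = replace(config.optimizer, seed=seeds[1], classic_mode=True)
                best, _ = ber.multi_run(evaluator, opt, dim)
                acc = _accuracy_of(best.position, bundle, protocol)
            else:  # random-search-CNN, budget matched to ABER's unique evals
                evaluator = FitnessEvaluator(x_train, y_train, protocol=protocol)
                budget = aber_evals or (
                    config.optimizer.population_size
                    * config.optimizer.n_runs
                )
                best = ber.random_search_baseline(
                    evaluator, budget, config.optimizer.bounds, dim, seed=seeds[2]
                )
                acc = _accuracy_of(best.position, bundle, protocol)
            rows.append({"model": model_name, "replicate": r, "accuracy": acc})
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
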