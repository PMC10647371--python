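"""Orchestrate the full experiment: dataset build, cross-validated model
comparison, significance tests, manifests.

``run_full_experiment`` builds (or loads) a balanced dataset, runs k-fold
cross-validation for each of the eight model variants — the CNN in
spectral / RGB / fused mode and linear SVMs on spectral, raw-pixel,
pixel+spectral, HOG and HOG+spectral features — and assembles a comparison
table (one row per model, Accuracy/Precision/Recall/F1 columns) with a
Wilcoxon signed-rank column against the fused CNN on pooled per-sample
zero-one losses.  Every random element derives from the config seed, so a
rerun from the same manifest reproduces the table.
"""

from __future__ import annotations

import json
import logging
import os
import time
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .augment import Dataset
from .classifiers import CNNConfig, SVMBaseline, TrainConfig, build_cnn, predict, train_cnn
from .evaluation import CVReport, kfold_cv, wilcoxon_compare
from .synth import generate_experiment

__all__ = ["RunConfig", "run_full_experiment", "MODEL_VARIANTS", "make_model_spec"]

logger = logging.getLogger("pelagiscan")

MODEL_VARIANTS = (
    "cnn-spectral",
    "cnn-rgb",
    "cnn-fused",
    "svm-spectral",
    "svm-rgb",
    "svm-rgb+spectral",
    "svm-hog",
    "svm-hog+spectral",
)
REFERENCE_MODEL = "cnn-fused"
_VARIANT_LABELS = {
    "cnn-spectral": "CNN (Spectral)",
    "cnn-rgb": "CNN (RGB)",
    "cnn-fused": "CNN (RGB + Spectral)",
    "svm-spectral": "SVM (Spectral)",
    "svm-rgb": "SVM (RGB)",
    "svm-rgb+spectral": "SVM (RGB + Spectral)",
    "svm-hog": "SVM (HOG)",
    "svm-hog+spectral": "SVM (HOG + Spectral)",
}
_SVM_KINDS = {
    "svm-spectral": "spectral",
    "svm-rgb": "pixels",
    "svm-rgb+spectral": "pixels+spectral",
    "svm-hog": "hog",
    "svm-hog+spectral": "hog+spectral",
}


class RunConfig(BaseModel):
    """Full-experiment parameters; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    seed: int = 0
    n_per_class: int = 1000
    delta: float = 1.0
    noise_sigma: float = 0.02
    n_bands: int = 281
    scene_rows: int = 400
    scene_cols: int = 600
    fish_scale: float = 1.0
    image_size: int = 256
    lc_prime: int = 200
    roi_pixels: int = 256
    k_folds: int = 5
    fold_modes: tuple[Literal["sample", "grouped"], ...] = ("sample", "grouped")
    models: tuple[str, ...] = MODEL_VARIANTS
    max_epochs: int = 4000
    patience: int = 50
    learning_rate: float = 0.05
    batch_size: int = 32
    version: str = "pelagiscan-0.1.0"


def make_model_spec(name: str, cfg: RunConfig, classes: tuple[str, ...]):
    """Build a ``(train_dataset, seed) -> fitted-predictor`` callable."""
    if name not in MODEL_VARIANTS:
        raise ValueError(f"unknown model variant '{name}'")
    if name.startswith("svm"):
        def spec(train_ds: Dataset, seed: int):
            return SVMBaseline(_SVM_KINDS[name]).fit(train_ds, seed)
        return spec

    mode = {"cnn-spectral": "spectral", "cnn-rgb": "spatial", "cnn-fused": "fused"}[name]

    def spec(train_ds: Dataset, seed: int):
        arch = CNNConfig(
            classes=classes,
            image_size=cfg.image_size,
            input_signature_length=cfg.lc_prime,
        )
        model = build_cnn(arch, mode=mode, seed=seed)
        train_cnn(
            model,
            train_ds,
            TrainConfig(
                learning_rate=cfg.learning_rate,
                batch_size=cfg.batch_size,
                max_epochs=cfg.max_epochs,
                patience=cfg.patience,
                seed=seed,
            ),
        )

        class _Predictor:
            def predict(self, ds: Dataset):
                return predict(model, ds)[0]

        return _Predictor()

    return spec


def run_full_experiment(
    cfg: RunConfig, dataset: Dataset | None = None, outdir: str | None = None
) -> dict:
    """Build the dataset, cross-validate every model variant, and compare.

    Returns ``{"table": DataFrame, "reports": {fold_mode: {model: CVReport}},
    "dataset_size": int, "manifest": dict}``; when ``outdir`` is given also
    writes ``report.json``, ``table2_like.csv`` and ``manifest.json``.
    """
    t0 = time.time()
    if dataset is None:
        logger.info("building synthetic dataset: %d per class", cfg.n_per_class)
        dataset = generate_experiment(
            n_per_class=cfg.n_per_class,
            seed=cfg.seed,
            scene_shape=(cfg.scene_rows, cfg.scene_cols),
            n_bands=cfg.n_bands,
            delta=cfg.delta,
            noise_sigma=cfg.noise_sigma,
            fish_scale=cfg.fish_scale,
            image_size=cfg.image_size,
            lc_prime=cfg.lc_prime,
            roi_pixels=cfg.roi_pixels,
        )
    classes = tuple(dataset.classes)
    reports: dict[str, dict[str, CVReport]] = {}
    rows = []
    for fold_mode in cfg.fold_modes:
        grouped = fold_mode == "grouped"
        reports[fold_mode] = {}
        for name in cfg.models:
            logger.info("cross-validating %s (%s folds)", name, fold_mode)
            spec = make_model_spec(name, cfg, classes)
            report = kfold_cv(
                dataset, spec, k=cfg.k_folds, seed=cfg.seed, group_by_source=grouped
            )
            reports[fold_mode][name] = report
        ref_losses = reports[fold_mode][REFERENCE_MODEL].losses
        for name in cfg.models:
            report = reports[fold_mode][name]
            mean = report.mean_metrics
            if name == REFERENCE_MODEL:
                pval, mark = np.nan, ""
            else:
                res = wilcoxon_compare(report.losses, ref_losses)
                pval = res.pvalue
                mark = "*" if (not res.no_effect and res.pvalue < 0.05) else ""
            rows.append(
                {
                    "FoldMode": fold_mode,
                    "Classifier": _VARIANT_LABELS[name],
                    "Accuracy": mean["Accuracy"],
                    "Precision": mean["Precision"],
                    "Recall": mean["Recall"],
                    "F1": mean["F1"],
                    "WilcoxonP": pval,
                    "Significant": mark,
                }
            )
    table = pd.DataFrame(rows)
    manifest = {
        "config": json.loads(cfg.model_dump_json()),
        "classes": list(classes),
        "dataset_size": len(dataset),
        "runtime_s": round(time.time() - t0, 2),
    }
    result = {
        "table": table,
        "reports": reports,
        "dataset_size": len(dataset),
        "manifest": manifest,
    }
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        table.to_csv(os.path.join(outdir, "table2_like.csv"), index=False)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        serializable = {
            fold_mode: {
                name: {
                    "mean_metrics": rep.mean_metrics,
                    "fold_train_sizes": rep.fold_train_sizes,
                    "fold_test_sizes": rep.fold_test_sizes,
                    "mean_loss": float(rep.losses.mean()),
                }
                for name, rep in by_model.items()
            }
            for fold_mode, by_model in reports.items()
        }
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(serializable, fh, indent=1)
    return result
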