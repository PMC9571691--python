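"""End-to-end experiment pipeline shared by the CLI and scripted runs.

Stage order: load (or synthesise) the labelled beats -> binarize labels ->
split the normal beats 70/30 into train / validation / test -> fit min-max
normalization on the training normals and apply it everywhere -> train the
split autoencoder -> fit the anomaly threshold on training errors ->
evaluate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dataset as dio
from . import model as mdl
from . import synthetic
from .anomaly import (
    AnomalyDetector,
    evaluate,
    fit_threshold,
    reconstruction_accuracy,
)
from .config import ExperimentConfig
from .dataset import BeatDataset, SplitResult
from .model import SplitAutoencoder, TrainingHistory

__all__ = ["PreparedData", "TrainOutcome", "load_beats", "prepare_data", "run_training"]


@dataclass(frozen=True)
class PreparedData:
    """Normalized partitions ready for training and evaluation."""

    split: SplitResult  # normal beats only, all normalized
    abnormal: BeatDataset  # binarized label-0 beats, normalized
    normalization: tuple[float, float]


@dataclass(frozen=True)
class TrainOutcome:
    detector: AnomalyDetector
    history: TrainingHistory
    data: PreparedData
    report: dict


def load_beats(cfg: ExperimentConfig) -> BeatDataset:
    """Load the raw-labelled dataset named by the config (file or synthetic)."""
    if cfg.dataset.path is not None:
        return dio.read_ecg5000(cfg.dataset.path)
    spec = cfg.dataset.synthetic
    kinds = [
        synthetic.Abnormality(synthetic.AbnormalityKind[name], severity=spec.severity)
        for name in spec.kinds
    ]
    import dataclasses

    template = dataclasses.replace(synthetic.DEFAULT_TEMPLATE, noise_sd=spec.noise_sd)
    return synthetic.make_dataset(
        n_normal=spec.n_normal,
        n_abnormal_per_kind=spec.n_abnormal_per_kind,
        kinds=kinds,
        template=template,
        seed=spec.seed,
        length=spec.length,
    )


def prepare_data(cfg: ExperimentConfig, beats: BeatDataset | None = None) -> PreparedData:
    """Binarize, split the normals, and normalize every partition consistently."""
    if beats is None:
        beats = load_beats(cfg)
    binary = dio.binarize_labels(beats)
    normals = BeatDataset(
        records=[r for r in binary.records if r.label == 1],
        length=binary.length,
        source=f"{binary.source}[normals]",
    )
    abnormal = BeatDataset(
        records=[r for r in binary.records if r.label == 0],
        length=binary.length,
        source=f"{binary.source}[abnormal]",
    )
    split = dio.split_normals(
        normals, train_fraction=cfg.split.train_fraction, seed=cfg.split.seed
    )
    lo, hi = dio.fit_normalization(split.train)
    norm = lambda ds: dio.apply_normalization(ds, lo, hi)
    split = SplitResult(
        train=norm(split.train),
        validation=norm(split.validation),
        test=norm(split.test),
        seed=split.seed,
        train_fraction=split.train_fraction,
    )
    return PreparedData(split=split, abnormal=norm(abnormal), normalization=(lo, hi))


def run_training(cfg: ExperimentConfig, data: PreparedData | None = None) -> TrainOutcome:
    """Train the model per config and fit the detector; returns a full report."""
    if data is None:
        data = prepare_data(cfg)
    model = mdl.build_model(
        input_width=cfg.model.input_width,
        latent_width=cfg.model.latent_width,
        hidden_widths=cfg.model.hidden_widths,
        init_seed=cfg.model.init_seed,
    )
    model, history = mdl.train(
        model,
        data.split.train,
        data.split.validation,
        epochs=cfg.training.epochs,
        batch_size=cfg.training.batch_size,
        seed=cfg.training.seed,
        learning_rate=cfg.training.learning_rate,
        patience=cfg.training.patience,
    )
    detector = fit_threshold(model, data.split.train, k=cfg.threshold.k)

    test_metrics = evaluate(detector, data.split.test)
    report = {
        "config_digest": cfg.digest(),
        "seeds": {
            "dataset": cfg.dataset.synthetic.seed if cfg.dataset.path is None else None,
            "split": cfg.split.seed,
            "init": cfg.model.init_seed,
            "training": cfg.training.seed,
        },
        "sizes": {
            "train": len(data.split.train),
            "validation": len(data.split.validation),
            "test": len(data.split.test),
            "abnormal": len(data.abnormal),
        },
        "normalization": list(data.normalization),
        "epochs_run": len(history),
        "final_train_loss": history.train_loss[-1],
        "final_val_loss": history.val_loss[-1] if history.val_loss else None,
        "threshold": detector.threshold,
        "train_error_mean": detector.train_error_mean,
        "train_error_std": detector.train_error_std,
        "test_per_record_errors_mean": float(np.mean(test_metrics.errors)),
        "test_reconstruction_accuracy_pct": reconstruction_accuracy(test_metrics.errors),
        "test_specificity": test_metrics.specificity,
    }
    return TrainOutcome(detector=detector, history=history, data=data, report=report)
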