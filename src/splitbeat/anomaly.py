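"""Reconstruction-error anomaly detection on top of a trained autoencoder.

An autoencoder trained only on normal heartbeats reconstructs unseen normal
beats well and abnormal beats poorly, so the per-beat mean squared
reconstruction error is the anomaly statistic. The decision threshold is
fitted on the training errors as mean + k * std (population std, k = 1 by
default) and a beat is flagged anomalous iff its error strictly exceeds it.

The reconstruction-accuracy summary is (1 - mean MSE) * 100 on [0, 1]-scaled
signals, so perfect reconstruction reads 100% and a mean error of 5.3e-4
reads 99.947%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import BeatDataset
from .model import ModelError, SplitAutoencoder, encode, decode, forward

__all__ = [
    "ThresholdRule",
    "AnomalyDetector",
    "Detection",
    "EvaluationMetrics",
    "reconstruction_error",
    "reconstruction_accuracy",
    "threshold_from_errors",
    "fit_threshold",
    "detect",
    "evaluate",
]


def reconstruction_error(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean squared difference between a beat and its reconstruction."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


def reconstruction_accuracy(errors) -> float:
    """Accuracy percentage (1 - mean(errors)) * 100.

    Meaningful only for errors computed on signals normalized to the training
    [0, 1] range; equals 100 iff every error is zero.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("cannot summarise an empty error list")
    if np.any(errors < 0):
        raise ValueError("reconstruction errors must be non-negative")
    return float((1.0 - errors.mean()) * 100.0)


@dataclass(frozen=True)
class ThresholdRule:
    """Threshold = mean(train errors) + k * std(train errors)."""

    statistic: str = "mean"
    spread: str = "std"
    k: float = 1.0


@dataclass
class AnomalyDetector:
    """A trained model plus its fitted decision threshold.

    ``train_error_mean``/``train_error_std`` are stored so the threshold is
    recomputable from the rule; ``normalization`` carries the training-set
    (min, max) needed to scale incoming raw beats.
    """

    model: SplitAutoencoder
    threshold: float
    rule: ThresholdRule
    train_error_mean: float
    train_error_std: float
    normalization: tuple[float, float] | None = None


@dataclass(frozen=True)
class Detection:
    """Outcome for one beat: the decision, its error, and the latent code."""

    anomalous: bool
    error: float
    latent: np.ndarray

    @property
    def decision(self) -> str:
        return "anomalous" if self.anomalous else "normal"


def _per_record_errors(model: SplitAutoencoder, ds: BeatDataset) -> np.ndarray:
    x = ds.to_array()
    x_hat = forward(model, x)
    return np.mean((x - x_hat) ** 2, axis=1)


def threshold_from_errors(errors, k: float = 1.0) -> tuple[float, float, float]:
    """(threshold, mean, std) from per-record errors: mean + k * population std."""
    if k < 0:
        raise ValueError("threshold multiplier k must be non-negative")
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("cannot fit a threshold on an empty error list")
    mean = float(errors.mean())
    std = float(errors.std())  # population std: ddof=0
    return mean + k * std, mean, std


def fit_threshold(model: SplitAutoencoder, train_ds: BeatDataset, k: float = 1.0) -> AnomalyDetector:
    """Fit the mean + k*std threshold on per-record training errors."""
    if not model.trained:
        raise ModelError("cannot fit a threshold on an untrained model")
    threshold, mean, std = threshold_from_errors(_per_record_errors(model, train_ds), k)
    return AnomalyDetector(
        model=model,
        threshold=threshold,
        rule=ThresholdRule(k=k),
        train_error_mean=mean,
        train_error_std=std,
        normalization=train_ds.normalization,
    )


def detect(detector: AnomalyDetector, beat: np.ndarray) -> Detection:
    """Classify one normalized beat; errors strictly above threshold are anomalous.

    Returns the latent code alongside the decision, mirroring the sensor-node
    output where the encoder activation is transmitted with each prediction.
    """
    latent = encode(detector.model, beat)
    x_hat = decode(detector.model, latent)
    err = reconstruction_error(beat, x_hat)
    return Detection(anomalous=err > detector.threshold, error=err, latent=latent)


@dataclass(frozen=True)
class EvaluationMetrics:
    """Confusion-matrix summary; undefined rates are None, never 0."""

    true_positives: int
    false_positives: int
    true_negatives: int
    false_negatives: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float
    errors: np.ndarray

    @property
    def n(self) -> int:
        return (
            self.true_positives
            + self.false_positives
            + self.true_negatives
            + self.false_negatives
        )


def evaluate(detector: AnomalyDetector, ds: BeatDataset) -> EvaluationMetrics:
    """Evaluate on a binary-labelled dataset (1 normal, 0 abnormal).

    "Positive" means anomalous. Sensitivity is the detection rate on abnormal
    beats, specificity the pass rate on normal beats; either is reported as
    ``None`` when its class is absent.
    """
    labels = ds.labels
    if not set(labels.tolist()) <= {0, 1}:
        raise ValueError("evaluate expects binarized labels (1 normal, 0 abnormal)")
    errors = _per_record_errors(detector.model, ds)
    flagged = errors > detector.threshold
    abnormal = labels == 0

    tp = int(np.sum(flagged & abnormal))
    fn = int(np.sum(~flagged & abnormal))
    fp = int(np.sum(flagged & ~abnormal))
    tn = int(np.sum(~flagged & ~abnormal))

    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else None
    accuracy = (tp + tn) / len(ds) if len(ds) else 0.0
    return EvaluationMetrics(
        true_positives=tp,
        false_positives=fp,
        true_negatives=tn,
        false_negatives=fn,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        errors=errors,
    )
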