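"""Model and detector persistence.

Everything is stored as a self-describing JSON document: widths, activation
names and parameter arrays, plus (for a detector) the threshold rule and the
training-set normalization. JSON keeps the archives plain-text and
platform-independent; float64 values survive the round trip exactly via
``repr``-precision serialisation.

The encoder and decoder halves can be exported and loaded independently — the
deployment target for the decoder is a different device than the encoder's.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .anomaly import AnomalyDetector, ThresholdRule
from .model import (
    DecoderHalf,
    EncoderHalf,
    ModelError,
    SplitAutoencoder,
    _Layer,
)

__all__ = [
    "save_model",
    "load_model",
    "save_detector",
    "load_detector",
    "export_decoder",
    "load_decoder",
    "export_encoder",
    "load_encoder",
]

_FORMAT_VERSION = 1


def _layer_to_json(layer: _Layer) -> dict:
    return {
        "W": layer.W.tolist(),
        "b": layer.b.tolist(),
        "activation": layer.activation,
    }


def _layer_from_json(obj: dict) -> _Layer:
    return _Layer(
        W=np.asarray(obj["W"], dtype=float),
        b=np.asarray(obj["b"], dtype=float),
        activation=obj["activation"],
    )


def _model_to_json(model: SplitAutoencoder) -> dict:
    return {
        "format": "splitbeat-model",
        "format_version": _FORMAT_VERSION,
        "input_width": model.input_width,
        "latent_width": model.latent_width,
        "hidden_widths": list(model.hidden_widths),
        "trained": model.trained,
        "training_seed": model.training_seed,
        "encoder": [_layer_to_json(l) for l in model.encoder_params],
        "decoder": [_layer_to_json(l) for l in model.decoder_params],
    }


def _model_from_json(obj: dict) -> SplitAutoencoder:
    if obj.get("format") != "splitbeat-model":
        raise ModelError(f"not a model archive: format={obj.get('format')!r}")
    return SplitAutoencoder(
        input_width=obj["input_width"],
        latent_width=obj["latent_width"],
        hidden_widths=tuple(obj["hidden_widths"]),
        encoder_params=[_layer_from_json(l) for l in obj["encoder"]],
        decoder_params=[_layer_from_json(l) for l in obj["decoder"]],
        trained=obj["trained"],
        training_seed=obj["training_seed"],
    )


def save_model(model: SplitAutoencoder, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_model_to_json(model)))
    return path


def load_model(path: str | Path) -> SplitAutoencoder:
    return _model_from_json(json.loads(Path(path).read_text()))


def save_detector(detector: AnomalyDetector, path: str | Path) -> Path:
    doc = {
        "format": "splitbeat-detector",
        "format_version": _FORMAT_VERSION,
        "model": _model_to_json(detector.model),
        "threshold": detector.threshold,
        "rule": {
            "statistic": detector.rule.statistic,
            "spread": detector.rule.spread,
            "k": detector.rule.k,
        },
        "train_error_mean": detector.train_error_mean,
        "train_error_std": detector.train_error_std,
        "normalization": list(detector.normalization) if detector.normalization else None,
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_detector(path: str | Path) -> AnomalyDetector:
    obj = json.loads(Path(path).read_text())
    if obj.get("format") != "splitbeat-detector":
        raise ModelError(f"not a detector archive: format={obj.get('format')!r}")
    return AnomalyDetector(
        model=_model_from_json(obj["model"]),
        threshold=obj["threshold"],
        rule=ThresholdRule(**obj["rule"]),
        train_error_mean=obj["train_error_mean"],
        train_error_std=obj["train_error_std"],
        normalization=tuple(obj["normalization"]) if obj["normalization"] else None,
    )


def export_decoder(model: SplitAutoencoder, path: str | Path) -> Path:
    """Write the decoder half alone, for deployment on the edge node."""
    doc = {
        "format": "splitbeat-decoder",
        "format_version": _FORMAT_VERSION,
        "latent_width": model.latent_width,
        "output_width": model.input_width,
        "layers": [_layer_to_json(l) for l in model.decoder_params],
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_decoder(path: str | Path) -> DecoderHalf:
    obj = json.loads(Path(path).read_text())
    if obj.get("format") != "splitbeat-decoder":
        raise ModelError(f"not a decoder archive: format={obj.get('format')!r}")
    return DecoderHalf(
        latent_width=obj["latent_width"],
        output_width=obj["output_width"],
        layers=tuple(_layer_from_json(l) for l in obj["layers"]),
    )


def export_encoder(model: SplitAutoencoder, path: str | Path) -> Path:
    """Write the encoder half alone, for deployment on the sensor node."""
    doc = {
        "format": "splitbeat-encoder",
        "format_version": _FORMAT_VERSION,
        "input_width": model.input_width,
        "latent_width": model.latent_width,
        "layers": [_layer_to_json(l) for l in model.encoder_params],
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_encoder(path: str | Path) -> EncoderHalf:
    obj = json.loads(Path(path).read_text())
    if obj.get("format") != "splitbeat-encoder":
        raise ModelError(f"not an encoder archive: format={obj.get('format')!r}")
    return EncoderHalf(
        input_width=obj["input_width"],
        latent_width=obj["latent_width"],
        layers=tuple(_layer_from_json(l) for l in obj["layers"]),
    )
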