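"""Reference experiment runs under the study's standard conditions.

These functions freeze the configurations used to validate the pipeline and
are shared by the test suite and the results-reproduction script:

* ``detection_power_trial`` — train on 2,000 synthetic normals (noise sd 0.03,
  3% of the R amplitude), threshold at mean + 1*std of training errors, and
  evaluate on a balanced 400-beat test set (200 fresh normals, 200 severity-0.8
  abnormal beats, 50 per kind).
* ``reference_split_run`` — the full dataset procedure at benchmark scale:
  2,919 normal beats split 70/30 into (2043, 438, 438), training-set min-max
  normalization, training, and reconstruction accuracy on the 438 test normals.
* ``split_equivalence_max_diff`` — the deployment correctness bound: transmit
  latent codes as float32 payloads and compare the edge-side reconstruction
  against the sensor-side monolithic forward pass.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import dataset as dio
from . import model as mdl
from . import packets
from . import synthetic as syn
from .anomaly import evaluate, fit_threshold, reconstruction_accuracy

__all__ = [
    "detection_power_trial",
    "reference_split_run",
    "split_equivalence_max_diff",
    "train_reference_detector",
]


def _noisy_template(noise_sd: float = 0.03) -> syn.BeatTemplate:
    return dataclasses.replace(syn.DEFAULT_TEMPLATE, noise_sd=noise_sd)


def train_reference_detector(
    n_normal: int,
    seed: int,
    noise_sd: float = 0.03,
    epochs: int = 100,
    k: float = 1.0,
):
    """Generate normals, normalize, train and fit the threshold; returns
    (detector, normalization, template)."""
    template = _noisy_template(noise_sd)
    train_ds = syn.make_dataset(n_normal, 0, [], template, seed=seed)
    lo, hi = dio.fit_normalization(train_ds)
    train_n = dio.apply_normalization(train_ds, lo, hi)
    model = mdl.build_model(init_seed=seed)
    model, _ = mdl.train(model, train_n, None, epochs=epochs, seed=seed)
    detector = fit_threshold(model, train_n, k=k)
    return detector, (lo, hi), template


def detection_power_trial(seed: int, severity: float = 0.8, noise_sd: float = 0.03) -> dict:
    """One seeded trial of the synthetic detection-power experiment."""
    detector, (lo, hi), template = train_reference_detector(2000, seed, noise_sd=noise_sd)
    kinds = [syn.Abnormality(k, severity=severity) for k in syn.AbnormalityKind]
    test_ds = syn.make_dataset(200, 50, kinds, template, seed=seed + 10_000)
    test_n = dio.apply_normalization(dio.binarize_labels(test_ds), lo, hi)
    metrics = evaluate(detector, test_n)
    return {
        "seed": seed,
        "n": metrics.n,
        "accuracy": metrics.accuracy,
        "specificity": metrics.specificity,
        "sensitivity": metrics.sensitivity,
    }


def reference_split_run(seed: int, n_normal: int = 2919, epochs: int = 100) -> dict:
    """Benchmark-scale dataset procedure plus test-set reconstruction accuracy."""
    template = _noisy_template()
    beats = syn.make_dataset(n_normal, 0, [], template, seed=seed)
    binary = dio.binarize_labels(beats)
    n_label_1 = int(np.sum(binary.labels == 1))
    split = dio.split_normals(binary, train_fraction=0.70, seed=seed)
    lo, hi = dio.fit_normalization(split.train)
    train_n = dio.apply_normalization(split.train, lo, hi)
    val_n = dio.apply_normalization(split.validation, lo, hi)
    test_n = dio.apply_normalization(split.test, lo, hi)

    model = mdl.build_model(init_seed=seed)
    model, history = mdl.train(model, train_n, val_n, epochs=epochs, seed=seed)
    x = test_n.to_array()
    errors = np.mean((x - mdl.forward(model, x)) ** 2, axis=1)
    return {
        "seed": seed,
        "n_normal": n_label_1,
        "sizes": (len(split.train), len(split.validation), len(split.test)),
        "epochs_run": len(history),
        "test_reconstruction_accuracy_pct": reconstruction_accuracy(errors),
        "mean_test_mse": float(errors.mean()),
    }


def split_equivalence_max_diff(seed: int, n_inputs: int = 100) -> float:
    """Max abs difference between edge-side and sensor-side reconstructions.

    Latent codes cross the (simulated) link as float32 packet payloads, so
    the two reconstructions may differ by the float32 round trip; with shared
    weights the difference is bounded well below 1e-6 on [0, 1]-scale data.
    """
    detector, _, _ = train_reference_detector(300, seed, epochs=40)
    model = detector.model
    edge = mdl.extract_decoder(model)
    rng = np.random.default_rng(seed)
    beats = rng.uniform(0.0, 1.0, size=(n_inputs, model.input_width))
    worst = 0.0
    for i, beat in enumerate(beats):
        code = mdl.encode(model, beat)
        wire = packets.pack(code, sequence_no=i, fingerprint=mdl.decoder_fingerprint(model))
        received = packets.unpack(wire).payload.astype(float)
        edge_recon = edge(received)
        monolithic = mdl.forward(model, beat)
        worst = max(worst, float(np.max(np.abs(edge_recon - monolithic))))
    return worst
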