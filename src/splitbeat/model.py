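"""Split encoder/decoder autoencoder.

The network compresses a 140-sample heartbeat through a fully connected
bottleneck of 5 units and reconstructs it: encoder 140 -> 32 -> 16 -> 5 with
ReLU activations, decoder 5 -> 16 -> 32 -> 140 with ReLU hidden layers and a
sigmoid output (signals are min-max normalized to [0, 1]). Encoder and
decoder are held as separate parameter stacks so they can be deployed on
different devices; the monolithic forward pass is *defined* as
``decode(encode(x))``, making split deployment a refactoring rather than an
approximation — both paths share the same arithmetic.

Training minimises per-point mean squared reconstruction error with Adam,
mini-batches, and optional early stopping on validation loss. All randomness
(weight init, batch shuffling) flows from explicit integer seeds, and the
pure-numpy single-threaded arithmetic makes runs bit-reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .dataset import BeatDataset

__all__ = [
    "ModelError",
    "DivergenceError",
    "SplitAutoencoder",
    "EncoderHalf",
    "DecoderHalf",
    "TrainingHistory",
    "extract_encoder",
    "extract_decoder",
    "build_model",
    "train",
    "encode",
    "decode",
    "forward",
    "decoder_fingerprint",
]


class ModelError(ValueError):
    """Invalid model configuration or misuse."""


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # Numerically stable piecewise form.
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class _Layer:
    W: np.ndarray  # (fan_in, fan_out)
    b: np.ndarray  # (fan_out,)
    activation: str  # "relu" | "sigmoid"

    def __call__(self, x: np.ndarray) -> np.ndarray:
        z = x @ self.W + self.b
        return _relu(z) if self.activation == "relu" else _sigmoid(z)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class SplitAutoencoder:
    """Paired encoder and decoder parameter stacks."""

    input_width: int
    latent_width: int
    hidden_widths: tuple[int, ...]
    encoder_params: list[_Layer]
    decoder_params: list[_Layer]
    trained: bool = False
    training_seed: int | None = None

    @property
    def layers(self) -> list[_Layer]:
        return self.encoder_params + self.decoder_params

    def parameter_arrays(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend([layer.W, layer.b])
        return out


@dataclass(frozen=True)
class EncoderHalf:
    """A stand-alone encoder, as deployed on the sensor node."""

    input_width: int
    latent_width: int
    layers: tuple[_Layer, ...]

    def __call__(self, beat: np.ndarray) -> np.ndarray:
        beat = np.asarray(beat, dtype=float)
        if beat.shape[-1] != self.input_width:
            raise ModelError(
                f"beat has {beat.shape[-1]} samples, encoder expects {self.input_width}"
            )
        h = beat
        for layer in self.layers:
            h = layer(h)
        return h


@dataclass(frozen=True)
class DecoderHalf:
    """A stand-alone decoder, as deployed on the edge node.

    Carries only the decoder parameter stack plus the widths needed for shape
    checks, so it can be shipped and loaded independently of the encoder.
    """

    latent_width: int
    output_width: int
    layers: tuple[_Layer, ...]

    def __call__(self, code: np.ndarray) -> np.ndarray:
        code = np.asarray(code, dtype=float)
        if code.shape[-1] != self.latent_width:
            raise ModelError(
                f"latent code has width {code.shape[-1]}, decoder expects {self.latent_width}"
            )
        h = code
        for layer in self.layers:
            h = layer(h)
        return h

    @property
    def fingerprint(self) -> int:
        return _params_fingerprint(self.layers)


@dataclass
class TrainingHistory:
    """Per-epoch train/validation loss curves."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


def build_model(
    input_width: int = 140,
    latent_width: int = 5,
    hidden_widths: tuple[int, ...] = (32, 16),
    init_seed: int = 0,
) -> SplitAutoencoder:
    """Build an untrained model with seeded Glorot-uniform initialization.

    Widths must be positive and the latent width strictly smaller than the
    input width (the bottleneck is the point). Two builds with the same
    arguments produce identical parameters.
    """
    widths = (input_width, latent_width, *hidden_widths)
    if any(int(w) <= 0 for w in widths):
        raise ModelError("all widths must be positive integers")
    if latent_width >= input_width:
        raise ModelError(
            f"latent width {latent_width} must be smaller than input width {input_width}"
        )
    rng = np.random.default_rng(init_seed)
    enc_dims = [input_width, *hidden_widths, latent_width]
    dec_dims = [latent_width, *reversed(hidden_widths), input_width]

    def _stack(dims: list[int], last_activation: str) -> list[_Layer]:
        stack = []
        for i, (fi, fo) in enumerate(zip(dims[:-1], dims[1:])):
            act = last_activation if i == len(dims) - 2 else "relu"
            stack.append(_Layer(W=_glorot(rng, fi, fo), b=np.zeros(fo), activation=act))
        return stack

    return SplitAutoencoder(
        input_width=int(input_width),
        latent_width=int(latent_width),
        hidden_widths=tuple(int(w) for w in hidden_widths),
        encoder_params=_stack(enc_dims, "relu"),
        decoder_params=_stack(dec_dims, "sigmoid"),
    )


def _require_trained(model: SplitAutoencoder) -> None:
    if not model.trained:
        raise ModelError("model is untrained; call train() first")


def _run_stack(layers: list[_Layer], x: np.ndarray) -> np.ndarray:
    h = x
    for layer in layers:
        h = layer(h)
    return h


def encode(model: SplitAutoencoder, beat: np.ndarray) -> np.ndarray:
    """Compress one beat (or a batch) to its latent code."""
    _require_trained(model)
    beat = np.asarray(beat, dtype=float)
    if beat.shape[-1] != model.input_width:
        raise ModelError(
            f"beat has {beat.shape[-1]} samples, model expects {model.input_width}"
        )
    return _run_stack(model.encoder_params, beat)


def decode(model: SplitAutoencoder, code: np.ndarray) -> np.ndarray:
    """Reconstruct a beat (or batch) from a latent code."""
    _require_trained(model)
    code = np.asarray(code, dtype=float)
    if code.shape[-1] != model.latent_width:
        raise ModelError(
            f"code has {code.shape[-1]} values, model expects {model.latent_width}"
        )
    return _run_stack(model.decoder_params, code)


def forward(model: SplitAutoencoder, beat: np.ndarray) -> np.ndarray:
    """Monolithic reconstruction — by construction identical to decode(encode(x))."""
    return decode(model, encode(model, beat))


def extract_decoder(model: SplitAutoencoder) -> DecoderHalf:
    """Detach the decoder for stand-alone (edge-side) deployment."""
    _require_trained(model)
    return DecoderHalf(
        latent_width=model.latent_width,
        output_width=model.input_width,
        layers=tuple(model.decoder_params),
    )


def extract_encoder(model: SplitAutoencoder) -> EncoderHalf:
    """Detach the encoder for stand-alone (sensor-side) deployment."""
    _require_trained(model)
    return EncoderHalf(
        input_width=model.input_width,
        latent_width=model.latent_width,
        layers=tuple(model.encoder_params),
    )


def _params_fingerprint(layers) -> int:
    h = hashlib.blake2s(digest_size=4)
    for layer in layers:
        h.update(np.ascontiguousarray(layer.W, dtype=np.float64).tobytes())
        h.update(np.ascontiguousarray(layer.b, dtype=np.float64).tobytes())
    return int.from_bytes(h.digest(), "little")


def decoder_fingerprint(model: SplitAutoencoder) -> int:
    """32-bit digest of the decoder parameters, carried in packet headers.

    Sensor and edge nodes agree on it iff their decoder halves came from the
    same trained model.
    """
    return _params_fingerprint(model.decoder_params)


# ---------------------------------------------------------------------------
# Training


def _forward_cached(layers: list[_Layer], x: np.ndarray):
    """Forward pass keeping post-activation values for backprop."""
    acts = [x]
    for layer in layers:
        acts.append(layer(acts[-1]))
    return acts


def _batch_loss_and_grads(layers: list[_Layer], x: np.ndarray):
    acts = _forward_cached(layers, x)
    x_hat = acts[-1]
    diff = x_hat - x
    loss = float(np.mean(diff**2))

    grads = []
    delta = 2.0 * diff / diff.size  # dL/d(x_hat)
    for i in range(len(layers) - 1, -1, -1):
        a_out, a_in = acts[i + 1], acts[i]
        if layers[i].activation == "sigmoid":
            dz = delta * a_out * (1.0 - a_out)
        else:  # relu
            dz = delta * (a_out > 0)
        gW = a_in.T @ dz
        gb = dz.sum(axis=0)
        grads.append((gW, gb))
        if i > 0:
            delta = dz @ layers[i].W.T
    grads.reverse()
    return loss, grads


def _dataset_loss(layers: list[_Layer], x: np.ndarray) -> float:
    x_hat = _run_stack(layers, x)
    return float(np.mean((x_hat - x) ** 2))


def train(
    model: SplitAutoencoder,
    train_ds: BeatDataset,
    val_ds: BeatDataset | None = None,
    epochs: int = 100,
    batch_size: int = 64,
    seed: int = 0,
    learning_rate: float = 2e-3,
    patience: int = 10,
) -> tuple[SplitAutoencoder, TrainingHistory]:
    """Train in place by mini-batch Adam on mean squared reconstruction error.

    Both datasets must carry normalization parameters (the sigmoid output and
    the accuracy metric assume [0, 1]-scale signals); unnormalized input is
    refused. Early stopping watches the validation loss with the given
    ``patience`` and restores the best-validation weights; pass
    ``patience=None`` or ``val_ds=None`` to disable it. A non-finite loss
    raises :class:`DivergenceError` naming the epoch.
    """
    if epochs < 1:
        raise ModelError("epochs must be >= 1")
    if train_ds.normalization is None:
        raise ModelError("training dataset is not normalized; fit and apply normalization first")
    if val_ds is not None and val_ds.normalization is None:
        raise ModelError("validation dataset is not normalized")
    if val_ds is not None and val_ds.normalization != train_ds.normalization:
        raise ModelError("validation dataset normalized with different parameters than training")

    x_train = train_ds.to_array()
    if x_train.shape[0] == 0:
        raise ModelError("training dataset is empty")
    if x_train.shape[1] != model.input_width:
        raise ModelError(
            f"training beats have {x_train.shape[1]} samples, model expects {model.input_width}"
        )
    x_val = val_ds.to_array() if val_ds is not None else None

    layers = model.layers
    rng = np.random.default_rng(seed)

    # Adam state per parameter array.
    params = [(layer, name) for layer in layers for name in ("W", "b")]
    m = [np.zeros_like(getattr(layer, name)) for layer, name in params]
    v = [np.zeros_like(getattr(layer, name)) for layer, name in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history = TrainingHistory()
    best_val = np.inf
    best_weights: list[np.ndarray] | None = None
    stale = 0
    n = x_train.shape[0]

    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            batch = x_train[order[start : start + batch_size]]
            loss, grads = _batch_loss_and_grads(layers, batch)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            step += 1
            gi = 0
            for layer, (gW, gb) in zip(layers, grads):
                for name, g in (("W", gW), ("b", gb)):
                    m[gi] = beta1 * m[gi] + (1 - beta1) * g
                    v[gi] = beta2 * v[gi] + (1 - beta2) * g**2
                    m_hat = m[gi] / (1 - beta1**step)
                    v_hat = v[gi] / (1 - beta2**step)
                    arr = getattr(layer, name)
                    arr -= learning_rate * m_hat / (np.sqrt(v_hat) + eps)
                    gi += 1

        epoch_train = _dataset_loss(layers, x_train)
        if not np.isfinite(epoch_train):
            raise DivergenceError(f"non-finite training loss at epoch {epoch}")
        history.train_loss.append(epoch_train)
        if x_val is not None:
            epoch_val = _dataset_loss(layers, x_val)
            history.val_loss.append(epoch_val)
            if patience is not None:
                if epoch_val < best_val:
                    best_val = epoch_val
                    best_weights = [p.copy() for p in model.parameter_arrays()]
                    stale = 0
                else:
                    stale += 1
                    if stale > patience:
                        break

    if best_weights is not None:
        for current, best in zip(model.parameter_arrays(), best_weights):
            current[...] = best

    model.trained = True
    model.training_seed = seed
    return model, history
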