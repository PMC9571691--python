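"""Experiment configuration: one YAML document drives every pipeline stage.

The config is a plain nested dataclass tree with a lossless YAML round trip,
so a run is fully reproducible from its config file plus the seeds recorded
in it. Defaults reproduce the reference study conditions: 140-sample beats,
a 5-unit latent code, the 70% training split of the 2919 normal beats, and
the printed link/inference parameters of the two latency scenarios.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "SyntheticSpec",
    "DatasetConfig",
    "SplitConfig",
    "ModelConfig",
    "TrainingConfig",
    "ThresholdConfig",
    "LinkConfig",
    "LatencyConfig",
    "ExperimentConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid configuration content; message names the offending field."""


@dataclass(frozen=True)
class SyntheticSpec:
    n_normal: int = 2919
    n_abnormal_per_kind: int = 520
    kinds: tuple[str, ...] = ("T_INVERSION", "QRS_WIDENING", "R_ATTENUATION", "P_ABSENCE")
    severity: float = 0.8
    noise_sd: float = 0.03
    seed: int = 0
    length: int = 140


@dataclass(frozen=True)
class DatasetConfig:
    path: str | None = None  # ECG5000-dialect file; None -> synthetic
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.70
    seed: int = 0


@dataclass(frozen=True)
class ModelConfig:
    input_width: int = 140
    latent_width: int = 5
    hidden_widths: tuple[int, ...] = (32, 16)
    init_seed: int = 0


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    learning_rate: float = 2e-3
    patience: int = 10


@dataclass(frozen=True)
class ThresholdConfig:
    k: float = 1.0


@dataclass(frozen=True)
class LinkConfig:
    name: str = "BLE"
    rate_bps: float = 16000.0
    bytes_per_point: int = 2
    per_packet_overhead_bytes: int = 0


@dataclass(frozen=True)
class LatencyConfig:
    """Measured component times for the two scenarios (milliseconds).

    The transmission fields are hardware measurements fed in as configuration;
    set either to None to compute transmission from the corresponding link
    parameters instead.
    """

    inference_ms: float = 0.48
    baseline_transmission_ms: float | None = 3.5
    ondevice_transmission_ms: float | None = 0.028


@dataclass(frozen=True)
class ExperimentConfig:
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    baseline_link: LinkConfig = field(default_factory=LinkConfig)
    ondevice_link: LinkConfig = field(
        default_factory=lambda: LinkConfig(name="SPI", rate_bps=1_000_000.0)
    )
    latency: LatencyConfig = field(default_factory=LatencyConfig)
    out_dir: str = "out"

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(_tuples_to_lists(self.to_dict()), sort_keys=True)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_yaml())
        return path

    @classmethod
    def from_dict(cls, obj: dict) -> "ExperimentConfig":
        try:
            return cls(
                dataset=DatasetConfig(
                    path=obj.get("dataset", {}).get("path"),
                    synthetic=_build(SyntheticSpec, obj.get("dataset", {}).get("synthetic", {}),
                                     tuple_fields=("kinds",)),
                ),
                split=_build(SplitConfig, obj.get("split", {})),
                model=_build(ModelConfig, obj.get("model", {}), tuple_fields=("hidden_widths",)),
                training=_build(TrainingConfig, obj.get("training", {})),
                threshold=_build(ThresholdConfig, obj.get("threshold", {})),
                baseline_link=_build(LinkConfig, obj.get("baseline_link", {})),
                ondevice_link=_build(
                    LinkConfig,
                    obj.get("ondevice_link", {"name": "SPI", "rate_bps": 1_000_000.0}),
                ),
                latency=_build(LatencyConfig, obj.get("latency", {})),
                out_dir=obj.get("out_dir", "out"),
            )
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        obj = yaml.safe_load(text)
        if obj is None:
            obj = {}
        if not isinstance(obj, dict):
            raise ConfigError("config root must be a mapping")
        return cls.from_dict(obj)

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_yaml(Path(path).read_text())

    def digest(self) -> str:
        """Short content hash of the canonical YAML form, for run provenance."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _build(cls, obj: dict, tuple_fields: tuple[str, ...] = ()):
    if not isinstance(obj, dict):
        raise ConfigError(f"expected a mapping for {cls.__name__}, got {type(obj).__name__}")
    kwargs = dict(obj)
    for name in tuple_fields:
        if name in kwargs and kwargs[name] is not None:
            kwargs[name] = tuple(kwargs[name])
    return cls(**kwargs)
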