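"""Synthetic ECG5000-shaped heartbeat generation.

Generates fixed-length (default 140-point) labelled heartbeats so the whole
pipeline — loading, splitting, training, split inference — is testable without
the real ECG5000 recording. A beat is modelled as a baseline plus five Gaussian
bumps standing in for the P, Q, R, S and T waves, plus white Gaussian noise.
Abnormal classes are produced by systematic, severity-scaled distortions of the
normal morphology (T-wave inversion, QRS widening, R attenuation, P absence),
which raise reconstruction error under an autoencoder trained on normals.

This is deliberately not a physiological simulator: there is no RR-interval
variability, baseline wander or multi-lead structure. It emulates the *shape*
of the benchmark data (one majority normal class, minority abnormal classes
with consistent morphological differences), not its clinical content.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

from .dataset import BeatDataset, BeatRecord

__all__ = [
    "BeatTemplate",
    "Abnormality",
    "AbnormalityKind",
    "DEFAULT_TEMPLATE",
    "make_beat",
    "make_dataset",
]

#: ECG5000 beats are 140 samples long.
DEFAULT_BEAT_LENGTH = 140

# Wave order within the template arrays. Centers must be strictly increasing
# in this order (P before Q before R before S before T).
_WAVES = ("P", "Q", "R", "S", "T")
_P, _Q, _R, _S, _T = range(5)


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology of a normal heartbeat.

    Amplitudes are in arbitrary signal units; centers and widths are fractions
    of the beat length, so a template is resolution-independent.
    """

    wave_amplitudes: tuple[float, float, float, float, float]
    wave_centers: tuple[float, float, float, float, float]
    wave_widths: tuple[float, float, float, float, float]
    baseline: float = 0.0
    noise_sd: float = 0.03

    def __post_init__(self) -> None:
        amps = np.asarray(self.wave_amplitudes, dtype=float)
        centers = np.asarray(self.wave_centers, dtype=float)
        widths = np.asarray(self.wave_widths, dtype=float)
        if amps.shape != (5,) or centers.shape != (5,) or widths.shape != (5,):
            raise ValueError("template requires exactly five waves (P, Q, R, S, T)")
        values = np.concatenate([amps, centers, widths, [self.baseline, self.noise_sd]])
        if not np.all(np.isfinite(values)):
            raise ValueError("template parameters must be finite")
        if np.any(widths <= 0):
            raise ValueError("wave widths must be strictly positive")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("wave centers must be strictly increasing (P<Q<R<S<T)")
        if np.any(centers < 0) or np.any(centers >= 1):
            raise ValueError("wave centers must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


#: Default normal-beat morphology: upright P and T, tall narrow R flanked by
#: small negative Q and S deflections. R amplitude 1.0 sets the signal scale;
#: noise_sd 0.03 is 3% of the R amplitude.
DEFAULT_TEMPLATE = BeatTemplate(
    wave_amplitudes=(0.15, -0.15, 1.0, -0.25, 0.35),
    wave_centers=(0.18, 0.36, 0.42, 0.48, 0.70),
    wave_widths=(0.045, 0.018, 0.022, 0.018, 0.070),
    baseline=0.0,
    noise_sd=0.03,
)


class AbnormalityKind(enum.Enum):
    """Named morphology distortions standing in for abnormal rhythm classes."""

    T_INVERSION = "T_INVERSION"
    QRS_WIDENING = "QRS_WIDENING"
    R_ATTENUATION = "R_ATTENUATION"
    P_ABSENCE = "P_ABSENCE"


@dataclass(frozen=True)
class Abnormality:
    """An abnormality kind with a severity in (0, 1] scaling the distortion."""

    kind: AbnormalityKind
    severity: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.severity <= 1.0):
            raise ValueError("severity must lie in (0, 1]")

    def apply(self, template: BeatTemplate) -> BeatTemplate:
        """Return a distorted copy of ``template``.

        Each kind perturbs one morphological feature monotonically in
        severity: T_INVERSION flips the T amplitude towards -T, QRS_WIDENING
        multiplies the Q/R/S widths by (1 + severity), R_ATTENUATION scales
        the R amplitude by (1 - severity), and P_ABSENCE fades the P wave out.
        """
        amps = list(template.wave_amplitudes)
        widths = list(template.wave_widths)
        s = self.severity
        if self.kind is AbnormalityKind.T_INVERSION:
            # severity 1 -> fully inverted T; severity 0.5 -> flattened T.
            amps[_T] = template.wave_amplitudes[_T] * (1.0 - 2.0 * s)
        elif self.kind is AbnormalityKind.QRS_WIDENING:
            for i in (_Q, _R, _S):
                widths[i] = template.wave_widths[i] * (1.0 + s)
        elif self.kind is AbnormalityKind.R_ATTENUATION:
            amps[_R] = template.wave_amplitudes[_R] * (1.0 - s)
        elif self.kind is AbnormalityKind.P_ABSENCE:
            amps[_P] = template.wave_amplitudes[_P] * (1.0 - s)
        else:  # pragma: no cover - enum is closed
            raise ValueError(f"unknown abnormality kind {self.kind!r}")
        return replace(
            template,
            wave_amplitudes=tuple(amps),
            wave_widths=tuple(widths),
        )


def _beat_shape(template: BeatTemplate, length: int) -> np.ndarray:
    """Deterministic noise-free beat: baseline plus five Gaussian bumps."""
    t = np.arange(length, dtype=float)
    beat = np.full(length, template.baseline, dtype=float)
    for amp, center, width in zip(
        template.wave_amplitudes, template.wave_centers, template.wave_widths
    ):
        mu = center * length
        sigma = width * length
        beat += amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    return beat


def make_beat(template: BeatTemplate, length: int = DEFAULT_BEAT_LENGTH, seed: int = 0) -> np.ndarray:
    """Generate one heartbeat: shaped waves plus seeded Gaussian noise.

    Identical ``(template, length, seed)`` triples yield bitwise-identical
    vectors. ``length`` must be at least 10 so the wave structure is
    resolvable.
    """
    if length < 10:
        raise ValueError(f"beat length must be >= 10, got {length}")
    beat = _beat_shape(template, length)
    if template.noise_sd > 0:
        rng = np.random.default_rng(seed)
        beat = beat + rng.normal(0.0, template.noise_sd, size=length)
    return beat


def _record_seed(dataset_seed: int, index: int) -> int:
    """Per-record noise seed, a pure function of (dataset seed, record index).

    Spawning from a SeedSequence keyed on both values means appending records
    to a dataset never changes earlier records.
    """
    ss = np.random.SeedSequence(entropy=(int(dataset_seed) & 0xFFFFFFFF, index))
    return int(ss.generate_state(1)[0])


def make_dataset(
    n_normal: int,
    n_abnormal_per_kind: int,
    kinds: list[Abnormality] | None = None,
    template: BeatTemplate = DEFAULT_TEMPLATE,
    seed: int = 0,
    length: int = DEFAULT_BEAT_LENGTH,
) -> BeatDataset:
    """Generate a labelled dataset following the ECG5000 label convention.

    Label 1 marks normal beats; labels 2..5 mark the abnormality kinds in
    ``kinds`` order. At most four kinds fit in the label space. Records are
    emitted normals first, then each abnormal kind in turn; each record's
    noise is seeded independently from ``seed`` and its index.
    """
    kinds = list(kinds or [])
    if n_normal < 0 or n_abnormal_per_kind < 0:
        raise ValueError("record counts must be non-negative")
    if len(kinds) > 4:
        raise ValueError("at most 4 abnormality kinds (labels 2-5) are available")

    records: list[BeatRecord] = []
    index = 0
    for _ in range(n_normal):
        beat = make_beat(template, length, seed=_record_seed(seed, index))
        records.append(BeatRecord(label=1, samples=beat))
        index += 1
    for k, abnormality in enumerate(kinds):
        distorted = abnormality.apply(template)
        for _ in range(n_abnormal_per_kind):
            beat = make_beat(distorted, length, seed=_record_seed(seed, index))
            records.append(BeatRecord(label=2 + k, samples=beat))
            index += 1
    return BeatDataset(
        records=records,
        length=length,
        source=f"synthetic(seed={seed}, n_normal={n_normal}, "
        f"n_abnormal_per_kind={n_abnormal_per_kind}, kinds={[a.kind.value for a in kinds]})",
    )
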