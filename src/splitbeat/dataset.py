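"""ECG5000-dialect dataset handling.

The ECG5000 benchmark circulates as plain delimited text: one heartbeat per
line, an integer class label first, then 140 floating-point samples. Labels
run 1-5, with 1 the normal class and 2-5 abnormal rhythm classes. This module
reads and writes that dialect, collapses labels to the binary normal/abnormal
convention (1 = normal, 0 = abnormal), draws the seeded 70/30
train/validation/test split of the normal beats, and fits/applies global
min-max normalization on the training partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "BeatRecord",
    "BeatDataset",
    "SplitResult",
    "DatasetError",
    "ParseError",
    "read_ecg5000",
    "write_ecg5000",
    "binarize_labels",
    "split_normals",
    "fit_normalization",
    "apply_normalization",
    "invert_normalization",
]


class DatasetError(ValueError):
    """Invalid dataset content or operation."""


class ParseError(DatasetError):
    """Malformed ECG5000-dialect file; message names the offending line."""


@dataclass(frozen=True)
class BeatRecord:
    """One labelled heartbeat: an integer label and a fixed-length sample vector."""

    label: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise DatasetError("samples must be a 1-D vector")
        if not np.all(np.isfinite(samples)):
            raise DatasetError("samples must be finite")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "label", int(self.label))


@dataclass(frozen=True)
class BeatDataset:
    """Ordered heartbeat records sharing one length, with provenance.

    ``normalization`` is ``None`` until :func:`apply_normalization` stamps the
    (min, max) pair used to scale the samples.
    """

    records: list[BeatRecord]
    length: int
    normalization: tuple[float, float] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        for i, rec in enumerate(self.records):
            if rec.samples.shape[0] != self.length:
                raise DatasetError(
                    f"record {i} has {rec.samples.shape[0]} samples, expected {self.length}"
                )
        if self.normalization is not None:
            lo, hi = self.normalization
            if not hi > lo:
                raise DatasetError("normalization requires max > min")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def to_array(self) -> np.ndarray:
        """Samples stacked as an (n_records, length) array."""
        if not self.records:
            return np.empty((0, self.length), dtype=float)
        return np.stack([r.samples for r in self.records])


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train/validation/test partition of a normal-only dataset."""

    train: BeatDataset
    validation: BeatDataset
    test: BeatDataset
    seed: int
    train_fraction: float


def _parse_line(line: str, lineno: int, expected_fields: int | None) -> tuple[int, np.ndarray]:
    # Both whitespace- and comma-delimited copies of ECG5000 circulate.
    fields = line.replace(",", " ").split()
    if expected_fields is not None and len(fields) != expected_fields:
        raise ParseError(
            f"line {lineno}: expected {expected_fields} fields, found {len(fields)}"
        )
    try:
        values = np.array([float(f) for f in fields], dtype=float)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-numeric field ({exc})") from None
    label_f = values[0]
    if label_f != int(label_f):
        raise ParseError(f"line {lineno}: label {label_f!r} is not an integer")
    return int(label_f), values[1:]


def read_ecg5000(path: str | Path) -> BeatDataset:
    """Read an ECG5000-dialect file: one beat per line, label first.

    The delimiter (whitespace or comma) is auto-detected per line, the record
    length is inferred from the first line and enforced on every later one,
    and file order is preserved. Raw labels outside 1..5 are rejected.
    """
    path = Path(path)
    lines = [
        (i + 1, stripped)
        for i, raw in enumerate(path.read_text().splitlines())
        if (stripped := raw.strip())
    ]
    if not lines:
        raise ParseError(f"{path}: empty file")

    records: list[BeatRecord] = []
    expected_fields: int | None = None
    for lineno, line in lines:
        label, samples = _parse_line(line, lineno, expected_fields)
        if expected_fields is None:
            if samples.size == 0:
                raise ParseError(f"line {lineno}: no sample values after the label")
            expected_fields = samples.size + 1
        if not 1 <= label <= 5:
            raise ParseError(f"line {lineno}: raw label {label} outside 1..5")
        records.append(BeatRecord(label=label, samples=samples))
    return BeatDataset(records=records, length=expected_fields - 1, source=str(path))


def write_ecg5000(ds: BeatDataset, path: str | Path) -> Path:
    """Write a dataset in the ECG5000 dialect (space-delimited, label first).

    Samples are emitted with 12 significant digits, so a write/read round trip
    preserves labels exactly and samples to well under 1e-9 absolute error on
    unit-scale data.
    """
    if not ds.records:
        raise DatasetError("refusing to write an empty dataset")
    path = Path(path)
    with path.open("w") as fh:
        for rec in ds.records:
            fields = [str(rec.label)] + [format(v, ".12g") for v in rec.samples]
            fh.write(" ".join(fields) + "\n")
    return path


def binarize_labels(ds: BeatDataset) -> BeatDataset:
    """Collapse raw labels 1-5 to the binary convention: 1 normal, 0 abnormal."""
    for i, rec in enumerate(ds.records):
        if not 1 <= rec.label <= 5:
            raise DatasetError(f"record {i}: raw label {rec.label} outside 1..5")
    records = [
        BeatRecord(label=1 if rec.label == 1 else 0, samples=rec.samples)
        for rec in ds.records
    ]
    return replace(ds, records=records)


def split_normals(
    ds: BeatDataset,
    train_fraction: float = 0.70,
    seed: int = 0,
    allow_empty: bool = False,
) -> SplitResult:
    """Seeded train/validation/test split of a normal-only dataset.

    ``floor(train_fraction * n)`` records are drawn uniformly without
    replacement for training. The remainder, kept in original dataset order,
    is split into a first half (validation, ``floor(remainder / 2)``) and the
    rest (test). With n = 2919 and the default fraction this yields the sizes
    (2043, 438, 438).
    """
    if not 0.0 < train_fraction < 1.0:
        raise DatasetError("train_fraction must lie in (0, 1)")
    labels = set(ds.labels.tolist())
    if labels - {1}:
        raise DatasetError(f"split_normals expects only normal (label 1) records, got labels {sorted(labels)}")

    n = len(ds)
    n_train = int(np.floor(train_fraction * n))
    n_rest = n - n_train
    n_val = n_rest // 2
    if not allow_empty and min(n_train, n_val, n_rest - n_val) < 1:
        raise DatasetError(
            f"n={n} with fraction {train_fraction} leaves an empty part; "
            "pass allow_empty=True to permit this"
        )

    rng = np.random.default_rng(seed)
    train_idx = set(rng.choice(n, size=n_train, replace=False).tolist())
    rest_idx = [i for i in range(n) if i not in train_idx]  # original order

    def _part(indices, name):
        return BeatDataset(
            records=[ds.records[i] for i in indices],
            length=ds.length,
            normalization=ds.normalization,
            source=f"{ds.source}[{name}]",
        )

    return SplitResult(
        train=_part(sorted(train_idx), "train"),
        validation=_part(rest_idx[:n_val], "validation"),
        test=_part(rest_idx[n_val:], "test"),
        seed=seed,
        train_fraction=train_fraction,
    )


def fit_normalization(train: BeatDataset) -> tuple[float, float]:
    """Global (min, max) over every sample value of the training records."""
    if not train.records:
        raise DatasetError("cannot fit normalization on an empty dataset")
    arr = train.to_array()
    lo, hi = float(arr.min()), float(arr.max())
    if not hi > lo:
        raise DatasetError(f"degenerate range: all training values equal {lo}")
    return lo, hi


def apply_normalization(ds: BeatDataset, lo: float, hi: float) -> BeatDataset:
    """Map every value v to (v - lo) / (hi - lo); no clipping.

    Values outside the training range deliberately land outside [0, 1]:
    clipping would erase exactly the out-of-range excursions that make
    anomalous beats hard to reconstruct.
    """
    if not hi > lo:
        raise DatasetError("normalization requires max > min")
    scale = hi - lo
    records = [
        BeatRecord(label=rec.label, samples=(rec.samples - lo) / scale)
        for rec in ds.records
    ]
    return replace(ds, records=records, normalization=(float(lo), float(hi)))


def invert_normalization(ds: BeatDataset) -> BeatDataset:
    """Undo :func:`apply_normalization` using the parameters stamped on ``ds``."""
    if ds.normalization is None:
        raise DatasetError("dataset carries no normalization parameters")
    lo, hi = ds.normalization
    records = [
        BeatRecord(label=rec.label, samples=rec.samples * (hi - lo) + lo)
        for rec in ds.records
    ]
    return replace(ds, records=records, normalization=None)
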