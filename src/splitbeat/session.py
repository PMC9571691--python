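"""Software twin of the two-node split-inference test set-up.

A sensor node holds the complete detector (encoder + decoder + threshold); an
edge node holds only the stand-alone decoder. For every beat the sensor runs
detection locally and transmits a single latent-code packet — 5 float32
values plus header instead of the 140-sample raw beat — and the edge node
validates the packet, checks the decoder fingerprint, and reconstructs the
beat from the received code. The session log records, per beat, the on-device
decision, the bytes actually transmitted, and how closely the edge-side
reconstruction matches the sensor-side one (they differ only by the float32
round trip of the payload).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .anomaly import AnomalyDetector, detect
from .model import DecoderHalf, decode, decoder_fingerprint
from . import packets

__all__ = [
    "IncompatibleModelError",
    "SessionEntry",
    "SessionLog",
    "run_session",
    "write_session_log",
]


class IncompatibleModelError(RuntimeError):
    """Edge decoder fingerprint does not match the sensor's model."""


@dataclass(frozen=True)
class SessionEntry:
    sequence_no: int
    decision: str
    error: float
    transmitted_bytes: int
    payload_points: int
    edge_reconstruction: np.ndarray
    reconstruction_max_abs_diff: float


@dataclass(frozen=True)
class SessionLog:
    entries: list[SessionEntry]
    device_id: int
    raw_points_per_beat: int
    latent_points_per_beat: int

    def __len__(self) -> int:
        return len(self.entries)

    def summary(self) -> dict:
        n = len(self.entries)
        return {
            "beats": n,
            "anomalies_flagged": sum(e.decision == "anomalous" for e in self.entries),
            "payload_points_per_beat": self.latent_points_per_beat,
            "raw_points_per_beat": self.raw_points_per_beat,
            "total_transmitted_bytes": sum(e.transmitted_bytes for e in self.entries),
            "max_reconstruction_abs_diff": max(
                (e.reconstruction_max_abs_diff for e in self.entries), default=0.0
            ),
        }


def run_session(
    detector: AnomalyDetector,
    edge_decoder: DecoderHalf,
    beats,
    device_id: int = 1,
) -> SessionLog:
    """Stream normalized beats through the sensor -> edge pipeline.

    Raises :class:`IncompatibleModelError` before any transmission if the
    edge decoder was not extracted from the sensor's trained model (checked
    by the decoder-parameter fingerprint carried in every packet header).
    """
    sensor_fp = decoder_fingerprint(detector.model)
    if edge_decoder.fingerprint != sensor_fp:
        raise IncompatibleModelError(
            f"edge decoder fingerprint {edge_decoder.fingerprint:#010x} does not match "
            f"sensor model {sensor_fp:#010x}"
        )

    entries: list[SessionEntry] = []
    for seq, beat in enumerate(beats):
        beat = np.asarray(beat, dtype=float)
        # Sensor side: full detection, then one latent packet over the link.
        result = detect(detector, beat)
        wire = packets.pack(
            result.latent,
            anomaly_flag=result.anomalous,
            device_id=device_id,
            sequence_no=seq,
            fingerprint=sensor_fp,
        )
        # Edge side: validate, check provenance, reconstruct from the code.
        pkt = packets.unpack(wire)
        if pkt.fingerprint != edge_decoder.fingerprint:
            raise IncompatibleModelError("packet fingerprint does not match edge decoder")
        edge_recon = edge_decoder(pkt.payload.astype(float))
        onboard_recon = decode(detector.model, result.latent)
        entries.append(
            SessionEntry(
                sequence_no=seq,
                decision=result.decision,
                error=result.error,
                transmitted_bytes=len(wire),
                payload_points=pkt.n_points,
                edge_reconstruction=edge_recon,
                reconstruction_max_abs_diff=float(np.max(np.abs(edge_recon - onboard_recon))),
            )
        )
    return SessionLog(
        entries=entries,
        device_id=device_id,
        raw_points_per_beat=detector.model.input_width,
        latent_points_per_beat=detector.model.latent_width,
    )


def write_session_log(log: SessionLog, path: str | Path) -> Path:
    """Emit the per-beat session log as tab-separated text."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["sequence_no", "decision", "error", "transmitted_bytes", "payload_points", "recon_max_abs_diff"]
        )
        for e in log.entries:
            writer.writerow(
                [
                    e.sequence_no,
                    e.decision,
                    format(e.error, ".9g"),
                    e.transmitted_bytes,
                    e.payload_points,
                    format(e.reconstruction_max_abs_diff, ".3g"),
                ]
            )
    return path
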