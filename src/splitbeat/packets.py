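"""Binary packet format for latent-code telemetry.

The sensor node packages each encoder output (5 float32 values by default)
with a small fixed header so the edge node can validate, order and decode it.

Byte layout (little-endian, no padding)::

    offset  size  field
    0       1     version            (currently 1)
    1       2     device_id          uint16
    3       4     sequence_no        uint32, strictly increasing per session
    7       1     flags              bit 0: anomaly, bits 1-2: payload kind
    8       4     decoder fingerprint uint32 (digest of decoder parameters)
    12      1     payload length     number of float32 values
    13      4*n   payload            IEEE-754 float32, little-endian

The fingerprint lets the receiver verify that the transmitted latent code was
produced by the encoder matching its own decoder copy before reconstructing.
The codec is a bijection on its value domain: pack followed by unpack returns
every field bit-exactly.
"""

from __future__ import annotations

import enum
import struct
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PROTOCOL_VERSION",
    "PayloadKind",
    "LatentPacket",
    "PacketError",
    "FramingError",
    "VersionError",
    "pack",
    "unpack",
]

PROTOCOL_VERSION = 1

_HEADER = struct.Struct("<BHIBIB")  # version, device, seq, flags, fingerprint, n


class PacketError(ValueError):
    """Malformed packet."""


class FramingError(PacketError):
    """Truncated buffer or payload length disagreeing with the buffer."""


class VersionError(PacketError):
    """Unsupported protocol version."""


class PayloadKind(enum.IntEnum):
    LATENT = 0  # encoder output
    RAW = 1  # unencoded beat (no-intelligence baseline)
    ALERT = 2  # anomaly notification without payload data


@dataclass(frozen=True)
class LatentPacket:
    version: int
    device_id: int
    sequence_no: int
    payload_kind: PayloadKind
    anomaly_flag: bool
    fingerprint: int
    payload: np.ndarray  # float32

    @property
    def n_points(self) -> int:
        return int(self.payload.size)


def pack(
    payload,
    *,
    anomaly_flag: bool = False,
    device_id: int = 0,
    sequence_no: int = 0,
    fingerprint: int = 0,
    payload_kind: PayloadKind = PayloadKind.LATENT,
) -> bytes:
    """Serialize a payload of reals to the wire format (float32 LE)."""
    values = np.asarray(payload, dtype=np.float32)
    if values.ndim != 1:
        raise PacketError("payload must be a 1-D sequence of reals")
    if not np.all(np.isfinite(values)):
        raise PacketError("payload values must be finite")
    if values.size > 0xFF:
        raise PacketError(f"payload of {values.size} points exceeds the 255-point frame limit")
    flags = (0x01 if anomaly_flag else 0x00) | (int(payload_kind) << 1)
    header = _HEADER.pack(
        PROTOCOL_VERSION,
        int(device_id),
        int(sequence_no),
        flags,
        int(fingerprint) & 0xFFFFFFFF,
        values.size,
    )
    return header + values.astype("<f4").tobytes()


def unpack(buffer: bytes) -> LatentPacket:
    """Parse a wire buffer back into a :class:`LatentPacket`.

    Rejects unknown versions, truncated buffers and trailing garbage.
    """
    if len(buffer) < _HEADER.size:
        raise FramingError(
            f"buffer of {len(buffer)} bytes shorter than the {_HEADER.size}-byte header"
        )
    version, device_id, seq, flags, fingerprint, n = _HEADER.unpack_from(buffer)
    if version != PROTOCOL_VERSION:
        raise VersionError(f"unsupported packet version {version}")
    expected = _HEADER.size + 4 * n
    if len(buffer) != expected:
        raise FramingError(
            f"payload declares {n} points ({expected} bytes total), buffer has {len(buffer)}"
        )
    kind_bits = (flags >> 1) & 0x03
    try:
        kind = PayloadKind(kind_bits)
    except ValueError:
        raise FramingError(f"unknown payload kind {kind_bits}") from None
    payload = np.frombuffer(buffer, dtype="<f4", offset=_HEADER.size, count=n).copy()
    return LatentPacket(
        version=version,
        device_id=device_id,
        sequence_no=seq,
        payload_kind=kind,
        anomaly_flag=bool(flags & 0x01),
        fingerprint=fingerprint,
        payload=payload,
    )
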