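"""Transmission + inference latency accounting for the two deployment scenarios.

The model is deliberately parametric: link rates, bytes per point, packet
overhead and on-node inference times are configuration inputs, because in a
real deployment they are hardware measurements. The package computes only
what follows arithmetically — serialisation time of a payload over a link,
and the additive total of transmission and inference — and compares the
no-intelligence baseline (every raw sample crosses the link) against the
on-device-intelligence scenario (only the latent code does).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "LinkSpec",
    "LatencyScenario",
    "LatencyReport",
    "transmission_time_ms",
    "scenario_latency",
    "data_reduction_factor",
    "compare_scenarios",
]


@dataclass(frozen=True)
class LinkSpec:
    """A point-to-point data link: rate in bits/s, encoding width, framing overhead."""

    name: str
    rate_bps: float
    bytes_per_point: int = 2
    per_packet_overhead_bytes: int = 0

    def __post_init__(self) -> None:
        if self.rate_bps <= 0:
            raise ValueError("link rate must be positive")
        if self.bytes_per_point < 1:
            raise ValueError("bytes_per_point must be at least 1")
        if self.per_packet_overhead_bytes < 0:
            raise ValueError("overhead must be non-negative")


@dataclass(frozen=True)
class LatencyScenario:
    """One deployment scenario.

    Transmission time is computed from ``n_points`` over ``link`` unless a
    measured ``transmission_ms`` is supplied directly, in which case the link
    may be omitted. ``points_to_upper_layer`` defaults to ``n_points`` (raw
    streaming); the on-device-intelligence scenario sets it to the latent
    width.
    """

    n_points: int
    inference_ms: float
    link: LinkSpec | None = None
    transmission_ms: float | None = None
    points_to_upper_layer: int | None = None

    def __post_init__(self) -> None:
        if self.n_points < 0:
            raise ValueError("n_points must be non-negative")
        if self.inference_ms < 0:
            raise ValueError("inference time must be non-negative")
        if (self.link is None) == (self.transmission_ms is None):
            raise ValueError("provide exactly one of link or transmission_ms")
        if self.transmission_ms is not None and self.transmission_ms < 0:
            raise ValueError("transmission time must be non-negative")


@dataclass(frozen=True)
class LatencyReport:
    transmission_ms: float
    inference_ms: float
    total_ms: float
    points_to_upper_layer: int


def transmission_time_ms(n_points: int, link: LinkSpec) -> float:
    """Time to serialise ``n_points`` samples (plus framing) over ``link``.

    (n_points * bytes_per_point + overhead) * 8 bits / rate, in milliseconds.
    """
    if n_points < 0:
        raise ValueError("n_points must be non-negative")
    bits = (n_points * link.bytes_per_point + link.per_packet_overhead_bytes) * 8
    return bits / link.rate_bps * 1000.0


def scenario_latency(scenario: LatencyScenario) -> LatencyReport:
    """Total latency of a scenario: transmission plus inference, exactly additive."""
    if scenario.transmission_ms is not None:
        tx = float(scenario.transmission_ms)
    else:
        tx = transmission_time_ms(scenario.n_points, scenario.link)
    points = (
        scenario.points_to_upper_layer
        if scenario.points_to_upper_layer is not None
        else scenario.n_points
    )
    return LatencyReport(
        transmission_ms=tx,
        inference_ms=float(scenario.inference_ms),
        total_ms=tx + float(scenario.inference_ms),
        points_to_upper_layer=int(points),
    )


def data_reduction_factor(input_width: int, latent_width: int) -> float:
    """Payload reduction from sending the latent code instead of the raw beat.

    140 input samples against a 5-value latent code gives a factor of 28.
    """
    if latent_width < 1:
        raise ValueError("latent width must be at least 1")
    if input_width < 1:
        raise ValueError("input width must be at least 1")
    return input_width / latent_width


def compare_scenarios(
    baseline: LatencyScenario, ondevice: LatencyScenario
) -> dict[str, LatencyReport]:
    """Side-by-side latency reports for the two deployment options."""
    return {
        "no_on_device_intelligence": scenario_latency(baseline),
        "with_on_device_intelligence": scenario_latency(ondevice),
    }
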