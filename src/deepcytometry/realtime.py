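"""Real-time sorting feasibility: inference latency, latency-to-travel
distance, minimum channel length, and prediction-to-charge mapping.

For label-free sorting the classification decision must arrive before the
cell reaches the sorter, so the microfluidic channel must be at least as
long as the distance the cell travels during inference:
d = latency x flow speed.  At the reference 1.3 m/s flow, single-example
inference latencies of 23.2 / 8.6 / 3.6 ms correspond to 30.2 / 11.2 /
4.7 mm of travel.

Sorter charge mapping: SW-480 drops are charged negative, OT-II drops
positive, blank drops get no charge.
"""

from __future__ import annotations

import platform
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import Network

__all__ = [
    "LatencyReport",
    "SortDecision",
    "CHARGE_MAP",
    "travel_distance",
    "travel_distance_mm",
    "required_channel_length",
    "sort_decision",
    "measure_latency",
]

#: class index -> droplet charge
CHARGE_MAP = {0: "negative", 1: "positive", 2: "none"}


@dataclass
class SortDecision:
    predicted_class: int
    charge: str


@dataclass
class LatencyReport:
    rows: list  # [(batch_size, mean per-example latency ms)]
    hardware: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["batch_size", "ms_per_example"])


def travel_distance(latency_s: float, flow_speed: float) -> float:
    """Distance (m) a cell travels during ``latency_s`` at ``flow_speed``."""
    if latency_s < 0:
        raise ValueError("latency must be non-negative")
    if not flow_speed > 0:
        raise ValueError("flow_speed must be positive")
    return latency_s * flow_speed


def travel_distance_mm(latency_s: float, flow_speed: float) -> float:
    """Reporting helper: travel distance in mm, rounded to 0.1 mm."""
    return round(travel_distance(latency_s, flow_speed) * 1e3, 1)


def required_channel_length(latency_s: float, flow_speed: float,
                            margin: float = 0.0) -> float:
    """Minimum channel length (m): the travel distance times (1 + margin)."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    return travel_distance(latency_s, flow_speed) * (1.0 + margin)


def sort_decision(probabilities) -> SortDecision:
    """Map a 3-class probability vector to a droplet-charge decision.

    Argmax decides the class; exact ties are broken toward blank (no
    charge), the conservative no-sort outcome.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.shape != (3,):
        raise ValueError("expected a 3-class probability vector")
    if abs(p.sum() - 1.0) > 1e-3:
        raise ValueError("probability vector does not sum to 1")
    winners = np.flatnonzero(p == p.max())
    cls = 2 if 2 in winners else int(winners[0])
    return SortDecision(predicted_class=cls, charge=CHARGE_MAP[cls])


def measure_latency(network: Network, batch_sizes, repetitions: int = 10,
                    warmup: int = 2, seed: int = 0) -> LatencyReport:
    """Time eval-mode forward passes per batch size.

    Warm-up runs are excluded; the reported value is the mean wall-clock
    batch latency divided by the batch size (ms/example).  Absolute values
    are hardware-dependent and never asserted.
    """
    rng = np.random.default_rng(seed)
    H, W = network.config.input_shape
    rows = []
    for bs in batch_sizes:
        batch = rng.normal(size=(int(bs), H, W))
        for _ in range(warmup):
            network.forward(batch)
        times = []
        for _ in range(repetitions):
            t0 = time.perf_counter()
            network.forward(batch)
            times.append(time.perf_counter() - t0)
        rows.append((int(bs), float(np.mean(times)) / int(bs) * 1e3))
    hardware = f"{platform.processor() or platform.machine()} ({platform.system()})"
    return LatencyReport(rows=rows, hardware=hardware)
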