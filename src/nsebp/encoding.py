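"""Input generation and temporal encoding.

Three encoders feed the experiments: homogeneous Poisson spike trains
(the synthetic study condition for the forward-pass and training
benchmarks), the two-neurons-per-bit XOR segment encoding, and the
Gaussian receptive-field population encoding that maps a normalized
scalar feature onto M firing latencies (with a non-firing sentinel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .srm0 import SRM0Params
from .trainer import TargetSpec, valid_target

__all__ = [
    "EncodingConfig",
    "NO_FIRE",
    "poisson_train",
    "encode_xor",
    "xor_label",
    "xor_dataset",
    "xor_targets",
    "encode_population",
    "class_targets_from_inputs",
]

#: code of a neuron kept silent by the population encoder
NO_FIRE = -1.0


@dataclass(frozen=True)
class EncodingConfig:
    """Parameters of the encoders.

    ``M`` Gaussian receptive fields tile the normalized feature range
    (0, 1); field ``i`` (1-based) is centred at ``(2i - 3)/(2(M - 2))``
    with common width ``sigma = 1/(beta*(M - 2))``.  A feature value
    activates each field by ``a_i = exp(-(x - mu_i)^2 / (2 sigma^2))``
    and fires at latency ``t_max * (1 - a_i)`` rounded to 0.1 ms;
    fields with ``a_i`` below ``no_fire_threshold`` stay silent
    (sentinel -1).  The XOR bits are encoded by two neurons per bit
    firing at ``xor_zero_times`` for a 0 and ``xor_one_times`` for a 1.
    """

    M: int = 12
    value_range: Tuple[float, float] = (0.0, 1.0)
    beta: float = 1.5
    t_max: float = 200.0
    no_fire_threshold: float = 0.05
    xor_zero_times: Tuple[float, float] = (1.0, 2.0)
    xor_one_times: Tuple[float, float] = (3.0, 4.0)
    xor_target_c1: float = 10.0
    xor_target_c2: float = 15.0

    def __post_init__(self) -> None:
        if self.M < 3:
            raise ValueError("population encoding needs M >= 3 fields")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")


def poisson_train(
    rate: float, length: float, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson spike train on [0, length) ms at ``rate`` Hz."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if length <= 0:
        raise ValueError("length must be positive")
    if rate == 0:
        return np.empty(0)
    mean_isi_ms = 1000.0 / rate
    # draw in blocks of exponential inter-arrival times until past the horizon
    times: List[float] = []
    t = 0.0
    n_guess = max(8, int(2 * rate * length / 1000.0))
    while True:
        isis = rng.exponential(mean_isi_ms, size=n_guess)
        for isi in isis:
            t += isi
            if t >= length:
                return np.asarray(times)
            times.append(t)


def xor_label(bits: Tuple[int, int]) -> int:
    """Class index: 0 for {00, 11} (C1), 1 for {01, 10} (C2)."""
    b1, b2 = bits
    return int(b1 != b2)


def encode_xor(bits: Tuple[int, int], cfg: EncodingConfig) -> List[np.ndarray]:
    """Four input spike trains for one XOR bit pattern.

    Each bit is carried by a segment of two neurons firing at the
    configured (t_a, t_b) pair: (1, 2) ms for a 0 and (3, 4) ms for a 1
    by default; the two segments are concatenated over 4 neurons.
    """
    if tuple(bits) not in {(0, 0), (0, 1), (1, 0), (1, 1)}:
        raise ValueError(f"bits must be binary, got {bits}")
    trains: List[np.ndarray] = []
    for b in bits:
        t_a, t_b = cfg.xor_one_times if b else cfg.xor_zero_times
        trains.append(np.asarray([t_a]))
        trains.append(np.asarray([t_b]))
    return trains


def xor_targets(cfg: EncodingConfig, params: SRM0Params) -> Dict[int, np.ndarray]:
    """Per-class target spike times on the single output neuron.

    C1 (patterns 00/11) targets 10 ms, C2 (01/10) targets 15 ms; both
    must be reachable from the encoded inputs under the relaxed
    target-validity rule (any input spike before the target).
    """
    targets = {0: np.asarray([cfg.xor_target_c1]), 1: np.asarray([cfg.xor_target_c2])}
    all_inputs = np.concatenate(
        [np.concatenate(encode_xor(b, cfg)) for b in [(0, 0), (0, 1), (1, 0), (1, 1)]]
    )
    for c, times in targets.items():
        for t_d in times:
            if not valid_target(float(t_d), all_inputs, 2, "nsebp", params):
                raise ValueError(f"XOR target {t_d} ms for class {c} is unreachable")
    return targets


def xor_dataset(
    cfg: EncodingConfig, params: SRM0Params
) -> Tuple[List[Tuple[List[np.ndarray], TargetSpec]], List[int], Dict[int, np.ndarray]]:
    """The four encoded XOR patterns, their labels and the class targets.

    Returns ``(patterns, labels, class_targets)`` where each pattern is
    ``(input_trains, TargetSpec)`` with the output-neuron target being
    its own class's target time.
    """
    class_targets = xor_targets(cfg, params)
    patterns = []
    labels = []
    for bits in [(0, 0), (0, 1), (1, 0), (1, 1)]:
        label = xor_label(bits)
        patterns.append(
            (encode_xor(bits, cfg), TargetSpec({0: class_targets[label]}))
        )
        labels.append(label)
    return patterns, labels, class_targets


def encode_population(x: float, cfg: EncodingConfig) -> np.ndarray:
    """Population receptive-field code of a normalized feature value.

    Returns ``M`` firing latencies in ms with -1 for silent fields.
    Values outside [0, 1] are clipped (the encoder tiles only the
    normalized range).
    """
    lo, hi = cfg.value_range
    if not lo <= x <= hi:
        x = min(max(x, lo), hi)
    x01 = (x - lo) / (hi - lo)
    i = np.arange(1, cfg.M + 1, dtype=float)
    mu = (2.0 * i - 3.0) / (2.0 * (cfg.M - 2.0))
    sigma = 1.0 / (cfg.beta * (cfg.M - 2.0))
    act = np.exp(-((x01 - mu) ** 2) / (2.0 * sigma**2))
    times = np.round(cfg.t_max * (1.0 - act), 1)
    times[act < cfg.no_fire_threshold] = NO_FIRE
    return times


def population_trains(codes: np.ndarray) -> List[np.ndarray]:
    """Turn a latency code vector (with -1 sentinels) into spike trains."""
    return [
        np.asarray([c]) if c != NO_FIRE else np.empty(0) for c in np.asarray(codes)
    ]


def class_targets_from_inputs(
    input_trains: Sequence[np.ndarray], params: SRM0Params
) -> np.ndarray:
    """Target times placing every input spike at its kernel peak.

    ``t_d = t_in + 2*tau2*ln 2`` -- under ``tau1 = 2*tau2`` this is the
    lag of the PSP-kernel maximum, so each input contributes maximally
    at its own derived target.  Duplicates (to 0.1 ms) are merged.
    """
    offset = 2.0 * params.tau2 * math.log(2.0)
    times = np.concatenate(
        [np.asarray(t, dtype=float) + offset for t in input_trains if len(t)]
        or [np.empty(0)]
    )
    return np.unique(np.round(np.sort(times), 6))
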