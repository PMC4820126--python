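"""Event-driven forward pass for SRM0 networks.

Instead of scanning the membrane voltage at every time step, the
output spike times of an SRM0 neuron (with ``tau1 = 2*tau2``) are the
roots of a quadratic in ``z = exp(-t/tau1)`` on each inter-input-spike
interval::

    a z^2 - b z + theta = 0,
    a = sum_m w_m exp(t_m/tau2),
    b = sum_m w_m exp(t_m/tau1) - A2 exp(t_hat/tau1),

where the sums run over input spikes at or before the interval start
and ``t_hat`` is the neuron's last output spike.  A brute-force
time-stepped simulator (:func:`oracle_simulate`) is provided purely as
an independent reference for equivalence testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _fast
from .srm0 import SpikeTrain, SRM0Params

__all__ = [
    "QuadCoeffs",
    "solve_interval",
    "simulate_neuron",
    "simulate_network",
    "oracle_simulate",
    "merge_weighted",
    "read_spike_csv",
    "write_spike_csv",
]

#: tolerance under which a slightly negative discriminant is treated as
#: an exact tangency
DISC_TOL = 1e-12


@dataclass(frozen=True)
class QuadCoeffs:
    """Accumulated quadratic coefficients for one interval.

    ``a`` and ``b`` are the input-spike sums above, optionally expressed
    relative to a reference time ``t_ref`` (each ``t_m`` replaced by
    ``t_m - t_ref``) to keep the exponentials bounded; the root formula
    then returns ``t - t_ref``.
    """

    a: float
    b: float
    t_ref: float = 0.0

    @classmethod
    def assemble(
        cls,
        spikes: Sequence[Tuple[float, float]],
        last_out: Optional[float],
        params: SRM0Params,
        t_ref: float = 0.0,
    ) -> "QuadCoeffs":
        """Build a, b from weighted spikes (time, weight) and the last output."""
        a = sum(w * math.exp((t - t_ref) / params.tau2) for t, w in spikes)
        b = sum(w * math.exp((t - t_ref) / params.tau1) for t, w in spikes)
        if last_out is not None:
            b -= params.A2 * math.exp((last_out - t_ref) / params.tau1)
        return cls(a=a, b=b, t_ref=t_ref)


def solve_interval(
    coeffs: QuadCoeffs,
    window: Tuple[float, float],
    params: SRM0Params,
) -> Optional[float]:
    """Earliest threshold crossing in ``[t_start, t_end)``, or ``None``.

    Implements the closed-form firing-time solution: if ``a != 0`` and
    ``b^2 - 4 a theta >= 0``, the candidate times are
    ``t = t_ref - tau1 * ln((b +- sqrt(b^2 - 4 a theta)) / (2 a))`` for
    roots with positive argument; the smallest candidate inside the
    window is the output spike.  Absence of a root is a normal outcome.
    """
    t_start, t_end = window
    if not t_start < t_end:
        raise ValueError(f"empty interval [{t_start}, {t_end})")
    a, b = coeffs.a, coeffs.b
    if a == 0.0:
        return None
    disc = b * b - 4.0 * a * params.theta
    if disc < 0.0:
        if disc > -DISC_TOL:
            disc = 0.0
        else:
            return None
    sq = math.sqrt(disc)
    best: Optional[float] = None
    for sign in (+1.0, -1.0):
        z = (b + sign * sq) / (2.0 * a)
        if z <= 0.0:
            continue
        t = coeffs.t_ref - params.tau1 * math.log(z)
        if t_start <= t < t_end and (best is None or t < best):
            best = t
    return best


def merge_weighted(
    trains: Sequence[np.ndarray], weights: Sequence[float]
) -> np.ndarray:
    """Merge per-neuron spike trains into one (time, weight) array sorted by time."""
    parts = [
        np.column_stack([np.asarray(t, dtype=float), np.full(len(t), w, dtype=float)])
        for t, w in zip(trains, weights)
        if len(t)
    ]
    if not parts:
        return np.empty((0, 2))
    merged = np.vstack(parts)
    order = np.argsort(merged[:, 0], kind="stable")
    return merged[order]


def _as_sorted_spikes(pre_spikes) -> np.ndarray:
    arr = np.asarray(pre_spikes, dtype=float)
    if arr.size == 0:
        return np.empty((0, 2))
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pre_spikes must be a sequence of (time, weight) pairs")
    if np.any(np.diff(arr[:, 0]) < 0):
        raise ValueError("pre_spikes must be sorted by time")
    return arr


def simulate_neuron(
    pre_spikes,
    params: SRM0Params,
    horizon: float,
    *,
    one_per_interval: bool = False,
    return_ops: bool = False,
):
    """Event-driven output spike train for one postsynaptic neuron.

    Iterates the inter-input-spike intervals (the last one extended to
    ``horizon``), solving the threshold quadratic in each; after every
    emission the refractory coefficient changes, so the remainder of the
    interval is re-solved.  With ``one_per_interval=True`` at most one
    spike is emitted per interval (the strict pseudo-code behaviour).

    Returns the output spike-time array; with ``return_ops=True``, a
    ``(times, n_solve_ops)`` tuple instead.
    """
    arr = _as_sorted_spikes(pre_spikes)
    arr = arr[arr[:, 0] <= horizon]
    times, ops = _fast.event_times(
        np.ascontiguousarray(arr[:, 0]),
        np.ascontiguousarray(arr[:, 1]),
        params.tau1,
        params.tau2,
        params.theta,
        params.A2,
        float(horizon),
        one_per_interval,
    )
    if return_ops:
        return times, int(ops)
    return times


def oracle_simulate(
    pre_spikes,
    params: SRM0Params,
    horizon: float,
    dt: float,
    *,
    return_ops: bool = False,
):
    """Brute-force time-stepped forward pass on a grid of step ``dt``.

    Evaluates the membrane potential at every grid point and emits a
    spike at the first point where ``u >= theta``; reference
    implementation for equivalence tests against the event-driven path.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    arr = _as_sorted_spikes(pre_spikes)
    arr = arr[arr[:, 0] <= horizon]
    times, ops = _fast.grid_times(
        np.ascontiguousarray(arr[:, 0]),
        np.ascontiguousarray(arr[:, 1]),
        params.tau1,
        params.tau2,
        params.theta,
        params.A2,
        float(horizon),
        float(dt),
    )
    if return_ops:
        return times, int(ops)
    return times


def simulate_network(
    input_trains: Sequence[np.ndarray],
    layers: Sequence,
    params: SRM0Params,
    horizon: float,
    *,
    engine: str = "event",
    dt: float = 1e-3,
) -> List[List[np.ndarray]]:
    """Layer-by-layer forward pass.

    ``layers`` is a sequence of objects with a ``matrix`` (pre x post)
    and optional ``mask`` attribute (see :class:`nsebp.trainer.LayerWeights`);
    plain arrays are accepted too.  Returns activity for every layer,
    ``result[0]`` being the input trains, so hidden activity can be
    inspected and reused by the trainer.
    """
    activity: List[List[np.ndarray]] = [
        [np.asarray(t, dtype=float) for t in input_trains]
    ]
    for li, layer in enumerate(layers):
        w = np.asarray(getattr(layer, "matrix", layer), dtype=float)
        mask = getattr(layer, "mask", None)
        if w.shape[0] != len(activity[-1]):
            raise ValueError(
                f"layer {li}: weight matrix has {w.shape[0]} presynaptic rows "
                f"but previous layer has {len(activity[-1])} neurons"
            )
        eff = w if mask is None else w * mask
        out_layer = []
        for post in range(w.shape[1]):
            merged = merge_weighted(activity[-1], eff[:, post])
            if engine == "event":
                out = simulate_neuron(merged, params, horizon)
            elif engine == "oracle":
                out = oracle_simulate(merged, params, horizon, dt)
            else:
                raise ValueError(f"unknown engine {engine!r}")
            out_layer.append(out)
        activity.append(out_layer)
    return activity


def write_spike_csv(path, trains: Sequence[SpikeTrain]) -> None:
    """Write spike trains as a two-column CSV ``neuron_id,time_ms``."""
    rows = [(tr.neuron_id, t) for tr in trains for t in tr.times]
    df = pd.DataFrame(rows, columns=["neuron_id", "time_ms"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_spike_csv(path, n_neurons: Optional[int] = None) -> List[SpikeTrain]:
    """Read spike trains from the two-column CSV dialect.

    Returns one :class:`SpikeTrain` per neuron id present (plus empty
    trains up to ``n_neurons`` when given), sorted by id.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["neuron_id", "time_ms"]:
        raise ValueError(
            f"expected header 'neuron_id,time_ms', got {list(df.columns)}"
        )
    ids = sorted(df["neuron_id"].unique().tolist())
    if n_neurons is not None:
        ids = sorted(set(ids) | set(range(n_neurons)))
    trains = []
    for nid in ids:
        times = np.sort(df.loc[df["neuron_id"] == nid, "time_ms"].to_numpy(float))
        trains.append(SpikeTrain(neuron_id=int(nid), times=times))
    return trains
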