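"""Spike-train similarity, decision rule and convergence accounting."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .srm0 import SRM0Params

__all__ = [
    "FilteredTrain",
    "gaussian_filter_train",
    "measure_C",
    "classify",
    "accuracy",
    "epochs_to_convergence",
    "NOT_CONVERGED",
]

#: sentinel returned when the convergence criterion never held
NOT_CONVERGED = -1


@dataclass
class FilteredTrain:
    """A spike train convolved with a Gaussian filter on a fixed grid."""

    grid: np.ndarray
    values: np.ndarray


def gaussian_filter_train(
    times: np.ndarray, grid: np.ndarray, sigma: float
) -> FilteredTrain:
    """Intensity ``v(t) = sum_m exp(-(t - t_m)^2 / sigma^2)`` on ``grid``."""
    times = np.asarray(times, dtype=float)
    vals = np.zeros_like(grid)
    if times.size and grid.size:
        # each spike only touches grid points within a few sigma
        step = grid[1] - grid[0] if grid.size > 1 else 1.0
        half = max(1, int(np.ceil(8.0 * sigma / step)))
        idx = np.searchsorted(grid, times)
        for t, i in zip(times, idx):
            lo = max(0, i - half)
            hi = min(grid.size, i + half + 1)
            vals[lo:hi] += np.exp(-((grid[lo:hi] - t) ** 2) / sigma**2)
    return FilteredTrain(grid=grid, values=vals)


def measure_C(
    train1,
    train2,
    sigma: float = 1.0,
    resolution: float = 1.0,
) -> float:
    """Correlation-based similarity of two spike trains, in [0, 1].

    Both trains are convolved with a Gaussian filter of standard
    deviation ``sigma`` on a common grid of step ``resolution`` covering
    both, and C is the cosine of the two filtered vectors.  C = 1 for
    identical trains and decays toward 0 for unrelated ones.  Two empty
    trains are identical (C = 1); one empty train shares no mass with a
    non-empty one (C = 0).
    """
    t1 = np.asarray(train1, dtype=float).ravel()
    t2 = np.asarray(train2, dtype=float).ravel()
    if not t1.size and not t2.size:
        return 1.0
    if not t1.size or not t2.size:
        return 0.0
    lo = min(t1.min(), t2.min()) - 5.0 * sigma
    hi = max(t1.max(), t2.max()) + 5.0 * sigma
    grid = np.arange(lo, hi + resolution, resolution)
    v1 = gaussian_filter_train(t1, grid, sigma).values
    v2 = gaussian_filter_train(t2, grid, sigma).values
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    if denom == 0.0:
        return 0.0
    return float(np.dot(v1, v2) / denom)


def classify(
    voltages: Union[Mapping, "callable"],
    params: SRM0Params,
    class_targets: Optional[Mapping] = None,
):
    """Choose the class with the smallest summed voltage error.

    For every class ``c`` the score is ``sum_t |theta - u(t)|`` over its
    target times; the label with the minimum score wins, ties broken by
    class order (sorted labels).  ``voltages`` is either a mapping
    ``label -> sequence of u values`` (one per target time of that
    class), or a callable ``u(t)`` used together with ``class_targets``
    (``label -> target times``).
    """
    if callable(voltages):
        if class_targets is None:
            raise ValueError("a callable voltage needs class_targets")
        u_by_class = {
            c: [voltages(float(t)) for t in np.atleast_1d(times)]
            for c, times in class_targets.items()
        }
    else:
        u_by_class = voltages
    best_label = None
    best_score = math.inf
    for label in sorted(u_by_class):
        score = float(sum(abs(params.theta - u) for u in u_by_class[label]))
        if score < best_score:
            best_score = score
            best_label = label
    return best_label


def accuracy(predictions: Sequence, labels: Sequence) -> float:
    """Fraction of agreeing entries."""
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must have equal length")
    if not len(predictions):
        raise ValueError("cannot score an empty prediction set")
    return float(np.mean([p == l for p, l in zip(predictions, labels)]))


def epochs_to_convergence(report) -> int:
    """First epoch count after which the criterion held to the end.

    ``report`` is a :class:`nsebp.trainer.ErrorReport` (or anything with
    a ``criterion_history`` evaluated after 0, 1, 2, ... training
    epochs).  Returns :data:`NOT_CONVERGED` if the criterion never held
    through the end of the history.
    """
    hist = list(report.criterion_history)
    if not hist:
        raise ValueError("empty report")
    epoch = NOT_CONVERGED
    for i in range(len(hist) - 1, -1, -1):
        if hist[i]:
            epoch = i
        else:
            break
    return epoch
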