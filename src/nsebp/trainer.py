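"""Normalized voltage-error backpropagation (NSEBP) for SRM0 networks.

The trainer drives the postsynaptic voltage at instructor-given target
times to the firing threshold.  The error ``err = theta - u(t_d)`` is
split by a normalized factor ``r`` between the current layer (closed
form, rate-free weight updates through the normalized PSP learning
window) and the previous layers (presynaptic spike jitter: each
influential presynaptic spike is assigned a share of the voltage error
and the time shift realizing that share is solved in closed form; the
jittered times become the previous layer's target times).  Absent
interference between targets, one visit drives ``u(t_d)`` exactly to
threshold; with interference the same visit schedule is iterated over
epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .feedforward import simulate_network
from .srm0 import (
    SRM0Params,
    epsilon_kernel,
    influence_window,
    psp_window,
    refractory_kernel,
)

__all__ = [
    "LayerWeights",
    "TargetSpec",
    "TrainConfig",
    "ErrorReport",
    "ZeroWeightError",
    "voltage_error",
    "allocate_error",
    "influential_spikes",
    "jitter_shares",
    "clamp_delta_u",
    "solve_jitter",
    "weight_shares",
    "weight_update",
    "add_spikes",
    "valid_target",
    "train_target",
    "fit",
    "output_voltage",
    "init_weights",
    "target_voltage",
]

#: relative margin used when clamping onto an open feasibility bound
_OPEN_BOUND_MARGIN = 1e-9


class ZeroWeightError(ValueError):
    """Raised by :func:`solve_jitter` for a zero-weight spike (skip it)."""


@dataclass
class LayerWeights:
    """Dense pre x post weight matrix with an optional binary mask.

    Masked-out entries are forced to exactly 0 at construction and are
    never updated.
    """

    matrix: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("weight matrix must be 2-D (pre x post)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.matrix.shape:
                raise ValueError("mask shape must match the weight matrix")
            self.matrix[~self.mask] = 0.0

    @property
    def n_pre(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_post(self) -> int:
        return self.matrix.shape[1]

    def connected(self, post: int) -> np.ndarray:
        """Indices of presynaptic neurons wired to ``post``."""
        if self.mask is None:
            return np.arange(self.n_pre)
        return np.flatnonzero(self.mask[:, post])

    def copy(self) -> "LayerWeights":
        return LayerWeights(
            self.matrix.copy(), None if self.mask is None else self.mask.copy()
        )


@dataclass
class TargetSpec:
    """Per output neuron, the sorted target spike times (ms)."""

    times_by_neuron: Dict[int, np.ndarray]

    def __post_init__(self) -> None:
        self.times_by_neuron = {
            int(k): np.sort(np.asarray(v, dtype=float))
            for k, v in self.times_by_neuron.items()
        }

    def items(self):
        return sorted(self.times_by_neuron.items())


@dataclass
class TrainConfig:
    """Knobs of the training loop.

    ``r`` is the fraction of the voltage error assigned to the layer
    currently visited; ``None`` selects the balanced default ``1/n``
    for ``n`` trainable layers.  ``S`` is the number of spikes inserted
    when no presynaptic spike falls in the influence window.  ``tol``
    is the per-visit no-op threshold on ``|err|``; ``convergence_tol``
    (default ``1e-3 * theta``) is the spike-train-task convergence
    criterion.
    """

    r: Optional[float] = None
    S: int = 1
    max_epochs: int = 100
    tol: float = 1e-9
    convergence_tol: Optional[float] = None
    seed: int = 0
    #: ms; an output spike closer than this to the target is treated as
    #: the target spike itself and excluded from the refractory term
    refractory_guard: float = 2.0

    def __post_init__(self) -> None:
        if self.r is not None and not 0.0 < self.r <= 1.0:
            raise ValueError(f"r must lie in (0, 1], got {self.r}")
        if self.S < 1:
            raise ValueError("S must be >= 1")


@dataclass
class ErrorReport:
    """Per-visit errors plus per-epoch convergence accounting."""

    rows: List[Tuple[int, int, int, float, float]] = field(default_factory=list)
    #: criterion evaluated after k training epochs, k = 0, 1, ...
    criterion_history: List[bool] = field(default_factory=list)
    accuracy_history: List[float] = field(default_factory=list)
    converged: bool = False
    epochs: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.rows, columns=["epoch", "pattern", "neuron", "t_d", "err"]
        )


# ---------------------------------------------------------------------------
# elementary operations


def voltage_error(u_td: float, params: SRM0Params) -> float:
    """``err = theta - u(t_d)``; positive error drives weight increase."""
    return params.theta - u_td


def allocate_error(err: float, cfg) -> Tuple[float, float]:
    """Split ``err`` into (current-layer, previous-layers) shares.

    ``err_w = r*err`` and ``err_t = (1 - r)*err``; their sum is exactly
    ``err``.  ``cfg`` may be a :class:`TrainConfig` or a bare ``r``.
    """
    r = cfg.r if hasattr(cfg, "r") else float(cfg)
    if r is None:
        raise ValueError("allocate_error needs a resolved r")
    err_w = r * err
    return err_w, err - err_w


def influential_spikes(
    pre_spikes, t_d: float, params: SRM0Params
) -> np.ndarray:
    """Subset of ``(time, weight, source)`` rows inside the influence window.

    A spike participates in training iff its lag ``t_d - t`` satisfies
    ``eps(lag) > theta_v``, i.e. lies strictly inside ``(s_lo, s_hi)``.
    """
    arr = np.asarray(pre_spikes, dtype=float).reshape(-1, 3)
    if not arr.size:
        return arr
    s_lo, s_hi = influence_window(params)
    lag = t_d - arr[:, 0]
    keep = (lag > s_lo) & (lag < s_hi)
    return arr[keep]


def jitter_shares(subset, t_d: float, err: float, params: SRM0Params) -> np.ndarray:
    """Normalized error shares for the spike-jitter path.

    For ``err > 0`` spikes far from the learning-window peak carry more
    of the error (``A1 - W_ind`` weighting, as the rule is defined);
    for ``err < 0`` the shares follow ``W_ind`` itself.  Shares always
    sum to 1; a degenerate zero denominator falls back to uniform.
    """
    arr = np.asarray(subset, dtype=float).reshape(-1, 3)
    if not len(arr):
        raise ValueError("jitter_shares needs a non-empty subset")
    wind = np.atleast_1d(psp_window(t_d - arr[:, 0], params))
    raw = (params.A1 - wind) if err > 0 else wind
    total = raw.sum()
    if total <= 0:
        return np.full(len(arr), 1.0 / len(arr))
    return raw / total


def weight_shares(subset, t_d: float, params: SRM0Params) -> np.ndarray:
    """Normalized learning-window shares ``W_ind(s_j) / sum_k W_ind(s_k)``."""
    arr = np.asarray(subset, dtype=float).reshape(-1, 3)
    if not len(arr):
        raise ValueError("weight_shares needs a non-empty subset")
    wind = np.atleast_1d(psp_window(t_d - arr[:, 0], params))
    total = wind.sum()
    if total <= 0:
        return np.full(len(arr), 1.0 / len(arr))
    return wind / total


def clamp_delta_u(delta_u: float, w: float, lag: float, params: SRM0Params) -> float:
    """Clamp a requested voltage change into the jitter feasibility interval.

    For ``w > 0`` the realizable change is ``(-w*eps, (1/4 - eps)*w]``
    (mirrored for ``w < 0``): the spike cannot contribute less than
    nothing nor more than the kernel peak.  Open bounds are approached
    with a tiny relative margin so the solved jitter stays finite.
    """
    if w == 0.0:
        raise ZeroWeightError("zero-weight spike cannot realize a voltage change")
    eps = epsilon_kernel(lag, params)
    lo_open = -w * eps  # eps_new -> 0
    hi_closed = (0.25 - eps) * w  # eps_new -> kernel peak
    if w > 0:
        lo = lo_open + abs(w) * max(eps, 1e-12) * _OPEN_BOUND_MARGIN
        return float(min(max(delta_u, lo), hi_closed))
    hi = lo_open - abs(w) * max(eps, 1e-12) * _OPEN_BOUND_MARGIN
    return float(max(min(delta_u, hi), hi_closed))


def solve_jitter(
    delta_u: float, w: float, t_pre: float, t_d: float, params: SRM0Params
) -> float:
    """Presynaptic time shift realizing a voltage change at ``t_d``.

    Solves ``w * eps(t_d - t_pre - dt) = w * eps(t_d - t_pre) + delta_u``
    as a quadratic in ``z = exp(dt/tau1)`` with coefficients

    ``a = -w exp((t_pre - t_d)/tau2)``,
    ``b =  w exp((t_pre - t_d)/tau1)``,
    ``c = -a - b - delta_u``,

    keeping positive roots and returning the shift with the minimum
    absolute value (ties broken toward the delaying, positive shift).
    ``delta_u`` is clamped to the feasibility interval first.
    """
    w = float(w)
    if w == 0.0:
        raise ZeroWeightError("zero-weight spike cannot be jittered")
    lag = float(t_d) - float(t_pre)
    du = clamp_delta_u(float(delta_u), w, lag, params)
    e1 = math.exp(-lag / params.tau1)
    e2 = math.exp(-lag / params.tau2)
    a = -w * e2
    b = w * e1
    c = -a - b - du
    disc = b * b - 4.0 * a * c
    if not math.isfinite(disc):
        raise ValueError("jitter quadratic overflow (runaway weight)")
    if disc < 0.0:
        if disc < -1e-9 * max(b * b, 1.0):
            raise ValueError("infeasible jitter after clamping (negative discriminant)")
        disc = 0.0
    sq = math.sqrt(disc)
    best: Optional[float] = None
    for sign in (+1.0, -1.0):
        z = (-b + sign * sq) / (2.0 * a)
        if z <= 0.0:
            continue
        dt = params.tau1 * math.log(z)
        if (
            best is None
            or abs(dt) < abs(best)
            or (abs(dt) == abs(best) and dt > best)
        ):
            best = dt
    if best is None:
        raise ValueError("no positive root for the jitter quadratic")
    return best


def weight_update(subset, err_w: float, t_d: float, params: SRM0Params) -> np.ndarray:
    """Per-spike weight increments ``dw_j = gamma_j * err_w / eps_j``.

    Applying all increments changes ``u(t_d)`` by exactly ``err_w``
    since ``sum_j eps_j * dw_j = err_w * sum_j gamma_j = err_w``.
    """
    arr = np.asarray(subset, dtype=float).reshape(-1, 3)
    if not len(arr):
        raise ValueError("weight_update needs a non-empty subset")
    gamma = weight_shares(arr, t_d, params)
    eps = np.atleast_1d(epsilon_kernel(t_d - arr[:, 0], params))
    return gamma * err_w / eps


def add_spikes(
    hidden_spike_counts: Sequence[int],
    window: Tuple[float, float],
    S: int,
    rng: np.random.Generator,
) -> List[Tuple[int, float]]:
    """Insert ``S`` spikes on sparsely firing neurons inside ``window``.

    Neuron ``i`` is drawn with probability proportional to ``1/n_i``
    (``n_i = 0.5`` for silent neurons), so quiet neurons are recruited
    preferentially; each placement time is uniform in the window.
    """
    counts = np.asarray(hidden_spike_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("add_spikes needs at least one candidate neuron")
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"empty placement window ({lo}, {hi})")
    inv = 1.0 / np.where(counts > 0, counts, 0.5)
    p = inv / inv.sum()
    neurons = rng.choice(counts.size, size=S, p=p)
    times = rng.uniform(lo, hi, size=S)
    return [(int(n), float(t)) for n, t in zip(neurons, times)]


def valid_target(
    t_d: float,
    input_spikes,
    n_layers: int,
    mode: str,
    params: SRM0Params,
) -> bool:
    """Reachability check for a candidate target time.

    ``traditional`` requires an input spike within the causal reach of
    rising PSP fronts chained over ``n - 1`` layers, i.e. in
    ``[t_d - (n-1)*tau1*ln2, t_d)``.  ``nsebp`` only needs any input
    spike in ``[0, t_d)``.  ``nsebp-windowed`` applies the per-layer
    influence-window delay: some input lag must lie in
    ``[L*s_lo, L*s_hi]`` for a traversed-layer count ``L <= n``.
    """
    if t_d <= 0:
        raise ValueError("target times must be positive")
    times = np.asarray(input_spikes, dtype=float).ravel()
    if not times.size:
        return False
    if mode == "traditional":
        reach = (n_layers - 1) * params.peak_lag
        return bool(np.any((times >= t_d - reach) & (times < t_d)))
    if mode == "nsebp":
        return bool(np.any((times >= 0.0) & (times < t_d)))
    if mode == "nsebp-windowed":
        s_lo, s_hi = influence_window(params)
        lags = t_d - times
        for depth in range(1, n_layers + 1):
            if np.any((lags >= depth * s_lo) & (lags <= depth * s_hi)):
                return True
        return False
    raise ValueError(f"unknown target-validity mode {mode!r}")


# ---------------------------------------------------------------------------
# layer visits and the training loop


def mean_window_kernel(params: SRM0Params) -> float:
    """Average PSP-kernel value over the influence window.

    ``(1/(s_hi - s_lo)) * int eps(s) ds`` with the antiderivative
    ``-tau1 e^{-s/tau1} + tau2 e^{-s/tau2}``; the natural kernel scale
    of one influential spike (~0.17 for theta_v = 0.05).
    """
    s_lo, s_hi = influence_window(params)

    def anti(s: float) -> float:
        return -params.tau1 * math.exp(-s / params.tau1) + params.tau2 * math.exp(
            -s / params.tau2
        )

    return (anti(s_hi) - anti(s_lo)) / (s_hi - s_lo)


def init_weights(
    n_pre: int,
    n_post: int,
    params: SRM0Params,
    rng: np.random.Generator,
    mask: Optional[np.ndarray] = None,
) -> LayerWeights:
    """Random uniform initialization on ``[0, 2*theta/F_eff]``.

    ``F_eff = F * eps_bar`` is the fan-in F expressed in kernel units
    (``eps_bar`` = mean kernel value over the influence window), so a
    neuron receiving one influential spike per afferent starts with
    ``u`` near threshold: it fires from the first epoch at diverse
    times and both error signs occur during training.
    """
    w = np.zeros((n_pre, n_post))
    if mask is None:
        fan_in = np.full(n_post, n_pre, dtype=float)
        sel = np.ones((n_pre, n_post), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        fan_in = np.maximum(mask.sum(axis=0), 1).astype(float)
        sel = mask
    hi = 2.0 * params.theta / (fan_in * mean_window_kernel(params))
    draw = rng.uniform(0.0, 1.0, size=(n_pre, n_post)) * hi[None, :]
    w[sel] = draw[sel]
    return LayerWeights(w, mask)


def _gather_pre_spikes(
    weights: LayerWeights, pre_activity: Sequence[np.ndarray], post: int
) -> np.ndarray:
    """Rows (time, weight, source) for all connected presynaptic spikes."""
    rows = []
    for p in weights.connected(post):
        times = np.asarray(pre_activity[p], dtype=float)
        if times.size:
            w = weights.matrix[p, post]
            rows.append(
                np.column_stack(
                    [times, np.full(times.size, w), np.full(times.size, float(p))]
                )
            )
    if not rows:
        return np.empty((0, 3))
    arr = np.vstack(rows)
    return arr[np.argsort(arr[:, 0], kind="stable")]


def target_voltage(
    weights: LayerWeights,
    pre_activity: Sequence[np.ndarray],
    post: int,
    t_d: float,
    params: SRM0Params,
) -> float:
    """Weighted PSP sum at ``t_d`` (refractory term excluded).

    This is the voltage the feedback pass and the decision rule use:
    the training derivations treat ``u(t_d)`` as the weighted sum of
    input-spike kernels, while the forward simulation additionally
    carries the refractory reset.
    """
    arr = _gather_pre_spikes(weights, pre_activity, post)
    if not arr.size:
        return params.u_ext
    return params.u_ext + float(
        np.dot(arr[:, 1], np.atleast_1d(epsilon_kernel(t_d - arr[:, 0], params)))
    )


def output_voltage(
    weights: LayerWeights,
    pre_activity: Sequence[np.ndarray],
    own_spikes: np.ndarray,
    post: int,
    t_d: float,
    params: SRM0Params,
    guard: float = 2.0,
) -> float:
    """Full SRM voltage at ``t_d``: PSP sum plus the guarded refractory.

    The refractory term comes from the neuron's last simulated spike at
    least ``guard`` ms before ``t_d``: a spike closer than that is the
    (possibly slightly early) realization of the target spike itself,
    and counting its reset against the target voltage would make the
    error jump by ``A2`` exactly at the solution.  This is the voltage
    the training error and the class decision rule share.
    """
    u = target_voltage(weights, pre_activity, post, t_d, params)
    own = np.asarray(own_spikes, dtype=float)
    before = own[own < t_d - guard]
    if before.size:
        u += refractory_kernel(t_d - float(before[-1]), params)
    return float(u)


def train_target(
    layers: Sequence[LayerWeights],
    activities: Sequence[Sequence[np.ndarray]],
    post_layer: int,
    neuron: int,
    t_d: float,
    r_eff: float,
    cfg: TrainConfig,
    params: SRM0Params,
    rng: np.random.Generator,
    include_refractory: bool = False,
) -> Tuple[float, Dict[int, List[float]]]:
    """One feedback visit of a single target time.

    Measures ``err = theta - u(t_d)`` from the presynaptic activity of
    layer ``post_layer`` (index 1 = first hidden layer's activity);
    when ``|err|`` exceeds the tolerance, applies the jitter pass with
    share ``1 - r_eff`` (returning the jittered times as previous-layer
    targets) and the normalized weight update with share ``r_eff`` to
    the incoming weights of ``neuron``.  If no presynaptic spike falls
    in the influence window and the previous layer is hidden, spikes
    are inserted first (and also returned as previous-layer targets).

    ``include_refractory`` adds the neuron's own guarded refractory
    term (see :func:`output_voltage`) to the measured voltage.  The
    training loop enables it for output-layer visits, where it makes
    the error the same quantity the decision rule scores and lets the
    pattern's own firing history disambiguate otherwise collinear
    target voltages; hidden-layer visits stay refractory-free (their
    targets track small shifts of existing crossings).

    Returns ``(err, previous_layer_targets)``.
    """
    if t_d <= 0:
        raise ValueError("target times must be positive")
    weights = layers[post_layer - 1]
    pre_activity = activities[post_layer - 1]
    spikes = _gather_pre_spikes(weights, pre_activity, neuron)
    u = params.u_ext
    if spikes.size:
        u += float(
            np.dot(spikes[:, 1], np.atleast_1d(epsilon_kernel(t_d - spikes[:, 0], params)))
        )
    if include_refractory and post_layer < len(activities):
        own = np.asarray(activities[post_layer][neuron], dtype=float)
        before = own[own < t_d - cfg.refractory_guard]
        if before.size:
            u += refractory_kernel(t_d - float(before[-1]), params)
    err = voltage_error(u, params)
    prev_targets: Dict[int, List[float]] = {}
    if abs(err) <= cfg.tol:
        return err, prev_targets

    subset = influential_spikes(spikes, t_d, params)
    s_lo, s_hi = influence_window(params)
    if not len(subset) and post_layer - 1 >= 1:
        lo = max(0.0, t_d - s_hi)
        hi = t_d - s_lo
        if lo < hi:
            conn = weights.connected(neuron)
            counts = [len(pre_activity[p]) for p in conn]
            placements = add_spikes(counts, (lo, hi), cfg.S, rng)
            extra = []
            for local_idx, t in placements:
                p = int(conn[local_idx])
                prev_targets.setdefault(p, []).append(t)
                extra.append([t, weights.matrix[p, neuron], float(p)])
            if extra:
                subset = np.vstack([subset.reshape(-1, 3), np.asarray(extra)])
    if not len(subset):
        return err, prev_targets

    if r_eff < 1.0:
        gamma_t = jitter_shares(subset, t_d, err, params)
        err_t = (1.0 - r_eff) * err
        for j in range(len(subset)):
            t_pre, w, src = subset[j]
            if w == 0.0:
                continue
            try:
                dt = solve_jitter(gamma_t[j] * err_t, w, t_pre, t_d, params)
            except (ZeroWeightError, ValueError):
                continue
            t_new = t_pre + dt
            if t_new > 0.0:
                prev_targets.setdefault(int(src), []).append(float(t_new))

    dw = weight_update(subset, r_eff * err, t_d, params)
    for j in range(len(subset)):
        p = int(subset[j, 2])
        weights.matrix[p, neuron] += dw[j]
    return err, prev_targets


def _layer_r(post_layer: int, n_layers: int, cfg: TrainConfig) -> float:
    """Error fraction kept by the layer currently visited.

    The output layer uses the configured ``r`` (default ``1/n``);
    deeper visits split their residual evenly over the layers still to
    come, and a layer fed directly by the input layer keeps everything
    (input spikes are never jittered).
    """
    if post_layer == 1:
        return 1.0
    k = n_layers - post_layer + 1  # 1 at the output layer
    if k == 1 and cfg.r is not None:
        return cfg.r
    return 1.0 / (n_layers - k + 1)


def _train_pattern(
    layers: Sequence[LayerWeights],
    activities,
    targets: TargetSpec,
    cfg: TrainConfig,
    params: SRM0Params,
    rng: np.random.Generator,
    record,
) -> None:
    n_layers = len(layers)
    out_layer = n_layers
    for neuron, times in targets.items():
        for t_d in times:
            _visit(layers, activities, out_layer, neuron, float(t_d), cfg, params, rng, record)


def _visit(layers, activities, li, neuron, t_d, cfg, params, rng, record) -> None:
    err, prev = train_target(
        layers, activities, li, neuron, t_d, _layer_r(li, len(layers), cfg), cfg, params, rng,
        include_refractory=li == len(layers),
    )
    record(li, neuron, t_d, err)
    if li - 1 < 1:
        return
    min_input = min(
        (float(t[0]) for t in activities[0] if len(t)), default=None
    )
    for p, times in sorted(prev.items()):
        ts = sorted(t for t in times if min_input is not None and t > min_input)
        if not ts:
            continue  # unreachable targets for the previous layer
        # one target per presynaptic neuron per visit (the median jittered
        # time): conflicting same-visit constraints on one weight row
        # would otherwise overwrite each other
        if len(ts) > 1:
            ts = [ts[len(ts) // 2]]
        for t in ts:
            _visit(layers, activities, li - 1, p, t, cfg, params, rng, record)


def fit(
    layers: Sequence[LayerWeights],
    patterns: Sequence[Tuple[Sequence[np.ndarray], TargetSpec]],
    cfg: TrainConfig,
    params: SRM0Params,
    *,
    class_targets: Optional[Dict] = None,
    labels: Optional[Sequence] = None,
    horizon: Optional[float] = None,
) -> ErrorReport:
    """Layer-wise training loop over a dataset of spike patterns.

    Each pattern is ``(input_trains, TargetSpec)``.  Per epoch, per
    pattern, the network is simulated forward and every target time is
    visited in ascending order at the output layer; jitter-derived
    targets are trained recursively on earlier layers.  Convergence is
    checked before each epoch: with ``class_targets``/``labels`` given
    the criterion is correct classification of every pattern, otherwise
    ``|err| <= convergence_tol`` at every target.  Fully deterministic
    for a given ``cfg.seed``.
    """
    from .evaluation import classify  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    conv_tol = (
        cfg.convergence_tol if cfg.convergence_tol is not None else 1e-3 * params.theta
    )
    if cfg.r is None and len(layers) > 1:
        import dataclasses

        cfg = dataclasses.replace(cfg, r=1.0 / len(layers))
    if horizon is None:
        horizon = 0.0
        for inputs, targets in patterns:
            for t in inputs:
                if len(t):
                    horizon = max(horizon, float(np.max(t)))
            for _, times in targets.items():
                if len(times):
                    horizon = max(horizon, float(np.max(times)))
        if class_targets:
            for times in class_targets.values():
                horizon = max(horizon, float(np.max(times)))
        horizon += params.tau1

    report = ErrorReport()

    def _converged() -> Tuple[bool, float]:
        n_ok = 0
        worst = 0.0
        for idx, (inputs, targets) in enumerate(patterns):
            acts = simulate_network(inputs, layers, params, horizon)
            if class_targets is not None:
                u_by_class = {
                    c: [
                        output_voltage(
                            layers[-1], acts[-2], acts[-1][0], 0, float(t),
                            params, guard=cfg.refractory_guard,
                        )
                        for t in np.atleast_1d(times)
                    ]
                    for c, times in class_targets.items()
                }
                pred = classify(u_by_class, params)
                n_ok += int(pred == labels[idx])
            else:
                for neuron, times in targets.items():
                    for t_d in times:
                        u = output_voltage(
                            layers[-1], acts[-2], acts[-1][neuron], neuron,
                            float(t_d), params, guard=cfg.refractory_guard,
                        )
                        worst = max(worst, abs(params.theta - u))
        if class_targets is not None:
            acc = n_ok / len(patterns)
            return acc == 1.0, acc
        return worst <= conv_tol, worst

    for epoch in range(cfg.max_epochs + 1):
        ok, score = _converged()
        report.criterion_history.append(ok)
        report.accuracy_history.append(score)
        if ok:
            report.converged = True
            report.epochs = epoch
            return report
        if epoch == cfg.max_epochs:
            break
        for p_idx, (inputs, targets) in enumerate(patterns):
            acts = simulate_network(inputs, layers, params, horizon)
            _train_pattern(
                layers,
                acts,
                targets,
                cfg,
                params,
                rng,
                lambda li, nn, td, err, _p=p_idx, _e=epoch: report.rows.append(
                    (_e, _p, nn, td, err)
                ),
            )
    report.converged = False
    report.epochs = cfg.max_epochs
    return report
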