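"""SRM0 neuron-model primitives.

The simplified Spike Response Model (SRM0) drives everything in this
package: the membrane voltage of a neuron is the weighted sum of
double-exponential post-synaptic potential (PSP) kernels evoked by its
presynaptic spikes, plus a refractory kernel anchored at its own last
output spike, plus a constant external voltage::

    u(t) = eta(t - t_out) + sum_j w_j * eps(t - t_j) + u_ext

with the PSP kernel ``eps(s) = [exp(-s/tau1) - exp(-s/tau2)] * H(s)``
and the refractory kernel ``eta(s) = -A2 * exp(-s/tau1)``.  The whole
closed-form machinery of this package (event-driven firing-time solver,
jitter solver, normalized weight updates) rests on the constraint
``tau1 = 2*tau2``, under which the kernel maximum is exactly 1/4 at lag
``tau1*ln 2`` and every threshold-crossing equation reduces to a
quadratic in ``z = exp(-t/tau1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SRM0Params",
    "SpikeTrain",
    "epsilon_kernel",
    "refractory_kernel",
    "psp_window",
    "membrane_potential",
    "influence_window",
    "PEAK_LAG_FACTOR",
]

#: lag of the PSP-kernel maximum, in units of tau1 (valid for tau1 = 2*tau2)
PEAK_LAG_FACTOR = math.log(2.0)


@dataclass(frozen=True)
class SRM0Params:
    """All neuron-model and learning-window constants.

    Parameters
    ----------
    tau1, tau2
        PSP time constants in ms.  ``tau2`` defaults to ``tau1 / 2`` and
        the identity ``tau1 == 2 * tau2`` is enforced: it is the model
        assumption that makes all firing-time equations quadratic.
    theta
        Firing threshold (dimensionless voltage), > 0.
    A1
        Learning-window amplitude (the window is ``A1 * eps``).
    A2
        Refractory amplitude >= 0.  Defaults to ``theta`` (reset by one
        threshold depth) since only positivity is required by the model.
    u_ext
        Constant external voltage; 0 in all closed-form derivations.
    theta_v
        Influence threshold on the PSP kernel: only presynaptic spikes
        with ``eps(lag) > theta_v`` at the target time are trained.
        Must lie in (0, 1/4) because 1/4 is the kernel maximum.
    """

    tau1: float = 5.0
    tau2: Optional[float] = None
    theta: float = 1.0
    A1: float = 1.0
    A2: Optional[float] = None
    u_ext: float = 0.0
    theta_v: float = 0.05

    def __post_init__(self) -> None:
        if self.tau1 <= 0:
            raise ValueError(f"tau1 must be positive, got {self.tau1}")
        if self.tau2 is None:
            object.__setattr__(self, "tau2", self.tau1 / 2.0)
        elif not math.isclose(self.tau1, 2.0 * self.tau2, rel_tol=1e-12):
            raise ValueError(
                f"tau1 = 2*tau2 is required (got tau1={self.tau1}, tau2={self.tau2})"
            )
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.A2 is None:
            object.__setattr__(self, "A2", self.theta)
        elif self.A2 < 0:
            raise ValueError(f"A2 must be >= 0, got {self.A2}")
        if not 0.0 < self.theta_v < 0.25:
            raise ValueError(
                f"theta_v must lie in (0, 1/4), got {self.theta_v} "
                "(1/4 is the kernel maximum under tau1 = 2*tau2)"
            )

    @property
    def peak_lag(self) -> float:
        """Lag (ms) of the PSP-kernel maximum, ``tau1 * ln 2``."""
        return self.tau1 * PEAK_LAG_FACTOR


@dataclass
class SpikeTrain:
    """One neuron's sorted spike times in ms.

    ``times`` must be strictly increasing and non-negative; duplicates
    are forbidden.
    """

    neuron_id: int
    times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be a 1-D sequence")
        if self.times.size:
            if np.any(self.times < 0):
                raise ValueError("spike times must be >= 0")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    def __iter__(self):
        return iter(self.times)


def epsilon_kernel(s, params: SRM0Params):
    """PSP kernel ``eps(s) = [exp(-s/tau1) - exp(-s/tau2)] * H(s)``.

    Total function: returns 0 for negative lags.  Accepts scalars or
    arrays; the result lies in [0, 1/4] for tau1 = 2*tau2.
    """
    s = np.asarray(s, dtype=float)
    with np.errstate(over="ignore"):
        val = np.where(
            s >= 0.0,
            np.exp(-s / params.tau1) - np.exp(-s / params.tau2),
            0.0,
        )
    if val.ndim == 0:
        return float(val)
    return val


def refractory_kernel(s, params: SRM0Params):
    """Refractory kernel ``eta(s) = -A2 * exp(-s/tau1)`` for s >= 0.

    ``s is None`` is the explicit "no previous output spike" sentinel
    and yields exactly 0 (the s -> inf limit).
    """
    if s is None:
        return 0.0
    s = np.asarray(s, dtype=float)
    val = -params.A2 * np.exp(-s / params.tau1)
    if val.ndim == 0:
        return float(val)
    return val


def psp_window(s, params: SRM0Params):
    """Learning window ``W_ind(s) = A1 * eps(s)`` for s >= 0, else 0."""
    return params.A1 * epsilon_kernel(s, params)


def membrane_potential(
    t: float,
    inputs: Sequence[Tuple[float, float]],
    last_out: Optional[float],
    params: SRM0Params,
) -> float:
    """Evaluate u(t) for a set of weighted presynaptic spikes.

    Parameters
    ----------
    t
        Evaluation time, ms.
    inputs
        Sequence of ``(spike_time, weight)`` pairs; may be empty.
    last_out
        Time of the neuron's most recent output spike, or ``None`` for
        the "never fired" sentinel (refractory term exactly 0).
    """
    u = params.u_ext + refractory_kernel(None if last_out is None else t - last_out, params)
    if len(inputs):
        arr = np.asarray(inputs, dtype=float)
        u += float(np.dot(arr[:, 1], epsilon_kernel(t - arr[:, 0], params)))
    return float(u)


def influence_window(params: SRM0Params) -> Tuple[float, float]:
    """Lag interval (s_lo, s_hi) on which ``eps(s) > theta_v``.

    Solving ``eps(s) = theta_v`` with ``z = exp(-s/tau1)`` gives
    ``z - z**2 = theta_v``, hence ``z = (1 +- sqrt(1 - 4*theta_v))/2``
    and ``s = -tau1 * ln z``.  The larger z root yields the earlier lag.
    """
    disc = 1.0 - 4.0 * params.theta_v
    if disc <= 0.0:
        raise ValueError(
            f"influence window is empty: theta_v={params.theta_v} >= 1/4"
        )
    root = math.sqrt(disc)
    s_lo = -params.tau1 * math.log((1.0 + root) / 2.0)
    s_hi = -params.tau1 * math.log((1.0 - root) / 2.0)
    return s_lo, s_hi
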