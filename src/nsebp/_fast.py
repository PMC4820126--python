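"""Compiled inner loops for the two forward-pass engines.

Both functions operate on a merged, time-sorted train of weighted
presynaptic spikes for a single postsynaptic SRM0 neuron and return the
output spike times together with an operation counter.

The event-driven engine solves the threshold-crossing quadratic once
per inter-input-spike interval; the grid engine ("traditional" precise
time scan) evaluates the voltage at every grid point.  To keep the
exponentials bounded, both maintain running accumulators relative to
the current time: moving the reference from t to t' multiplies an
accumulator with time constant tau by exp(-(t'-t)/tau), which is
algebraically identical to the textbook sums a = sum w*exp(t_m/tau2),
b = sum w*exp(t_m/tau1) - A2*exp(t_hat/tau1).
"""

import numpy as np
from numba import njit

# hard cap on output spikes per simulation; hit only by runaway
# configurations (e.g. A2 = 0 with a permanently super-threshold drive)
MAX_OUT = 2_000_000


@njit(cache=False)
def event_times(times, weights, tau1, tau2, theta, a2, horizon, one_per_interval):
    """Event-driven forward pass. Returns (out_times, n_solve_ops)."""
    n = times.shape[0]
    out = np.empty(256, dtype=np.float64)
    n_out = 0
    ops = 0
    # accumulators relative to the current interval start t_ref
    acc_a = 0.0  # sum w * exp((t_m - t_ref)/tau2)
    acc_b = 0.0  # sum w * exp((t_m - t_ref)/tau1)
    t_ref = 0.0
    have_out = False
    t_last_out = 0.0
    j = 0
    while j < n:
        t_a = times[j]
        # decay accumulators to the new interval start
        acc_a *= np.exp(-(t_a - t_ref) / tau2)
        acc_b *= np.exp(-(t_a - t_ref) / tau1)
        t_ref = t_a
        # absorb every spike at exactly t_a (merged trains may collide)
        while j < n and times[j] == t_a:
            acc_a += weights[j]
            acc_b += weights[j]
            j += 1
        t_b = horizon if j >= n else times[j]
        if t_b <= t_a:
            continue
        # solve repeatedly inside [t_a, t_b): each emission resets the
        # refractory term, so re-solve the remainder of the interval
        t_lo = t_a
        while True:
            ops += 1
            b = acc_b
            if have_out:
                b -= a2 * np.exp((t_last_out - t_ref) / tau1)
            a = acc_a
            if a == 0.0:
                break
            disc = b * b - 4.0 * a * theta
            if disc < 0.0:
                if disc > -1e-12:
                    disc = 0.0  # tangency tolerance
                else:
                    break
            sq = np.sqrt(disc)
            # roots in z' = exp(-(t - t_ref)/tau1); t = t_ref - tau1*ln z'
            z_hi = np.exp(-(t_lo - t_ref) / tau1)   # t >= t_lo
            z_lo = np.exp(-(t_b - t_ref) / tau1)    # t <  t_b
            best = -1.0
            for sign in (-1.0, 1.0):
                z = (b + sign * sq) / (2.0 * a)
                # earliest time <-> largest z inside (z_lo, z_hi]
                if z_lo < z <= z_hi and z > best:
                    best = z
            # strict t > t_last_out so an emission is never re-found
            if have_out and best > 0.0:
                if t_ref - tau1 * np.log(best) <= t_last_out:
                    best = -1.0
            if best <= 0.0:
                break
            t_out = t_ref - tau1 * np.log(best)
            if t_out < t_a:
                t_out = t_a
            if n_out >= out.shape[0]:
                grown = np.empty(out.shape[0] * 2, dtype=np.float64)
                grown[: n_out] = out[: n_out]
                out = grown
            if n_out >= MAX_OUT:
                break
            out[n_out] = t_out
            n_out += 1
            have_out = True
            t_last_out = t_out
            t_lo = t_out
            if one_per_interval:
                break
            if a2 == 0.0:
                break  # no reset: the same root would recur forever
    return out[:n_out].copy(), ops


@njit(cache=False)
def max_drive(times, weights, tau1, tau2, horizon, dt):
    """Maximum of the pure PSP drive (no reset) on a grid of step dt."""
    n = times.shape[0]
    n_steps = int(np.floor(horizon / dt)) + 1
    d1 = np.exp(-dt / tau1)
    d2 = np.exp(-dt / tau2)
    e1 = 0.0
    e2 = 0.0
    k = 0
    best = 0.0
    for step in range(n_steps):
        t_g = step * dt
        if step > 0:
            e1 *= d1
            e2 *= d2
        while k < n and times[k] <= t_g:
            e1 += weights[k] * np.exp(-(t_g - times[k]) / tau1)
            e2 += weights[k] * np.exp(-(t_g - times[k]) / tau2)
            k += 1
        u = e1 - e2
        if u > best:
            best = u
    return best


@njit(cache=False)
def grid_times(times, weights, tau1, tau2, theta, a2, horizon, dt):
    """Time-stepped forward pass on a grid of step dt.

    Emits a spike at the first grid point where u >= theta, then resets
    the refractory term.  Returns (out_times, n_grid_ops).
    """
    n = times.shape[0]
    n_steps = int(np.floor(horizon / dt)) + 1
    out = np.empty(256, dtype=np.float64)
    n_out = 0
    d1 = np.exp(-dt / tau1)
    d2 = np.exp(-dt / tau2)
    e1 = 0.0  # sum w * exp(-(t_g - t_m)/tau1) over t_m <= t_g
    e2 = 0.0
    r = 0.0   # refractory term, -A2 at an emission then decaying
    k = 0
    ops = 0
    t_g = 0.0
    for step in range(n_steps):
        t_g = step * dt
        if step > 0:
            e1 *= d1
            e2 *= d2
            r *= d1
        while k < n and times[k] <= t_g:
            e1 += weights[k] * np.exp(-(t_g - times[k]) / tau1)
            e2 += weights[k] * np.exp(-(t_g - times[k]) / tau2)
            k += 1
        ops += 1
        u = e1 - e2 + r
        if u >= theta:
            if n_out >= out.shape[0]:
                grown = np.empty(out.shape[0] * 2, dtype=np.float64)
                grown[: n_out] = out[: n_out]
                out = grown
            if n_out >= MAX_OUT:
                break
            out[n_out] = t_g
            n_out += 1
            r = -a2
    return out[:n_out].copy(), ops
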