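# Methods

## Model

All neurons are SRM0 units: the membrane voltage is a weighted sum of
postsynaptic-potential (PSP) kernels `eps(s) = e^{-s/tau1} - e^{-s/tau2}`
(gated to `s >= 0`) evoked by presynaptic spikes, plus a refractory
kernel `eta(s) = -A2 e^{-s/tau1}` anchored at the neuron's most recent
output spike, plus a constant external voltage (0 throughout).  A spike
is emitted whenever the voltage reaches the threshold `theta` from
below.  The package enforces `tau1 = 2*tau2` at construction: under
this constraint the kernel maximum is exactly 1/4 at lag `tau1*ln 2`,
and every threshold-crossing and spike-jitter equation reduces to a
quadratic in an exponential substitution — the closed forms the whole
package is built on.

Times are milliseconds, continuous, measured from stimulus onset.
"No previous output spike" is an explicit sentinel (refractory term
exactly 0), never a large negative time.

### Well-posedness of the reset

If the pure synaptic drive `sum w_j eps(t - t_j)` exceeds
`theta + A2`, the reset cannot pull the voltage back below threshold
and the continuous-time model fires at an unbounded rate; the
event-driven solver then produces an accumulation point of spike times
and no time discretization can agree with it.  Every experiment in
this package therefore keeps its drive below that bound: the Poisson
equivalence benchmark rescales each neuron's afferent weights so the
peak drive is at most `0.9*(theta + A2)` (measured on a 0.05 ms grid),
and the training benchmarks use a deep reset (below).  This is a
property of the model, not of the solver; the voltage threshold is
simply not a rate bound once the reset is exceeded.

## Forward pass

Between two consecutive input-spike times the voltage is a fixed
linear combination of `e^{-t/tau1}` and `e^{-t/tau2}`, so the
crossing times of `theta` are roots of `a z^2 - b z + theta = 0` with
`z = e^{-t/tau1}`; `a` and `b` accumulate `w_m e^{t_m/tau2}` and
`w_m e^{t_m/tau1} - A2 e^{t_hat/tau1}` over all spikes at or before
the interval start.  Numerically the accumulators are kept relative to
the current interval start (each move multiplies them by a decaying
exponential), which is algebraically identical but bounded.  Within an
interval the earliest in-window root is emitted, the refractory
coefficient is updated, and the remainder of the interval is re-solved
(the model allows several spikes per interval; a strict
one-per-interval mode exists as an option).  A discriminant in
`(-1e-12, 0)` is treated as an exact tangency.

The reference simulator (`oracle_simulate`) scans the voltage on a
fixed grid and fires at the first grid point with `u >= theta`.  It is
deliberately independent of the event-driven path — incremental decay
recurrences over grid points rather than interval algebra — and serves
as the equivalence oracle in the tests.  Both inner loops are compiled
with numba.

The forward-equivalence study uses the 50-input Poisson benchmark with
drive-conditioned random weights across rates 10–1000 Hz and lengths
200–2800 ms.  The full matrix with 100 hidden neurons, 20 realizations
per cell, runs in a few minutes; the shipped acceptance test uses the
same rate x length matrix with 30 hidden neurons and 2 realizations
per cell (about a minute), sizes chosen to keep the default test run
short.  Observed agreement: every spike matched one-to-one within
1e-2 ms (the grid scan localizes near-tangent crossings a few grid
steps late, which bounds the agreement) and measure C = 1 to four
decimals at 1 ms resolution.

## Feedback pass

At a target time `t_d` of an output neuron the error is
`err = theta - u(t_d)`.  Only *influential* presynaptic spikes are
trained: those whose lag to `t_d` lies strictly inside the influence
window where `eps > theta_v` (solved in closed form:
`s = -tau1 ln((1 ± sqrt(1-4*theta_v))/2)`).  The error is split by
`r` (default `1/n` for `n` trainable layers):

* weight share `r*err`: increments `dw_j = gamma_j r err / eps_j`
  with `gamma_j` the normalized learning-window shares.  Since
  `sum gamma_j = 1`, applying all increments changes `u(t_d)` by
  exactly `r*err` — an identity the tests verify to 1e-9.
* jitter share `(1-r)*err`: each influential spike is assigned a
  voltage share (for positive errors weighted toward far-from-peak
  spikes, as the rule is defined; for negative errors by the window
  itself), the realizing time shift is solved from the jitter
  quadratic (minimum-|shift| positive root convention, ties toward
  delay), and the jittered times become target times for the
  previous layer.  Requests outside the feasibility interval
  (`(-w*eps, (1/4 - eps)*w]` for `w > 0`, mirrored for `w < 0`) are
  clamped to the boundary, which maps to the kernel-peak lag.

A layer fed directly by the input layer keeps the whole error for its
weights (`r = 1`, one exact visit per target): input spikes are data
and cannot be jittered.  If no presynaptic spike falls inside the
influence window and the presynaptic layer is hidden, `S` spikes
(default 1) are inserted on neurons drawn with probability
proportional to `1/n_i` (`n_i = 0.5` for silent neurons, favouring
quiet units) at uniform positions in the window; the insertions join
the current update and become previous-layer targets.

### Voltage conventions (a deliberate asymmetry)

Hidden-layer visits measure `u(t_d)` as the bare weighted PSP sum:
their targets track small shifts of existing threshold crossings, and
budgeting the neuron's own reset against a target right after its
spike would demand unbounded weight growth.

Output-layer visits and the class-decision rule use the full SRM
voltage including the neuron's own refractory term, with one guard:
output spikes within `refractory_guard` (default 2 ms) before `t_d`
are treated as the — slightly early — realization of the target spike
itself and excluded, because counting their reset makes the error jump
by `A2` exactly at the solution.  The refractory term matters here:
with a single output neuron and two class target times, the bare PSP
sums at the two targets are nearly proportional for every pattern
(hidden spikes all precede the drive peak), so the per-class
constraints are jointly unsatisfiable; the reset contribution depends
on when the pattern actually made the output fire, which breaks the
collinearity and is what lets one output unit separate the classes.

### Visit schedule and stabilizer

Per epoch, per pattern (dataset order): simulate forward, visit the
pattern's target times in ascending order at the output layer, then
recursively train each previous layer on the jitter-derived targets
using the same forward snapshot.  From the jittered times of one
presynaptic neuron, only the median is kept as that neuron's target
for the visit — several same-visit constraints on one weight row would
overwrite each other and demonstrably slow convergence.  Derived
targets earlier than the first input spike are unreachable and
dropped.  All randomness (insertions, initialization) flows from one
seeded generator; repeated runs are bit-identical.

Convergence is evaluated before every training epoch: classification
tasks require every training pattern correct (so
`epochs_to_convergence` counts completed training epochs);
spike-train tasks require `|err| <= 1e-3*theta` at every target.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `tau1` (`tau2 = tau1/2`) | 5 | ms | PSP time constants; kernel peak at `tau1 ln 2` |
| `theta` | 1 | – | firing threshold |
| `A1` | 1 | – | learning-window amplitude |
| `A2` | `theta` | – | refractory depth; XOR study uses `8*theta` |
| `theta_v` | 0.05 | – | influence threshold, must be < 1/4 |
| `r` | `1/n` | – | error share kept by the visited layer (XOR: 0.5) |
| `S` | 1 | – | spikes inserted on an empty influence window |
| `refractory_guard` | 2 | ms | own-spike exclusion zone before a target |

Weight initialization is uniform on `[0, 2*theta/F_eff]` with
`F_eff = F * eps_bar`, the fan-in `F` expressed in kernel units
(`eps_bar` = mean kernel value over the influence window, ~0.17 at
`theta_v = 0.05`).  A neuron receiving roughly one influential spike
per afferent then starts near threshold, fires from the first epoch at
diverse times, and both error signs occur.  (The naive `2*theta/F`
scale caps the attainable voltage at `0.5*theta*`kernel-peak` = theta/8`
and leaves the network permanently silent.)

The refractory depth `A2` is a free model constant.  The training
benchmarks set `A2 = 8*theta`: a deep reset confines each neuron to
one spike per input volley, which keeps the model well-posed under the
weight growth training produces and makes the output neuron's reset a
clean per-pattern signature (see the collinearity point above).
Shallow resets (`A2 = theta`) put the XOR task in the bursting regime
where training demonstrably diverges.

## Benchmarks and what they show

**XOR.**  Bits are encoded on two neurons each — (1, 2) ms for a 0,
(3, 4) ms for a 1 — and the classes {00, 11} / {01, 10} target 10 ms /
15 ms on the single output.  With `theta = 1`, `tau1 = 5`, `r = 0.5`
and 10 hidden neurons, all 50 random initializations reach accuracy 1;
the mean epochs-to-convergence is ~9–11 (median ~6) with a heavy tail
(occasional runs need tens of epochs: the visit dynamics are a
projection iteration on a moving spike configuration, and some
initializations cycle before settling).  The firing-threshold sweep
{0.5–5} leaves accuracy at 1 everywhere and moves the mean epochs only
within ~9.3–10.8 — threshold-insensitive, though the per-point means sit
above the single-digit epoch counts an idealized interference-free
analysis of the update rule would suggest.

**Spike-train targets.**  Single-target problems converge in one visit
(exactly, by the update identity); multi-layer spike-train tasks
converge to `|err| < 1e-3` within tens of epochs in the deep-reset
regime.

**Classification on tabular data.**  Features normalized to [0, 1] on
the training split are population-encoded by 12 Gaussian receptive
fields per feature (centres `(2i-3)/(2(M-2))`, common width
`1/(beta (M-2))`, `beta = 1.5`; latency `t_max (1 - activation)`
rounded to 0.1 ms, `t_max = 200` ms; activations below 0.05 stay
silent).  The network is 12F–F–1 with local connections (hidden unit f
sees only feature f's fields), output weight fixed at 1, and only
input-to-hidden weights trained, each sample against its own targets
`t_in + tau1 ln 2`.  The decision is nearest-prototype in voltage
error: each training sample's target trains form a prototype, distance
is the summed mean `|theta - u|` at the prototype's targets,
symmetrized between sample and prototype because the causal kernel
ignores spikes arriving after a target.  Training accuracy is scored
leave-one-out.  The declared convergence protocol is the training
accuracy plateau (first epoch not improved upon for 3 epochs), reached
within a couple of epochs on both bundled datasets (iris, and the
30-feature Wisconsin diagnostic breast-cancer set).

Known limitation: the achieved accuracies (~0.65 iris / ~0.55 WDBC
test) are far below what the latent codes support (a euclidean 1-NN on
the same codes scores ~0.95 on iris).  The voltage-error metric is a
causal, saturating alignment score with a ~15 ms window, while the
encoder's within-class latency scatter is tens of ms; no recoverable
setting of the encoder constants reconciles the two scales, and the
decision rule's discriminative power suffers accordingly.  The epochs
accounting, which is what the classification benchmark is used for
here, does not depend on this.

## What the synthetic conditions do and do not show

The Poisson trains, the four XOR patterns and the drive-conditioned
random weights exercise every code path (interval solving, resets,
insertion, jitter clamping, masks) under controlled, well-posed
conditions.  They do not emulate correlated natural spike statistics,
noisy thresholds, conduction delays, or datasets whose class structure
is not expressible as spike-time alignment — results here bound what
the algorithm does in its own regime, not its behaviour on such data.

## Numerical choices

* Discriminant tolerance 1e-12 (tangencies); open feasibility bounds
  approached with a 1e-9 relative margin so solved shifts stay finite.
* Jitter-root selection: minimum absolute shift; exact ties take the
  positive (delaying) root.
* Class-decision ties take the lowest class label.
* Degenerate zero denominators in the share formulas fall back to
  uniform shares.
* Measure C: Gaussian filter sigma = 1 ms on a 1 ms grid covering both
  trains (vectors accumulated with ±8 sigma local support); two empty
  trains score 1, one empty train scores 0.
* Spike CSV round-trips exactly (`%.17g` on write, round-trip float
  parsing on read).
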