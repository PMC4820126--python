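# nsebp

Event-driven simulation and normalized voltage-error backpropagation
(NSEBP) for multilayer spiking neural networks built on the simplified
Spike Response Model (SRM0).

## The problem

Temporal-coding spiking networks carry information in precise spike
times, which makes the two standard training steps expensive: the
forward pass scans the membrane voltage at every time step, and the
backward pass chains gradients through non-differentiable spike events.
This package implements an alternative that exploits the structure of
the SRM0 voltage

```
u(t) = eta(t - t_out) + sum_j w_j * eps(t - t_j) + u_ext,
eps(s) = [exp(-s/tau1) - exp(-s/tau2)] * H(s),
eta(s) = -A2 * exp(-s/tau1),
```

under the kernel constraint `tau1 = 2*tau2`:

* **Forward pass in closed form.** On each inter-input-spike interval,
  `u(t) = theta` reduces (via `z = exp(-t/tau1)`) to the quadratic
  `a z^2 - b z + theta = 0` with `a = sum w_m exp(t_m/tau2)` and
  `b = sum w_m exp(t_m/tau1) - A2 exp(t_hat/tau1)`, so output spike
  times are solved algebraically instead of scanned.  Work scales with
  the number of input spikes, not the simulated horizon.
* **Feedback by voltage error and spike jitter.** At each instructor
  target time `t_d` the error `err = theta - u(t_d)` is split by a
  normalized factor `r`: a share `r*err` is realized exactly by
  rate-free weight updates `dw_j = gamma_j * r * err / eps_j` through
  the normalized PSP learning window (`sum_j gamma_j = 1`), and the
  remainder is assigned to presynaptic spikes as voltage shares whose
  realizing time shifts are again roots of a quadratic; the jittered
  times become the previous layer's target times, giving layer-wise
  training without gradient chains.

The library also ships the surrounding apparatus: homogeneous Poisson
generators, the XOR segment encoding, Gaussian receptive-field
population encoding, the correlation measure C for spike-train
similarity, a class-decision rule based on voltage errors, and
reproducible experiment runners.

## Worked example

`examples/02_xor_training.py` trains the 4-10-1 XOR benchmark
(`theta = 1`, `tau1 = 5` ms, `r = 0.5`; class targets 10 ms for
patterns {00, 11} and 15 ms for {01, 10}) and prints:

```
converged: True after 21 training epochs
pattern 00: u(10) =  1.126, u(15) = -0.173 -> class C1 (true C1)
pattern 01: u(10) =  1.549, u(15) =  0.567 -> class C2 (true C2)
pattern 10: u(10) = -0.066, u(15) =  0.190 -> class C2 (true C2)
pattern 11: u(10) =  1.797, u(15) = -0.376 -> class C1 (true C1)
```

Each line shows the output neuron's voltage at the two class target
times; the pattern is assigned to the class whose target voltage is
closer to the threshold 1.0, and after convergence all four patterns
classify correctly.  The other example scripts demonstrate the
closed-form firing-time solution against a brute-force grid scan
(`01`), the population encoder (`03`) and the forward-pass equivalence
benchmark with operation counts (`04`).

A thin CLI wraps the same runners:

```
nsebp --out out --seed 1 xor --seeds 50
nsebp --out out equivalence --rates 10,100 --lengths 200,1000
nsebp --out out fixtures
```

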