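"""Event-driven vs time-stepped forward pass on Poisson drive.

A small version of the equivalence benchmark: Poisson spike trains
feed a 50-input network, the closed-form engine and a dt = 1 us grid
scan produce the layer's output trains, and the correlation measure C
(1 for identical trains) plus the operation counts are reported.
"""

from nsebp.experiments import run_feedforward_equivalence

df = run_feedforward_equivalence(
    rates=(10.0, 100.0, 1000.0),
    lengths=(200.0, 1000.0),
    n_seeds=1,
    n_hidden=10,
)
print(df.to_string(index=False))
print(
    "\nC = 1 and sub-0.01-ms mismatches everywhere: both engines produce\n"
    "the same spike trains, but the event engine's operation count tracks\n"
    "the number of input spikes while the grid scan's tracks the horizon."
)
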