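"""Reproducible experiment runners.

Each runner is a pure function of its arguments (all randomness flows
from explicit seeds) and returns plain pandas DataFrames / dicts so the
CLI and the test-suite share one code path.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .encoding import (
    EncodingConfig,
    class_targets_from_inputs,
    encode_population,
    poisson_train,
    population_trains,
    xor_dataset,
)
from .evaluation import NOT_CONVERGED, accuracy, classify, measure_C
from .feedforward import (
    merge_weighted,
    oracle_simulate,
    simulate_neuron,
    write_spike_csv,
)
from .srm0 import SpikeTrain, SRM0Params, epsilon_kernel
from .trainer import (
    LayerWeights,
    TrainConfig,
    fit,
    init_weights,
    train_target,
)

__all__ = [
    "run_feedforward_equivalence",
    "run_xor",
    "run_parameter_sweep",
    "run_uci",
    "make_fixtures",
    "save_network",
    "load_network",
]


def _match_trains(t1: np.ndarray, t2: np.ndarray) -> float:
    """Worst one-to-one spike-time mismatch; inf on count disagreement."""
    if len(t1) != len(t2):
        return math.inf
    if not len(t1):
        return 0.0
    return float(np.max(np.abs(np.asarray(t1) - np.asarray(t2))))


def _drive_scaled_weights(
    n_pre: int,
    n_post: int,
    total_spikes: int,
    length: float,
    params: SRM0Params,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random weights scaled so the mean drive sits near threshold.

    The stationary mean voltage under a spike flux of ``total_spikes``
    over ``length`` ms is ``flux * mean_w * (tau1 - tau2)`` (the PSP
    kernel integral), so uniform weights on [0, hi] with
    ``hi = theta*length / (total_spikes*(tau1 - tau2))`` put the mean
    voltage at ``theta/2``: fluctuations cross threshold at a healthy
    but bounded rate.  The scale is additionally capped at
    ``theta + A2`` so sparse trains cannot push the voltage past the
    refractory reset depth, where the continuous-time model's firing
    rate becomes unbounded and no discretization can follow it.
    """
    hi = params.theta * length / (max(total_spikes, 1) * (params.tau1 - params.tau2))
    hi = min(hi, params.theta + params.A2)
    return rng.uniform(0.0, hi, size=(n_pre, n_post))


def _condition_drive(
    merged: np.ndarray, params: SRM0Params, horizon: float, margin: float = 0.9
) -> np.ndarray:
    """Rescale a merged weighted train so the peak drive stays physical.

    If the pure PSP drive ever exceeds ``theta + A2`` the continuous
    SRM0 model fires at an unbounded rate (the reset cannot pull the
    voltage back below threshold) and no time discretization can agree
    with the closed-form solution; afferent weights are scaled down so
    the peak drive is at most ``margin * (theta + A2)``.
    """
    if not len(merged):
        return merged
    from ._fast import max_drive

    peak = max_drive(
        np.ascontiguousarray(merged[:, 0]),
        np.ascontiguousarray(merged[:, 1]),
        params.tau1,
        params.tau2,
        horizon,
        0.05,
    )
    cap = margin * (params.theta + params.A2)
    if peak > cap:
        merged = merged.copy()
        merged[:, 1] *= cap / peak
    return merged


def run_feedforward_equivalence(
    rates: Sequence[float] = (10.0, 50.0, 100.0, 500.0, 1000.0),
    lengths: Sequence[float] = (200.0, 1000.0, 2800.0),
    n_seeds: int = 20,
    n_input: int = 50,
    n_hidden: int = 100,
    dt: float = 1e-3,
    params: Optional[SRM0Params] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Event-driven vs time-stepped forward pass on Poisson input.

    Builds the 50-100-1 benchmark network with random weights, drives
    it with homogeneous Poisson trains for every (rate, length) cell
    and compares the two engines neuron by neuron: the correlation
    measure C at 1 ms resolution, the worst one-to-one spike-time
    mismatch, and the operation counts of both engines.
    """
    params = params or SRM0Params(tau1=5.0)
    rows = []
    for rate in rates:
        for length in lengths:
            for k in range(n_seeds):
                rng = np.random.default_rng([seed, int(rate), int(length), k])
                inputs = [poisson_train(rate, length, rng) for _ in range(n_input)]
                n_spk = sum(len(t) for t in inputs)
                w1 = _drive_scaled_weights(n_input, n_hidden, n_spk, length, params, rng)
                worst_c = 1.0
                worst_dt = 0.0
                ev_ops = 0
                or_ops = 0
                hidden_ev: List[np.ndarray] = []
                hidden_or: List[np.ndarray] = []
                for h in range(n_hidden):
                    merged = _condition_drive(
                        merge_weighted(inputs, w1[:, h]), params, length
                    )
                    te, oe = simulate_neuron(merged, params, length, return_ops=True)
                    to, oo = oracle_simulate(merged, params, length, dt, return_ops=True)
                    ev_ops += oe
                    or_ops += oo
                    worst_c = min(worst_c, measure_C(te, to))
                    worst_dt = max(worst_dt, _match_trains(te, to))
                    hidden_ev.append(te)
                    hidden_or.append(to)
                n_hid_spk = sum(len(t) for t in hidden_ev)
                w2 = _drive_scaled_weights(n_hidden, 1, n_hid_spk, length, params, rng)
                me = _condition_drive(merge_weighted(hidden_ev, w2[:, 0]), params, length)
                mo = _condition_drive(merge_weighted(hidden_or, w2[:, 0]), params, length)
                te, oe = simulate_neuron(me, params, length, return_ops=True)
                to, oo = oracle_simulate(mo, params, length, dt, return_ops=True)
                ev_ops += oe
                or_ops += oo
                worst_c = min(worst_c, measure_C(te, to))
                worst_dt = max(worst_dt, _match_trains(te, to))
                rows.append(
                    dict(
                        rate=rate,
                        length=length,
                        seed=k,
                        C=worst_c,
                        max_mismatch_ms=worst_dt,
                        event_ops=ev_ops,
                        oracle_ops=or_ops,
                    )
                )
    return pd.DataFrame(rows)


def _xor_accuracy(layers, patterns, labels, class_targets, params, horizon, guard):
    from .feedforward import simulate_network
    from .trainer import output_voltage

    preds = []
    for inputs, _ in patterns:
        acts = simulate_network(inputs, layers, params, horizon)
        u_by_class = {
            c: [
                output_voltage(layers[-1], acts[-2], acts[-1][0], 0, float(t), params, guard)
                for t in times
            ]
            for c, times in class_targets.items()
        }
        preds.append(classify(u_by_class, params))
    return accuracy(preds, labels)


def run_xor(
    n_hidden: int = 10,
    n_seeds: int = 50,
    theta: float = 1.0,
    tau1: float = 5.0,
    r: float = 0.5,
    max_epochs: int = 200,
    theta_v: float = 0.05,
    seed: int = 0,
    encoding: Optional[EncodingConfig] = None,
) -> pd.DataFrame:
    """XOR benchmark: 4-H-1 network, class targets 10 ms / 15 ms.

    The refractory amplitude is set to ``8*theta``: a deep reset keeps
    each neuron to (at most) one spike per input volley, which is the
    regime in which the pattern's own firing history disambiguates the
    two class targets.  Returns one row per seed with the number of
    training epochs until all four patterns classify correctly and the
    final accuracy.
    """
    params = SRM0Params(tau1=tau1, theta=theta, theta_v=theta_v, A2=8.0 * theta)
    enc = encoding or EncodingConfig()
    patterns, labels, class_targets = xor_dataset(enc, params)
    horizon = max(enc.xor_target_c1, enc.xor_target_c2) + params.tau1
    rows = []
    for k in range(n_seeds):
        rng = np.random.default_rng([seed, 7, k])
        layers = [
            init_weights(len(patterns[0][0]), n_hidden, params, rng),
            init_weights(n_hidden, 1, params, rng),
        ]
        cfg = TrainConfig(r=r, max_epochs=max_epochs, seed=int(rng.integers(2**31)))
        report = fit(
            layers,
            patterns,
            cfg,
            params,
            class_targets=class_targets,
            labels=labels,
            horizon=horizon,
        )
        final_acc = _xor_accuracy(
            layers, patterns, labels, class_targets, params, horizon, cfg.refractory_guard
        )
        rows.append(
            dict(
                seed=k,
                epochs=report.epochs if report.converged else NOT_CONVERGED,
                converged=report.converged,
                accuracy=final_acc,
            )
        )
    return pd.DataFrame(rows)


def run_parameter_sweep(
    parameter: str,
    grid: Sequence[float],
    n_seeds: int = 50,
    seed: int = 0,
    max_epochs: int = 200,
) -> pd.DataFrame:
    """Mean XOR epochs-to-convergence over a parameter grid.

    All other knobs stay at the benchmark values (hidden = 10,
    r = 0.5, tau1 = 5, theta = 1).
    """
    if parameter not in {"theta", "hidden", "r", "tau1"}:
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    rows = []
    for value in grid:
        kwargs = dict(
            n_hidden=10, theta=1.0, tau1=5.0, r=0.5,
            n_seeds=n_seeds, seed=seed, max_epochs=max_epochs,
        )
        if parameter == "theta":
            kwargs["theta"] = float(value)
        elif parameter == "hidden":
            kwargs["n_hidden"] = int(value)
        elif parameter == "r":
            kwargs["r"] = float(value)
        else:
            kwargs["tau1"] = float(value)
        df = run_xor(**kwargs)
        conv = df[df.converged]
        rows.append(
            dict(
                parameter=parameter,
                value=value,
                mean_epochs=float(conv.epochs.mean()) if len(conv) else math.nan,
                frac_converged=float(df.converged.mean()),
                mean_accuracy=float(df.accuracy.mean()),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# UCI classification


def _encode_sample(x01: np.ndarray, enc: EncodingConfig) -> List[List[np.ndarray]]:
    """Per-feature lists of 12 spike trains for one normalized sample."""
    return [population_trains(encode_population(float(v), enc)) for v in x01]


class _PrototypeScorer:
    """Nearest-prototype class decision in voltage-error space.

    Every training sample contributes a prototype: its per-feature
    target spike trains (input latencies shifted to the kernel peak).
    The distance between a sample and a prototype is the summed mean
    voltage error ``|theta - u_f(t)|`` of the sample's hidden voltages
    at the prototype's target times, symmetrized with the prototype's
    voltage at the sample's targets (the PSP kernel is causal, so a
    one-sided evaluation would miss spikes arriving after a target).
    A feature where one side is silent is scored by how far the other
    side's voltage is from silence.  The predicted class is the label
    of the closest prototype -- "the class with the smallest voltage
    error".
    """

    def __init__(self, proto_enc, proto_labels, n_feat, params, extra_targets=()):
        self.params = params
        self.n_feat = n_feat
        self.labels = np.asarray(proto_labels)
        self.protos = proto_enc
        # evaluation-time grid per feature: all target times that will
        # ever be scored (prototype targets plus any extra, e.g. the
        # test split's own targets)
        self.times = []
        for f in range(n_feat):
            cols = [tg[f] for _, tg in proto_enc if len(tg[f])]
            cols += [tg[f] for tg in extra_targets if len(tg[f])]
            self.times.append(
                np.unique(np.round(np.concatenate(cols), 4)) if cols else np.empty(0)
            )
        # per-feature averaging matrices over each prototype's targets
        self.avg = []
        self.has_targets = []
        for f in range(n_feat):
            m = np.zeros((len(self.times[f]), len(proto_enc)))
            for p, (_, tg) in enumerate(proto_enc):
                if len(tg[f]):
                    idx = np.searchsorted(self.times[f], np.round(tg[f], 4))
                    m[idx, p] = 1.0 / len(tg[f])
            self.avg.append(m)
            self.has_targets.append(m.sum(axis=0) > 0)
        self._proto_err = None

    def _voltages(self, weights, flat, f, times):
        """(|theta - u_f|, |u_f|) of one sample at an array of times."""
        tis, wis = [], []
        for j in range(12 * f, 12 * (f + 1)):
            if len(flat[j]):
                tis.append(flat[j][0])
                wis.append(weights.matrix[j, f])
        if not len(times):
            return np.empty(0), np.empty(0)
        if not tis:
            z = np.zeros(len(times))
            return np.full(len(times), self.params.theta), z
        lags = np.asarray(times)[:, None] - np.asarray(tis)[None, :]
        u = np.asarray(epsilon_kernel(lags, self.params)) @ np.asarray(wis)
        return np.abs(self.params.theta - u), np.abs(u)

    def prepare(self, weights):
        """Precompute every prototype's voltage errors on the grid."""
        self._proto_err = []
        for f in range(self.n_feat):
            e_theta = np.zeros((len(self.protos), len(self.times[f])))
            e_zero = np.zeros_like(e_theta)
            for p, (pflat, _) in enumerate(self.protos):
                e_theta[p], e_zero[p] = self._voltages(weights, pflat, f, self.times[f])
            self._proto_err.append((e_theta, e_zero))
        return self

    def predict(self, weights, flat, own_targets, exclude: Optional[int] = None):
        n_proto = len(self.protos)
        dist = np.zeros(n_proto)
        for f in range(self.n_feat):
            e_theta, e_zero = self._voltages(weights, flat, f, self.times[f])
            has_t = self.has_targets[f]
            term_sp = e_theta @ self.avg[f]
            pe_theta, pe_zero = self._proto_err[f]
            if len(own_targets[f]):
                idx = np.searchsorted(self.times[f], np.round(own_targets[f], 4))
                term_sp[~has_t] = float(np.mean(e_zero[idx]))
                term_ps = pe_theta[:, idx].mean(axis=1)
            else:
                term_ps = (pe_zero @ self.avg[f])  # sample silent: proto u -> 0
            dist += 0.5 * (term_sp + term_ps)
        if exclude is not None:
            dist[exclude] = np.inf
        return int(self.labels[int(np.argmin(dist))])


def run_uci(
    dataset: str,
    seed: int = 0,
    max_epochs: int = 25,
    patience: int = 3,
    params: Optional[SRM0Params] = None,
    encoding: Optional[EncodingConfig] = None,
    test_size: float = 0.5,
    max_train: Optional[int] = None,
) -> Dict:
    """Population-encoded UCI classification with local connections.

    Protocol (declared here, reported with the results): stratified
    train/test split (default 50/50) by seed; per-feature min-max
    normalization fitted on the training split; network 12F-F-1 where
    hidden neuron f sees only the 12 fields of feature f; the output
    weight is fixed to 1 and only input-to-hidden weights are trained
    (r = 1, one exact visit per target), each sample against its own
    targets ``t_in + 2*tau2*ln 2``.  The class decision is the
    nearest-prototype rule of :class:`_PrototypeScorer`.  Convergence
    is declared at the training-accuracy plateau: the first epoch whose
    accuracy is not exceeded during the following ``patience`` epochs.
    ``max_train`` caps the number of training samples (stratified
    subsample) to bound runtime on the larger dataset.
    """
    from sklearn.datasets import load_breast_cancer, load_iris
    from sklearn.model_selection import train_test_split

    if dataset == "iris":
        data = load_iris()
    elif dataset == "bcw":
        data = load_breast_cancer()
    else:
        raise ValueError(f"unknown dataset {dataset!r} (use 'iris' or 'bcw')")
    params = params or SRM0Params(tau1=5.0)
    enc = encoding or EncodingConfig()
    X, y = np.asarray(data.data, dtype=float), np.asarray(data.target)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    if max_train is not None and len(X_tr) > max_train:
        X_tr, _, y_tr, _ = train_test_split(
            X_tr, y_tr, train_size=max_train, stratify=y_tr, random_state=seed
        )
    lo = X_tr.min(axis=0)
    hi = X_tr.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    n_feat = X.shape[1]

    def encode_all(Xs):
        out = []
        for x in Xs:
            x01 = np.clip((x - lo) / span, 0.0, 1.0)
            feats = _encode_sample(x01, enc)
            flat = [t for ftrains in feats for t in ftrains]
            tgts = [class_targets_from_inputs(ftrains, params) for ftrains in feats]
            out.append((flat, tgts))
        return out

    train_enc = encode_all(X_tr)
    test_enc = encode_all(X_te)
    scorer = _PrototypeScorer(
        train_enc, y_tr, n_feat, params,
        extra_targets=[tgts for _, tgts in test_enc],
    )

    mask = np.zeros((12 * n_feat, n_feat), dtype=bool)
    for f in range(n_feat):
        mask[12 * f : 12 * (f + 1), f] = True
    rng = np.random.default_rng([seed, 11])
    w1 = init_weights(12 * n_feat, n_feat, params, rng, mask=mask)
    cfg = TrainConfig(r=1.0, max_epochs=max_epochs, seed=seed)

    def score(enc_set, ys, loo=False):
        scorer.prepare(w1)
        preds = [
            scorer.predict(w1, flat, tgts, exclude=i if loo else None)
            for i, (flat, tgts) in enumerate(enc_set)
        ]
        return accuracy(preds, [int(v) for v in ys])

    # training accuracy is leave-one-out: a sample may not match its
    # own prototype, otherwise the score is trivially perfect
    acc_history = [score(train_enc, y_tr, loo=True)]
    best_epoch = 0
    for epoch in range(1, max_epochs + 1):
        for flat, tgts in train_enc:
            for f in range(n_feat):
                for t_d in tgts[f]:
                    train_target(
                        [w1], [flat], 1, f, float(t_d), 1.0, cfg, params, rng
                    )
        acc_history.append(score(train_enc, y_tr, loo=True))
        if acc_history[epoch] > acc_history[best_epoch]:
            best_epoch = epoch
        if epoch - best_epoch >= patience:
            break
    return dict(
        dataset=dataset,
        n_features=n_feat,
        n_input=12 * n_feat,
        n_hidden=n_feat,
        seed=seed,
        protocol=f"stratified {int((1-test_size)*100)}/{int(test_size*100)} split, "
        f"train-split min-max normalization, nearest-prototype voltage-error "
        f"decision, accuracy-plateau patience {patience}",
        epochs=best_epoch,
        train_accuracy=acc_history[best_epoch],
        final_train_accuracy=acc_history[-1],
        test_accuracy=score(test_enc, y_te),
        accuracy_history=acc_history,
    )


# ---------------------------------------------------------------------------
# fixtures and checkpoints


def save_network(path, layers: Sequence[LayerWeights], params: SRM0Params) -> None:
    """Serialize weights + masks + model constants as CSV blocks."""
    with open(path, "w") as fh:
        fh.write("format=nsebp-checkpoint-v1\n")
        for key in ("tau1", "tau2", "theta", "A1", "A2", "u_ext", "theta_v"):
            fh.write(f"{key}={getattr(params, key)!r}\n")
        fh.write(f"n_layers={len(layers)}\n")
        for i, layer in enumerate(layers):
            fh.write(f"layer={i} shape={layer.n_pre}x{layer.n_post} "
                     f"mask={int(layer.mask is not None)}\n")
            for row in layer.matrix:
                fh.write(",".join(f"{v:.17g}" for v in row) + "\n")
            if layer.mask is not None:
                for row in layer.mask.astype(int):
                    fh.write(",".join(str(v) for v in row) + "\n")


def load_network(path) -> Tuple[List[LayerWeights], SRM0Params]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != "format=nsebp-checkpoint-v1":
        raise ValueError("not an nsebp checkpoint file")
    kv = {}
    idx = 1
    while "=" in lines[idx] and not lines[idx].startswith("layer="):
        k, v = lines[idx].split("=", 1)
        kv[k] = v
        idx += 1
    params = SRM0Params(
        tau1=float(kv["tau1"]), tau2=float(kv["tau2"]), theta=float(kv["theta"]),
        A1=float(kv["A1"]), A2=float(kv["A2"]), u_ext=float(kv["u_ext"]),
        theta_v=float(kv["theta_v"]),
    )
    layers = []
    for _ in range(int(kv["n_layers"])):
        head = lines[idx]
        idx += 1
        shape = head.split("shape=")[1].split(" ")[0]
        n_pre, n_post = (int(v) for v in shape.split("x"))
        has_mask = head.endswith("mask=1")
        mat = np.array(
            [[float(v) for v in lines[idx + r].split(",")] for r in range(n_pre)]
        )
        idx += n_pre
        mask = None
        if has_mask:
            mask = np.array(
                [[int(v) for v in lines[idx + r].split(",")] for r in range(n_pre)],
                dtype=bool,
            )
            idx += n_pre
        layers.append(LayerWeights(mat, mask))
    return layers, params


def make_fixtures(outdir, seed: int = 0) -> Dict[str, str]:
    """Write small seeded fixture files (Poisson CSV, XOR CSV, checkpoint)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    params = SRM0Params(tau1=5.0)
    poisson = [
        SpikeTrain(i, poisson_train(10.0, 200.0, rng)) for i in range(5)
    ]
    paths = {}
    paths["poisson"] = os.path.join(outdir, "poisson_trains.csv")
    write_spike_csv(paths["poisson"], poisson)
    enc = EncodingConfig()
    xor_rows = []
    for p_idx, bits in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
        from .encoding import encode_xor

        for nid, train in enumerate(encode_xor(bits, enc)):
            for t in train:
                xor_rows.append((p_idx, nid, t))
    paths["xor"] = os.path.join(outdir, "xor_patterns.csv")
    pd.DataFrame(xor_rows, columns=["pattern", "neuron_id", "time_ms"]).to_csv(
        paths["xor"], index=False
    )
    # same width as the Poisson fixture so `simulate` can chain them
    layers = [init_weights(5, 3, params, rng), init_weights(3, 1, params, rng)]
    paths["checkpoint"] = os.path.join(outdir, "tiny_network.nsebp")
    save_network(paths["checkpoint"], layers, params)
    return paths
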