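"""Feedback pass: error allocation, jitter solving, normalized updates."""

import math

import numpy as np
import pytest

from nsebp import (
    LayerWeights,
    SRM0Params,
    TargetSpec,
    TrainConfig,
    add_spikes,
    allocate_error,
    clamp_delta_u,
    epsilon_kernel,
    fit,
    influence_window,
    influential_spikes,
    init_weights,
    jitter_shares,
    solve_jitter,
    target_voltage,
    train_target,
    valid_target,
    voltage_error,
    weight_shares,
    weight_update,
)
from nsebp.trainer import ZeroWeightError


@pytest.fixture
def cfg():
    return TrainConfig(r=0.5, seed=7)


def _random_single_layer_problem(rng, params):
    """Random pre-spikes with at least one inside the influence window."""
    s_lo, s_hi = influence_window(params)
    t_d = float(rng.uniform(10.0, 30.0))
    n = int(rng.integers(2, 9))
    lags = rng.uniform(s_lo * 1.05, s_hi * 0.95, size=n)
    times = np.sort(t_d - lags)
    weights = LayerWeights(rng.uniform(0.1, 2.0, (n, 1)))
    activities = [[np.array([t]) for t in times], [np.empty(0)]]
    return activities, weights, t_d


class TestElementaryOps:
    def test_voltage_error_sign_convention(self, params5):
        assert voltage_error(params5.theta, params5) == 0.0
        assert voltage_error(0.4, SRM0Params(theta=1.0)) == pytest.approx(0.6)
        assert voltage_error(1.5, SRM0Params(theta=1.0)) < 0

    @pytest.mark.parametrize("r,err", [(1.0, 0.3), (0.5, 1.0), (0.25, -2.0)])
    def test_error_allocation_conserves_total(self, r, err):
        err_w, err_t = allocate_error(err, TrainConfig(r=r))
        assert err_w == pytest.approx(r * err)
        assert err_w + err_t == pytest.approx(err, abs=1e-15)

    def test_influential_subset_is_the_open_window(self, params5):
        s_lo, s_hi = influence_window(params5)
        t_d = 20.0
        spikes = np.array(
            [
                [t_d, 1.0, 0.0],               # lag 0: excluded
                [t_d - params5.peak_lag, 1.0, 1.0],  # kernel peak: included
                [t_d - s_hi - 1.0, 1.0, 2.0],  # beyond the window: excluded
                [t_d - 0.5 * (s_lo + s_hi), 1.0, 3.0],
            ]
        )
        kept = influential_spikes(spikes, t_d, params5)
        assert sorted(kept[:, 2]) == [1.0, 3.0]

    def test_empty_subset_for_far_spikes(self, params5):
        spikes = np.array([[1.0, 1.0, 0.0]])
        assert len(influential_spikes(spikes, 100.0, params5)) == 0


class TestShares:
    def test_single_spike_takes_the_whole_share(self, params5):
        sub = np.array([[15.0, 1.0, 0.0]])
        assert jitter_shares(sub, 20.0, +1.0, params5)[0] == pytest.approx(1.0)
        assert jitter_shares(sub, 20.0, -1.0, params5)[0] == pytest.approx(1.0)
        assert weight_shares(sub, 20.0, params5)[0] == pytest.approx(1.0)

    def test_equal_lags_share_equally(self, params5):
        sub = np.array([[15.0, 1.0, 0.0], [15.0, 2.0, 1.0]])
        np.testing.assert_allclose(jitter_shares(sub, 20.0, 1.0, params5), [0.5, 0.5])
        np.testing.assert_allclose(weight_shares(sub, 20.0, params5), [0.5, 0.5])

    @pytest.mark.parametrize("err", [1.0, -1.0])
    def test_shares_normalize_for_random_subsets(self, err, params5, rng):
        for _ in range(50):
            n = int(rng.integers(1, 8))
            times = rng.uniform(6.0, 19.0, n)
            sub = np.column_stack([times, rng.uniform(0.1, 2, n), np.arange(n)])
            assert jitter_shares(sub, 20.0, err, params5).sum() == pytest.approx(1.0)
            assert weight_shares(sub, 20.0, params5).sum() == pytest.approx(1.0)

    def test_weight_shares_favor_near_peak_spikes(self, params5):
        t_d = 20.0
        sub = np.array(
            [[t_d - params5.peak_lag, 1.0, 0.0], [t_d - 13.0, 1.0, 1.0]]
        )
        g = weight_shares(sub, t_d, params5)
        assert g[0] > g[1]


class TestJitterSolver:
    def test_zero_request_gives_zero_shift(self, params2, peak_lag2):
        assert solve_jitter(0.0, 1.0, 0.0, peak_lag2, params2) == pytest.approx(0.0)

    def test_worked_example_minimum_magnitude_root(self, params2, peak_lag2):
        dt = solve_jitter(-0.05, 1.0, 0.0, peak_lag2, params2)
        assert dt == pytest.approx(0.739280, abs=1e-5)
        new_eps = epsilon_kernel(peak_lag2 - dt, params2)
        assert new_eps == pytest.approx(0.20, abs=1e-9)

    def test_zero_weight_signals_skip(self, params2):
        with pytest.raises(ZeroWeightError):
            solve_jitter(0.1, 0.0, 0.0, 1.0, params2)

    def test_overshooting_request_clamps_to_kernel_peak(self, params2, peak_lag2):
        # lag 4 ms, eps ~ 0.1, asking for more than (1/4 - eps)*w
        dt = solve_jitter(5.0, 1.0, 0.0, 4.0, params2)
        assert 4.0 - dt == pytest.approx(peak_lag2, abs=1e-6)

    def test_round_trip_identity_over_random_cases(self, params2, rng):
        for _ in range(1000):
            w = float(rng.uniform(-2, 2))
            if abs(w) < 1e-3:
                continue
            lag = float(rng.uniform(0.1, 8.0))
            eps = epsilon_kernel(lag, params2)
            du_req = float(rng.uniform(-0.3, 0.3)) * abs(w)
            du = clamp_delta_u(du_req, w, lag, params2)
            dt = solve_jitter(du_req, w, 0.0, lag, params2)
            realized = (epsilon_kernel(lag - dt, params2) - eps) * w
            assert realized == pytest.approx(du, abs=1e-9)

    def test_clamp_preserves_sign_and_never_amplifies(self, params2, rng):
        for _ in range(300):
            w = float(rng.choice([-1, 1]) * rng.uniform(0.05, 2))
            lag = float(rng.uniform(0.2, 8.0))
            du = float(rng.uniform(-1, 1))
            c = clamp_delta_u(du, w, lag, params2)
            if du != 0:
                assert c * du >= 0
            assert abs(c) <= abs(du) + 1e-12


class TestWeightUpdate:
    def test_zero_error_is_a_noop(self, params5):
        sub = np.array([[15.0, 1.0, 0.0]])
        np.testing.assert_array_equal(weight_update(sub, 0.0, 20.0, params5), [0.0])

    def test_single_spike_at_kernel_peak(self, params2, peak_lag2):
        sub = np.array([[0.0, 1.0, 0.0]])
        dw = weight_update(sub, 0.5, peak_lag2, params2)
        assert dw[0] == pytest.approx(2.0)

    def test_voltage_change_identity(self, params5, rng):
        # sum_j eps_j * dw_j == err_w exactly, for random subsets
        for _ in range(200):
            n = int(rng.integers(1, 7))
            t_d = 25.0
            times = t_d - rng.uniform(1.0, 13.0, n)
            sub = np.column_stack([times, rng.uniform(-1, 2, n), np.arange(n)])
            err_w = float(rng.normal())
            dw = weight_update(sub, err_w, t_d, params5)
            eps = epsilon_kernel(t_d - times, params5)
            assert float(np.dot(np.atleast_1d(eps), dw)) == pytest.approx(err_w, abs=1e-9)


class TestAddSpikes:
    def test_inverse_count_probabilities(self, rng):
        # counts (1, 2) -> p = (2/3, 1/3); check empirically within 3 sigma
        n = 30_000
        placements = add_spikes([1, 2], (0.0, 5.0), 1, rng)
        draws = [add_spikes([1, 2], (0.0, 5.0), 1, rng)[0][0] for _ in range(n)]
        p_hat = np.mean(np.asarray(draws) == 0)
        sigma = math.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(p_hat - 2 / 3) < 3 * sigma
        lo, hi = 0.0, 5.0
        assert all(lo <= t < hi for _, t in placements)

    def test_all_silent_neurons_drawn_uniformly(self, rng):
        draws = [add_spikes([0, 0, 0], (0.0, 1.0), 1, rng)[0][0] for _ in range(9000)]
        freqs = np.bincount(draws, minlength=3) / 9000
        assert np.all(np.abs(freqs - 1 / 3) < 0.02)

    def test_empty_window_rejected(self, rng):
        with pytest.raises(ValueError):
            add_spikes([1], (3.0, 3.0), 1, rng)


class TestValidTarget:
    def test_no_input_before_target_fails_every_mode(self, params5):
        for mode in ("traditional", "nsebp", "nsebp-windowed"):
            assert not valid_target(5.0, [7.0, 9.0], 2, mode, params5)

    def test_traditional_reach_is_one_peak_lag_per_layer(self, params5):
        t_d = 20.0
        inside = t_d - params5.peak_lag
        assert valid_target(t_d, [inside], 2, "traditional", params5)
        outside = t_d - 1.5 * params5.peak_lag
        assert not valid_target(t_d, [outside], 2, "traditional", params5)
        # a third layer extends the reach
        assert valid_target(t_d, [outside], 3, "traditional", params5)

    def test_relaxed_mode_accepts_any_earlier_input(self, params5):
        assert valid_target(100.0, [0.5], 2, "nsebp", params5)

    def test_windowed_mode_uses_per_layer_window_multiples(self, params5):
        s_lo, s_hi = influence_window(params5)
        t_d = 40.0
        assert valid_target(t_d, [t_d - 1.5 * s_lo], 2, "nsebp-windowed", params5)
        assert not valid_target(t_d, [t_d - 0.5 * s_lo], 2, "nsebp-windowed", params5)


class TestTrainTarget:
    def test_one_visit_drives_voltage_to_threshold(self, params5, cfg, rng):
        # single trainable layer, r = 1: exact convergence in one call
        for _ in range(50):
            activities, weights, t_d = _random_single_layer_problem(rng, params5)
            train_target([weights], activities, 1, 0, t_d, 1.0, cfg, params5, rng)
            u = target_voltage(weights, activities[0], 0, t_d, params5)
            assert abs(u - params5.theta) < 1e-9

    def test_error_within_tolerance_is_a_noop(self, params5, rng):
        activities, weights, t_d = _random_single_layer_problem(rng, params5)
        cfg = TrainConfig(r=1.0, tol=1e-9)
        train_target([weights], activities, 1, 0, t_d, 1.0, cfg, params5, rng)
        before = weights.matrix.copy()
        err, prev = train_target([weights], activities, 1, 0, t_d, 1.0, cfg, params5, rng)
        assert abs(err) <= 1e-9
        assert prev == {}
        np.testing.assert_array_equal(weights.matrix, before)

    def test_nonpositive_target_rejected(self, params5, cfg, rng):
        activities, weights, _ = _random_single_layer_problem(rng, params5)
        with pytest.raises(ValueError):
            train_target([weights], activities, 1, 0, -1.0, 1.0, cfg, params5, rng)

    def test_monotone_error_decay_on_repeat_visits(self, params5, rng):
        activities, weights, t_d = _random_single_layer_problem(rng, params5)
        cfg = TrainConfig(r=0.5, tol=1e-12)
        errs = []
        for _ in range(6):
            err, _ = train_target([weights], activities, 1, 0, t_d, 0.5, cfg, params5, rng)
            errs.append(abs(err))
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))

    def test_empty_window_recruits_hidden_spikes(self, params5, rng):
        # two-layer stack with a silent hidden layer: the visit inserts
        # spikes and returns them as previous-layer targets
        w1 = init_weights(2, 3, params5, rng)
        w2 = init_weights(3, 1, params5, rng)
        activities = [
            [np.array([1.0]), np.array([2.0])],
            [np.empty(0)] * 3,
            [np.empty(0)],
        ]
        cfg = TrainConfig(r=1.0, S=2, seed=3)
        err, prev = train_target([w1, w2], activities, 2, 0, 10.0, 1.0, cfg, params5, rng)
        placed = [t for times in prev.values() for t in times]
        assert len(placed) == 2
        s_lo, s_hi = influence_window(params5)
        assert all(10.0 - s_hi <= t <= 10.0 - s_lo for t in placed)


class TestBookkeeping:
    """Exact voltage accounting of the split update (two-layer cases)."""

    def _two_layer_case(self, rng, params):
        s_lo, s_hi = influence_window(params)
        t_d = float(rng.uniform(16.0, 25.0))
        n_hidden = int(rng.integers(2, 6))
        lags = rng.uniform(s_lo * 1.1, s_hi * 0.9, n_hidden)
        hidden = [np.array([t_d - lag]) for lag in np.sort(lags)[::-1]]
        w2 = LayerWeights(rng.uniform(0.2, 1.5, (n_hidden, 1)))
        activities = [[np.array([1.0])], hidden, [np.empty(0)]]
        return activities, w2, t_d

    def test_weight_updates_alone_move_u_by_r_err(self, params5, rng):
        for _ in range(1000):
            activities, w2, t_d = self._two_layer_case(rng, params5)
            r = float(rng.uniform(0.2, 0.9))
            u0 = target_voltage(w2, activities[1], 0, t_d, params5)
            err = params5.theta - u0
            layers = [LayerWeights(np.ones((1, len(activities[1])))), w2]
            cfg = TrainConfig(r=r, tol=1e-15)
            train_target(layers, activities, 2, 0, t_d, r, cfg, params5, rng)
            u1 = target_voltage(w2, activities[1], 0, t_d, params5)
            assert u1 - u0 == pytest.approx(r * err, abs=1e-9)

    def test_exact_jitters_alone_move_u_by_complement(self, params5, rng):
        # apply the solved (unclamped) jitters in place and verify that
        # the presynaptic shifts realize (1 - r) * err exactly
        from nsebp import influential_spikes, jitter_shares, solve_jitter

        count = 0
        while count < 1000:
            activities, w2, t_d = self._two_layer_case(rng, params5)
            r = 0.5
            spikes = np.column_stack(
                [
                    np.concatenate(activities[1]),
                    w2.matrix[:, 0],
                    np.arange(len(activities[1])),
                ]
            )
            sub = influential_spikes(spikes, t_d, params5)
            if not len(sub):
                continue
            u0 = float(
                np.dot(sub[:, 1], np.atleast_1d(epsilon_kernel(t_d - sub[:, 0], params5)))
            )
            err = params5.theta - u0
            gamma = jitter_shares(sub, t_d, err, params5)
            requested = gamma * (1 - r) * err
            feasible = [
                abs(clamp_delta_u(q, w, t_d - t, params5) - q) < 1e-12
                for q, (t, w, _) in zip(requested, sub)
            ]
            if not all(feasible):
                continue
            du_total = 0.0
            for q, (t, w, _) in zip(requested, sub):
                dt = solve_jitter(q, w, t, t_d, params5)
                du_total += (
                    epsilon_kernel(t_d - t - dt, params5) - epsilon_kernel(t_d - t, params5)
                ) * w
            assert du_total == pytest.approx((1 - r) * err, abs=1e-9)
            count += 1


class TestFit:
    # deep reset keeps the toy spike-train task in the stable
    # one-spike-per-volley regime (see the XOR study conditions)
    deep = SRM0Params(tau1=5.0, theta=1.0, theta_v=0.05, A2=8.0)

    def _toy_problem(self, rng):
        inputs = [np.array([1.0, 4.0]), np.array([2.0])]
        layers = [
            init_weights(2, 4, self.deep, rng),
            init_weights(4, 1, self.deep, rng),
        ]
        targets = TargetSpec({0: np.array([12.0])})
        return inputs, layers, targets

    def test_seed_determinism_is_bitwise(self):
        reports = []
        for _ in range(2):
            rng = np.random.default_rng(5)
            inputs, layers, targets = self._toy_problem(rng)
            cfg = TrainConfig(r=0.5, max_epochs=10, seed=99)
            reports.append(fit(layers, [(inputs, targets)], cfg, self.deep))
        assert reports[0].rows == reports[1].rows
        assert reports[0].accuracy_history == reports[1].accuracy_history

    def test_already_converged_network_trains_zero_epochs(self, rng):
        inputs, layers, targets = self._toy_problem(rng)
        cfg = TrainConfig(r=0.5, max_epochs=30, seed=1)
        first = fit(layers, [(inputs, targets)], cfg, self.deep)
        assert first.converged
        again = fit(layers, [(inputs, targets)], cfg, self.deep)
        assert again.converged and again.epochs == 0

    def test_mask_blocks_updates_and_zeroes_weights(self, params5, rng):
        mask = np.array([[True], [False]])
        w = LayerWeights(rng.uniform(0.5, 1.0, (2, 1)), mask)
        assert w.matrix[1, 0] == 0.0
        activities = [[np.array([10.0]), np.array([10.0])], [np.empty(0)]]
        cfg = TrainConfig(r=1.0)
        train_target([w], activities, 1, 0, 10.0 + params5.peak_lag, 1.0, cfg, params5, rng)
        assert w.matrix[1, 0] == 0.0
        assert w.matrix[0, 0] != 0.0


class TestConfigValidation:
    @pytest.mark.parametrize("r", [0.0, 1.5, -0.2])
    def test_r_bounds(self, r):
        with pytest.raises(ValueError):
            TrainConfig(r=r)

    def test_spike_budget_positive(self):
        with pytest.raises(ValueError):
            TrainConfig(S=0)
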