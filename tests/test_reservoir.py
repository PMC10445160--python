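"""Reservoir construction and binary dynamics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from rbnres import (BALANCED, ActivityTrace, ReservoirConfig,
                    canonical_params, generate_reservoir, init_state,
                    load_reservoir, run_driven, run_free, save_reservoir,
                    step, toss_input_weights)


class TestCanonicalParams:
    @pytest.mark.parametrize("sigma_star, expected", [
        (-0.66, (-1.0, 0.66)),
        (BALANCED, (0.0, 1.0)),
        (4.0, (1.0, 4.0)),
        (-3.5, (-1.0, 3.5)),
    ])
    def test_reduction_to_canonical_form(self, sigma_star, expected):
        assert canonical_params(sigma_star) == expected

    @pytest.mark.parametrize("bad", [0.0, float("nan"), float("inf"), "foo"])
    def test_invalid_sigma_star_rejected(self, bad):
        with pytest.raises(ValueError):
            canonical_params(bad)


class TestGeneration:
    def test_fixed_in_degree_no_self_loops(self, small_reservoir):
        n, k = small_reservoir.n_neurons, small_reservoir.in_degree
        assert small_reservoir.pre_indices.shape == (n, k)
        rows = np.arange(n)[:, None]
        assert not np.any(small_reservoir.pre_indices == rows)
        for row in small_reservoir.pre_indices:
            assert len(np.unique(row)) == k

    def test_halves_partition_and_input_weight_range(self, small_reservoir):
        r = small_reservoir
        n = r.n_neurons
        assert len(r.input_indices) == len(r.readout_indices) == n // 2
        assert len(np.intersect1d(r.input_indices, r.readout_indices)) == 0
        nz = np.flatnonzero(r.input_weights)
        assert set(nz) <= set(r.input_indices.tolist())
        assert np.all(np.abs(r.input_weights) <= 0.5)

    def test_positive_weight_fraction_matches_normal_cdf(self, large_reservoir):
        # fraction of excitatory synapses ~ Phi(mu/sigma) = Phi(1/4)
        w = large_reservoir.weights
        p_hat = np.mean(w > 0)
        p = norm.cdf(1 / 4.0)
        se = np.sqrt(p * (1 - p) / w.size)
        assert abs(p_hat - p) < 3 * se

    def test_seeded_determinism(self):
        cfg = ReservoirConfig(100, 16, -0.66, seed=1)
        a, b = generate_reservoir(cfg), generate_reservoir(cfg)
        assert np.array_equal(a.pre_indices, b.pre_indices)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.input_weights, b.input_weights)

    def test_degenerate_configs_rejected(self):
        with pytest.raises(ValueError):
            ReservoirConfig(10, 10, -0.66, seed=0)  # K >= N
        with pytest.raises(ValueError):
            generate_reservoir(ReservoirConfig(101, 16, -0.66, seed=0))  # odd

    def test_tossing_redraws_values_on_same_half(self, small_reservoir):
        tossed = toss_input_weights(small_reservoir, 99)
        assert np.array_equal(tossed.input_indices,
                              small_reservoir.input_indices)
        assert not np.array_equal(tossed.input_weights,
                                  small_reservoir.input_weights)
        nz = np.flatnonzero(tossed.input_weights)
        assert set(nz) <= set(small_reservoir.input_indices.tolist())
        assert np.all(np.abs(tossed.input_weights) <= 0.5)


class TestInitState:
    @pytest.mark.parametrize("n, frac, expected_ones", [
        (10, 0.2, 2), (10, 0.0, 0), (10, 1.0, 10), (10_000, 0.2, 2000),
    ])
    def test_exact_active_count(self, n, frac, expected_ones):
        state = init_state(n, frac, 0)
        assert state.sum() == expected_ones
        assert set(np.unique(state)) <= {0, 1}

    @given(n=st.integers(2, 300), frac=st.floats(0, 1))
    @settings(max_examples=30, deadline=None)
    def test_round_half_up_count(self, n, frac):
        state = init_state(n, frac, 7)
        assert state.sum() == int(np.floor(frac * n + 0.5))


class TestStep:
    def test_zero_state_zero_input_is_absorbing(self, small_reservoir):
        zero = np.zeros(small_reservoir.n_neurons, dtype=np.uint8)
        assert np.array_equal(step(small_reservoir, zero, 0.0), zero)

    def test_all_negative_weights_extinguish_any_state(self, small_reservoir):
        res = dataclasses.replace(
            small_reservoir, weights=-np.abs(small_reservoir.weights) - 0.1)
        state = init_state(res.n_neurons, 0.5, 3)
        assert step(res, state, 0.0).sum() == 0

    def test_three_neuron_hand_evaluation(self):
        # ring 0->1->2->0 padded to K=2 with a duplicate-free second partner
        res = generate_reservoir(ReservoirConfig(4, 2, 1.0, seed=0))
        pre = np.array([[1, 2], [2, 3], [3, 0], [0, 1]])
        w = np.array([[0.5, -1.0], [2.0, 0.0], [-0.3, 0.2], [0.0, 0.0]])
        res = dataclasses.replace(res, pre_indices=pre, weights=w)
        state = np.array([1, 0, 1, 0], dtype=np.uint8)
        # neuron sums: 0: .5*0 + (-1)*1 = -1 -> 0 ; 1: 2*1 + 0*0 = 2 -> 1
        # 2: -.3*0 + .2*1 = .2 -> 1      ; 3: 0*1 + 0*0 = 0 -> theta(0)=0
        expected = np.array([0, 1, 1, 0], dtype=np.uint8)
        assert np.array_equal(step(res, state, 0.0), expected)

    def test_dimension_mismatch_rejected(self, small_reservoir):
        with pytest.raises(ValueError):
            step(small_reservoir, np.zeros(5), 0.0)


class TestRunFree:
    def test_trace_shape_and_activity_quantization(self, small_reservoir):
        state = init_state(200, 0.2, 1)
        trace = run_free(small_reservoir, state, 50, 70)
        assert len(trace.counts) == 120
        assert trace.n_transient == 50
        assert np.all((trace.activity * 200) % 1 == 0)
        assert trace.activity.min() >= 0 and trace.activity.max() <= 1

    def test_weak_excitation_saturates(self):
        res = generate_reservoir(ReservoirConfig(200, 16, 0.1, seed=2))
        trace = run_free(res, init_state(200, 0.2, 2), 100, 100)
        assert np.all(trace.steady_counts == 200)

    def test_weak_inhibition_extinguishes(self):
        res = generate_reservoir(ReservoirConfig(200, 16, -0.1, seed=2))
        trace = run_free(res, init_state(200, 0.2, 2), 100, 100)
        assert np.all(trace.steady_counts == 0)

    @pytest.mark.parametrize("lam", [2.0, 0.5])
    def test_scale_invariance_bit_exact(self, small_reservoir, lam):
        state = init_state(200, 0.2, 5)
        scaled = dataclasses.replace(small_reservoir,
                                     weights=lam * small_reservoir.weights)
        t1 = run_free(small_reservoir, state, 50, 100)
        t2 = run_free(scaled, state, 50, 100)
        assert np.array_equal(t1.counts, t2.counts)

    def test_steady_window_must_be_nonempty(self):
        with pytest.raises(ValueError):
            ActivityTrace(np.array([1, 2, 3]), 10, 3)


class TestRunDriven:
    def test_zero_input_matches_free_run(self, small_reservoir):
        state = init_state(200, 0.2, 9)
        free = run_free(small_reservoir, state, 1, 99)
        driven, history = run_driven(small_reservoir, state, np.zeros(100))
        assert np.array_equal(free.counts, driven.counts)
        assert history.shape == (100, 100)

    def test_readout_history_aligned_with_input(self, small_reservoir, rng):
        u = rng.uniform(0.1, 0.9, 40)
        _, history = run_driven(small_reservoir, init_state(200, 0.2, 1), u)
        assert history.shape == (40, 100)
        assert history.dtype == np.uint8

    def test_joint_scaling_of_recurrent_and_input_weights(self, small_reservoir,
                                                          rng):
        u = rng.uniform(0.1, 0.9, 60)
        state = init_state(200, 0.2, 4)
        scaled = dataclasses.replace(
            small_reservoir, weights=2.0 * small_reservoir.weights,
            input_weights=2.0 * small_reservoir.input_weights)
        t1, h1 = run_driven(small_reservoir, state, u)
        t2, h2 = run_driven(scaled, state, u)
        assert np.array_equal(t1.counts, t2.counts)
        assert np.array_equal(h1, h2)


def test_serialization_roundtrip(tmp_path, small_reservoir):
    path = tmp_path / "res.npz"
    save_reservoir(small_reservoir, path)
    loaded = load_reservoir(path)
    assert loaded.config == small_reservoir.config
    assert np.array_equal(loaded.weights, small_reservoir.weights)
    assert np.array_equal(loaded.pre_indices, small_reservoir.pre_indices)
    state = init_state(200, 0.2, 8)
    assert np.array_equal(run_free(loaded, state, 10, 20).counts,
                          run_free(small_reservoir, state, 10, 20).counts)
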