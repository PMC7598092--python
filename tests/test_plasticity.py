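"""Hebbian rule, synaptic normalization, and their interaction with the
chunked integrator, checked against scalar double-loop references."""

import numpy as np
import pytest

import neuromass as nm
from neuromass.model import INTERNAL_PRE_POST
from reference import (
    FullHistoryIntegrator,
    make_network_f,
    scalar_hebbian_external,
    scalar_hebbian_internal,
)


class TestNormalizeWeights:
    def test_incoming_rows_sum_to_one(self):
        W = np.array([[0.2, 0.6, 0.0, 1.2], [0.0] * 4, [1.0, 0, 0, 1.0], [0.5, 0, 0, 0]])
        out = nm.normalize_weights(W)
        assert np.allclose(out[0], [0.1, 0.3, 0.0, 0.6])
        assert np.array_equal(out[1], np.zeros(4))  # all-zero row untouched
        assert out.sum(axis=1)[2] == pytest.approx(1.0, abs=1e-15)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        W = rng.random((5, 5)) * (rng.random((5, 5)) < 0.5)
        once = nm.normalize_weights(W)
        twice = nm.normalize_weights(once)
        assert np.allclose(once, twice, atol=1e-15)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            nm.normalize_weights(np.array([[0.0, -0.1], [0.0, 0.0]]))


class TestExternalRule:
    def test_zero_source_or_unchanged_target_gives_zero_delta(self):
        W = np.array([[0.0, 0.5], [0.3, 0.0]])
        E_now, E_prev = np.array([0.4, 0.2]), np.array([0.4, 0.2])
        # unchanged target: no update at all (before normalization)
        out = nm.plasticity.hebbian_delta_external(W, np.ones((2, 2)), E_now, E_prev, 0.01)
        assert np.array_equal(out, W)
        # zero delayed source: also no update
        out = nm.plasticity.hebbian_delta_external(
            W, np.zeros((2, 2)), np.array([0.5, 0.1]), E_prev, 0.01)
        assert np.array_equal(out, W)

    def test_hand_computed_delta(self):
        # c=0.01, delayed source 0.5, target rises 0.3 -> 0.4: dW = 5e-4
        W = np.array([[0.0, 0.2], [0.0, 0.0]])
        E_delayed = np.array([[0.0, 0.5], [0.0, 0.0]])
        out = nm.plasticity.hebbian_delta_external(
            W, E_delayed, np.array([0.4, 0.0]), np.array([0.3, 0.0]), 0.01)
        assert out[0, 1] == pytest.approx(0.2 + 5e-4, abs=1e-15)

    def test_zero_weights_never_updated(self):
        rng = np.random.default_rng(2)
        W = rng.random((6, 6)) * (rng.random((6, 6)) < 0.4)
        np.fill_diagonal(W, 0.0)
        zero_mask = W == 0
        out = nm.plasticity.hebbian_delta_external(
            W, rng.random((6, 6)), rng.random(6), rng.random(6), 0.05)
        assert np.all(out[zero_mask] == 0.0)

    def test_clipped_at_zero(self):
        W = np.array([[0.0, 1e-6], [0.0, 0.0]])
        E_delayed = np.full((2, 2), 1.0)
        out = nm.plasticity.hebbian_delta_external(
            W, E_delayed, np.array([0.0, 0.0]), np.array([1.0, 0.0]), 0.5)
        assert out[0, 1] == 0.0

    def test_matches_scalar_reference(self):
        rng = np.random.default_rng(3)
        W = rng.random((8, 8)) * (rng.random((8, 8)) < 0.5)
        np.fill_diagonal(W, 0.0)
        E_delayed = rng.random((8, 8))
        E_now, E_prev = rng.random(8), rng.random(8)
        vec = nm.normalize_weights(
            nm.plasticity.hebbian_delta_external(W, E_delayed, E_now, E_prev, 0.02))
        ref = scalar_hebbian_external(W, E_delayed, E_now, E_prev, 0.02)
        assert np.allclose(vec, ref, atol=1e-14)


class TestInternalRule:
    def test_scalar_rule_examples(self):
        assert nm.hebbian_update_internal(1.0, 0.0, 0.5, 0.3, 0.01) == 1.0
        assert nm.hebbian_update_internal(1.0, 0.7, 0.5, 0.5, 0.01) == 1.0
        # c=0.01, pre=1.0, post falls 0.6 -> 0.5: dw = -1e-3
        assert nm.hebbian_update_internal(1.0, 1.0, 0.5, 0.6, 0.01) == pytest.approx(
            1.0 - 1e-3, abs=1e-15)
        # clipping at zero
        assert nm.hebbian_update_internal(1e-4, 1.0, 0.0, 1.0, 1.0) == 0.0

    def test_vectorized_conserves_total_and_matches_scalar(self):
        rng = np.random.default_rng(4)
        n = 6
        w = rng.uniform(0.1, 2.0, size=(n, 7))
        act_now = rng.random((3, n))
        act_prev = rng.random((3, n))
        out = nm.update_internal_weights(w, act_now, act_prev, 0.05)
        assert np.allclose(out.sum(axis=1), w.sum(axis=1), atol=1e-12)
        ref = scalar_hebbian_internal(w, act_now, act_prev, 0.05, INTERNAL_PRE_POST)
        assert np.allclose(out, ref, atol=1e-13)

    def test_partial_plastic_set_leaves_others_untouched(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(0.5, 1.5, size=(4, 7))
        out = nm.update_internal_weights(w, rng.random((3, 4)), rng.random((3, 4)),
                                         0.1, plastic_set=(1, 4))
        frozen = [1, 2, 4, 5, 6]  # 0-based indices of w2, w3, w5, w6, w7
        assert np.array_equal(out[:, frozen], w[:, frozen])
        assert np.allclose(out[:, [0, 3]].sum(axis=1), w[:, [0, 3]].sum(axis=1),
                           atol=1e-12)


class TestPlasticityInSimulation:
    def test_zero_learning_rate_is_bitwise_plasticity_off(self, small_random_connectome, params):
        cfg = nm.EngineConfig(t_end=300.0)
        res_off = nm.simulate(small_random_connectome, params, cfg,
                              snapshot_interval=100.0)
        res_zero = nm.simulate(small_random_connectome, params, cfg,
                               plasticity_config=nm.PlasticityConfig(c=0.0),
                               snapshot_interval=100.0)
        assert res_off.series.content_hash() == res_zero.series.content_hash()
        assert np.array_equal(res_off.final_state.stacked(),
                              res_zero.final_state.stacked())

    def test_sparsity_pattern_invariant(self, small_random_connectome, params):
        plast = nm.PlasticityConfig(c=0.01)
        res = nm.simulate(small_random_connectome, params,
                          nm.EngineConfig(t_end=500.0), plasticity_config=plast,
                          snapshot_interval=100.0)
        pattern0 = small_random_connectome.W > 0
        for W in res.series.external_weights:
            assert np.array_equal(W > 0, pattern0)

    def test_incoming_sums_one_after_every_update(self, small_random_connectome, params):
        plast = nm.PlasticityConfig(c=0.01, update_every=10)
        res = nm.simulate(small_random_connectome, params,
                          nm.EngineConfig(t_end=400.0), plasticity_config=plast,
                          snapshot_interval=10.0)
        # every snapshot from the first update onward has normalized rows
        for t, W in zip(res.series.times, res.series.external_weights):
            if t < 10.0:
                continue
            sums = W.sum(axis=1)
            assert np.all(np.abs(sums[sums > 0] - 1.0) < 1e-12)

    def test_weights_stay_nonnegative(self, small_random_connectome, params):
        plast = nm.PlasticityConfig(c=0.5)  # aggressive learning rate
        res = nm.simulate(small_random_connectome, params,
                          nm.EngineConfig(t_end=300.0), plasticity_config=plast,
                          snapshot_interval=50.0)
        for W, wint in zip(res.series.external_weights, res.series.internal_weights):
            assert np.all(W >= 0) and np.all(wint >= 0)

    def test_full_simulation_matches_scalar_reference(self, tiny_connectome, params):
        """100 steps of the 3-region network with plasticity every 10 steps:
        the engine must match a full-history integrator that applies the
        scalar double-loop rule."""
        h, n_steps, c = 1.0, 100, 0.01
        plast = nm.PlasticityConfig(c=c, update_every=10)
        res = nm.simulate(tiny_connectome, params,
                          nm.EngineConfig(t_end=float(n_steps), step=h),
                          plasticity_config=plast)

        n = tiny_connectome.n
        W_ref = tiny_connectome.W.copy()
        w_ref = params.internal_weights(n)
        D = tiny_connectome.D
        state = {"params": params.with_internal_weights(w_ref), "W": W_ref}
        ref = FullHistoryIntegrator(0.0, np.full(3 * n, 0.1))

        def f(t, y, interp):
            return make_network_f(state["W"], D, state["params"])(t, y, interp)

        def callback(step_idx):
            if step_idx % 10 != 0:
                return None
            t_now = float(step_idx)
            E_delayed = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    if state["W"][i, j] > 0:
                        E_delayed[i, j] = ref.interp(t_now - D[i, j])[j]
            E_now = ref.interp(t_now)[:n]
            E_prev = ref.interp(t_now - h)[:n]
            state["W"] = scalar_hebbian_external(state["W"], E_delayed, E_now, E_prev, c)
            y_now = ref.interp(t_now)
            y_prev = ref.interp(t_now - h)
            w_new = scalar_hebbian_internal(
                np.column_stack([np.asarray(getattr(state["params"], f"w{k}"))
                                 for k in range(1, 8)]),
                y_now.reshape(3, n), y_prev.reshape(3, n), c, INTERNAL_PRE_POST)
            state["params"] = state["params"].with_internal_weights(w_new)
            return f(t_now, ref.ys[-1], ref.interp)

        ref.run(f, h, n_steps, callback=callback)
        assert np.max(np.abs(res.final_state.stacked() - ref.ys[-1])) < 1e-9
        assert np.max(np.abs(res.final_external_weights - state["W"])) < 1e-11
        w_final_ref = np.column_stack([
            np.asarray(getattr(state["params"], f"w{k}")) for k in range(1, 8)])
        assert np.max(np.abs(res.final_internal_weights - w_final_ref)) < 1e-11

    def test_oja_rule_plugin_runs_and_differs(self, small_random_connectome, params):
        cfg = nm.EngineConfig(t_end=200.0)
        heb = nm.simulate(small_random_connectome, params, cfg,
                          plasticity_config=nm.PlasticityConfig(c=0.05, internal_on=False),
                          snapshot_interval=200.0)
        oja = nm.simulate(small_random_connectome, params, cfg,
                          plasticity_config=nm.PlasticityConfig(c=0.05, internal_on=False,
                                                                rule="oja"),
                          snapshot_interval=200.0)
        assert not np.array_equal(heb.series.external_weights[-1],
                                  oja.series.external_weights[-1])


class TestPlasticityConfig:
    @pytest.mark.parametrize("kwargs", [
        {"c": -0.1}, {"update_every": 0}, {"rule": "bcm"},
        {"plastic_internal_set": (0, 8)},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            nm.PlasticityConfig(**kwargs)
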