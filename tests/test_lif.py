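"""LIF neuron dynamics: worked examples, scalar-loop equivalence, and the
surrogate-gradient backward against a hand-unrolled autodiff oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spikehar as sh
from spikehar.lif import sigmoid

from oracles import lif_scalar_loop, unrolled_lif_network


def _seq(vals):
    return np.asarray(vals, dtype=np.float32).reshape(1, 1, -1)


class TestElementaryOps:
    @pytest.mark.parametrize("v_prev,c_t,tau,expected", [
        (0.0, 0.3, 1.0, 0.3),
        (0.3, 0.3, 1.0, 0.6),
        (0.8, 0.1, 0.0, 0.1),   # tau=0 erases history
    ])
    def test_charge(self, v_prev, c_t, tau, expected):
        out = sh.charge(np.float32(v_prev), np.float32(c_t), tau)
        assert out == pytest.approx(expected)

    def test_charge_shape_mismatch_names_shapes(self):
        with pytest.raises(ValueError, match=r"\(2,\).*\(3,\)"):
            sh.charge(np.zeros(2), np.zeros(3), 0.5)

    @pytest.mark.parametrize("v_pre,v_th,expected", [
        (0.6, 0.5, 1.0),
        (0.5, 0.5, 0.0),   # strict inequality: equality does not spike
        (-1.0, 0.5, 0.0),
    ])
    def test_fire(self, v_pre, v_th, expected):
        assert sh.fire(np.float32(v_pre), v_th) == expected

    @pytest.mark.parametrize("v_pre,s,mode,expected", [
        (0.6, 1.0, "soft", 0.1),
        (0.6, 1.0, "hard", 0.0),
        (0.3, 0.0, "soft", 0.3),
        (0.3, 0.0, "hard", 0.3),
    ])
    def test_reset(self, v_pre, s, mode, expected):
        out = sh.reset(np.float32(v_pre), np.float32(s), 0.5, mode)
        assert out == pytest.approx(expected, abs=1e-7)

    def test_reset_unknown_mode(self):
        with pytest.raises(ValueError, match="unknown reset mode"):
            sh.reset(np.float32(0.1), np.float32(0.0), 0.5, "bounce")

    @pytest.mark.parametrize("v_pre,v_th,expected", [
        (0.5, 0.5, 1.0),    # apex at threshold
        (0.0, 0.5, 0.0),    # left foot
        (1.0, 0.5, 0.0),    # right foot at 2*v_th
        (0.25, 0.5, 0.5),
        (-0.3, 0.5, 0.0),
        (2.0, 0.5, 0.0),
    ])
    def test_surrogate_triangle(self, v_pre, v_th, expected):
        assert sh.surrogate_grad(np.float32(v_pre), v_th) == pytest.approx(expected)


class TestForward:
    def test_worked_trace_soft_reset(self):
        """Input [0.3, 0.3, 0.3] with tau=1, v_th=0.5: charges to 0.6 at step 2,
        spikes once, soft reset leaves 0.1, then recharges to 0.4."""
        spikes, trace = sh.lif_forward(_seq([0.3, 0.3, 0.3]),
                                       sh.LIFConfig(tau=1.0, v_th=0.5, reset_mode="soft"))
        np.testing.assert_array_equal(spikes.values.ravel(), [0, 1, 0])
        np.testing.assert_allclose(trace.v_post.ravel(), [0.3, 0.1, 0.4], atol=1e-6)

    def test_zero_input_stays_silent(self):
        spikes, trace = sh.lif_forward(np.zeros((2, 3, 5), np.float32), sh.LIFConfig())
        assert not spikes.values.any()
        assert not trace.v_pre.any() and not trace.v_post.any()

    def test_empty_time_axis_raises(self):
        with pytest.raises(ValueError, match="T must be >= 1"):
            sh.lif_forward(np.zeros((1, 1, 0), np.float32), sh.LIFConfig())

    def test_tau0_is_stepwise_binary_activation(self):
        """With tau=0 each step thresholds independently: permuting the input's
        time steps permutes the spikes identically."""
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (2, 4, 12)).astype(np.float32)
        cfg = sh.LIFConfig(tau=0.0, v_th=0.5)
        perm = rng.permutation(12)
        s_then_perm = sh.lif_forward(x, cfg)[0].values[..., perm]
        s_of_perm = sh.lif_forward(x[..., perm], cfg)[0].values
        np.testing.assert_array_equal(s_then_perm, s_of_perm)
        np.testing.assert_array_equal(s_of_perm, (x[..., perm] > 0.5).astype(np.float32))

    def test_matches_scalar_reference_loop(self):
        """Vectorized dynamics agree bit-exactly with a naive per-neuron
        per-step loop over 200 random instances and all config combinations."""
        rng = np.random.default_rng(42)
        combos = [(tau, v_th, mode)
                  for tau in (0.0, 0.25, 0.5, 0.75, 1.0)
                  for v_th in (0.25, 0.5, 1.0)
                  for mode in ("hard", "soft")]
        for i in range(200):
            n = int(rng.integers(1, 5))
            c = int(rng.integers(1, 9))
            T = int(rng.integers(1, 17))
            x = rng.normal(0, 1.5, (n, c, T)).astype(np.float32)
            tau, v_th, mode = combos[i % len(combos)]
            cfg = sh.LIFConfig(tau=tau, v_th=v_th, reset_mode=mode)
            spikes, trace = sh.lif_forward(x, cfg)
            ref_s, ref_pre, ref_post = lif_scalar_loop(x, tau, v_th, mode)
            np.testing.assert_array_equal(spikes.values, ref_s)
            np.testing.assert_array_equal(trace.v_pre, ref_pre)
            np.testing.assert_array_equal(trace.v_post, ref_post)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariants_random_inputs(self, seed):
        """Spikes exactly binary; spike iff v_pre > v_th; soft-reset bookkeeping
        v_post + s*v_th == v_pre; hard reset zeroes exactly the spiking entries."""
        rng = np.random.default_rng(seed)
        x = (rng.normal(0, 2.0, (2, 3, 10)) * 10.0 ** rng.integers(-2, 3)).astype(np.float32)
        for mode in ("hard", "soft"):
            cfg = sh.LIFConfig(tau=float(rng.uniform(0, 1)), v_th=0.5, reset_mode=mode)
            spikes, trace = sh.lif_forward(x, cfg)
            s = spikes.values
            assert np.all((s == 0.0) | (s == 1.0))
            np.testing.assert_array_equal(s, (trace.v_pre > cfg.v_th).astype(np.float32))
            if mode == "soft":
                np.testing.assert_allclose(trace.v_post + s * np.float32(cfg.v_th),
                                           trace.v_pre, rtol=0, atol=0)
            else:
                assert not trace.v_post[s == 1.0].any()

    def test_monotone_in_current_charge(self):
        """At fixed history, increasing the charge at a step never turns that
        step's spike off."""
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, (1, 5, 8)).astype(np.float32)
        cfg = sh.LIFConfig(tau=0.6, v_th=0.5)
        s0 = sh.lif_forward(x, cfg)[0].values
        x_up = x.copy()
        x_up[..., 4] += 0.7
        s1 = sh.lif_forward(x_up, cfg)[0].values
        assert np.all(s1[..., 4] >= s0[..., 4])


class TestConfig:
    def test_learnable_tau_reads_sigmoid_of_b(self):
        cfg = sh.LIFConfig(learnable_tau=True, b=0.0)
        assert cfg.effective_tau == pytest.approx(0.5)
        cfg.b = 2.0
        assert cfg.effective_tau == pytest.approx(float(sigmoid(2.0)))

    @pytest.mark.parametrize("kw", [dict(tau=-0.1), dict(tau=1.5), dict(v_th=0.0),
                                    dict(v_th=-1.0), dict(reset_mode="none")])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            sh.LIFConfig(**kw)


class TestBackward:
    def test_single_step_chain(self):
        """T=1: dL/dc = dL/ds * surrogate(v_pre); no temporal terms."""
        x = _seq([0.3])
        cfg = sh.LIFConfig(tau=0.5, v_th=0.5)
        _, trace = sh.lif_forward(x, cfg)
        g = np.ones_like(x)
        gx, gb = sh.lif_backward(g, trace)
        assert gb is None
        assert gx.ravel()[0] == pytest.approx(sh.surrogate_grad(np.float32(0.3), 0.5))

    def test_tau0_has_no_cross_time_terms(self):
        """With tau=0 the gradient at step t depends only on step t."""
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (1, 2, 6)).astype(np.float32)
        cfg = sh.LIFConfig(tau=0.0, v_th=0.5)
        _, trace = sh.lif_forward(x, cfg)
        g = np.zeros_like(x)
        g[..., 3] = 1.0
        gx, _ = sh.lif_backward(g, trace)
        mask = np.ones(6, bool)
        mask[3] = False
        assert not gx[..., mask].any()

    @pytest.mark.parametrize("mode", ["soft", "hard"])
    @pytest.mark.parametrize("tau", [0.5, 0.75])
    def test_matches_unrolled_autodiff_oracle(self, mode, tau):
        """2-neuron, T=3 linear+LIF network: weight and input gradients equal a
        hand-unrolled scalar-autodiff evaluation with the same surrogate.

        Dyadic-rational inputs keep float32 arithmetic exact, so agreement is
        far tighter than the 1e-6 relative tolerance asserted.
        """
        x = np.array([[0.25, 0.75, -0.5], [0.5, -0.25, 1.0]])       # (C_in=2, T=3)
        W = np.array([[0.5, -0.25], [0.75, 0.125]])                 # (C_out=2, C_in=2)
        upstream = np.array([[1.0, -0.5, 0.25], [0.5, 1.0, -0.25]])
        v_th = 0.5
        dW_ref, dx_ref, _ = unrolled_lif_network(x, W, tau, v_th, mode, upstream)

        c = np.einsum("oi,it->ot", W, x)[None].astype(np.float32)   # (1, C_out, T)
        cfg = sh.LIFConfig(tau=tau, v_th=v_th, reset_mode=mode)
        _, trace = sh.lif_forward(c, cfg)
        gc, _ = sh.lif_backward(upstream[None].astype(np.float32), trace)
        dW = np.einsum("not,it->oi", gc, x.astype(np.float32))
        dx = np.einsum("not,oi->it", gc, W.astype(np.float32))
        np.testing.assert_allclose(dW, dW_ref, rtol=1e-6)
        np.testing.assert_allclose(dx, dx_ref, rtol=1e-6)

    @pytest.mark.parametrize("mode", ["soft", "hard"])
    def test_learnable_decay_gradient_matches_oracle(self, mode):
        """dL/db via dv_pre/dtau = v_post(t-1) and dtau/db = sigmoid'(b)."""
        x = np.array([[0.25, 0.75, -0.5], [0.5, -0.25, 1.0]])
        W = np.array([[0.5, -0.25], [0.75, 0.125]])
        upstream = np.array([[1.0, -0.5, 0.25], [0.5, 1.0, -0.25]])
        b0, v_th = 0.0, 0.5
        _, _, db_ref = unrolled_lif_network(x, W, 0.0, v_th, mode, upstream,
                                            learnable_tau_b=b0)
        c = np.einsum("oi,it->ot", W, x)[None].astype(np.float32)
        cfg = sh.LIFConfig(v_th=v_th, reset_mode=mode, learnable_tau=True, b=b0)
        _, trace = sh.lif_forward(c, cfg)
        _, db = sh.lif_backward(upstream[None].astype(np.float32), trace)
        assert db == pytest.approx(db_ref, rel=1e-5, abs=1e-7)
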