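"""LSTM cell, bidirectional combination, attention, head, and gradients."""

import math

import numpy as np
import pytest

from dolphinseg.features import BlockGrid
from dolphinseg.lstm import (
    LSTMParams,
    LSTMState,
    attention_pool,
    bilstm_states,
    init_lstm_params,
    lstm_cell_step,
    lstm_forward,
)
from dolphinseg.model import batch_loss_and_grads, init_model


def _zero_params(d, nh):
    return LSTMParams(np.zeros((d, 4 * nh)), np.zeros((nh, 4 * nh)), np.zeros(4 * nh))


def _scalar_cell_oracle(x, h_prev, c_prev, params):
    """Per-gate scalar-loop reference implementation of one cell step."""
    nh, d = params.hidden, params.d
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    h_out, c_out = np.zeros(nh), np.zeros(nh)
    for u in range(nh):
        acts = {}
        for gi, name in enumerate(("input", "forget", "candidate", "output")):
            a = params.b[gi * nh + u]
            for k in range(d):
                a += x[k] * params.W[k, gi * nh + u]
            for k in range(nh):
                a += h_prev[k] * params.U[k, gi * nh + u]
            acts[name] = a
        i = sig(acts["input"])
        f = sig(acts["forget"])
        g = math.tanh(acts["candidate"])
        o = sig(acts["output"])
        c_out[u] = f * c_prev[u] + i * g
        h_out[u] = o * math.tanh(c_out[u])
    return h_out, c_out


class TestCell:
    def test_zero_params_zero_state(self, rng):
        params = _zero_params(5, 3)
        out = lstm_cell_step(rng.normal(size=5), LSTMState(np.zeros(3), np.zeros(3)), params)
        assert np.allclose(out.h, 0.0) and np.allclose(out.c, 0.0)

    def test_zero_params_unit_cell(self, rng):
        # i = f = o = 0.5, g = 0 -> c = 0.5, h = 0.5*tanh(0.5)
        params = _zero_params(4, 2)
        out = lstm_cell_step(rng.normal(size=4), LSTMState(np.zeros(2), np.ones(2)), params)
        assert np.allclose(out.c, 0.5)
        assert np.allclose(out.h, 0.5 * math.tanh(0.5))

    def test_matches_scalar_oracle(self):
        for seed in range(50):
            r = np.random.default_rng(seed)
            d, nh = int(r.integers(1, 6)), int(r.integers(1, 5))
            params = init_lstm_params(d, nh, r, scale=0.5)
            x = r.normal(size=d)
            h_prev, c_prev = r.normal(size=nh), r.normal(size=nh)
            out = lstm_cell_step(x, LSTMState(h_prev, c_prev), params)
            h_ref, c_ref = _scalar_cell_oracle(x, h_prev, c_prev, params)
            assert np.allclose(out.h, h_ref, atol=1e-10)
            assert np.allclose(out.c, c_ref, atol=1e-10)

    def test_hidden_state_bounded(self, rng):
        params = init_lstm_params(3, 4, rng, scale=2.0)
        state = LSTMState(np.zeros(4), np.zeros(4))
        for _ in range(1000):
            state = lstm_cell_step(rng.normal(scale=3.0, size=3), state, params)
            assert np.all(np.abs(state.h) <= 1.0)

    def test_nonfinite_rejected(self):
        params = _zero_params(2, 2)
        with pytest.raises((FloatingPointError, ValueError)):
            lstm_cell_step(np.array([np.nan, 0.0]), LSTMState(np.zeros(2), np.zeros(2)), params)

    def test_gate_views(self, rng):
        params = init_lstm_params(3, 2, rng)
        Wf, Uf, bf = params.gate("forget")
        assert Wf.shape == (3, 2) and Uf.shape == (2, 2) and bf.shape == (2,)
        assert np.shares_memory(Wf, params.W)


class TestBidirectional:
    def test_shapes_and_t1(self, rng):
        fwd = init_lstm_params(4, 3, rng)
        bwd = init_lstm_params(4, 3, rng)
        X = rng.normal(size=(2, 1, 4))
        H, _, _ = bilstm_states(X, fwd, bwd)
        assert H.shape == (2, 1, 6)
        # T=1: both halves read the same single input from zero state
        hf, _, _ = lstm_forward(X, fwd)
        hb, _, _ = lstm_forward(X, bwd)
        assert np.allclose(H[:, 0, :3], hf[:, 0])
        assert np.allclose(H[:, 0, 3:], hb[:, 0])

    def test_backward_half_equals_reversed_forward_oracle(self, rng):
        """Backward states must equal running the backward params forward
        over the reversed sequence, then reversing — exactly."""
        fwd = init_lstm_params(5, 4, rng)
        bwd = init_lstm_params(5, 4, rng)
        X = rng.normal(size=(3, 7, 5))
        H, _, _ = bilstm_states(X, fwd, bwd)
        h_rev, _, _ = lstm_forward(X[:, ::-1], bwd)
        assert np.array_equal(H[..., 4:], h_rev[:, ::-1])

    def test_reversal_equivariance(self, rng):
        fwd = init_lstm_params(3, 2, rng)
        bwd = init_lstm_params(3, 2, rng)
        X = rng.normal(size=(1, 6, 3))
        H, _, _ = bilstm_states(X, fwd, bwd)
        H_swap, _, _ = bilstm_states(X[:, ::-1], bwd, fwd)
        assert np.allclose(H_swap[:, ::-1, :2], H[..., 2:])
        assert np.allclose(H_swap[:, ::-1, 2:], H[..., :2])

    def test_empty_sequence_rejected(self, rng):
        p = init_lstm_params(3, 2, rng)
        with pytest.raises(ValueError):
            bilstm_states(np.zeros((1, 0, 3)), p, p)

    def test_cell_state_mode(self, rng):
        fwd = init_lstm_params(3, 2, rng)
        bwd = init_lstm_params(3, 2, rng)
        X = rng.normal(size=(1, 4, 3))
        H, _, _ = bilstm_states(X, fwd, bwd, concat_cell_states=True)
        _, cf, _ = lstm_forward(X, fwd)
        assert np.allclose(H[..., :2], cf)


class TestAttention:
    def test_identical_rows_uniform(self, rng):
        row = rng.normal(size=6)
        H = np.tile(row, (5, 1))
        w, ctx = attention_pool(H, rng.normal(size=6))
        assert np.allclose(w, 0.2)
        assert np.allclose(ctx, row)

    def test_zero_scores_uniform(self, rng):
        H = rng.normal(size=(4, 6))
        w, _ = attention_pool(H, np.zeros(6))
        assert np.allclose(w, 0.25)

    def test_softmax_hand_value(self):
        # scores (0, ln 3) -> weights (0.25, 0.75)
        H = np.array([[0.0], [math.log(3.0)]])
        w, ctx = attention_pool(H, np.array([1.0]))
        assert np.allclose(w, [0.25, 0.75])
        assert np.allclose(ctx, [0.75 * math.log(3.0)])

    def test_simplex_property(self, rng):
        for _ in range(20):
            H = rng.normal(scale=5.0, size=(7, 4))
            w, ctx = attention_pool(H, rng.normal(size=4))
            assert np.all(w >= 0)
            assert abs(w.sum() - 1.0) < 1e-12
            assert np.allclose(ctx, (w[:, None] * H).sum(axis=0))


class TestGradients:
    @pytest.mark.parametrize("seed", range(5))
    def test_backprop_matches_finite_differences(self, seed):
        """Exact backprop vs central differences on a T=4, hidden=3, d=5 model."""
        r = np.random.default_rng(seed)
        grid = BlockGrid(2, 2, 2, 2, 4, 4)
        model = init_model(5, 3, r)
        X = r.normal(size=(2, 4, 5))
        masks = (r.random((2, 4, 4)) < 0.5).astype(float)
        _, grads = batch_loss_and_grads(model, X, masks, grid, "bilinear", 1.0)
        vec = model.to_vector()
        num = np.zeros_like(vec)
        h = 1e-6
        for k in range(vec.size):
            vp, vm = vec.copy(), vec.copy()
            vp[k] += h
            vm[k] -= h
            lp, _ = batch_loss_and_grads(model.from_vector(vp), X, masks, grid, "bilinear", 1.0)
            lm, _ = batch_loss_and_grads(model.from_vector(vm), X, masks, grid, "bilinear", 1.0)
            num[k] = (lp - lm) / (2 * h)
        scale = max(np.abs(num).max(), np.abs(grads).max(), 1e-12)
        assert np.abs(num - grads).max() / scale < 1e-4

    def test_gradient_through_dropout_mask_and_nearest(self):
        r = np.random.default_rng(7)
        grid = BlockGrid(2, 2, 2, 2, 4, 4)
        model = init_model(3, 2, r)
        X = r.normal(size=(1, 4, 3))
        masks = (r.random((1, 4, 4)) < 0.5).astype(float)
        drop = (r.random((1, 4, 4)) < 0.5) / 0.5
        _, grads = batch_loss_and_grads(model, X, masks, grid, "nearest", 1.0, drop)
        vec = model.to_vector()
        h = 1e-6
        for k in r.choice(vec.size, size=25, replace=False):
            vp, vm = vec.copy(), vec.copy()
            vp[k] += h
            vm[k] -= h
            lp, _ = batch_loss_and_grads(model.from_vector(vp), X, masks, grid, "nearest", 1.0, drop)
            lm, _ = batch_loss_and_grads(model.from_vector(vm), X, masks, grid, "nearest", 1.0, drop)
            assert (lp - lm) / (2 * h) == pytest.approx(grads[k], abs=1e-6, rel=1e-4)
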