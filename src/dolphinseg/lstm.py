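"""Bidirectional LSTM core: recurrences, attention pooling, prediction head,
and exact gradients for the whole stack.

The cell follows standard LSTM semantics with gate order (input, forget,
candidate, output):

    i_t = sigmoid(x_t W_i + h_{t-1} U_i + b_i)
    f_t = sigmoid(x_t W_f + h_{t-1} U_f + b_f)
    g_t = tanh   (x_t W_g + h_{t-1} U_g + b_g)
    o_t = sigmoid(x_t W_o + h_{t-1} U_o + b_o)
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

Two such recurrences run over the block sequence, one forward and one on
the reversed sequence; per-position hidden states are concatenated into
H, attention-pooled into a context vector c, and a per-position head
z_t = [H_t | c] . w_o + b_o produces the block probability grid.  All
arrays are batched (B, T, ...) and everything is plain numpy, so results
are bit-reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np

GATES = ("input", "forget", "candidate", "output")


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclasses.dataclass
class LSTMParams:
    """One direction's parameters, gates stacked along the last axis.

    W : (d, 4*hidden) input weights, U : (hidden, 4*hidden) recurrent
    weights, b : (4*hidden,) biases; slices in GATES order.
    """

    W: np.ndarray
    U: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        d4 = self.W.shape[1]
        if d4 % 4 or self.U.shape != (d4 // 4, d4) or self.b.shape != (d4,):
            raise ValueError("inconsistent LSTM parameter shapes")
        if not all(np.all(np.isfinite(a)) for a in (self.W, self.U, self.b)):
            raise ValueError("LSTM parameters must be finite")

    @property
    def hidden(self) -> int:
        return self.U.shape[0]

    @property
    def d(self) -> int:
        return self.W.shape[0]

    def gate(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(input weights, recurrent weights, bias) for one named gate."""
        k = GATES.index(name)
        sl = slice(k * self.hidden, (k + 1) * self.hidden)
        return self.W[:, sl], self.U[:, sl], self.b[sl]

    def copy(self) -> "LSTMParams":
        return LSTMParams(self.W.copy(), self.U.copy(), self.b.copy())


@dataclasses.dataclass
class LSTMState:
    """Hidden and cell vectors of one recurrence step."""

    h: np.ndarray
    c: np.ndarray


def init_lstm_params(d: int, hidden: int, rng: np.random.Generator,
                     scale: float = 0.08, forget_bias: float = 1.0) -> LSTMParams:
    """Uniform(-scale, scale) init; forget-gate bias offset for trainability."""
    W = rng.uniform(-scale, scale, size=(d, 4 * hidden))
    U = rng.uniform(-scale, scale, size=(hidden, 4 * hidden))
    b = rng.uniform(-scale, scale, size=4 * hidden)
    b[hidden : 2 * hidden] += forget_bias
    return LSTMParams(W, U, b)


def _gates(x: np.ndarray, h_prev: np.ndarray, params: LSTMParams):
    nh = params.hidden
    a = x @ params.W + h_prev @ params.U + params.b
    i = sigmoid(a[..., :nh])
    f = sigmoid(a[..., nh : 2 * nh])
    g = np.tanh(a[..., 2 * nh : 3 * nh])
    o = sigmoid(a[..., 3 * nh :])
    return i, f, g, o


def lstm_cell_step(x_t: np.ndarray, state: LSTMState, params: LSTMParams) -> LSTMState:
    """One recurrence step on a single input vector."""
    x_t = np.asarray(x_t, dtype=float)
    i, f, g, o = _gates(x_t, state.h, params)
    c_t = f * state.c + i * g
    h_t = o * np.tanh(c_t)
    for name, arr in zip(("input", "forget", "candidate", "output", "cell", "hidden"),
                         (i, f, g, o, c_t, h_t)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite value in LSTM {name} activation")
    return LSTMState(h_t, c_t)


def lstm_forward(X: np.ndarray, params: LSTMParams):
    """Run the recurrence over X of shape (B, T, d) from zero initial state.

    Returns (h_seq (B,T,hidden), c_seq (B,T,hidden), cache for backprop).
    """
    B, T, _ = X.shape
    nh = params.hidden
    h = np.zeros((B, nh))
    c = np.zeros((B, nh))
    h_seq = np.empty((B, T, nh))
    c_seq = np.empty((B, T, nh))
    cache = {"i": np.empty((B, T, nh)), "f": np.empty((B, T, nh)),
             "g": np.empty((B, T, nh)), "o": np.empty((B, T, nh)),
             "tc": np.empty((B, T, nh)), "X": X}
    for t in range(T):
        i, f, g, o = _gates(X[:, t], h, params)
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        h_seq[:, t] = h
        c_seq[:, t] = c
        cache["i"][:, t] = i
        cache["f"][:, t] = f
        cache["g"][:, t] = g
        cache["o"][:, t] = o
        cache["tc"][:, t] = tc
    if not np.all(np.isfinite(h_seq)):
        raise FloatingPointError("non-finite hidden state in LSTM forward pass")
    cache["h_seq"] = h_seq
    cache["c_seq"] = c_seq
    return h_seq, c_seq, cache


def lstm_backward(cache: dict, params: LSTMParams, dh_seq: np.ndarray,
                  dc_seq: np.ndarray | None = None):
    """Backpropagate through `lstm_forward`.

    dh_seq (and optionally dc_seq, for the cell-state readout mode) hold
    the loss gradients w.r.t. the per-step outputs.  Returns
    (dW, dU, db, dX).
    """
    X = cache["X"]
    B, T, _ = X.shape
    nh = params.hidden
    i_, f_, g_, o_, tc = cache["i"], cache["f"], cache["g"], cache["o"], cache["tc"]
    h_seq, c_seq = cache["h_seq"], cache["c_seq"]
    dW = np.zeros_like(params.W)
    dU = np.zeros_like(params.U)
    db = np.zeros_like(params.b)
    dX = np.zeros_like(X)
    dh_next = np.zeros((B, nh))
    dc_next = np.zeros((B, nh))
    for t in range(T - 1, -1, -1):
        dh = dh_seq[:, t] + dh_next
        dc = dc_next + dh * o_[:, t] * (1.0 - tc[:, t] ** 2)
        if dc_seq is not None:
            dc = dc + dc_seq[:, t]
        do = dh * tc[:, t]
        c_prev = c_seq[:, t - 1] if t > 0 else np.zeros((B, nh))
        h_prev = h_seq[:, t - 1] if t > 0 else np.zeros((B, nh))
        di = dc * g_[:, t]
        df = dc * c_prev
        dg = dc * i_[:, t]
        da = np.concatenate(
            [
                di * i_[:, t] * (1.0 - i_[:, t]),
                df * f_[:, t] * (1.0 - f_[:, t]),
                dg * (1.0 - g_[:, t] ** 2),
                do * o_[:, t] * (1.0 - o_[:, t]),
            ],
            axis=1,
        )
        dW += X[:, t].T @ da
        dU += h_prev.T @ da
        db += da.sum(axis=0)
        dX[:, t] = da @ params.W.T
        dh_next = da @ params.U.T
        dc_next = dc * f_[:, t]
    return dW, dU, db, dX


def bilstm_states(X: np.ndarray, forward: LSTMParams, backward: LSTMParams,
                  concat_cell_states: bool = False):
    """Concatenated bidirectional states H of shape (B, T, 2*hidden).

    Row t pairs the forward state after reading x_1..x_t with the
    backward state after reading x_T..x_t; both recurrences start from
    zero states.  With ``concat_cell_states`` the cell (not hidden)
    vectors are concatenated.
    """
    if X.ndim != 3 or X.shape[1] < 1:
        raise ValueError("X must be (B, T, d) with T >= 1")
    hf, cf, cache_f = lstm_forward(X, forward)
    hb_rev, cb_rev, cache_b = lstm_forward(X[:, ::-1], backward)
    hb = hb_rev[:, ::-1]
    cb = cb_rev[:, ::-1]
    if concat_cell_states:
        H = np.concatenate([cf, cb], axis=2)
    else:
        H = np.concatenate([hf, hb], axis=2)
    return H, cache_f, cache_b


def attention_pool(H: np.ndarray, Wa: np.ndarray):
    """Softmax attention over sequence positions.

    H : (T, 2*hidden) or batched (B, T, 2*hidden); Wa : (2*hidden,) or
    (2*hidden, 1).  Returns (weights summing to 1 along T, context =
    weighted row sum).
    """
    Wa = np.asarray(Wa, dtype=float).reshape(-1)
    single = H.ndim == 2
    Hb = H[None] if single else H
    scores = Hb @ Wa  # (B, T)
    scores = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    alpha = e / e.sum(axis=1, keepdims=True)
    context = np.einsum("bt,bth->bh", alpha, Hb)
    if single:
        return alpha[0], context[0]
    return alpha, context


def head_logits(H: np.ndarray, context: np.ndarray, wo: np.ndarray, bo: float) -> np.ndarray:
    """Per-position logits z_t = [H_t | context] . wo + bo, shape (B, T)."""
    nh2 = H.shape[-1]
    return H @ wo[:nh2] + (context @ wo[nh2:])[..., None] + bo
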