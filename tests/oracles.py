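"""Independent reference implementations used only as test oracles.

Each oracle is deliberately naive — scalar loops, per-event enumeration,
textbook formulas — and shares no code with the package internals it checks.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np


# --------------------------------------------------------------------------
# Scalar per-neuron LIF forward loop
# --------------------------------------------------------------------------

def lif_scalar_loop(pre_activation, tau, v_th, reset_mode):
    """Per-neuron, per-step python-loop LIF in float32 (matching arithmetic order)."""
    x = np.asarray(pre_activation, dtype=np.float32)
    n, c, T = x.shape
    spikes = np.zeros_like(x)
    v_post = np.zeros_like(x)
    v_pre = np.zeros_like(x)
    tau = np.float32(tau)
    v_th = np.float32(v_th)
    for i in range(n):
        for j in range(c):
            v = np.float32(0.0)
            for t in range(T):
                vp = np.float32(tau * v) + x[i, j, t]
                s = np.float32(1.0) if vp > v_th else np.float32(0.0)
                if reset_mode == "hard":
                    v = np.float32(vp * (np.float32(1.0) - s))
                else:
                    v = np.float32(vp - s * v_th)
                v_pre[i, j, t] = vp
                spikes[i, j, t] = s
                v_post[i, j, t] = v
    return spikes, v_pre, v_post


# --------------------------------------------------------------------------
# Scalar reverse-mode autodiff with a surrogate-gradient spike op
# --------------------------------------------------------------------------

class Value:
    """Minimal scalar autodiff value (micrograd style), float64."""

    def __init__(self, data: float, children=(), back=None):
        self.data = float(data)
        self.grad = 0.0
        self._children = children
        self._back = back or (lambda: None)

    def __add__(self, other):
        other = other if isinstance(other, Value) else Value(other)
        out = Value(self.data + other.data, (self, other))

        def back():
            self.grad += out.grad
            other.grad += out.grad
        out._back = back
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Value) else Value(other)
        out = Value(self.data * other.data, (self, other))

        def back():
            self.grad += other.data * out.grad
            other.grad += self.data * out.grad
        out._back = back
        return out

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-other if isinstance(other, Value) else Value(-other))

    __radd__ = __add__
    __rmul__ = __mul__

    def backward(self):
        topo: List[Value] = []
        seen = set()

        def visit(v):
            if id(v) not in seen:
                seen.add(id(v))
                for ch in v._children:
                    visit(ch)
                topo.append(v)
        visit(self)
        self.grad = 1.0
        for v in reversed(topo):
            v._back()


def spike(v_pre: Value, v_th: float) -> Value:
    """Step function forward; triangle surrogate max(0, 1-|v/v_th - 1|) backward."""
    s = 1.0 if v_pre.data > v_th else 0.0
    out = Value(s, (v_pre,))
    sg = max(0.0, 1.0 - abs(v_pre.data / v_th - 1.0))

    def back():
        v_pre.grad += sg * out.grad
    out._back = back
    return out


def unrolled_lif_network(x, W, tau, v_th, reset_mode, upstream,
                         learnable_tau_b=None):
    """Hand-unrolled tiny network: per-step linear map then LIF, loss = sum(upstream * s).

    x: (C_in, T) inputs; W: (C_out, C_in) weights; upstream: (C_out, T)
    loss-gradient coefficients.  Returns (dL/dW, dL/dx, dL/db or None), each
    computed purely by the scalar autodiff graph above.
    """
    C_in, T = x.shape
    C_out = W.shape[0]
    xs = [[Value(x[i, t]) for t in range(T)] for i in range(C_in)]
    Ws = [[Value(W[o, i]) for i in range(C_in)] for o in range(C_out)]
    if learnable_tau_b is not None:
        b = Value(learnable_tau_b)
        sig = 1.0 / (1.0 + math.exp(-b.data))
        tau_v = Value(sig, (b,))

        def back_tau():
            b.grad += sig * (1.0 - sig) * tau_v.grad
        tau_v._back = back_tau
    else:
        b = None
        tau_v = Value(tau)

    loss = Value(0.0)
    for o in range(C_out):
        v = Value(0.0)
        for t in range(T):
            c_t = Value(0.0)
            for i in range(C_in):
                c_t = c_t + Ws[o][i] * xs[i][t]
            v_pre = tau_v * v + c_t
            s = spike(v_pre, v_th)
            if reset_mode == "hard":
                v = v_pre * (Value(1.0) - s)
            else:
                v = v_pre - s * v_th
            loss = loss + Value(upstream[o, t]) * s
    loss.backward()

    dW = np.array([[Ws[o][i].grad for i in range(C_in)] for o in range(C_out)])
    dx = np.array([[xs[i][t].grad for t in range(T)] for i in range(C_in)])
    db = b.grad if b is not None else None
    return dW, dx, db


# --------------------------------------------------------------------------
# Per-event energy enumeration
# --------------------------------------------------------------------------

def enumerate_energy_conv1d(x, out_ch, kernel, pad_left, weight_count,
                            table, skipping, lif_updates=0):
    """Sum per-event costs of a same-padded 1-D conv by explicit loops.

    x: (N, C, T) layer input.  An accumulate event (and its weight-scratchpad
    access) happens for every (sample, out-channel, out-position, in-channel,
    tap) whose input entry lies inside the unpadded window; when ``skipping``,
    events on exactly-zero inputs are replaced by e_spa handling charged once
    per zero input entry.
    """
    N, C, T = x.shape
    macs = 0
    for n in range(N):
        for t_out in range(T):
            for dk in range(kernel):
                t_in = t_out + dk - pad_left
                if not (0 <= t_in < T):
                    continue
                for ci in range(C):
                    if (not skipping) or x[n, ci, t_in] != 0:
                        macs += out_ch
    n_zero = int((np.asarray(x) == 0).sum()) if skipping else 0
    compute = macs * table.e_mac + n_zero * table.e_spa + lif_updates * table.e_lif
    move = macs * table.e_wspad + x.size * table.e_ispad + weight_count * table.e_wspad
    return compute, move


def enumerate_energy_dense(x, out_dim, weight_count, table, skipping,
                           lif_updates=0):
    """Per-event cost sum for a dense layer on (N, F) or (N, F, T) input."""
    xf = np.asarray(x).reshape(-1)
    macs = 0
    for v in xf:
        if (not skipping) or v != 0:
            macs += out_dim
    n_zero = int((xf == 0).sum()) if skipping else 0
    compute = macs * table.e_mac + n_zero * table.e_spa + lif_updates * table.e_lif
    move = macs * table.e_wspad + xf.size * table.e_ispad + weight_count * table.e_wspad
    return compute, move


# --------------------------------------------------------------------------
# Textbook CKA (HSIC-ratio form on Gram matrices)
# --------------------------------------------------------------------------

def cka_hsic(X, Y) -> float:
    """Linear CKA via centered Gram matrices: HSIC(K,L)/sqrt(HSIC(K,K)HSIC(L,L))."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    n = X.shape[0]
    K = X @ X.T
    L = Y @ Y.T
    H = np.eye(n) - np.ones((n, n)) / n

    def hsic(A, B):
        return np.trace(A @ H @ B @ H)

    return float(hsic(K, L) / math.sqrt(hsic(K, K) * hsic(L, L)))
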