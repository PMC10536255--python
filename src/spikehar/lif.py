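"""Leaky integrate-and-fire (LIF) neuron dynamics and surrogate-gradient backward pass.

The LIF neuron keeps a membrane potential ``v`` per unit.  At every time step it

1. *charges*:  ``v_pre(t) = tau * v(t-1) + c(t)`` — the potential decays by a
   factor ``tau`` in [0, 1] and receives the pre-synaptic input charge ``c(t)``;
2. *fires*:    ``s(t) = 1`` iff ``v_pre(t) > v_th`` (strict), else 0;
3. *resets*:   hard reset zeroes the potential after a spike,
   soft reset subtracts the threshold ``v_th``.

``tau = 0`` removes all temporal memory (the neuron degenerates to a binary
activation applied independently per step); ``tau = 1`` is a perfect
integrator.

The step function in (2) has zero gradient almost everywhere, so training uses
a *triangle surrogate* for ``ds/dv_pre`` in the backward pass only:

    surrogate(v_pre) = max(0, 1 - |v_pre / v_th - 1|)

which is 1 at ``v_pre == v_th`` and falls to 0 at 0 and ``2 * v_th``.  The
forward pass always uses the exact step.  Backpropagation through time carries
the potential-to-potential factor ``tau`` per step, modulated by the literal
derivative of the reset formula (see :func:`lif_backward`).

The decay factor may be fixed or learnable; a learnable layer stores a raw
scalar ``b`` with ``tau = sigmoid(b)``, which keeps ``tau`` in (0, 1) without
constraints and yields the chain factor ``dtau/db = sigmoid(b)(1-sigmoid(b))``.

All tensors are float32; spikes are exactly 0.0 or 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "LIFConfig",
    "MembraneTrace",
    "SpikeTrain",
    "charge",
    "fire",
    "reset",
    "surrogate_grad",
    "lif_forward",
    "lif_backward",
    "sigmoid",
]

RESET_MODES = ("hard", "soft")


def sigmoid(x):
    """Numerically stable logistic function."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


@dataclass
class LIFConfig:
    """Configuration of one LIF layer.

    Parameters
    ----------
    tau
        Membrane decay factor in [0, 1].  Ignored when ``learnable_tau`` is
        set, in which case ``tau`` is always read as ``sigmoid(b)``.
    v_th
        Firing threshold, > 0, in membrane-potential units.
    reset_mode
        ``"hard"`` (potential zeroed after a spike) or ``"soft"``
        (``v_th`` subtracted after a spike).
    learnable_tau
        If True the decay factor is a trainable scalar parameterized as
        ``sigmoid(b)``.
    b
        Raw decay parameter, used only when ``learnable_tau``; ``b = 0``
        gives ``tau = 0.5``.
    """

    tau: float = 0.75
    v_th: float = 0.5
    reset_mode: str = "soft"
    learnable_tau: bool = False
    b: float = 0.0

    def __post_init__(self):
        if self.reset_mode not in RESET_MODES:
            raise ValueError(
                f"unknown reset_mode {self.reset_mode!r}; expected one of {RESET_MODES}"
            )
        if not self.learnable_tau and not (0.0 <= self.tau <= 1.0):
            raise ValueError(f"tau must lie in [0, 1], got {self.tau}")
        if not self.v_th > 0:
            raise ValueError(f"v_th must be > 0, got {self.v_th}")

    @property
    def effective_tau(self) -> float:
        """Decay factor actually used: ``sigmoid(b)`` when learnable, else ``tau``."""
        if self.learnable_tau:
            return float(sigmoid(self.b))
        return float(self.tau)


@dataclass
class MembraneTrace:
    """Full record of one LIF forward pass, needed for backpropagation.

    All arrays are shaped ``(batch, channels, T)``.  ``v_pre`` is the
    potential after charging but before reset; ``v_post`` after reset;
    ``spikes`` is the binary output.  ``v_init`` is the initial potential
    (batch, channels), zeros by default.
    """

    v_pre: np.ndarray
    v_post: np.ndarray
    spikes: np.ndarray
    v_init: np.ndarray
    config: LIFConfig = field(repr=False)


@dataclass
class SpikeTrain:
    """Binary activations over ``(batch, channels, T)`` — the currency between SNN layers."""

    values: np.ndarray

    def __post_init__(self):
        vals = self.values
        if not np.all((vals == 0.0) | (vals == 1.0)):
            raise ValueError("SpikeTrain entries must be exactly 0 or 1")

    @property
    def firing_rate(self) -> float:
        return float(self.values.mean())


def _check_shapes(a: np.ndarray, b: np.ndarray, op: str) -> None:
    if np.shape(a) != np.shape(b):
        raise ValueError(
            f"{op}: shape mismatch {np.shape(a)} vs {np.shape(b)}"
        )


def charge(v_prev, c_t, tau):
    """Membrane charging step: ``tau * v_prev + c_t`` elementwise."""
    v_prev = np.asarray(v_prev, dtype=np.float32)
    c_t = np.asarray(c_t, dtype=np.float32)
    _check_shapes(v_prev, c_t, "charge")
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    return np.float32(tau) * v_prev + c_t


def fire(v_pre, v_th):
    """Threshold crossing: 1 where ``v_pre > v_th`` strictly, else 0 (float32)."""
    if not v_th > 0:
        raise ValueError(f"v_th must be > 0, got {v_th}")
    return (np.asarray(v_pre) > v_th).astype(np.float32)


def reset(v_pre, s, v_th, mode):
    """Post-spike reset.  hard: ``v_pre * (1 - s)``; soft: ``v_pre - s * v_th``."""
    if mode not in RESET_MODES:
        raise ValueError(f"unknown reset mode {mode!r}; expected one of {RESET_MODES}")
    v_pre = np.asarray(v_pre, dtype=np.float32)
    s = np.asarray(s, dtype=np.float32)
    _check_shapes(v_pre, s, "reset")
    if mode == "hard":
        return v_pre * (np.float32(1.0) - s)
    return v_pre - s * np.float32(v_th)


def surrogate_grad(v_pre, v_th):
    """Triangle surrogate for ``ds/dv_pre``: ``max(0, 1 - |v_pre/v_th - 1|)``.

    Peaks at 1 when ``v_pre == v_th``; zero outside ``[0, 2*v_th]``.  Used in
    the backward pass only.
    """
    if not v_th > 0:
        raise ValueError(f"v_th must be > 0, got {v_th}")
    v_pre = np.asarray(v_pre, dtype=np.float32)
    return np.maximum(np.float32(0.0), np.float32(1.0) - np.abs(v_pre / np.float32(v_th) - np.float32(1.0)))


def lif_forward(
    pre_activation: np.ndarray,
    config: LIFConfig,
    v_init: Optional[np.ndarray] = None,
) -> Tuple[SpikeTrain, MembraneTrace]:
    """Run LIF dynamics along the last (time) axis of ``pre_activation``.

    The charge at step ``t`` is ``pre_activation[..., t]``: the data's own time
    dimension is the SNN time dimension, so no input repeat-coding is needed.

    Parameters
    ----------
    pre_activation
        Real tensor ``(batch, channels, T)`` with ``T >= 1``.
    config
        LIF parameters; the decay factor used is ``config.effective_tau``.
    v_init
        Initial membrane potential ``(batch, channels)``; defaults to zeros.

    Returns
    -------
    (SpikeTrain, MembraneTrace)
    """
    x = np.asarray(pre_activation, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError(f"pre_activation must be 3-D (batch, channels, T), got shape {x.shape}")
    n, c, T = x.shape
    if T == 0:
        raise ValueError("empty time axis: T must be >= 1")
    tau = np.float32(config.effective_tau)
    v_th = np.float32(config.v_th)
    mode = config.reset_mode

    if v_init is None:
        v = np.zeros((n, c), dtype=np.float32)
    else:
        v = np.asarray(v_init, dtype=np.float32).copy()
        _check_shapes(v, x[..., 0], "lif_forward v_init")
    v_init_arr = v.copy()

    v_pre_all = np.empty_like(x)
    v_post_all = np.empty_like(x)
    s_all = np.empty_like(x)
    for t in range(T):
        v_pre = tau * v + x[..., t]
        s = (v_pre > v_th).astype(np.float32)
        if mode == "hard":
            v = v_pre * (np.float32(1.0) - s)
        else:
            v = v_pre - s * v_th
        v_pre_all[..., t] = v_pre
        v_post_all[..., t] = v
        s_all[..., t] = s

    trace = MembraneTrace(v_pre=v_pre_all, v_post=v_post_all, spikes=s_all,
                          v_init=v_init_arr, config=config)
    return SpikeTrain(values=s_all), trace


def lif_backward(
    grad_spikes: np.ndarray,
    trace: MembraneTrace,
    config: Optional[LIFConfig] = None,
) -> Tuple[np.ndarray, Optional[float]]:
    """Backpropagate through time through a recorded LIF forward pass.

    ``ds/dv_pre`` is replaced by the triangle surrogate; every other factor is
    the literal derivative of the update rules.  In particular the gradient
    flows through the reset formula *including* its dependence on the spike via
    the surrogate:

    - hard reset:  ``dv_post/dv_pre = (1 - s) - v_pre * surrogate(v_pre)``
    - soft reset:  ``dv_post/dv_pre = 1 - v_th * surrogate(v_pre)``

    and the potential-to-potential path contributes a factor ``tau`` per step.

    Parameters
    ----------
    grad_spikes
        Upstream gradient of the loss w.r.t. the spike train, shape
        ``(batch, channels, T)``.
    trace
        The MembraneTrace returned by :func:`lif_forward`.
    config
        Defaults to ``trace.config``.

    Returns
    -------
    (grad_pre_activation, grad_b)
        ``grad_b`` is None unless ``config.learnable_tau``; otherwise it is the
        scalar gradient w.r.t. the raw decay parameter ``b``, using
        ``dv_pre/dtau = v_post(t-1)`` and ``dtau/db = sigmoid(b)(1 - sigmoid(b))``.
    """
    if trace is None:
        raise RuntimeError("lif_backward called before a forward pass (no trace)")
    cfg = config if config is not None else trace.config
    gs = np.asarray(grad_spikes, dtype=np.float32)
    _check_shapes(gs, trace.spikes, "lif_backward")
    T = gs.shape[-1]
    tau = np.float32(cfg.effective_tau)
    v_th = np.float32(cfg.v_th)

    sg = surrogate_grad(trace.v_pre, cfg.v_th)  # (n, c, T)
    if cfg.reset_mode == "hard":
        dpost_dpre = (np.float32(1.0) - trace.spikes) - trace.v_pre * sg
    else:
        dpost_dpre = np.float32(1.0) - v_th * sg

    grad_c = np.empty_like(gs)
    grad_tau = 0.0
    # carry = dL/dv_post(t) accumulated from steps > t
    carry = np.zeros(gs.shape[:-1], dtype=np.float32)
    for t in range(T - 1, -1, -1):
        g_vpre = gs[..., t] * sg[..., t] + carry * dpost_dpre[..., t]
        grad_c[..., t] = g_vpre
        if cfg.learnable_tau:
            v_prev = trace.v_post[..., t - 1] if t > 0 else trace.v_init
            grad_tau += float(np.sum(g_vpre * v_prev))
        carry = tau * g_vpre

    if cfg.learnable_tau:
        sig = sigmoid(cfg.b)
        return grad_c, grad_tau * float(sig * (1.0 - sig))
    return grad_c, None
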