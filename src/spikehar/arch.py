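"""Network architectures for sensor-window classification, spiking and artificial.

Two families are built from a shared declarative layer-spec language:

* ``SpikeCNN`` / ``CNN`` — ``C32-MP2-C64-MP2-C64-MP2-FC`` with 1-D
  convolutions of kernel size 8 along the time axis;
* ``SpikeDCL`` / ``DCL`` (DeepConvLSTM) — ``C64-C64-C64-C64-LSTM64`` with
  kernel size 5, an LSTM consuming the (spike) sequence over time, and a
  dense head applied per step.

The spiking variants use LIF activations; the artificial twins use ReLU plus
dropout after each activation.  Both share the identical weight skeleton, so
trainable-parameter counts match (up to the optional learnable decay scalars).

Conventions (documented design choices):

* convolutions use "same" zero padding with stride 1, so only the pooling
  stages shorten the time axis — the SNN time dimension stays aligned with the
  sensor time dimension;
* the first conv layer consumes real-valued sensor data directly (direct
  coding); binary spikes first appear after the first LIF;
* max-pooling over binary spikes is a logical OR over the pool window;
* class scores are the readout: the final dense layer's outputs summed over
  whatever time axis survives (for SpikeCNN the head sees a flattened
  channels-by-time spike tensor, so the sum is over a single step);
* no normalization layers anywhere.

Everything runs on numpy arrays shaped ``(batch, channels, time)`` internally;
:class:`Network` accepts dataset windows ``(N, T, D)`` and transposes once on
entry.  Every layer implements ``forward``/``backward`` with cached state, so
the whole model trains by explicit reverse-mode accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .lif import LIFConfig, lif_forward, lif_backward, sigmoid

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "build_spike_cnn",
    "build_spike_dcl",
    "build_cnn",
    "build_dcl",
    "build_ann_counterpart",
    "strip_ann_counterpart",
    "readout",
    "Network",
    "build_network",
    "MODEL_BUILDERS",
]

LAYER_KINDS = ("conv1d", "maxpool1d", "recurrent", "dense", "activation", "dropout", "flatten")
ACTIVATION_KINDS = ("relu", "lif")


# --------------------------------------------------------------------------
# Declarative specs
# --------------------------------------------------------------------------

@dataclass
class LayerSpec:
    """One layer in a declarative model description."""

    kind: str
    width: int = 0          # output channels / units (conv, recurrent, dense)
    kernel: int = 0         # kernel size in time steps (conv only)
    pool: int = 0           # pool window (maxpool only)
    activation_kind: str = ""   # "relu" | "lif" (activation only)
    dropout_p: float = 0.0  # dropout probability (dropout only)

    def __post_init__(self):
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv1d" and (self.width < 1 or self.kernel < 1):
            raise ValueError("conv1d needs positive width and kernel")
        if self.kind == "activation" and self.activation_kind not in ACTIVATION_KINDS:
            raise ValueError(f"activation_kind must be one of {ACTIVATION_KINDS}")


@dataclass
class ModelSpec:
    """Ordered layer list plus input/output dimensions; serializable."""

    name: str
    layers: List[LayerSpec]
    n_classes: int
    input_channels: int

    def __post_init__(self):
        if not self.layers or self.layers[-1].kind != "dense" or self.layers[-1].width != self.n_classes:
            raise ValueError("last layer must be dense with width == n_classes")
        kinds = {l.activation_kind for l in self.layers if l.kind == "activation"}
        if len(kinds) > 1:
            raise ValueError(f"mixed activation kinds in one model: {sorted(kinds)}")

    @property
    def activation_kind(self) -> str:
        for l in self.layers:
            if l.kind == "activation":
                return l.activation_kind
        return ""

    @property
    def is_spiking(self) -> bool:
        return self.activation_kind == "lif"

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_classes": self.n_classes,
            "input_channels": self.input_channels,
            "layers": [asdict(l) for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            name=d["name"],
            layers=[LayerSpec(**l) for l in d["layers"]],
            n_classes=int(d["n_classes"]),
            input_channels=int(d["input_channels"]),
        )


def _act(kind: str) -> LayerSpec:
    return LayerSpec(kind="activation", activation_kind=kind)


def build_spike_cnn(input_channels: int, n_classes: int,
                    lif_config: Optional[LIFConfig] = None) -> ModelSpec:
    """SpikeCNN: ``C32-MP2-C64-MP2-C64-MP2-FC``, kernel size 8, LIF activations.

    The final dense head consumes the flattened (channels x pooled-time) spike
    tensor.  Needs input time length >= 8 (three pool-by-2 stages).
    """
    if input_channels < 1:
        raise ValueError("input_channels must be >= 1")
    layers = []
    for width in (32, 64, 64):
        layers.append(LayerSpec(kind="conv1d", width=width, kernel=8))
        layers.append(_act("lif"))
        layers.append(LayerSpec(kind="maxpool1d", pool=2))
    layers.append(LayerSpec(kind="flatten"))
    layers.append(LayerSpec(kind="dense", width=n_classes))
    return ModelSpec(name="spike_cnn", layers=layers, n_classes=n_classes,
                     input_channels=input_channels)


def build_spike_dcl(input_channels: int, n_classes: int,
                    lif_config: Optional[LIFConfig] = None) -> ModelSpec:
    """SpikeDCL (DeepConvLSTM): ``C64-C64-C64-C64-LSTM64``, kernel size 5.

    Four conv+LIF stages (no pooling between them), a 64-unit LSTM consuming
    the spike sequence, then a dense head applied per time step; class scores
    are the per-step head outputs summed over time.
    """
    if input_channels < 1:
        raise ValueError("input_channels must be >= 1")
    layers = []
    for _ in range(4):
        layers.append(LayerSpec(kind="conv1d", width=64, kernel=5))
        layers.append(_act("lif"))
    layers.append(LayerSpec(kind="recurrent", width=64))
    layers.append(LayerSpec(kind="dense", width=n_classes))
    return ModelSpec(name="spike_dcl", layers=layers, n_classes=n_classes,
                     input_channels=input_channels)


def build_ann_counterpart(snn_spec: ModelSpec, dropout_p: float = 0.5) -> ModelSpec:
    """Artificial twin of an SNN spec: ReLU in place of LIF, dropout after each activation."""
    layers = []
    for l in snn_spec.layers:
        if l.kind == "activation":
            layers.append(_act("relu"))
            layers.append(LayerSpec(kind="dropout", dropout_p=dropout_p))
        else:
            layers.append(LayerSpec(**asdict(l)))
    name = snn_spec.name.replace("spike_", "")
    return ModelSpec(name=name, layers=layers, n_classes=snn_spec.n_classes,
                     input_channels=snn_spec.input_channels)


def strip_ann_counterpart(ann_spec: ModelSpec) -> ModelSpec:
    """Inverse of :func:`build_ann_counterpart`: drop dropout, swap relu -> lif."""
    layers = []
    for l in ann_spec.layers:
        if l.kind == "dropout":
            continue
        if l.kind == "activation":
            layers.append(_act("lif"))
        else:
            layers.append(LayerSpec(**asdict(l)))
    return ModelSpec(name="spike_" + ann_spec.name, layers=layers,
                     n_classes=ann_spec.n_classes, input_channels=ann_spec.input_channels)


def build_cnn(input_channels: int, n_classes: int, dropout_p: float = 0.5) -> ModelSpec:
    return build_ann_counterpart(build_spike_cnn(input_channels, n_classes), dropout_p)


def build_dcl(input_channels: int, n_classes: int, dropout_p: float = 0.5) -> ModelSpec:
    return build_ann_counterpart(build_spike_dcl(input_channels, n_classes), dropout_p)


MODEL_BUILDERS: dict = {
    "spike_cnn": build_spike_cnn,
    "spike_dcl": build_spike_dcl,
    "cnn": build_cnn,
    "dcl": build_dcl,
}


def readout(head_outputs: np.ndarray, n_classes: Optional[int] = None) -> np.ndarray:
    """Class scores from the final dense layer's outputs.

    For a time-indexed head output ``(N, K, T)`` the score is the sum over
    time steps (equivalently, the integrated membrane potential of a
    non-firing output layer starting from zero).  A 2-D ``(N, K)`` input is a
    single-step readout and is returned unchanged.  Softmax is applied by the
    loss, not here.
    """
    out = np.asarray(head_outputs)
    if out.ndim == 3:
        if out.shape[-1] == 0:
            raise ValueError("readout over an empty time axis")
        scores = out.sum(axis=-1)
    elif out.ndim == 2:
        scores = out
    else:
        raise ValueError(f"head outputs must be 2-D or 3-D, got shape {out.shape}")
    if n_classes is not None and scores.shape[1] != n_classes:
        raise ValueError(f"head width {scores.shape[1]} != n_classes {n_classes}")
    return scores


# --------------------------------------------------------------------------
# Runtime layers (numpy, explicit backward)
# --------------------------------------------------------------------------

class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    spec: Optional[LayerSpec] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> List[Param]:
        return []


class Conv1D(Layer):
    """1-D convolution along time, "same" zero padding, stride 1.

    Input ``(N, C_in, T)`` -> output ``(N, C_out, T)``.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 name: str = "conv"):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        bound = 1.0 / np.sqrt(in_ch * kernel)
        self.W = Param(f"{name}.W", rng.uniform(-bound, bound, (out_ch, in_ch * kernel)))
        self.b = Param(f"{name}.b", rng.uniform(-bound, bound, out_ch))
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left
        self._cols = None
        self._in_shape = None

    def forward(self, x, train=False):
        n, c, T = x.shape
        if c != self.in_ch:
            raise ValueError(f"conv expects {self.in_ch} channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        # (N, C, T, k) sliding windows -> (N, C*k, T)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        cols = win.transpose(0, 1, 3, 2).reshape(n, c * self.kernel, T)
        self._cols = np.ascontiguousarray(cols, dtype=np.float32)
        self._in_shape = x.shape
        y = np.einsum("of,nft->not", self.W.value, self._cols, optimize=True)
        return y + self.b.value[None, :, None]

    def backward(self, grad):
        n, c, T = self._in_shape
        self.W.grad += np.einsum("not,nft->of", grad, self._cols, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        gcols = np.einsum("of,not->nft", self.W.value, grad, optimize=True)
        gcols = gcols.reshape(n, c, self.kernel, T)
        gx_pad = np.zeros((n, c, T + self.kernel - 1), dtype=np.float32)
        for dk in range(self.kernel):
            gx_pad[:, :, dk:dk + T] += gcols[:, :, dk, :]
        return gx_pad[:, :, self.pad_left:self.pad_left + T]

    def params(self):
        return [self.W, self.b]


class MaxPool1D(Layer):
    """Max over non-overlapping windows along time; on binary spikes this is a logical OR.

    A trailing remainder (T not divisible by the pool size) is dropped.
    """

    def __init__(self, pool: int):
        self.pool = pool
        self._argmax = None
        self._in_shape = None

    def forward(self, x, train=False):
        n, c, T = x.shape
        Tp = T // self.pool
        if Tp < 1:
            raise ValueError(f"time length {T} too short for pool size {self.pool}")
        xw = x[:, :, :Tp * self.pool].reshape(n, c, Tp, self.pool)
        self._argmax = xw.argmax(axis=-1)
        self._in_shape = x.shape
        return xw.max(axis=-1)

    def backward(self, grad):
        n, c, T = self._in_shape
        Tp = grad.shape[-1]
        gx = np.zeros((n, c, Tp, self.pool), dtype=np.float32)
        np.put_along_axis(gx, self._argmax[..., None], grad[..., None], axis=-1)
        gx = gx.reshape(n, c, Tp * self.pool)
        if Tp * self.pool < T:
            gx = np.pad(gx, ((0, 0), (0, 0), (0, T - Tp * self.pool)))
        return gx


class LIFActivation(Layer):
    """LIF activation over the time axis; the trainable-decay variant exposes ``b``."""

    def __init__(self, config: LIFConfig, name: str = "lif"):
        self.config = config
        self.b_param: Optional[Param] = None
        if config.learnable_tau:
            self.b_param = Param(f"{name}.b", np.asarray(config.b, dtype=np.float32))
        self._trace = None

    def _cfg(self) -> LIFConfig:
        if self.b_param is not None:
            return LIFConfig(tau=self.config.tau, v_th=self.config.v_th,
                             reset_mode=self.config.reset_mode, learnable_tau=True,
                             b=float(self.b_param.value))
        return self.config

    @property
    def tau(self) -> float:
        return self._cfg().effective_tau

    def forward(self, x, train=False):
        spikes, self._trace = lif_forward(x, self._cfg())
        return spikes.values

    def backward(self, grad):
        if self._trace is None:
            raise RuntimeError("LIF backward called before forward")
        gx, gb = lif_backward(grad, self._trace)
        if self.b_param is not None:
            self.b_param.grad += np.float32(gb)
        return gx

    def params(self):
        return [self.b_param] if self.b_param is not None else []


class ReLUActivation(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, grad):
        return np.where(self._mask, grad, np.float32(0.0))


class Dropout(Layer):
    """Inverted dropout; identity in eval mode.  Draws masks from the network RNG."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout_p must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.p)
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    """(N, C, T) -> (N, C*T)."""

    def __init__(self):
        self._in_shape = None

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Dense(Layer):
    """Affine map; applied per time step when the input is 3-D ``(N, F, T)``."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 name: str = "dense"):
        self.in_dim, self.out_dim = in_dim, out_dim
        bound = 1.0 / np.sqrt(in_dim)
        self.W = Param(f"{name}.W", rng.uniform(-bound, bound, (out_dim, in_dim)))
        self.b = Param(f"{name}.b", rng.uniform(-bound, bound, out_dim))
        self._x = None

    def forward(self, x, train=False):
        if x.shape[1] != self.in_dim:
            raise ValueError(f"dense expects {self.in_dim} features, got {x.shape[1]}")
        self._x = x
        if x.ndim == 2:
            return x @ self.W.value.T + self.b.value
        return np.einsum("of,nft->not", self.W.value, x, optimize=True) + self.b.value[None, :, None]

    def backward(self, grad):
        x = self._x
        if x.ndim == 2:
            self.W.grad += grad.T @ x
            self.b.grad += grad.sum(axis=0)
            return grad @ self.W.value
        self.W.grad += np.einsum("not,nft->of", grad, x, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        return np.einsum("of,not->nft", self.W.value, grad, optimize=True)

    def params(self):
        return [self.W, self.b]


class LSTM(Layer):
    """Single-layer LSTM over the time axis: ``(N, C, T) -> (N, H, T)``.

    Gates are the standard input/forget/cell/output quadruple; internal gates
    are real-valued (the recurrent layer is not spiking).
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 name: str = "lstm"):
        self.in_dim, self.hidden = in_dim, hidden
        bound = 1.0 / np.sqrt(hidden)
        self.Wx = Param(f"{name}.Wx", rng.uniform(-bound, bound, (4 * hidden, in_dim)))
        self.Wh = Param(f"{name}.Wh", rng.uniform(-bound, bound, (4 * hidden, hidden)))
        self.b = Param(f"{name}.b", rng.uniform(-bound, bound, 4 * hidden))
        self._cache = None

    def forward(self, x, train=False):
        n, c, T = x.shape
        H = self.hidden
        h = np.zeros((n, H), dtype=np.float32)
        cc = np.zeros((n, H), dtype=np.float32)
        hs = np.empty((n, H, T), dtype=np.float32)
        cache = []
        for t in range(T):
            xt = x[:, :, t]
            z = xt @ self.Wx.value.T + h @ self.Wh.value.T + self.b.value
            i = sigmoid(z[:, :H]).astype(np.float32)
            f = sigmoid(z[:, H:2 * H]).astype(np.float32)
            g = np.tanh(z[:, 2 * H:3 * H]).astype(np.float32)
            o = sigmoid(z[:, 3 * H:]).astype(np.float32)
            c_new = f * cc + i * g
            tc = np.tanh(c_new).astype(np.float32)
            h_new = o * tc
            cache.append((xt, h, cc, i, f, g, o, c_new, tc))
            h, cc = h_new, c_new
            hs[:, :, t] = h
        self._cache = (x.shape, cache)
        return hs

    def backward(self, grad):
        (n, c, T), cache = self._cache
        H = self.hidden
        gx = np.zeros((n, c, T), dtype=np.float32)
        dh_next = np.zeros((n, H), dtype=np.float32)
        dc_next = np.zeros((n, H), dtype=np.float32)
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, c_new, tc = cache[t]
            dh = grad[:, :, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1).astype(np.float32)
            self.Wx.grad += dz.T @ xt
            self.Wh.grad += dz.T @ h_prev
            self.b.grad += dz.sum(axis=0)
            gx[:, :, t] = dz @ self.Wx.value
            dh_next = dz @ self.Wh.value
            dc_next = dc * f
        return gx

    def params(self):
        return [self.Wx, self.Wh, self.b]


class SumTime(Layer):
    """Readout reduction: sum a per-step head output ``(N, K, T)`` over time."""

    def __init__(self):
        self._T = None

    def forward(self, x, train=False):
        if x.ndim != 3 or x.shape[-1] == 0:
            raise ValueError("SumTime expects (N, K, T) with T >= 1")
        self._T = x.shape[-1]
        return x.sum(axis=-1)

    def backward(self, grad):
        return np.repeat(grad[..., None], self._T, axis=-1)


# --------------------------------------------------------------------------
# Network assembly
# --------------------------------------------------------------------------

class Network:
    """A runtime model instantiated from a :class:`ModelSpec`.

    ``forward`` accepts dataset windows ``(N, T, D)``, transposes to the
    internal ``(N, C, T)`` layout, and returns class scores ``(N, K)``.
    With ``debug=True``, every tensor leaving an LIF activation is asserted
    binary before it crosses into the next weighted layer.
    """

    def __init__(self, spec: ModelSpec, layers: List[Layer], debug: bool = False):
        self.spec = spec
        self.layers = layers
        self.debug = debug

    def forward(self, windows: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(windows, dtype=np.float32).transpose(0, 2, 1)
        for layer, lspec in zip(self.layers, self._runtime_specs):
            x = layer.forward(x, train=train)
            if self.debug and isinstance(layer, LIFActivation):
                assert np.all((x == 0.0) | (x == 1.0)), "non-binary spike tensor"
        return x

    def backward(self, grad_scores: np.ndarray) -> None:
        g = np.asarray(grad_scores, dtype=np.float32)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def params(self) -> List[Param]:
        out: List[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_params(self, include_tau: bool = True) -> int:
        total = 0
        for p in self.params():
            if not include_tau and p.name.endswith("lif.b"):
                continue
            total += p.value.size
        return total

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()

    @property
    def _runtime_specs(self):
        return [getattr(l, "spec", None) for l in self.layers]

    def capture(self, windows: np.ndarray) -> List[Tuple[Layer, np.ndarray, np.ndarray]]:
        """Eval-mode forward that records (layer, input, output) for every layer."""
        x = np.asarray(windows, dtype=np.float32).transpose(0, 2, 1)
        records = []
        for layer in self.layers:
            y = layer.forward(x, train=False)
            records.append((layer, x, y))
            x = y
        return records


def min_input_length(spec: ModelSpec) -> int:
    """Smallest time length that survives every pooling stage with T >= 1."""
    n_pools = sum(1 for l in spec.layers if l.kind == "maxpool1d")
    m = 1
    for l in reversed([l for l in spec.layers if l.kind == "maxpool1d"]):
        m *= l.pool
    return max(m, 1)


def _pooled_length(spec: ModelSpec, T: int) -> int:
    for l in spec.layers:
        if l.kind == "maxpool1d":
            T = T // l.pool
    return T


def build_network(
    spec: ModelSpec,
    input_T: int,
    lif_config: Optional[LIFConfig] = None,
    rng: Optional[np.random.Generator] = None,
    debug: bool = False,
) -> Network:
    """Instantiate runtime layers (and their weights) from a declarative spec.

    ``input_T`` fixes the window time length; it is needed up front because the
    flattened dense head's fan-in depends on the pooled time length.  Raises a
    shape error at build time if ``input_T`` cannot survive the pooling
    stages.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    min_T = min_input_length(spec)
    if input_T < min_T:
        raise ValueError(
            f"input time length {input_T} too short for {spec.name}: "
            f"minimum is {min_T} (pooling stages)"
        )
    lif_config = lif_config or LIFConfig()

    layers: List[Layer] = []
    ch = spec.input_channels
    T = input_T
    flat = False
    lif_idx = 0
    for i, l in enumerate(spec.layers):
        if l.kind == "conv1d":
            layers.append(Conv1D(ch, l.width, l.kernel, rng, name=f"L{i}.conv"))
            ch = l.width
        elif l.kind == "maxpool1d":
            layers.append(MaxPool1D(l.pool))
            T = T // l.pool
        elif l.kind == "activation":
            if l.activation_kind == "lif":
                cfg = LIFConfig(tau=lif_config.tau, v_th=lif_config.v_th,
                                reset_mode=lif_config.reset_mode,
                                learnable_tau=lif_config.learnable_tau,
                                b=lif_config.b)
                layers.append(LIFActivation(cfg, name=f"L{i}.lif"))
                lif_idx += 1
            else:
                layers.append(ReLUActivation())
        elif l.kind == "dropout":
            layers.append(Dropout(l.dropout_p, rng))
        elif l.kind == "flatten":
            layers.append(Flatten())
            flat = True
        elif l.kind == "recurrent":
            layers.append(LSTM(ch, l.width, rng, name=f"L{i}.lstm"))
            ch = l.width
        elif l.kind == "dense":
            in_dim = ch * T if flat else ch
            layers.append(Dense(in_dim, l.width, rng, name=f"L{i}.dense"))
            ch = l.width
        else:  # pragma: no cover
            raise ValueError(f"unhandled layer kind {l.kind}")
        layers[-1].spec = l
    if not flat:
        layers.append(SumTime())  # per-step dense head -> integrate over time
    return Network(spec, layers, debug=debug)
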