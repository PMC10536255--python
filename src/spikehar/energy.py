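"""Op-counting energy model for a sparsity-aware systolic-array accelerator.

The hardware model is a processing-element (PE) array with small per-PE
scratchpads for inputs and weights.  Per-operation energies are normalized to
one ANN multiply-accumulate (MAC):

======== ======================================================= =======
symbol   operation                                               cost
======== ======================================================= =======
e_mac    one MAC (for spikes the multiply is a logical AND)      0.175
e_spa    handling one skipped (zero-spike) input                 0
e_lif    one LIF membrane update                                 0.383
e_ispad  one input-scratchpad access                             0.107
e_wspad  one weight-scratchpad access                            1.712
======== ======================================================= =======

For spiking layers, a zero input spike skips both the accumulation and the
weight-scratchpad access, so MAC and weight-access counts scale with the
number of *nonzero* inputs; artificial layers compute densely (a flag enables
the alternative accounting that lets ANNs skip exact zeros too, for
sensitivity analysis).  Per layer:

    compute = macs * e_mac + skipped_inputs * e_spa + lif_updates * e_lif
    move    = macs * e_wspad + input_total * e_ispad + weight_count * e_wspad

where ``macs`` counts actual multiply-accumulate events (exact, including
convolution boundary effects), the ``input_total * e_ispad`` term reads every
input once, and the ``weight_count * e_wspad`` term is the one-time load of
the layer's weights into the scratchpads.  These formulas are this package's
own transparent definitions; array size and buffer capacities affect
scheduling, not op counts, and are carried as metadata only.  DRAM traffic
beyond the per-layer weight load, and membrane-potential scratchpad traffic
(folded into e_lif), are out of scope.

LSTM layers are counted as the dense MACs of their four gates; the input-side
MACs are skippable on zero spikes, the recurrent-side (real-valued hidden
state) MACs are not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .arch import Conv1D, Dense, LSTM, LIFActivation, ReLUActivation, Network

__all__ = [
    "EnergyTable",
    "LayerStats",
    "EnergyReport",
    "measure_sparsity",
    "collect_layer_stats",
    "estimate_energy",
    "compare_models",
]


@dataclass
class EnergyTable:
    """Normalized PE-level energy costs; defaults as tabulated above."""

    e_mac: float = 0.175
    e_spa: float = 0.0
    e_lif: float = 0.383
    e_ispad: float = 0.107
    e_wspad: float = 1.712
    unit: str = "ANN-MAC-normalized"
    # metadata only; does not enter the op counts
    n_pe: int = 128
    w_buffer_bytes: int = 32 * 1024
    s_buffer_bytes: int = 576

    def __post_init__(self):
        for name in ("e_mac", "e_spa", "e_lif", "e_ispad", "e_wspad"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class LayerStats:
    """Exact event counts for one weighted layer over a dataset pass.

    ``macs_nonzero`` counts MAC events with the zero-input skip active;
    ``macs_total`` counts them dense.  ``lif_updates`` is the neuron x
    time-step x batch count of the LIF activation fed by this layer (0 for
    artificial layers and for the readout head).  ``act_sparsity`` is the
    zero fraction of that activation's output (NaN when there is none).
    """

    name: str
    is_spiking: bool
    input_nonzeros: int
    input_total: int
    macs_nonzero: int
    macs_total: int
    lif_updates: int = 0
    weight_count: int = 0
    act_sparsity: float = float("nan")

    def __post_init__(self):
        if min(self.input_nonzeros, self.input_total, self.macs_nonzero,
               self.macs_total, self.lif_updates, self.weight_count) < 0:
            raise ValueError(f"negative count in layer stats {self.name!r}")
        if self.input_nonzeros > self.input_total:
            raise ValueError(f"{self.name}: input_nonzeros > input_total")

    @property
    def sparsity(self) -> float:
        return 1.0 - self.input_nonzeros / self.input_total if self.input_total else 0.0

    @property
    def macs_per_nonzero(self) -> float:
        """Average weight connections touched per nonzero input."""
        return self.macs_nonzero / self.input_nonzeros if self.input_nonzeros else float("nan")


@dataclass
class EnergyReport:
    """Per-layer and total compute / data-moving energy, normalized units."""

    layers: pd.DataFrame           # layer,kind,sparsity,compute_e,move_e,total_e
    compute_total: float
    move_total: float
    total: float
    unit: str = "ANN-MAC-normalized"
    activation_sparsity: List[float] = field(default_factory=list)

    def to_csv(self, path: str) -> None:
        self.layers.to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "unit": self.unit,
            "compute_total": self.compute_total,
            "move_total": self.move_total,
            "total": self.total,
            "mean_activation_sparsity": (float(np.mean(self.activation_sparsity))
                                         if self.activation_sparsity else float("nan")),
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2)


def measure_sparsity(activations: np.ndarray) -> float:
    """Fraction of exactly-zero entries; for a spike train this is 1 - firing rate."""
    a = np.asarray(activations)
    if a.size == 0:
        raise ValueError("no activations recorded")
    return float((a == 0).mean())


def _conv_touches(T: int, kernel: int, pad_left: int) -> np.ndarray:
    """touches[t]: output positions a same-padded conv tap reaches from input step t."""
    t = np.arange(T)
    lo = np.maximum(0, t + pad_left - (T - 1))
    hi = np.minimum(kernel - 1, t + pad_left)
    return np.maximum(0, hi - lo + 1)


def collect_layer_stats(
    net: Network,
    windows: np.ndarray,
    batch: int = 128,
) -> List[LayerStats]:
    """One :class:`LayerStats` per weighted layer (conv / dense / LSTM),
    aggregated over a full pass of ``windows`` in eval mode.

    The LIF updates of the activation applied to a layer's output are
    attributed to that layer; the first conv layer consumes real-valued sensor
    input (direct coding), so its own input is never skippable in an SNN —
    what is spiking is decided per layer by whether its *input* comes from an
    LIF (the sensor-facing conv computes densely in both model families).
    """
    windows = np.asarray(windows, dtype=np.float32)
    if windows.ndim != 3:
        raise ValueError(f"windows must be (N, T, D), got {windows.shape}")

    weighted = [(i, l) for i, l in enumerate(net.layers)
                if isinstance(l, (Conv1D, Dense, LSTM))]
    # which activation (if any) consumes each weighted layer's output, before
    # the next weighted layer
    follow_act: List[Optional[int]] = []
    for pos, (i, _) in enumerate(weighted):
        nxt = weighted[pos + 1][0] if pos + 1 < len(weighted) else len(net.layers)
        act = None
        for j in range(i + 1, nxt):
            if isinstance(net.layers[j], (LIFActivation, ReLUActivation)):
                act = j
                break
        follow_act.append(act)
    # a weighted layer's input is binary iff, walking back past shape-only
    # layers (pool/flatten/dropout preserve binarity), it comes from an LIF
    from .arch import MaxPool1D, Flatten, Dropout

    def _input_is_spikes(i: int) -> bool:
        j = i - 1
        while j >= 0 and isinstance(net.layers[j], (MaxPool1D, Flatten, Dropout)):
            j -= 1
        return j >= 0 and isinstance(net.layers[j], LIFActivation)

    agg = [dict(nnz=0, total=0, macs_nz=0, macs_tot=0, lif=0, act_nnz=0, act_tot=0)
           for _ in weighted]

    for b0 in range(0, len(windows), batch):
        records = net.capture(windows[b0:b0 + batch])
        for pos, (i, layer) in enumerate(weighted):
            x = records[i][1]
            a = agg[pos]
            nnz = int(np.count_nonzero(x))
            a["nnz"] += nnz
            a["total"] += x.size
            if isinstance(layer, Conv1D):
                touches = _conv_touches(x.shape[-1], layer.kernel, layer.pad_left)
                nnz_t = np.count_nonzero(x, axis=(0, 1))
                a["macs_nz"] += int((nnz_t * touches).sum()) * layer.out_ch
                a["macs_tot"] += int(touches.sum()) * x.shape[0] * x.shape[1] * layer.out_ch
            elif isinstance(layer, Dense):
                a["macs_nz"] += nnz * layer.out_dim
                a["macs_tot"] += x.size * layer.out_dim
            else:  # LSTM: input side skippable, recurrent side dense
                n, c, T = x.shape
                H = layer.hidden
                rec_macs = n * T * H * 4 * H
                a["macs_nz"] += nnz * 4 * H + rec_macs
                a["macs_tot"] += x.size * 4 * H + rec_macs
            j = follow_act[pos]
            if j is not None:
                out = records[j][2]
                a["act_nnz"] += int(np.count_nonzero(out))
                a["act_tot"] += out.size
                if isinstance(net.layers[j], LIFActivation):
                    a["lif"] += out.size

    stats = []
    for pos, (i, layer) in enumerate(weighted):
        a = agg[pos]
        stats.append(LayerStats(
            name=f"{type(layer).__name__.lower()}_{i}",
            is_spiking=_input_is_spikes(i),
            input_nonzeros=a["nnz"],
            input_total=a["total"],
            macs_nonzero=a["macs_nz"],
            macs_total=a["macs_tot"],
            lif_updates=a["lif"],
            weight_count=sum(p.value.size for p in layer.params()),
            act_sparsity=(1.0 - a["act_nnz"] / a["act_tot"]) if a["act_tot"] else float("nan"),
        ))
    return stats


def estimate_energy(
    stats: Sequence[LayerStats],
    table: Optional[EnergyTable] = None,
    ann_skip_zeros: bool = False,
) -> EnergyReport:
    """Total the per-layer compute and data-moving energy from event counts.

    Spiking layers skip MACs and weight-scratchpad accesses for zero-spike
    inputs; artificial layers compute densely unless ``ann_skip_zeros``.
    """
    if not stats:
        raise ValueError("no layer stats to estimate from")
    table = table or EnergyTable()
    rows = []
    for s in stats:
        skipping = s.is_spiking or ann_skip_zeros
        macs = s.macs_nonzero if skipping else s.macs_total
        skipped = (s.input_total - s.input_nonzeros) if skipping else 0
        compute = macs * table.e_mac + skipped * table.e_spa + s.lif_updates * table.e_lif
        move = macs * table.e_wspad + s.input_total * table.e_ispad + s.weight_count * table.e_wspad
        rows.append({
            "layer": s.name,
            "kind": "snn" if s.is_spiking else "ann",
            "sparsity": s.sparsity,
            "compute_e": compute,
            "move_e": move,
            "total_e": compute + move,
        })
    df = pd.DataFrame(rows)
    act_sp = [s.act_sparsity for s in stats if np.isfinite(s.act_sparsity)]
    return EnergyReport(
        layers=df,
        compute_total=float(df["compute_e"].sum()),
        move_total=float(df["move_e"].sum()),
        total=float(df["total_e"].sum()),
        unit=table.unit,
        activation_sparsity=act_sp,
    )


def compare_models(report_snn: EnergyReport, report_ann: EnergyReport) -> float:
    """Percent energy reduction of the SNN relative to the ANN: 100*(1 - snn/ann).

    Negative when the SNN costs more.
    """
    if report_snn.unit != report_ann.unit:
        raise ValueError(
            f"unit mismatch: {report_snn.unit!r} vs {report_ann.unit!r}"
        )
    return 100.0 * (1.0 - report_snn.total / report_ann.total)
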