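"""Representation similarity (linear CKA) and convergence-curve extraction.

Centered kernel alignment compares two layers' activation matrices on the
same probe examples.  With column-centered ``X`` (n x p) and ``Y`` (n x q),
the linear form is

    CKA(X, Y) = ||Y^T X||_F^2 / (||X^T X||_F * ||Y^T Y||_F)

which lies in [0, 1], is symmetric, and is invariant to orthogonal
transformations and isotropic scaling of either argument.  This is the
biased (plain centered-Gram) estimator.

For spiking layers, the per-example feature vector is the time-summed spike
count per neuron — the same reduction the classification readout uses; a
``reduction="flatten"`` option keeps every (channel, time) entry as a feature
instead.  Artificial layers use the same reduction so the comparison is
like-for-like.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .arch import Conv1D, LIFActivation, ReLUActivation, Network
from .train import RunRecord

__all__ = [
    "ActivationMatrix",
    "SimilarityMap",
    "linear_cka",
    "collect_activations",
    "similarity_map",
    "record_curves",
]


@dataclass
class ActivationMatrix:
    """One layer's activations on a probe set: (examples n, features p)."""

    values: np.ndarray
    layer_id: str
    model_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"activation matrix must be 2-D, got {self.values.shape}")


@dataclass
class SimilarityMap:
    """Grid of CKA values indexed by (layer of model A, layer of model B)."""

    values: np.ndarray
    rows: List[str]
    cols: List[str]
    model_a: str = "A"
    model_b: str = "B"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rows, columns=self.cols)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path)

    def to_heatmap(self, path: str) -> None:
        """Render the grid as a heatmap image (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(self.cols), 1.0 + 0.6 * len(self.rows)))
        im = ax.imshow(self.values, vmin=0.0, vmax=1.0, cmap="viridis")
        ax.set_xticks(range(len(self.cols)), self.cols, rotation=45, ha="right")
        ax.set_yticks(range(len(self.rows)), self.rows)
        ax.set_xlabel(self.model_b)
        ax.set_ylabel(self.model_a)
        fig.colorbar(im, ax=ax, label="linear CKA")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def linear_cka(X, Y) -> float:
    """Linear CKA between two activation matrices with equal example counts.

    Raises on degenerate input (a matrix that is all-constant after column
    centering has no defined similarity) and on results outside
    ``[-1e-8, 1 + 1e-8]``, which would indicate an implementation bug rather
    than numerical noise.
    """
    Xv = X.values if isinstance(X, ActivationMatrix) else np.asarray(X, dtype=np.float64)
    Yv = Y.values if isinstance(Y, ActivationMatrix) else np.asarray(Y, dtype=np.float64)
    if Xv.ndim != 2 or Yv.ndim != 2:
        raise ValueError("linear_cka expects 2-D matrices (examples x features)")
    if Xv.shape[0] != Yv.shape[0]:
        raise ValueError(f"example counts differ: {Xv.shape[0]} vs {Yv.shape[0]}")
    Xc = Xv - Xv.mean(axis=0, keepdims=True)
    Yc = Yv - Yv.mean(axis=0, keepdims=True)
    xx = np.linalg.norm(Xc.T @ Xc)
    yy = np.linalg.norm(Yc.T @ Yc)
    if xx == 0.0 or yy == 0.0:
        raise ValueError("degenerate activation matrix: all-constant after centering")
    xy = np.linalg.norm(Yc.T @ Xc) ** 2
    val = float(xy / (xx * yy))
    if not (-1e-8 <= val <= 1.0 + 1e-8):
        raise AssertionError(f"CKA value {val} outside [0, 1] beyond tolerance")
    return min(max(val, 0.0), 1.0)


def collect_activations(
    net: Network,
    probe: np.ndarray,
    layer_filter: Sequence[str] = ("conv", "activation"),
    reduction: str = "sum_time",
    model_id: str = "model",
    batch: int = 256,
) -> List[ActivationMatrix]:
    """Activation matrices at conv and/or activation layers on a probe set.

    ``reduction="sum_time"`` sums a ``(N, C, T)`` output over time to one
    feature per channel (spike counts for LIF layers); ``"flatten"`` keeps the
    full channel-by-time feature vector.  Activations are taken
    post-activation, pre-pooling.
    """
    if not layer_filter:
        raise ValueError("empty layer_filter")
    if reduction not in ("sum_time", "flatten"):
        raise ValueError(f"unknown reduction {reduction!r}")
    want_conv = "conv" in layer_filter
    want_act = "activation" in layer_filter
    sel = []
    for i, layer in enumerate(net.layers):
        if (want_conv and isinstance(layer, Conv1D)) or \
           (want_act and isinstance(layer, (LIFActivation, ReLUActivation))):
            sel.append((i, layer))
    if not sel:
        raise ValueError(f"no layers match filter {layer_filter!r}")

    chunks: List[List[np.ndarray]] = [[] for _ in sel]
    for b0 in range(0, len(probe), batch):
        records = net.capture(probe[b0:b0 + batch])
        for pos, (i, _) in enumerate(sel):
            out = records[i][2]
            if out.ndim == 3:
                feat = out.sum(axis=-1) if reduction == "sum_time" else out.reshape(len(out), -1)
            else:
                feat = out
            chunks[pos].append(np.asarray(feat, dtype=np.float64))

    mats = []
    for pos, (i, layer) in enumerate(sel):
        kind = type(layer).__name__.lower().replace("activation", "")
        mats.append(ActivationMatrix(
            values=np.concatenate(chunks[pos], axis=0),
            layer_id=f"{kind or 'act'}_{i}",
            model_id=model_id,
        ))
    return mats


def similarity_map(
    model_a: Network,
    model_b: Network,
    probe: np.ndarray,
    layer_filter: Sequence[str] = ("conv", "activation"),
    reduction: str = "sum_time",
) -> SimilarityMap:
    """CKA grid between two models' layers on identical probe inputs."""
    A = collect_activations(model_a, probe, layer_filter, reduction,
                            model_id=model_a.spec.name)
    B = collect_activations(model_b, probe, layer_filter, reduction,
                            model_id=model_b.spec.name)
    grid = np.empty((len(A), len(B)))
    for i, x in enumerate(A):
        for j, y in enumerate(B):
            grid[i, j] = linear_cka(x, y)
    return SimilarityMap(values=grid,
                         rows=[m.layer_id for m in A],
                         cols=[m.layer_id for m in B],
                         model_a=model_a.spec.name,
                         model_b=model_b.spec.name)


def record_curves(run_record: RunRecord) -> pd.DataFrame:
    """Per-epoch train/validation accuracy and loss as a plot-ready long table."""
    if not run_record.train_acc:
        raise ValueError("empty run record: no epochs logged")
    rows = []
    for metric, series in (
        ("train_acc", run_record.train_acc),
        ("val_acc", run_record.val_acc),
        ("train_loss", run_record.train_loss),
        ("val_loss", run_record.val_loss),
    ):
        for epoch, value in enumerate(series):
            rows.append({
                "model": run_record.model_name,
                "seed": run_record.seed,
                "epoch": epoch,
                "metric": metric,
                "value": value,
                "is_best_epoch": epoch == run_record.best_epoch,
            })
    return pd.DataFrame(rows)
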