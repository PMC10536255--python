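"""Sensor-window datasets: container, synthetic generator, splits, and file I/O.

A dataset holds ``N`` windows of multichannel wearable-sensor time series,
each ``(T, D)`` — e.g. a 3-axis accelerometer gives ``D = 3`` — with one
integer activity label per window and a train/val/test split assignment.

The synthetic generator emulates the structure of public HAR corpora
(windowed accelerometer/gyroscope streams) with analytic control over class
separation: class ``k`` emits a sinusoid at a class-specific frequency with a
random phase per window, scaled per channel, plus a slow random-walk baseline
drift and i.i.d. Gaussian noise.  Only the oscillation frequency carries the
class, so the task is temporal by construction: amplitude statistics of a
short snippet are uninformative, and the default frequencies are low enough
(periods much longer than one conv kernel) that integrating evidence over
time helps.

File formats:

* delimited text — CSV with header ``window_id,t,label,ch_0..ch_{D-1}``,
  one row per (window, time step); a JSON sidecar ``<path>.meta.json``
  carries the split assignment and metadata so the round trip is exact;
* binary container — NumPy ``.npz`` with arrays ``windows`` (N, T, D)
  float32, ``labels`` (N,) int64, ``split`` (N,) int8 coded 0/1/2, and the
  metadata as a JSON string.

Both round-trip bit-exactly at float32 precision.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SensorDataset",
    "SyntheticSpec",
    "generate_synthetic",
    "split_dataset",
    "write_windows",
    "read_windows",
    "TRAIN",
    "VAL",
    "TEST",
]

TRAIN, VAL, TEST = 0, 1, 2
SPLIT_NAMES = {TRAIN: "train", VAL: "val", TEST: "test"}


@dataclass
class SensorDataset:
    """Windowed sensor data: ``windows`` (N, T, D) float32, integer ``labels``,
    per-window ``split`` codes (0 train / 1 val / 2 test), and free-form ``meta``."""

    windows: np.ndarray
    labels: np.ndarray
    split: np.ndarray
    meta: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.split = np.asarray(self.split, dtype=np.int8)
        if self.windows.ndim != 3:
            raise ValueError(f"windows must be (N, T, D), got shape {self.windows.shape}")
        n = self.windows.shape[0]
        if len(self.labels) != n or len(self.split) != n:
            raise ValueError(
                f"length mismatch: {n} windows, {len(self.labels)} labels, {len(self.split)} split entries"
            )

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def T(self) -> int:
        return self.windows.shape[1]

    @property
    def D(self) -> int:
        return self.windows.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def subset(self, which: int) -> Tuple[np.ndarray, np.ndarray]:
        """(windows, labels) of one split: TRAIN, VAL or TEST."""
        m = self.split == which
        return self.windows[m], self.labels[m]

    def fingerprint(self) -> str:
        import hashlib
        h = hashlib.sha256()
        h.update(self.windows.tobytes())
        h.update(self.labels.tobytes())
        h.update(self.split.tobytes())
        return h.hexdigest()[:16]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic wearable-sensor generator.

    ``base_freqs`` are per-class oscillation frequencies in cycles per window;
    defaults to ``3 + 2k`` for class ``k`` — periods of tens of samples, so
    class identity is carried by structure far longer than a conv kernel.
    ``amp`` is the oscillation amplitude in sensor units; ``noise_sd`` the
    i.i.d. Gaussian noise sd (``amp/2`` by default: classes overlap but remain
    comfortably separable); ``drift_sd`` the per-step sd of a random-walk
    baseline drift emulating slow sensor bias.
    """

    n_per_class: int = 100
    n_classes: int = 3
    T: int = 128
    D: int = 3
    base_freqs: Optional[Sequence[float]] = None
    amp: float = 1.0
    noise_sd: float = 0.5
    drift_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1 or self.n_classes < 1 or self.T < 1 or self.D < 1:
            raise ValueError("all counts must be positive")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise_sd and drift_sd must be >= 0")
        if self.base_freqs is None:
            self.base_freqs = [3.0 + 2.0 * k for k in range(self.n_classes)]
        self.base_freqs = list(float(f) for f in self.base_freqs)
        if len(self.base_freqs) != self.n_classes:
            raise ValueError("need one base frequency per class")
        if len(set(self.base_freqs)) != self.n_classes:
            raise ValueError(f"base_freqs must be distinct, got {self.base_freqs}")


def generate_synthetic(spec: SyntheticSpec) -> SensorDataset:
    """Generate a class-balanced synthetic sensor dataset, reproducible from ``spec.seed``.

    Window of class ``k``, channel ``d``:

        x[t, d] = amp * a_d * sin(2*pi*f_k*t/T + phi) + drift_d[t] + eps[t, d]

    with phase ``phi ~ U(0, 2*pi)`` per window, channel scaling
    ``a_d ~ U(0.5, 1.5)`` per window and channel (class-independent, so the
    spatial pattern carries no label information), drift a Gaussian random
    walk with step sd ``drift_sd``, and ``eps ~ N(0, noise_sd^2)``.
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.n_per_class * spec.n_classes
    T, D = spec.T, spec.D
    t = np.arange(T, dtype=np.float64)

    windows = np.empty((N, T, D), dtype=np.float32)
    labels = np.repeat(np.arange(spec.n_classes, dtype=np.int64), spec.n_per_class)
    for i in range(N):
        k = labels[i]
        phi = rng.uniform(0.0, 2.0 * np.pi)
        a = rng.uniform(0.5, 1.5, size=D)
        tone = np.sin(2.0 * np.pi * spec.base_freqs[k] * t / T + phi)
        x = spec.amp * tone[:, None] * a[None, :]
        if spec.drift_sd > 0:
            x = x + np.cumsum(rng.normal(0.0, spec.drift_sd, size=(T, D)), axis=0)
        if spec.noise_sd > 0:
            x = x + rng.normal(0.0, spec.noise_sd, size=(T, D))
        windows[i] = x.astype(np.float32)

    meta = {
        "channel_names": [f"ch_{d}" for d in range(D)],
        "sampling_rate_hz": 50.0,
        "class_names": [f"class_{k}" for k in range(spec.n_classes)],
        "generator": "synthetic-sinusoid-v1",
        "base_freqs": spec.base_freqs,
        "seed": spec.seed,
    }
    return SensorDataset(windows=windows, labels=labels,
                         split=np.zeros(N, dtype=np.int8), meta=meta)


def split_dataset(
    dataset: SensorDataset,
    fractions: Tuple[float, float, float] = (0.64, 0.16, 0.20),
    seed: int = 0,
) -> SensorDataset:
    """Assign a stratified train/val/test split (64/16/20 by default).

    Per class, windows are shuffled with the given seed and apportioned by the
    largest-remainder rule, so split sizes per class are within one window of
    the exact fractions.  Returns a new dataset sharing the data arrays.
    """
    fr = tuple(float(f) for f in fractions)
    if len(fr) != 3 or abs(sum(fr) - 1.0) > 1e-9 or any(f < 0 for f in fr):
        raise ValueError(f"fractions must be three non-negatives summing to 1, got {fr}")
    rng = np.random.default_rng(seed)
    split = np.empty(dataset.n_windows, dtype=np.int8)
    for k in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == k)
        if len(idx) < 3 and sum(f > 0 for f in fr) == 3:
            raise ValueError(f"class {k} has only {len(idx)} windows; need >= 3 to stratify")
        rng.shuffle(idx)
        n = len(idx)
        raw = [f * n for f in fr]
        counts = [int(np.floor(r)) for r in raw]
        rem = n - sum(counts)
        order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainder first
        for j in range(rem):
            counts[order[j]] += 1
        a, b = counts[0], counts[0] + counts[1]
        split[idx[:a]] = TRAIN
        split[idx[a:b]] = VAL
        split[idx[b:]] = TEST
    out = SensorDataset(windows=dataset.windows, labels=dataset.labels,
                        split=split, meta=dict(dataset.meta))
    if fr[0] > 0:
        present = set(np.unique(out.labels[out.split == TRAIN]))
        missing = set(np.unique(out.labels)) - present
        if missing:
            raise ValueError(f"classes {sorted(missing)} absent from train split")
    return out


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------

def _validate_for_write(dataset: SensorDataset) -> None:
    bad = np.flatnonzero(~np.isfinite(dataset.windows).all(axis=(1, 2)))
    if len(bad):
        raise ValueError(f"window {bad[0]} contains NaN/inf values")


def write_windows(dataset: SensorDataset, path: str) -> None:
    """Write a dataset; format chosen by extension (``.csv`` text, ``.npz`` binary)."""
    _validate_for_write(dataset)
    if path.endswith(".npz"):
        np.savez(
            path,
            windows=dataset.windows.astype(np.float32),
            labels=dataset.labels.astype(np.int64),
            split=dataset.split.astype(np.int8),
            meta=np.array(json.dumps(dataset.meta, sort_keys=True)),
        )
        return
    if not path.endswith(".csv"):
        raise ValueError(f"unknown dataset format for {path!r} (use .csv or .npz)")
    N, T, D = dataset.windows.shape
    cols = ["window_id", "t", "label"] + [f"ch_{d}" for d in range(D)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(cols) + "\n")
        for i in range(N):
            lab = dataset.labels[i]
            for t in range(T):
                vals = ",".join(repr(float(v)) for v in dataset.windows[i, t])
                fh.write(f"{i},{t},{lab},{vals}\n")
    sidecar = {"split": dataset.split.tolist(), "meta": dataset.meta}
    with open(path + ".meta.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, sort_keys=True)


def read_windows(path: str) -> SensorDataset:
    """Read a dataset written by :func:`write_windows`; text and binary compare equal."""
    if path.endswith(".npz"):
        with np.load(path, allow_pickle=False) as z:
            windows = z["windows"].astype(np.float32)
            labels = z["labels"].astype(np.int64)
            split = z["split"].astype(np.int8) if "split" in z else np.zeros(len(labels), np.int8)
            meta = json.loads(str(z["meta"])) if "meta" in z else {}
        if len(labels) != windows.shape[0]:
            raise ValueError(
                f"label count {len(labels)} does not match {windows.shape[0]} windows"
            )
        _check_values(windows)
        return SensorDataset(windows=windows, labels=labels, split=split, meta=meta)

    if not path.endswith(".csv"):
        raise ValueError(f"unknown dataset format for {path!r} (use .csv or .npz)")
    import pandas as pd

    df = pd.read_csv(path)
    required = {"window_id", "t", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV missing required columns {sorted(required - set(df.columns))}")
    ch_cols = [c for c in df.columns if c.startswith("ch_")]
    if not ch_cols:
        raise ValueError("CSV has no channel columns (ch_0..)")
    wids = df["window_id"].to_numpy()
    uniq = np.unique(wids)
    counts = df.groupby("window_id").size()
    if counts.nunique() != 1:
        ragged = counts[counts != counts.mode()[0]].index[0]
        raise ValueError(f"ragged windows: window {ragged} has {counts[ragged]} rows")
    T = int(counts.iloc[0])
    N, D = len(uniq), len(ch_cols)
    df = df.sort_values(["window_id", "t"])
    windows = df[ch_cols].to_numpy(dtype=np.float32).reshape(N, T, D)
    if df["label"].isna().any():
        w = wids[df["label"].isna().to_numpy()][0]
        raise ValueError(f"window {w} is missing its label")
    lab_per_window = df.groupby("window_id")["label"].nunique()
    if (lab_per_window != 1).any():
        w = lab_per_window[lab_per_window != 1].index[0]
        raise ValueError(f"window {w} has inconsistent labels")
    labels = df.groupby("window_id")["label"].first().to_numpy(dtype=np.int64)
    _check_values(windows)

    split = np.zeros(N, dtype=np.int8)
    meta: Dict = {"channel_names": ch_cols}
    sidecar_path = path + ".meta.json"
    if os.path.exists(sidecar_path):
        with open(sidecar_path, encoding="utf-8") as fh:
            sidecar = json.load(fh)
        split = np.asarray(sidecar.get("split", split), dtype=np.int8)
        meta = sidecar.get("meta", meta)
    return SensorDataset(windows=windows, labels=labels, split=split, meta=meta)


def _check_values(windows: np.ndarray) -> None:
    bad = np.flatnonzero(~np.isfinite(windows).all(axis=(1, 2)))
    if len(bad):
        raise ValueError(f"window {bad[0]} contains NaN/inf values")
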