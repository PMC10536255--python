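"""Training protocol: Adam + cosine-annealed learning rate, cross-entropy on the
time-integrated readout, model selection at the best validation epoch,
multi-seed evaluation, and ablation grids over the LIF hyperparameters.

The reference protocol trains for 60 epochs with batch size 128, picks the
learning rate from {1e-4, 3e-4, 1e-3} by best validation accuracy, and reports
the test accuracy at the epoch of maximum validation accuracy, averaged over
the five seeds 1000..1004.  All of that is configurable; tests and the bundled
synthetic benchmark use fewer epochs.

Runs are deterministic given (seed, config, dataset) in single-threaded
execution: one seeded generator drives weight init, batch shuffling, and
dropout masks in a fixed order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .arch import ModelSpec, Network, build_network
from .data import SensorDataset, TRAIN, VAL, TEST
from .lif import LIFConfig

__all__ = [
    "TrainConfig",
    "RunRecord",
    "SuiteResult",
    "train",
    "evaluate",
    "select_learning_rate",
    "run_seed_suite",
    "ablate",
    "DEFAULT_SEEDS",
]

DEFAULT_SEEDS = (1000, 1001, 1002, 1003, 1004)
LR_CANDIDATES = (1e-4, 3e-4, 1e-3)


@dataclass
class TrainConfig:
    """Optimization settings.  Defaults follow the reference protocol."""

    epochs: int = 60
    batch_size: int = 128
    learning_rate: float = 1e-3
    schedule: str = "cosine"      # cosine annealing to 0 over `epochs`, or "constant"
    seeds: Tuple[int, ...] = DEFAULT_SEEDS
    eval_batch: int = 256

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs >= 1, batch_size >= 1, learning_rate > 0 required")
        if self.schedule not in ("cosine", "constant"):
            raise ValueError(f"unknown schedule {self.schedule!r}")


@dataclass
class RunRecord:
    """Everything one training run produced."""

    model_name: str
    seed: int
    learning_rate: float
    train_acc: List[float] = field(default_factory=list)
    val_acc: List[float] = field(default_factory=list)
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_acc: float = -1.0
    test_acc: float = float("nan")
    status: str = "ok"            # "ok" | "diverged"
    fingerprint: str = ""
    network: Optional[Network] = field(default=None, repr=False)

    def check_consistency(self) -> None:
        """The reported test accuracy must correspond to the stored best-val epoch."""
        if self.status != "ok":
            return
        assert self.best_epoch == int(np.argmax(self.val_acc)), \
            "best_epoch is not the (earliest) argmax of the validation curve"


@dataclass
class SuiteResult:
    """Mean +/- sample sd of test accuracy over a seed suite."""

    mean: float
    sd: float
    records: List[RunRecord]
    single_seed: bool = False

    def __str__(self):
        return f"{100 * self.mean:.2f} +/- {100 * self.sd:.2f} (%)"


class Adam:
    """Plain Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float):
        self.params = params
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self, lr: Optional[float] = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)


def _softmax_xent(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the scores."""
    z = scores - scores.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = float(-np.log(np.maximum(p[np.arange(n), labels], 1e-30)).mean())
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


def evaluate(net: Network, windows: np.ndarray, labels: np.ndarray,
             batch: int = 256) -> Tuple[float, float]:
    """(accuracy, mean loss) of a network on a window set, eval mode."""
    n = len(labels)
    if n == 0:
        return float("nan"), float("nan")
    correct = 0
    loss_sum = 0.0
    for i in range(0, n, batch):
        xb, yb = windows[i:i + batch], labels[i:i + batch]
        scores = net.forward(xb, train=False)
        loss, _ = _softmax_xent(scores.copy(), yb)
        loss_sum += loss * len(yb)
        correct += int((scores.argmax(axis=1) == yb).sum())
    return correct / n, loss_sum / n


def _fingerprint(model_spec: ModelSpec, config: TrainConfig,
                 lif_config: Optional[LIFConfig], dataset: SensorDataset,
                 seed: int) -> str:
    payload = {
        "model": model_spec.to_dict(),
        "train": {k: v for k, v in asdict(config).items()},
        "lif": asdict(lif_config) if lif_config else None,
        "dataset": dataset.fingerprint(),
        "seed": seed,
        "init": "uniform-fan-in",
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def train(
    model_spec: ModelSpec,
    dataset: SensorDataset,
    config: Optional[TrainConfig] = None,
    seed: int = 1000,
    lif_config: Optional[LIFConfig] = None,
) -> RunRecord:
    """Train one model on one dataset split; deterministic given ``seed``.

    Per-epoch training accuracy is accumulated over the minibatches as seen
    during optimization; validation is evaluated after each epoch, and the
    test set only at epochs where validation improves (ties break to the
    earliest epoch).  A NaN loss marks the run ``diverged`` and stops it
    without raising.
    """
    config = config or TrainConfig()
    Xtr, ytr = dataset.subset(TRAIN)
    Xval, yval = dataset.subset(VAL)
    Xte, yte = dataset.subset(TEST)
    if len(ytr) == 0:
        raise ValueError("dataset has an empty train split")
    if model_spec.input_channels != dataset.D:
        raise ValueError(
            f"model expects {model_spec.input_channels} channels, dataset has {dataset.D}"
        )

    rng = np.random.default_rng(seed)
    net = build_network(model_spec, input_T=dataset.T, lif_config=lif_config, rng=rng)
    opt = Adam(net.params(), config.learning_rate)
    rec = RunRecord(model_name=model_spec.name, seed=seed,
                    learning_rate=config.learning_rate,
                    fingerprint=_fingerprint(model_spec, config, lif_config, dataset, seed),
                    network=net)

    n = len(ytr)
    for epoch in range(config.epochs):
        if config.schedule == "cosine":
            lr = config.learning_rate * 0.5 * (1.0 + np.cos(np.pi * epoch / config.epochs))
        else:
            lr = config.learning_rate
        order = rng.permutation(n)
        correct = 0
        loss_sum = 0.0
        diverged = False
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            net.zero_grad()
            scores = net.forward(xb, train=True)
            correct += int((scores.argmax(axis=1) == yb).sum())
            loss, gscores = _softmax_xent(scores, yb)
            if not np.isfinite(loss):
                diverged = True
                break
            loss_sum += loss * len(yb)
            net.backward(gscores)
            opt.step(lr)
        if diverged:
            rec.status = "diverged"
            break
        rec.train_acc.append(correct / n)
        rec.train_loss.append(loss_sum / n)
        vacc, vloss = evaluate(net, Xval, yval, config.eval_batch)
        rec.val_acc.append(vacc)
        rec.val_loss.append(vloss)
        if vacc > rec.best_val_acc:   # strict: ties keep the earliest epoch
            rec.best_val_acc = vacc
            rec.best_epoch = epoch
            rec.test_acc, _ = evaluate(net, Xte, yte, config.eval_batch)
    return rec


def select_learning_rate(
    model_spec: ModelSpec,
    dataset: SensorDataset,
    candidates: Sequence[float] = LR_CANDIDATES,
    seed: int = 1000,
    config: Optional[TrainConfig] = None,
    lif_config: Optional[LIFConfig] = None,
) -> Tuple[float, Dict[float, RunRecord]]:
    """Train once per candidate learning rate (same seed); return the candidate
    with the highest best-validation accuracy, ties to the smaller rate."""
    if not candidates:
        raise ValueError("empty learning-rate candidate list")
    config = config or TrainConfig()
    records: Dict[float, RunRecord] = {}
    for lr in candidates:
        c = TrainConfig(**{**asdict(config), "learning_rate": lr})
        records[lr] = train(model_spec, dataset, c, seed=seed, lif_config=lif_config)
    ok = {lr: r for lr, r in records.items() if r.status == "ok"}
    if not ok:
        raise RuntimeError(
            "all learning-rate candidates diverged: "
            + ", ".join(f"{lr:g}={r.status}" for lr, r in records.items())
        )
    best = min(sorted(ok), key=lambda lr: (-ok[lr].best_val_acc, lr))
    return best, records


def run_seed_suite(
    model_spec: ModelSpec,
    dataset: SensorDataset,
    config: Optional[TrainConfig] = None,
    lif_config: Optional[LIFConfig] = None,
    seeds: Optional[Sequence[int]] = None,
) -> SuiteResult:
    """Train across seeds; report mean and sample sd of test accuracy."""
    config = config or TrainConfig()
    seeds = tuple(seeds if seeds is not None else config.seeds)
    records = [train(model_spec, dataset, config, seed=s, lif_config=lif_config)
               for s in seeds]
    accs = [r.test_acc for r in records if r.status == "ok"]
    if not accs:
        raise RuntimeError("every run in the seed suite diverged")
    mean = float(np.mean(accs))
    sd = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
    return SuiteResult(mean=mean, sd=sd, records=records, single_seed=len(accs) == 1)


ABLATION_AXES = ("tau", "v_th", "reset", "learnable_tau")


def ablate(
    model_spec: ModelSpec,
    dataset: SensorDataset,
    axis: str,
    grid: Sequence,
    config: Optional[TrainConfig] = None,
    base_lif: Optional[LIFConfig] = None,
    seeds: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """One seed suite per grid point, all other LIF settings at their defaults.

    ``axis`` is one of ``tau`` (grid values in [0,1] or the string ``"param"``
    for the learnable decay), ``v_th``, ``reset`` (hard/soft), or
    ``learnable_tau`` (booleans).  Returns a long-format table with columns
    ``model,dataset,axis,value,seed,val_best,test_acc``.
    """
    if axis not in ABLATION_AXES:
        raise ValueError(f"axis must be one of {ABLATION_AXES}, got {axis!r}")
    if not len(grid):
        raise ValueError("empty ablation grid")
    base = base_lif or LIFConfig()
    ds_name = dataset.meta.get("generator", "dataset")
    rows = []
    for value in grid:
        kw = dict(tau=base.tau, v_th=base.v_th, reset_mode=base.reset_mode,
                  learnable_tau=base.learnable_tau, b=base.b)
        if axis == "tau":
            if isinstance(value, str) and value == "param":
                kw["learnable_tau"], kw["b"] = True, 0.0
            else:
                kw["tau"], kw["learnable_tau"] = float(value), False
        elif axis == "v_th":
            kw["v_th"] = float(value)
        elif axis == "reset":
            kw["reset_mode"] = str(value)
        else:
            kw["learnable_tau"] = bool(value)
        suite = run_seed_suite(model_spec, dataset, config,
                               lif_config=LIFConfig(**kw), seeds=seeds)
        for r in suite.records:
            rows.append({
                "model": model_spec.name, "dataset": ds_name, "axis": axis,
                "value": value, "seed": r.seed, "val_best": r.best_val_acc,
                "test_acc": r.test_acc,
            })
    return pd.DataFrame(rows)
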