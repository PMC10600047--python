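"""Task-free continual-learning experiment harness.

Runs a learner sequentially over an ordered ``TaskSequence`` under one of
two evaluation regimes:

* ``fixed_epochs`` — every task is trained for the same number of epochs
  and performance is swept over a learning-rate grid;
* ``early_stop`` — the learning rate is fixed and training on each task
  stops once a training batch reaches a minimum accuracy, swept over that
  accuracy threshold.

The harness never tells a learner where one task ends and the next begins:
no task index is passed, no state is reset, no loss is changed.  Results
are collected in a long-format pandas ``EvalTable``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .learners import make_learner
from .network import DivergenceError, DynamicsConfig
from .sparsity import SparsityConfig

__all__ = [
    "Task",
    "TaskSequence",
    "ProtocolConfig",
    "train_on_task",
    "evaluate_all",
    "run_protocol",
    "run_sequence_with_records",
    "window_aggregate",
    "default_lr_grid",
]

EVAL_COLUMNS = [
    "variant",
    "lr",
    "stop_acc",
    "seed",
    "task_index",
    "phase",
    "accuracy",
]


@dataclass
class Task:
    """One supervised task; ``classes`` are the original class identities
    (e.g. digits) and ``c_train``/``c_test`` give them per sample, while
    ``y`` holds labels in the learner's output space."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    classes: Tuple[int, ...]
    c_train: np.ndarray
    c_test: np.ndarray


@dataclass
class TaskSequence:
    """Ordered tasks plus protocol metadata.

    ``paradigm`` is ``"domain"`` (all tasks share one label set, e.g.
    parity) or ``"class"`` (each task introduces fresh labels).
    """

    tasks: List[Task]
    paradigm: str
    n_outputs: int

    def __post_init__(self) -> None:
        if self.paradigm not in ("domain", "class"):
            raise ValueError("paradigm must be 'domain' or 'class'")
        label_sets = [set(np.unique(t.y_train)) for t in self.tasks]
        if self.paradigm == "domain":
            if any(ls != label_sets[0] for ls in label_sets):
                raise ValueError("domain-IL tasks must share one label set")
        else:
            for i, a in enumerate(label_sets):
                for b in label_sets[i + 1 :]:
                    if a & b:
                        raise ValueError("class-IL label sets must be disjoint")

    @property
    def input_dim(self) -> int:
        return self.tasks[0].X_train.shape[1]


@dataclass
class ProtocolConfig:
    """Evaluation-protocol knobs for ``run_protocol``.

    ``lr_grid`` drives the fixed-epoch sweep; ``stop_grid`` (with the fixed
    ``lr``) drives the early-stop sweep.  ``hidden_sizes`` fixes the shared
    architecture; five seeds by default.
    """

    regime: str = "fixed_epochs"
    n_epochs: int = 4
    max_epochs: int = 10
    stop_acc: Optional[float] = None
    lr: float = 1e-3
    lr_grid: Sequence[float] = field(default_factory=lambda: default_lr_grid())
    stop_grid: Sequence[float] = field(default_factory=lambda: [0.6, 0.8, 0.9, 0.95, 0.99])
    seeds: Sequence[int] = (0, 1, 2, 3, 4)
    batch_size: int = 32
    hidden_sizes: Sequence[int] = (32, 32)
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.regime not in ("fixed_epochs", "early_stop"):
            raise ValueError("regime must be 'fixed_epochs' or 'early_stop'")
        if len(self.lr_grid) == 0 or len(self.stop_grid) == 0:
            raise ValueError("grids must be nonempty")
        if self.stop_acc is not None and not (0.0 <= self.stop_acc):
            raise ValueError("stop_acc must be >= 0")


def default_lr_grid(
    lo_exp: float = -2.5, hi_exp: float = 0.0, per_decade: int = 4
) -> List[float]:
    """Log-spaced learning-rate grid, quarter-decade steps by default.

    The default range spans under-learning to catastrophic forgetting for
    the desk-scale synthetic sequences this package trains by default.
    """
    n = int(round((hi_exp - lo_exp) * per_decade)) + 1
    return list(np.logspace(lo_exp, hi_exp, n))


def _iter_batches(
    n: int, batch_size: int, rng: Optional[np.random.Generator], shuffle: bool
):
    idx = np.arange(n)
    if shuffle and rng is not None:
        rng.shuffle(idx)
    for start in range(0, n, batch_size):
        yield idx[start : start + batch_size]


def train_on_task(
    learner,
    task: Task,
    protocol: ProtocolConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[Dict]:
    """Train on one task; returns the per-batch training log.

    Under ``early_stop`` the loop exits as soon as the accuracy on the
    current training batch reaches ``protocol.stop_acc``; with
    ``stop_acc = 0`` that is after the first batch.  The learner is never
    told that a task boundary occurred.
    """
    early = protocol.regime == "early_stop"
    n_epochs = protocol.max_epochs if early else protocol.n_epochs
    stop_acc = protocol.stop_acc if protocol.stop_acc is not None else 1.01
    log: List[Dict] = []
    for epoch in range(n_epochs):
        for batch in _iter_batches(
            len(task.X_train), protocol.batch_size, rng, protocol.shuffle
        ):
            Xb, yb = task.X_train[batch], task.y_train[batch]
            info = learner.partial_fit(Xb, yb)
            acc = float(np.mean(learner.predict(Xb) == yb))
            log.append(
                {
                    "epoch": epoch,
                    "batch_size": len(batch),
                    "train_acc": acc,
                    "mean_output_error": info.get("mean_output_error", np.nan),
                    "converged": info.get("converged", True),
                }
            )
            if early and acc >= stop_acc:
                return log
    return log


def evaluate_all(learner, sequence: TaskSequence) -> Tuple[float, List[float]]:
    """Accuracy on the union of all tasks' test sets, plus the per-task
    breakdown.  Inference is a pure feedforward pass."""
    per_task: List[float] = []
    n_total = 0
    n_correct = 0
    for task in sequence.tasks:
        pred = learner.predict(task.X_test)
        correct = int(np.sum(pred == task.y_test))
        per_task.append(correct / len(task.y_test))
        n_correct += correct
        n_total += len(task.y_test)
    return n_correct / n_total, per_task


def _run_one(
    variant: str,
    sequence: TaskSequence,
    protocol: ProtocolConfig,
    lr: float,
    seed: int,
    dynamics: Optional[DynamicsConfig],
    sparsity: Optional[SparsityConfig],
):
    layer_sizes = [sequence.input_dim, *protocol.hidden_sizes, sequence.n_outputs]
    learner = make_learner(
        variant, layer_sizes, lr=lr, seed=seed, dynamics=dynamics, sparsity=sparsity
    )
    rng = np.random.default_rng(seed + 10_000)
    for task in sequence.tasks:
        train_on_task(learner, task, protocol, rng)
    return learner


def run_protocol(
    variant: str,
    sequence: TaskSequence,
    protocol: ProtocolConfig,
    dynamics: Optional[DynamicsConfig] = None,
    sparsity: Optional[SparsityConfig] = None,
) -> pd.DataFrame:
    """Full sweep for one variant; returns the long-format ``EvalTable``.

    ``fixed_epochs``: every (lr, seed) pair; ``early_stop``: every
    (stop_acc, seed) pair at the fixed ``protocol.lr``.  Each cell is a
    fresh initialisation, sequential training over all tasks, and a final
    all-task evaluation.  Diverged runs are recorded with phase
    ``"failed"`` rather than aborting the sweep.
    """
    rows: List[Dict] = []
    if protocol.regime == "fixed_epochs":
        cells = [(lr, None) for lr in protocol.lr_grid]
    else:
        cells = [(protocol.lr, sa) for sa in protocol.stop_grid]
    for lr, stop_acc in cells:
        proto = ProtocolConfig(**{**protocol.__dict__, "stop_acc": stop_acc})
        for seed in protocol.seeds:
            base = {
                "variant": variant,
                "lr": lr,
                "stop_acc": np.nan if stop_acc is None else stop_acc,
                "seed": seed,
            }
            try:
                learner = _run_one(
                    variant, sequence, proto, lr, seed, dynamics, sparsity
                )
            except DivergenceError:
                rows.append(
                    {**base, "task_index": -1, "phase": "failed", "accuracy": np.nan}
                )
                continue
            overall, per_task = evaluate_all(learner, sequence)
            rows.append(
                {**base, "task_index": -1, "phase": "final", "accuracy": overall}
            )
            for t, acc in enumerate(per_task):
                rows.append(
                    {**base, "task_index": t, "phase": "final", "accuracy": acc}
                )
    return pd.DataFrame(rows, columns=EVAL_COLUMNS)


def run_sequence_with_records(
    learner,
    sequence: TaskSequence,
    protocol: ProtocolConfig,
    rng: Optional[np.random.Generator] = None,
    n_record: int = 100,
):
    """Sequential training with activation capture for the analysis module.

    Records, for every task ``i`` and each of its classes, the last hidden
    layer's stable-state targets and pure feedforward activations at three
    checkpoints: ``task_start`` (before training task ``i``),
    ``first_learned`` (right after task ``i``) and ``final`` (end of the
    whole sequence); plus a readout-weight snapshot at every task end.
    Recording never feeds information back into the learner.
    """
    from .analysis import ActivationRecord

    rec = ActivationRecord()
    if rng is None:
        rng = np.random.default_rng(0)

    def capture(task_idx: int, task: Task, checkpoint: str, with_ff: bool = True):
        for cls in task.classes:
            sel = np.flatnonzero(task.c_train == cls)[:n_record]
            X = task.X_train[sel]
            y = task.y_train[sel]
            if hasattr(learner, "compute_stable_state"):
                ss = learner.compute_stable_state(X, y)
                r_ss = np.atleast_2d(ss.r_ss[-2])
            else:  # BP has no controlled dynamics; targets are feedforward
                r_ss = np.atleast_2d(learner.forward(X)[-2])
            r_ff = np.atleast_2d(learner.forward(X)[-2]) if with_ff else None
            rec.add(
                task_idx,
                cls,
                checkpoint,
                r_ss=r_ss,
                r_ff=r_ff,
                label=int(task.y_train[sel][0]) if len(sel) else -1,
            )

    for i, task in enumerate(sequence.tasks):
        capture(i, task, "task_start", with_ff=True)
        train_on_task(learner, task, protocol, rng)
        capture(i, task, "first_learned", with_ff=True)
        rec.set_readout(i, learner.params.W[-1].copy())
    for i, task in enumerate(sequence.tasks):
        capture(i, task, "final", with_ff=True)
    return learner, rec


def window_aggregate(
    table: pd.DataFrame, window: int = 6
) -> Tuple[float, Tuple[float, float]]:
    """Best mean accuracy over a contiguous learning-rate window.

    Seed-averaged final all-task accuracies are computed per LR, the sorted
    grid is scanned with a contiguous window of ``window`` LRs, and the
    maximum windowed mean plus that window's LR range is returned.
    """
    final = table[(table["phase"] == "final") & (table["task_index"] == -1)]
    by_lr = final.groupby("lr")["accuracy"].mean().sort_index()
    lrs = by_lr.index.to_numpy()
    if len(lrs) < window:
        raise ValueError(f"need at least {window} distinct LRs, got {len(lrs)}")
    best, best_range = -np.inf, (np.nan, np.nan)
    vals = by_lr.to_numpy()
    for start in range(len(lrs) - window + 1):
        m = float(vals[start : start + window].mean())
        if m > best:
            best = m
            best_range = (float(lrs[start]), float(lrs[start + window - 1]))
    return best, best_range
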