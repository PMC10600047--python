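"""Representation-geometry statistics for stored activations.

Quantifies how a learner's hidden representations are organised across
classes and tasks:

* **separation** — one minus the cosine similarity between two classes'
  summed absolute activation profiles; 0 for identical profiles, 1 for
  disjoint active populations;
* **normalized inter-label separation** — mean separation of different-
  label class pairs minus mean separation of same-label pairs;
* **hyperplane alignment / movement** — how well a new task's targets fall
  on the correct side of the previously learned readout boundary, and how
  much old feedforward representations drift toward that boundary;
* **effective dimensionality** — the exponential singular-value entropy
  (effective rank) of an activation matrix;
* **unaltered dimensionality fraction (gamma)** — the share of earlier
  tasks' principal subspace that a new task's subspace leaves untouched.
"""

from __future__ import annotations

import math
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "ActivationRecord",
    "separation_from_profiles",
    "separation",
    "mean_pairwise_separation",
    "normalized_inter_label_separation",
    "effective_dimensionality",
    "hyperplane_alignment",
    "hyperplane_movement",
    "subspace_unaltered_fraction",
    "unaltered_dimensionality_fraction",
    "plot_metric_vs_lr",
]

CHECKPOINTS = ("task_start", "first_learned", "final")


class ActivationRecord:
    """Stable-state targets and feedforward activations, keyed by
    ``(task, class, checkpoint)``, plus per-task readout snapshots."""

    def __init__(self) -> None:
        self._data: Dict[Tuple[int, int, str], Dict[str, Optional[np.ndarray]]] = {}
        self._readout: Dict[int, np.ndarray] = {}
        self.label_map: Dict[int, int] = {}
        self.task_of: Dict[int, int] = {}

    def add(
        self,
        task: int,
        cls: int,
        checkpoint: str,
        r_ss: np.ndarray,
        r_ff: Optional[np.ndarray] = None,
        label: Optional[int] = None,
    ) -> None:
        if checkpoint not in CHECKPOINTS:
            raise ValueError(f"checkpoint must be one of {CHECKPOINTS}")
        self._data[(task, cls, checkpoint)] = {
            "r_ss": np.asarray(r_ss, dtype=float),
            "r_ff": None if r_ff is None else np.asarray(r_ff, dtype=float),
        }
        if label is not None:
            self.label_map[cls] = label
        self.task_of[cls] = task

    def get(self, task: int, cls: int, checkpoint: str, kind: str = "r_ss") -> np.ndarray:
        try:
            entry = self._data[(task, cls, checkpoint)]
        except KeyError:
            raise KeyError(
                f"no record for task={task}, class={cls}, checkpoint={checkpoint!r}"
            ) from None
        arr = entry[kind]
        if arr is None:
            raise KeyError(f"{kind} not stored for ({task}, {cls}, {checkpoint})")
        return arr

    def set_readout(self, task: int, W_out: np.ndarray) -> None:
        self._readout[task] = np.asarray(W_out, dtype=float)

    def readout(self, task: int) -> np.ndarray:
        try:
            return self._readout[task]
        except KeyError:
            raise KeyError(f"no readout snapshot for task {task}") from None

    @property
    def classes(self) -> List[int]:
        return sorted(self.task_of)

    @property
    def tasks(self) -> List[int]:
        return sorted({t for t in self.task_of.values()})

    def save(self, path) -> None:
        arrays = {}
        meta = []
        for (task, cls, cp), entry in self._data.items():
            key = f"t{task}_c{cls}_{cp}"
            arrays[key + "_rss"] = entry["r_ss"]
            if entry["r_ff"] is not None:
                arrays[key + "_rff"] = entry["r_ff"]
            meta.append((task, cls, cp, self.label_map.get(cls, -1)))
        for task, w in self._readout.items():
            arrays[f"readout_{task}"] = w
        arrays["_meta"] = np.array(
            [(t, c, cp, lb) for t, c, cp, lb in meta], dtype=object
        )
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path) -> "ActivationRecord":
        rec = cls()
        with np.load(Path(path), allow_pickle=True) as data:
            for task, c, cp, lb in data["_meta"]:
                key = f"t{task}_c{c}_{cp}"
                r_ff = data[key + "_rff"] if key + "_rff" in data else None
                rec.add(int(task), int(c), str(cp), data[key + "_rss"], r_ff, int(lb))
            for name in data.files:
                if name.startswith("readout_"):
                    rec.set_readout(int(name.split("_")[1]), data[name])
        return rec


# -- separation ------------------------------------------------------------


def _profile(X: np.ndarray) -> np.ndarray:
    """Summed absolute activation profile ``a = sum_j |r_j|`` of a class."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.abs(X).sum(axis=0)


def separation_from_profiles(a1: np.ndarray, a2: np.ndarray) -> float:
    """``1 - cos(a1, a2)``; in [0, 1] for nonnegative profiles."""
    n1, n2 = np.linalg.norm(a1), np.linalg.norm(a2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("separation undefined for an all-zero activation profile")
    return float(1.0 - (a1 @ a2) / (n1 * n2))


def separation(
    rec: ActivationRecord,
    digit1: int,
    digit2: int,
    checkpoint: str = "final",
    kind: str = "r_ss",
) -> float:
    """Representational separation between two classes at a checkpoint."""
    a1 = _profile(rec.get(rec.task_of[digit1], digit1, checkpoint, kind))
    a2 = _profile(rec.get(rec.task_of[digit2], digit2, checkpoint, kind))
    return separation_from_profiles(a1, a2)


def mean_pairwise_separation(
    rec: ActivationRecord, checkpoint: str = "first_learned", kind: str = "r_ss"
) -> float:
    """Mean separation over all unordered class pairs."""
    pairs = list(combinations(rec.classes, 2))
    return float(np.mean([separation(rec, a, b, checkpoint, kind) for a, b in pairs]))


def normalized_inter_label_separation(
    rec: ActivationRecord,
    label_map: Optional[Dict[int, int]] = None,
    checkpoint: str = "final",
    kind: str = "r_ss",
) -> float:
    """Mean inter-label separation minus mean intra-label separation.

    Class pairs are enumerated once (unordered, no self-pairs); pairs whose
    classes share a label contribute to the intra mean, the rest to the
    inter mean.
    """
    labels = label_map if label_map is not None else rec.label_map
    classes = rec.classes
    if len({labels[c] for c in classes}) < 2:
        raise ValueError("need at least two distinct labels")
    inter, intra = [], []
    for d1, d2 in combinations(classes, 2):
        s = separation(rec, d1, d2, checkpoint, kind)
        (intra if labels[d1] == labels[d2] else inter).append(s)
    if not intra:
        raise ValueError("no same-label class pair available for the intra mean")
    return float(np.mean(inter) - np.mean(intra))


# -- dimensionality --------------------------------------------------------


def effective_dimensionality(
    X: np.ndarray, center: bool = True, method: str = "erank"
) -> float:
    """Effective rank of an activation matrix.

    ``erank``: singular values of the (optionally centred) matrix are
    normalised to a distribution ``p_k = sigma_k / sum(sigma)`` and
    ``ED = exp(-sum p_k log p_k)``.  ``participation``: the participation
    ratio ``(sum sigma^2)^2 / sum sigma^4``.  An all-zero (or rank-0)
    matrix returns 1 by convention.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2 and center:
        return 1.0
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(X, compute_uv=False)
    sv = sv[sv > 1e-12 * max(1.0, sv[0] if len(sv) else 1.0)]
    if len(sv) == 0:
        return 1.0
    if method == "erank":
        p = sv / sv.sum()
        return float(np.exp(-np.sum(p * np.log(p))))
    if method == "participation":
        s2 = sv**2
        return float(s2.sum() ** 2 / np.sum(s2**2))
    raise ValueError("method must be 'erank' or 'participation'")


# -- hyperplane geometry ---------------------------------------------------


def _task_label_pair(rec: ActivationRecord, task_i: int) -> Tuple[int, int]:
    classes = [c for c, t in rec.task_of.items() if t == task_i]
    labels = sorted({rec.label_map[c] for c in classes})
    if len(labels) != 2:
        raise ValueError(
            f"hyperplane metrics need exactly two labels in task {task_i}, got {labels}"
        )
    return labels[0], labels[1]


def hyperplane_alignment(rec: ActivationRecord, task_i: int) -> float:
    """Fraction of task ``i``'s initial targets separated correctly by the
    readout learned on task ``i - 1``."""
    if task_i < 1:
        raise ValueError("alignment needs a previous task's readout")
    W = rec.readout(task_i - 1)
    classes = sorted(c for c, t in rec.task_of.items() if t == task_i)
    correct = 0
    total = 0
    for cls in classes:
        X = rec.get(task_i, cls, "task_start", "r_ss")
        pred = np.argmax(X @ W.T, axis=1)
        correct += int(np.sum(pred == rec.label_map[cls]))
        total += len(X)
    return correct / total


def hyperplane_movement(rec: ActivationRecord, task_i: int) -> float:
    """Normalised movement of task ``i``'s feedforward activations toward
    the decision boundary stored at the end of task ``i``.

    For each sample the displacement between the ``first_learned`` and
    ``final`` checkpoints is decomposed; only decreases of the signed
    distance to the hyperplane, on the sample's label side, count as
    movement toward.  Returned as (sum of movement toward) / (sum of total
    displacement), 0 when nothing moved.
    """
    a, b = _task_label_pair(rec, task_i)
    W = rec.readout(task_i)
    normal = W[a] - W[b]
    nn = np.linalg.norm(normal)
    if nn == 0.0:
        raise ValueError("degenerate readout: zero separating normal")
    normal = normal / nn
    toward = 0.0
    total = 0.0
    for cls in sorted(c for c, t in rec.task_of.items() if t == task_i):
        X0 = rec.get(task_i, cls, "first_learned", "r_ff")
        X1 = rec.get(task_i, cls, "final", "r_ff")
        if len(X0) != len(X1):
            raise ValueError("checkpoint sample counts differ")
        sign = 1.0 if rec.label_map[cls] == a else -1.0
        d0 = sign * (X0 @ normal)
        d1 = sign * (X1 @ normal)
        toward += float(np.sum(np.maximum(0.0, d0 - d1)))
        total += float(np.sum(np.linalg.norm(X1 - X0, axis=1)))
    return 0.0 if total == 0.0 else toward / total


# -- subspace overlap ------------------------------------------------------


def _principal_basis(X: np.ndarray, k: int) -> np.ndarray:
    Xc = X - X.mean(axis=0, keepdims=True)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    return Vt[:k]


def subspace_unaltered_fraction(X_prev: np.ndarray, X_new: np.ndarray) -> float:
    """Gamma: the fraction of the previous tasks' principal subspace left
    unused by the new task's representations.

    Both matrices are reduced to their leading ``ceil(ED)`` principal
    components; the shared dimensionality is the squared Frobenius norm of
    the inner-product matrix between the two orthonormal bases, and
    ``gamma = (ED_prev - shared) / ED_prev``, clipped to [0, 1].
    """
    ed_prev = effective_dimensionality(X_prev)
    ed_new = effective_dimensionality(X_new)
    U_prev = _principal_basis(np.atleast_2d(X_prev), int(math.ceil(ed_prev)))
    U_new = _principal_basis(np.atleast_2d(X_new), int(math.ceil(ed_new)))
    shared = float(np.sum((U_prev @ U_new.T) ** 2))
    return float(np.clip((ed_prev - shared) / ed_prev, 0.0, 1.0))


def unaltered_dimensionality_fraction(
    rec: ActivationRecord, task_i: int, checkpoint: str = "first_learned"
) -> float:
    """Gamma for task ``i`` against the pooled targets of tasks ``< i``."""
    if task_i < 1:
        raise ValueError("gamma is undefined for the first task")
    prev = [
        rec.get(t, c, checkpoint, "r_ss")
        for c, t in rec.task_of.items()
        if t < task_i
    ]
    new = [
        rec.get(task_i, c, checkpoint, "r_ss")
        for c, t in rec.task_of.items()
        if t == task_i
    ]
    if not prev or not new:
        raise ValueError("missing activation records for gamma")
    return subspace_unaltered_fraction(np.vstack(prev), np.vstack(new))


# -- plotting --------------------------------------------------------------


def plot_metric_vs_lr(table, value: str = "accuracy", ax=None):
    """Seed-averaged metric against learning rate, one line per variant."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    final = table[(table["phase"] == "final") & (table["task_index"] == -1)]
    for variant, sub in final.groupby("variant"):
        agg = sub.groupby("lr")[value].agg(["mean", "std"]).sort_index()
        ax.errorbar(agg.index, agg["mean"], yerr=agg["std"], label=variant)
    ax.set_xscale("log")
    ax.set_xlabel("learning rate")
    ax.set_ylabel(value)
    ax.legend()
    return ax
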