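"""Task-sequence generation and MNIST-format ingestion.

The synthetic generator emulates the statistical structure of split-MNIST:
each task is a pair of Gaussian class clusters living on a small set of
informative input dimensions, a tunable fraction of which is shared across
tasks (split-MNIST digits reuse strokes; later tasks interfere with
earlier ones exactly because useful features overlap).  Labels follow
either the domain-incremental rule (all tasks share one label set, the
parity analogue) or the class-incremental rule (every class gets its own
output unit).

Real MNIST-style data in IDX format can be read with :func:`read_idx` and
split into the canonical five two-digit tasks with
:func:`split_by_classes`.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .harness import Task, TaskSequence

__all__ = [
    "SyntheticSpec",
    "generate_sequence",
    "read_idx",
    "write_idx",
    "split_by_classes",
    "DEFAULT_PAIRS",
]

DEFAULT_PAIRS: Tuple[Tuple[int, int], ...] = ((0, 1), (2, 3), (4, 5), (6, 7), (8, 9))


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic split-task generator.

    ``class_separation`` is the Euclidean distance between the two class
    means of a task; ``cluster_spread`` the isotropic within-class standard
    deviation, so ``class_separation / cluster_spread`` controls single-task
    difficulty (4 gives ~98% linearly separable classes, comparable to an
    easy digit pair).  ``task_feature_overlap`` is the fraction of each
    task's informative dimensions drawn from a pool shared by all tasks —
    the knob that creates cross-task interference.
    """

    n_tasks: int = 5
    classes_per_task: int = 2
    input_dim: int = 64
    samples_per_class: int = 500
    test_samples_per_class: int = 100
    cluster_spread: float = 0.25
    class_separation: float = 1.0
    task_feature_overlap: float = 0.5
    dims_per_task: int = 16
    label_rule: str = "parity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim <= 0 or self.dims_per_task <= 0:
            raise ValueError("dimensions must be positive")
        if not (0.0 <= self.task_feature_overlap <= 1.0):
            raise ValueError("task_feature_overlap must lie in [0, 1]")
        if self.label_rule not in ("parity", "distinct"):
            raise ValueError("label_rule must be 'parity' or 'distinct'")
        n_shared = round(self.task_feature_overlap * self.dims_per_task)
        needed = n_shared + self.n_tasks * (self.dims_per_task - n_shared)
        if needed > self.input_dim:
            raise ValueError(
                f"input_dim={self.input_dim} too small for {self.n_tasks} tasks "
                f"with {self.dims_per_task} informative dims at overlap "
                f"{self.task_feature_overlap} (needs {needed})"
            )


def generate_sequence(spec: SyntheticSpec) -> TaskSequence:
    """Deterministically generate a :class:`TaskSequence` from a spec.

    Each task owns an informative dimension set (partly shared across
    tasks); its two classes sit at ``0.5 +- (separation / 2) z`` on those
    dimensions for a random unit direction ``z``, with isotropic Gaussian
    noise everywhere and values clipped to [0, 1] to mirror pixel range.
    Train and test sets are disjoint draws.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.input_dim
    m = spec.dims_per_task
    n_shared = round(spec.task_feature_overlap * m)

    perm = rng.permutation(d)
    shared = perm[:n_shared]
    pool = perm[n_shared:]
    own_per_task = m - n_shared

    n_classes = spec.n_tasks * spec.classes_per_task
    tasks: List[Task] = []
    for t in range(spec.n_tasks):
        own = pool[t * own_per_task : (t + 1) * own_per_task]
        dims = np.concatenate([shared, own]).astype(int)
        z = rng.standard_normal(m)
        z /= np.linalg.norm(z)

        means = []
        for c in range(spec.classes_per_task):
            sign = 1.0 if c % 2 == 0 else -1.0
            mu = np.zeros(d)
            mu[dims] = 0.5 + sign * (spec.class_separation / 2.0) * z
            means.append(mu)

        def draw(n: int, mu: np.ndarray) -> np.ndarray:
            X = mu + rng.normal(0.0, spec.cluster_spread, size=(n, d))
            return np.clip(X, 0.0, 1.0)

        X_tr, y_tr, c_tr, X_te, y_te, c_te = [], [], [], [], [], []
        classes = []
        for c, mu in enumerate(means):
            cls = t * spec.classes_per_task + c
            classes.append(cls)
            label = c if spec.label_rule == "parity" else cls
            X_tr.append(draw(spec.samples_per_class, mu))
            y_tr.append(np.full(spec.samples_per_class, label))
            c_tr.append(np.full(spec.samples_per_class, cls))
            X_te.append(draw(spec.test_samples_per_class, mu))
            y_te.append(np.full(spec.test_samples_per_class, label))
            c_te.append(np.full(spec.test_samples_per_class, cls))
        tasks.append(
            Task(
                X_train=np.vstack(X_tr),
                y_train=np.concatenate(y_tr),
                X_test=np.vstack(X_te),
                y_test=np.concatenate(y_te),
                classes=tuple(classes),
                c_train=np.concatenate(c_tr),
                c_test=np.concatenate(c_te),
            )
        )
    n_outputs = spec.classes_per_task if spec.label_rule == "parity" else n_classes
    paradigm = "domain" if spec.label_rule == "parity" else "class"
    return TaskSequence(tasks=tasks, paradigm=paradigm, n_outputs=n_outputs)


# -- IDX (MNIST) format ----------------------------------------------------

_IDX_IMAGES_MAGIC = 2051
_IDX_LABELS_MAGIC = 2049


def read_idx(path_images, path_labels) -> Tuple[np.ndarray, np.ndarray]:
    """Read an IDX image/label file pair (the standard MNIST layout).

    Images are flattened to float vectors scaled to [0, 1]; labels are
    returned as integers.  Raises ``ValueError`` on a bad magic number,
    truncated data, or mismatched image/label counts.
    """
    img_bytes = Path(path_images).read_bytes()
    lab_bytes = Path(path_labels).read_bytes()
    if len(img_bytes) < 16:
        raise ValueError("truncated IDX image file (header incomplete)")
    if len(lab_bytes) < 8:
        raise ValueError("truncated IDX label file (header incomplete)")
    magic, n, rows, cols = struct.unpack(">iiii", img_bytes[:16])
    if magic != _IDX_IMAGES_MAGIC:
        raise ValueError(f"bad IDX image magic number {magic} (expected 2051)")
    lmagic, ln = struct.unpack(">ii", lab_bytes[:8])
    if lmagic != _IDX_LABELS_MAGIC:
        raise ValueError(f"bad IDX label magic number {lmagic} (expected 2049)")
    if n != ln:
        raise ValueError(f"image count {n} != label count {ln}")
    n_pix = n * rows * cols
    if len(img_bytes) - 16 < n_pix:
        raise ValueError("truncated IDX image file (pixel data incomplete)")
    if len(lab_bytes) - 8 < n:
        raise ValueError("truncated IDX label file (label data incomplete)")
    images = np.frombuffer(img_bytes, dtype=np.uint8, count=n_pix, offset=16)
    images = images.reshape(n, rows * cols).astype(float) / 255.0
    labels = np.frombuffer(lab_bytes, dtype=np.uint8, count=n, offset=8).astype(int)
    return images, labels


def write_idx(
    path_images, path_labels, images: np.ndarray, labels: np.ndarray, shape=None
) -> None:
    """Write an image/label pair in IDX format (inverse of :func:`read_idx`).

    ``images`` may be uint8 pixels or floats in [0, 1] (scaled by 255);
    ``shape`` gives (rows, cols) and defaults to a flat 1xD layout.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    if len(images) != len(labels):
        raise ValueError("image and label counts differ")
    if images.dtype != np.uint8:
        images = np.round(np.clip(images, 0.0, 1.0) * 255.0).astype(np.uint8)
    n = len(images)
    rows, cols = shape if shape is not None else (1, images.reshape(n, -1).shape[1])
    with open(path_images, "wb") as fh:
        fh.write(struct.pack(">iiii", _IDX_IMAGES_MAGIC, n, rows, cols))
        fh.write(images.reshape(n, rows * cols).tobytes())
    with open(path_labels, "wb") as fh:
        fh.write(struct.pack(">ii", _IDX_LABELS_MAGIC, n))
        fh.write(labels.astype(np.uint8).tobytes())


def split_by_classes(
    inputs: np.ndarray,
    labels: np.ndarray,
    test_inputs: np.ndarray,
    test_labels: np.ndarray,
    pairs: Optional[Sequence[Sequence[int]]] = None,
    paradigm: str = "domain",
) -> TaskSequence:
    """Split a labelled dataset into an ordered sequence of class-pair tasks.

    Default pairs are the consecutive digits (0,1)...(8,9).  Under
    ``domain`` the label is the class parity (shared even/odd outputs);
    under ``class`` each class keeps its own output unit.
    """
    pairs = [tuple(p) for p in (pairs if pairs is not None else DEFAULT_PAIRS)]
    labels = np.asarray(labels)
    test_labels = np.asarray(test_labels)
    present = set(np.unique(labels)) & set(np.unique(test_labels))
    for p in pairs:
        for cls in p:
            if cls not in present:
                raise ValueError(f"class {cls} missing from the dataset")
    all_classes = sorted({c for p in pairs for c in p})
    tasks: List[Task] = []
    for pair in pairs:
        tr = np.isin(labels, pair)
        te = np.isin(test_labels, pair)

        def relabel(c: np.ndarray) -> np.ndarray:
            if paradigm == "domain":
                return c % 2
            return c

        tasks.append(
            Task(
                X_train=np.asarray(inputs)[tr],
                y_train=relabel(labels[tr]),
                X_test=np.asarray(test_inputs)[te],
                y_test=relabel(test_labels[te]),
                classes=tuple(pair),
                c_train=labels[tr],
                c_test=test_labels[te],
            )
        )
    n_outputs = 2 if paradigm == "domain" else len(all_classes)
    return TaskSequence(tasks=tasks, paradigm=paradigm, n_outputs=n_outputs)
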