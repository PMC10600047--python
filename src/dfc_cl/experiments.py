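"""Canned desk-scale continual-learning studies.

These functions bundle the study conditions used throughout the package's
evaluation: a five-task synthetic sequence (64-dimensional inputs, two
Gaussian classes per task, half of each task's informative features shared
across tasks), a 32-32 hidden architecture, four training epochs per task,
and five random seeds.  The learning rate 0.1 sits mid-range on the
package's default grid (1e-2.5 ... 1), inside the regime where learning is
strong enough for sequential training to cause forgetting — which is where
continual-learning methods separate from plain backpropagation.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from .analysis import (
    effective_dimensionality,
    mean_pairwise_separation,
    unaltered_dimensionality_fraction,
)
from .datasets import SyntheticSpec, generate_sequence
from .harness import (
    ProtocolConfig,
    evaluate_all,
    run_sequence_with_records,
    train_on_task,
)
from .learners import make_learner

__all__ = [
    "STUDY_LR",
    "study_protocol",
    "study_spec",
    "forgetting_study",
    "representation_study",
]

STUDY_LR = 0.1
HIDDEN = (32, 32)


def study_protocol(**overrides) -> ProtocolConfig:
    return ProtocolConfig(n_epochs=4, hidden_sizes=HIDDEN, **overrides)


def study_spec(paradigm: str = "domain", data_seed: int = 0) -> SyntheticSpec:
    return SyntheticSpec(
        label_rule="parity" if paradigm == "domain" else "distinct",
        seed=data_seed,
    )


def forgetting_study(
    variants: Sequence[str] = ("bp", "dfc_sparse", "dfc_sparse_rec"),
    seeds: Sequence[int] = tuple(range(10)),
    lr: float = STUDY_LR,
    data_seed: int = 0,
) -> Dict[str, Dict]:
    """Final all-task accuracy after sequential domain-IL training.

    Ten seeds by default: the sparse-only variant's final accuracy is the
    noisiest of the three (its seed-to-seed spread is several times BP's),
    so the accuracy comparison needs more replicates than the
    representation study to estimate the means well.

    Returns ``{variant: {"per_seed": [...], "mean": float, "sd": float}}``.
    """
    seq = generate_sequence(study_spec("domain", data_seed))
    proto = study_protocol()
    layer_sizes = [seq.input_dim, *HIDDEN, seq.n_outputs]
    out: Dict[str, Dict] = {}
    for variant in variants:
        accs = []
        for seed in seeds:
            learner = make_learner(variant, layer_sizes, lr=lr, seed=seed)
            rng = np.random.default_rng(seed + 10_000)
            for task in seq.tasks:
                train_on_task(learner, task, proto, rng)
            overall, _ = evaluate_all(learner, seq)
            accs.append(float(overall))
        out[variant] = {
            "per_seed": accs,
            "mean": float(np.mean(accs)),
            "sd": float(np.std(accs)),
        }
    return out


def representation_study(
    variants: Sequence[str] = ("dfc", "dfc_rec", "dfc_sparse", "dfc_sparse_rec"),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    lr: float = STUDY_LR,
    data_seed: int = 0,
    n_record: int = 100,
) -> Dict[str, Dict]:
    """Class-IL representation geometry of the last hidden layer's targets.

    For each variant and seed: mean pairwise class separation (targets right
    after their task is learned), effective dimensionality of per-task
    target matrices (averaged over tasks), and the unaltered dimensionality
    fraction gamma (averaged over tasks 2..T).
    """
    seq = generate_sequence(study_spec("class", data_seed))
    proto = study_protocol()
    layer_sizes = [seq.input_dim, *HIDDEN, seq.n_outputs]
    out: Dict[str, Dict] = {}
    for variant in variants:
        seps, eds, gammas = [], [], []
        for seed in seeds:
            learner = make_learner(variant, layer_sizes, lr=lr, seed=seed)
            rng = np.random.default_rng(seed + 10_000)
            _, rec = run_sequence_with_records(learner, seq, proto, rng, n_record)
            seps.append(mean_pairwise_separation(rec, "first_learned"))
            eds.append(
                float(
                    np.mean(
                        [
                            effective_dimensionality(
                                np.vstack(
                                    [
                                        rec.get(t, c, "first_learned", "r_ss")
                                        for c, tt in rec.task_of.items()
                                        if tt == t
                                    ]
                                )
                            )
                            for t in rec.tasks
                        ]
                    )
                )
            )
            gammas.append(
                float(
                    np.mean(
                        [
                            unaltered_dimensionality_fraction(rec, t)
                            for t in rec.tasks[1:]
                        ]
                    )
                )
            )
        out[variant] = {
            "separation": {"per_seed": seps, "mean": float(np.mean(seps))},
            "effective_dimensionality": {"per_seed": eds, "mean": float(np.mean(eds))},
            "gamma": {"per_seed": gammas, "mean": float(np.mean(gammas))},
        }
    return out
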