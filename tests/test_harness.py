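"""Continual-learning harness: training loops, regimes, aggregation."""

import numpy as np
import pandas as pd
import pytest

import dfc_cl.harness as harness_mod
from dfc_cl.datasets import SyntheticSpec, generate_sequence
from dfc_cl.harness import (
    ProtocolConfig,
    TaskSequence,
    evaluate_all,
    run_protocol,
    train_on_task,
    window_aggregate,
)
from dfc_cl.learners import BPLearner, DFCLearner, make_learner


@pytest.fixture(scope="module")
def tiny_sequence():
    """2 easy tasks, 16-dim inputs, small sample counts: fast to train."""
    spec = SyntheticSpec(
        n_tasks=2,
        input_dim=16,
        dims_per_task=8,
        samples_per_class=60,
        test_samples_per_class=30,
        class_separation=1.5,
        cluster_spread=0.2,
        seed=7,
    )
    return generate_sequence(spec)


@pytest.fixture
def fast_protocol():
    return ProtocolConfig(n_epochs=2, hidden_sizes=(16,), seeds=(0,))


class TestTrainOnTask:
    def test_degenerate_stop_threshold_stops_after_first_batch(self, tiny_sequence):
        proto = ProtocolConfig(regime="early_stop", stop_acc=0.0, hidden_sizes=(8,))
        learner = BPLearner([16, 8, 2], lr=0.05, seed=0)
        log = train_on_task(learner, tiny_sequence.tasks[0], proto)
        assert len(log) == 1

    def test_separable_task_reaches_full_training_accuracy(self, tiny_sequence):
        task = tiny_sequence.tasks[0]
        learner = BPLearner([16, 16, 2], lr=0.5, seed=0)
        proto = ProtocolConfig(n_epochs=30, hidden_sizes=(16,))
        train_on_task(learner, task, proto, np.random.default_rng(0))
        acc = np.mean(learner.predict(task.X_train) == task.y_train)
        assert acc == 1.0

    def test_no_task_information_in_learner_api(self):
        # the learner surface carries no task/boundary vocabulary at all
        for cls in (DFCLearner, BPLearner):
            public = [m for m in dir(cls) if not m.startswith("_")]
            assert not any("task" in m.lower() or "reset" in m.lower() for m in public)


class TestEvaluateAll:
    def test_untrained_balanced_accuracy_near_chance(self, tiny_sequence):
        # an untrained net predicts near-constantly per cluster, so accuracy
        # is a cluster-level coin flip: average over init seeds
        accs = []
        for seed in range(10):
            learner = BPLearner([16, 16, 2], lr=0.0, seed=seed)
            overall, per_task = evaluate_all(learner, tiny_sequence)
            accs.append(overall)
        assert len(per_task) == 2
        assert 0.3 < np.mean(accs) < 0.7

    def test_consistency_single_task(self, tiny_sequence):
        task = tiny_sequence.tasks[0]
        learner = BPLearner([16, 16, 2], lr=0.3, seed=0)
        proto = ProtocolConfig(n_epochs=5, hidden_sizes=(16,))
        train_on_task(learner, task, proto, np.random.default_rng(0))
        _, per_task = evaluate_all(learner, tiny_sequence)
        direct = np.mean(learner.predict(task.X_test) == task.y_test)
        assert per_task[0] == pytest.approx(direct)

    def test_joint_training_dominates_sequential(self, tiny_sequence):
        # forgetting only hurts: training on the shuffled union of tasks is
        # at least as good as sequential training (up to seed noise)
        proto = ProtocolConfig(n_epochs=4, hidden_sizes=(16,))
        rng = np.random.default_rng(0)
        seq_learner = BPLearner([16, 16, 2], lr=0.5, seed=0)
        for task in tiny_sequence.tasks:
            train_on_task(seq_learner, task, proto, rng)
        seq_acc, _ = evaluate_all(seq_learner, tiny_sequence)

        X = np.vstack([t.X_train for t in tiny_sequence.tasks])
        y = np.concatenate([t.y_train for t in tiny_sequence.tasks])
        joint = BPLearner([16, 16, 2], lr=0.5, seed=0)
        order = np.random.default_rng(1).permutation(len(X))
        for _ in range(proto.n_epochs):
            for start in range(0, len(X), 32):
                b = order[start : start + 32]
                joint.partial_fit(X[b], y[b])
        joint_acc, _ = evaluate_all(joint, tiny_sequence)
        assert joint_acc >= seq_acc - 0.05


class TestRunProtocol:
    def test_single_cell_table_layout(self, tiny_sequence):
        proto = ProtocolConfig(
            n_epochs=1, lr_grid=[0.05], seeds=(0,), hidden_sizes=(8,)
        )
        table = run_protocol("bp", tiny_sequence, proto)
        finals = table[table["phase"] == "final"]
        # one overall row + one per task
        assert len(finals) == 1 + len(tiny_sequence.tasks)
        assert set(finals["task_index"]) == {-1, 0, 1}
        assert ((finals["accuracy"] >= 0) & (finals["accuracy"] <= 1)).all()

    def test_deterministic_given_seed(self, tiny_sequence):
        proto = ProtocolConfig(
            n_epochs=1, lr_grid=[0.1], seeds=(1,), hidden_sizes=(8,)
        )
        t1 = run_protocol("dfc", tiny_sequence, proto)
        t2 = run_protocol("dfc", tiny_sequence, proto)
        pd.testing.assert_frame_equal(t1, t2)

    def test_bp_sanity_on_toy_task(self, tiny_sequence):
        proto = ProtocolConfig(
            n_epochs=10, lr_grid=[0.5], seeds=(0,), hidden_sizes=(16,)
        )
        single = TaskSequence(
            tasks=[tiny_sequence.tasks[0]], paradigm="domain", n_outputs=2
        )
        table = run_protocol("bp", single, proto)
        overall = table[(table["phase"] == "final") & (table["task_index"] == -1)]
        assert overall["accuracy"].iloc[0] >= 0.95

    def test_sparse_variant_at_zero_sparsity_matches_dense(self, tiny_sequence):
        # all-ones masks at s = 0 make the sparse code path coincide with
        # the dense one (centring held equal on both sides)
        from dfc_cl.sparsity import SparsityConfig

        proto = ProtocolConfig(n_epochs=1, hidden_sizes=(8,))
        task = tiny_sequence.tasks[0]
        dense = DFCLearner([16, 8, 2], lr=0.1, seed=5, center_updates=True)
        sparse = DFCLearner(
            [16, 8, 2],
            lr=0.1,
            seed=5,
            sparse=True,
            sparsity=SparsityConfig(s_ss=[0.0]),
            center_updates=True,
        )
        train_on_task(dense, task, proto, np.random.default_rng(9))
        train_on_task(sparse, task, proto, np.random.default_rng(9))
        for a, b in zip(dense.params.W, sparse.params.W):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_regime_equivalence_unreachable_stop(self, tiny_sequence):
        fixed = ProtocolConfig(
            regime="fixed_epochs", n_epochs=2, lr_grid=[0.1], seeds=(0,), hidden_sizes=(8,)
        )
        early = ProtocolConfig(
            regime="early_stop",
            max_epochs=2,
            lr=0.1,
            stop_grid=[1.01],
            seeds=(0,),
            hidden_sizes=(8,),
        )
        t_fixed = run_protocol("bp", tiny_sequence, fixed)
        t_early = run_protocol("bp", tiny_sequence, early)
        np.testing.assert_allclose(
            t_fixed[t_fixed["phase"] == "final"]["accuracy"].to_numpy(),
            t_early[t_early["phase"] == "final"]["accuracy"].to_numpy(),
        )


class TestTaskFreeContract:
    def test_spy_sees_only_data_batches_and_no_resets(self, tiny_sequence, monkeypatch):
        calls = []
        constructions = []
        real_make = harness_mod.make_learner

        class Spy:
            def __init__(self, inner):
                self.inner = inner
                self.param_id = id(inner.params.W[0])

            def partial_fit(self, *args, **kwargs):
                calls.append((len(args), sorted(kwargs)))
                assert id(self.inner.params.W[0]) == self.param_id, (
                    "weights were reinitialised mid-sequence"
                )
                return self.inner.partial_fit(*args, **kwargs)

            def predict(self, X):
                return self.inner.predict(X)

        def spying_make(variant, layer_sizes, **kwargs):
            constructions.append(variant)
            return Spy(real_make(variant, layer_sizes, **kwargs))

        monkeypatch.setattr(harness_mod, "make_learner", spying_make)
        proto = ProtocolConfig(
            n_epochs=1, lr_grid=[0.05, 0.1], seeds=(0,), hidden_sizes=(8,)
        )
        run_protocol("dfc", tiny_sequence, proto)
        # one fresh learner per grid cell, never one per task
        assert len(constructions) == 2
        # every update call carries exactly (X, y) and nothing else
        assert calls and all(c == (2, []) for c in calls)


class TestWindowAggregate:
    @staticmethod
    def _table(lrs, accs):
        rows = []
        for lr, acc in zip(lrs, accs):
            rows.append(
                {
                    "variant": "x",
                    "lr": lr,
                    "stop_acc": np.nan,
                    "seed": 0,
                    "task_index": -1,
                    "phase": "final",
                    "accuracy": acc,
                }
            )
        return pd.DataFrame(rows)

    def test_constant_accuracy_returns_it(self):
        lrs = np.logspace(-4, -1, 9)
        best, _ = window_aggregate(self._table(lrs, [0.7] * 9), window=6)
        assert best == pytest.approx(0.7)

    def test_forced_maximum_window(self):
        accs = [0, 0, 1, 1, 1, 1, 1, 1, 0]
        best, (lo, hi) = window_aggregate(
            self._table(np.logspace(-4, -1, 9), accs), window=6
        )
        assert best == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self, rng):
        lrs = np.logspace(-4, -1, 10)
        accs = rng.random(10)
        best, _ = window_aggregate(self._table(lrs, accs), window=6)
        brute = max(np.mean(accs[i : i + 6]) for i in range(5))
        assert best == pytest.approx(brute)

    def test_too_few_lrs_raises(self):
        with pytest.raises(ValueError):
            window_aggregate(self._table([1e-3, 1e-2], [0.5, 0.5]), window=6)

    def test_averages_over_seeds_before_windowing(self):
        rows = []
        for seed, offset in [(0, 0.0), (1, 0.2)]:
            for lr in np.logspace(-4, -1, 6):
                rows.append(
                    {
                        "variant": "x",
                        "lr": lr,
                        "stop_acc": np.nan,
                        "seed": seed,
                        "task_index": -1,
                        "phase": "final",
                        "accuracy": 0.5 + offset,
                    }
                )
        best, _ = window_aggregate(pd.DataFrame(rows), window=6)
        assert best == pytest.approx(0.6)


def test_sequence_invariants_enforced(tiny_sequence):
    with pytest.raises(ValueError):
        TaskSequence(tasks=tiny_sequence.tasks, paradigm="weird", n_outputs=2)
    # class-IL with overlapping label sets must be rejected
    with pytest.raises(ValueError):
        TaskSequence(tasks=tiny_sequence.tasks, paradigm="class", n_outputs=2)
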