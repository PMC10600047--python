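# dfc-cl — task-free continual learning with sparse-recurrent Deep Feedback Control

Artificial networks trained sequentially on a series of tasks
catastrophically forget earlier ones, and nearly every remedy assumes the
learner is told when one task ends and the next begins — an assumption
brains cannot rely on.  `dfc-cl` implements a *task-free* alternative
built from three biologically motivated ingredients:

1. **Deep Feedback Control (DFC)** — during learning, a
   proportional-integral controller injects the output error into every
   layer through per-sample feedback weights, and the leaky-integrator
   dynamics

       τ_v v̇_i = −v_i + W_i φ(v_{i−1}) + Q_i u(t)

   settle into a stable state whose activations r_{i,ss} ("targets")
   drive a local learning rule
   ΔW_i = η (r_{i,ss} − φ(v_i_ff,ss)) r_{i−1,ss}ᵀ — no backpropagated
   gradients, no task labels, no loss switching.
2. **Dynamic winner-take-all sparsity** — a ramped fraction s_i(t) of each
   hidden layer is silenced, ranked by a mix of feedforward and feedback
   drive, so different inputs (and different labels) claim different
   neuron populations and learning is restricted to the active ones.
3. **Hebbian lateral gating** — multiplicative within-layer connections
   σ(R_i |r_i|) ∈ (0,1), renormalised to preserve total activity, learn an
   anti-Hebbian rule on suppressed neurons
   (ΔR_i = −η |φ(v_ff,ss)| |r_ss|ᵀ) and stabilise which neurons fire
   together.  At test time the network is a plain feedforward MLP.

The package provides the four ablation variants (`dfc`, `dfc_sparse`,
`dfc_rec`, `dfc_sparse_rec`) plus a backpropagation baseline (`bp`), a
continual-learning harness with two evaluation regimes (fixed-epoch
learning-rate sweeps and fixed-LR early-stop sweeps, with
window-of-six-LRs aggregation), representation-geometry analysis
(class-pair separation, normalized inter-label separation, hyperplane
alignment/movement, effective dimensionality, unaltered dimensionality
fraction γ), a synthetic split-task generator with controllable cross-task
feature overlap, and an IDX reader for real MNIST-style data
(split-MNIST).  It is aimed at researchers studying biologically plausible
learning rules and catastrophic forgetting.

## Worked example

Train the sparse-recurrent learner on a five-task synthetic sequence
(Gaussian class pairs on partially shared informative dimensions — the
structure that makes split-MNIST a forgetting benchmark) and compare it
with backpropagation:

```python
import numpy as np
from dfc_cl import (SyntheticSpec, generate_sequence, make_learner,
                    ProtocolConfig, train_on_task, evaluate_all)

seq = generate_sequence(SyntheticSpec(seed=0))        # 5 tasks, domain-IL
proto = ProtocolConfig(n_epochs=4, hidden_sizes=(32, 32))

for variant in ("bp", "dfc_sparse_rec"):
    learner = make_learner(variant, [64, 32, 32, 2], lr=0.1, seed=0)
    rng = np.random.default_rng(10_000)
    for task in seq.tasks:                             # no task IDs passed
        train_on_task(learner, task, proto, rng)
    overall, per_task = evaluate_all(learner, seq)
    print(f"{variant:16s} all-task accuracy {overall:.3f}  "
          f"per task {[round(a, 2) for a in per_task]}")
```

```
bp               all-task accuracy 0.661  per task [0.44, 0.45, 0.53, 0.94, 0.96]
dfc_sparse_rec   all-task accuracy 0.696  per task [0.5, 0.37, 0.71, 0.94, 0.95]
```

The per-task profile is the signature of catastrophic forgetting: both
networks score well on the last tasks they saw and poorly on the first.
Seed-averaged over ten runs the gap is systematic (bp 0.676 ± 0.013 vs
sparse-recurrent DFC 0.723 ± 0.041 under these conditions, with the
sparse-only ablation at 0.684 in between), and the sparse-recurrent
variant also keeps its accuracy at learning rates where backpropagation
collapses.  The same
learners in the class-incremental setting, analysed with
`dfc_cl.analysis`, show why: sparsity drives class representations apart
(higher pairwise separation), and lateral gating compresses each task's
targets into a low-dimensional subspace that later tasks leave largely
untouched (lower effective dimensionality, higher γ).

A thin CLI mirrors this workflow (`dfc-cl generate`, `dfc-cl train`,
`dfc-cl sweep --regime lr|early-stop`, `dfc-cl analyze`); see
`dfc-cl --help`.

## Layout

- `dfc_cl.network` — controlled dynamics, PI controller, per-sample
  feedback weights, stable states
- `dfc_cl.sparsity` — WTA schedule/selection and lateral gating
- `dfc_cl.plasticity` — masked, zero-mean-centred forward/lateral updates
- `dfc_cl.learners` — DFC variants and the BP baseline
- `dfc_cl.harness` — task sequences, protocols, sweeps, activation capture
- `dfc_cl.analysis` — representation-geometry metrics
- `dfc_cl.datasets` — synthetic generator, IDX reader, class-pair splitting
- `dfc_cl.experiments` — canned desk-scale studies
- `docs/methods.md` — model details, defaults and their rationale, known
  limitations
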