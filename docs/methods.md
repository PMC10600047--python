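# Methods

This note documents the model implemented by `dfc_cl`, the choices made
where the underlying learning framework leaves details open, and what the
synthetic benchmark does and does not show.

## The learning model

### Controlled dynamics

During learning, every non-input layer of the network is a leaky
integrator driven by feedforward input and by a top-down control signal:

    tau_v dv_i/dt = -v_i + v_i_ff + Q_i u(t),      r_i = phi(v_i)

with `v_i_ff = W_i phi(v_{i-1})` (lateral gating modifies this, below) and
`phi = tanh` by default.  The controller output `u(t)` is a
proportional-integral (PI) signal computed from the output error
`e(t) = r_L* - r_L(t)` on post-nonlinearity outputs:

    u_int <- u_int + dt (e - alpha_leak * u_int)
    u = k_p e + k_i u_int

The desired output `r_L*` is the one-hot label, optionally softened toward
the feedforward output by the `target_nudge` parameter (default 1 = pure
label).  The feedback weights `Q_i` are not learned: they are
re-initialised for every sample as the transposed Jacobian of the network
output with respect to layer `i`'s pre-activations, evaluated along the
pure feedforward pass.  Controlling the output directly (rather than a
scalar loss) pairs naturally with a vector-valued PI controller; the
output layer's own feedback is its local derivative `diag(phi'(v_L))`, so
the output is itself controllable.  Feedback reaches hidden and output
layers only, never the clamped input.

The dynamics are integrated with explicit Euler, `dt/tau_v = 0.2`,
`n_steps = 150`.  Saturating nonlinearities under integral control
approach their stable state with a long slow tail (`|dv/dt|` decays
roughly like 1/t once the output saturates), so the default protocol runs
a fixed schedule and takes the final step as the stable state, as is usual
for this family of models.  An optional `convergence_tol` enables early
exit and a per-simulation `converged` flag.  The controller constants
(`k_p = 0.5`, `k_i = 1.0`, `alpha_leak = 1e-3`) are not dictated by the
learning rules; they were chosen for stable tracking on linear toy plants
(the test suite verifies second-order ODE tracking analytically) and are
all exposed in `DynamicsConfig`.  Activations exceeding 1e6 raise a
divergence error rather than propagating overflow.

### Winner-take-all sparsity

At each step a fraction `s_i(t)` of each hidden layer is silenced.  The
fraction ramps linearly from 0 to the stable-state level `s_ss[i]` over
`ramp_steps` (default half the schedule), so the controller first sees the
dense network.  Neurons are ranked by the mixed score
`(1-beta_fb)|v_ff| + beta_fb|v_fb|` and the `floor(s*n)` lowest are
masked; the mix (default 0.5) selects the population only — the activity
that flows through the network is the ordinary combined drive.  The mask
is re-evaluated every step; the final mask defines the suppressed
population for learning.  Default stable-state levels are 0.4 for the
first hidden layer and 0.8 for deeper ones: early layers encode generic
features shared across classes, late layers class-specific ones, so
shallow layers tolerate less sparsity.  The output layer is never
sparsified unless explicitly requested.

### Lateral recurrent gating

With recurrence enabled, the feedforward drive of hidden layer `i` is
gated multiplicatively:

    v_i_ff = (W_i phi(v_{i-1})) ⊙ sigmoid(R_i |r_i|)

then rescaled by a scalar so its L2 norm equals that of the ungated drive
— gating redistributes activity without changing its total level.  ("Total
level" is ambiguous between L1 and L2; L2 is the default and the norm
order is a parameter.)  `R` is initialised to zero, which makes every gate
0.5 and the renormalised gating an exact identity, so an untrained
recurrent network behaves as a plain MLP.  Gating uses `|r_i|` because the
gate modulates magnitude, not sign.

### Plasticity

Forward weights learn from the stable state:

    dW_i = eta (r_i_ss - phi(v_i_ff_ss)) r_{i-1,ss}^T

restricted to rows of neurons left active by the WTA mask.  Lateral
weights learn the anti-Hebbian rule

    dR_i = -eta |phi(v_i_ff_ss)| |r_i_ss|^T

restricted to rows of *suppressed* neurons, with a zero diagonal.  The
recurrent-only ablation, which has no suppressed population, instead
applies the full-rule form `dR_i = eta (|r_ss| - |phi(v_ff_ss)|)|r_ss|^T`
to all neurons.  Both deltas are shifted to zero mean before application
so that no neuron becomes systematically more excitable and monopolises
the WTA competition.  Centring runs over the entries actually eligible for
update (active rows for `dW`; suppressed rows' off-diagonal entries for
`dR`): centring over frozen rows would silently update protected weights.
Centring is enabled for the sparse/recurrent variants and off for standard
DFC, where no WTA competition exists to bias.  There are no bias terms,
and no optimizer state: updates are plain online additions.  Inference is
a pure feedforward pass — no controller, no gating, no masks — so the
deployed model is an ordinary MLP.

Stable-state computation is vectorised over a minibatch (default 32
samples) with per-sample feedback weights and per-sample masks; the
applied delta is the batch average of the per-sample masked, centred
deltas.  Batch size 1 recovers the strictly online rule, and the unit
tests exercise that path.

## Evaluation protocols

Two regimes, both sweeping the learning/forgetting trade-off:

* **fixed epochs** — 4 epochs per task, accuracy measured across a
  log-spaced learning-rate grid (default 1e-2.5 … 1, quarter-decade
  steps).  Grid summaries use the best contiguous window of six LRs,
  averaged over seeds.
* **early stop** — fixed LR, training on each task stops once a training
  batch reaches a minimum accuracy (cap 10 epochs), swept over that
  threshold.

Setting the threshold above 1 makes the early-stop regime reproduce the
fixed-epoch regime exactly, which the tests assert.  Learners never
receive a task index, boundary flag, or reset; a spy test enforces this at
the API level.  The backpropagation baseline shares the architecture and
nonlinearity and minimises MSE to the same one-hot targets with minibatch
SGD.

## Synthetic benchmark

The generator emulates the structure that makes split-image benchmarks
interesting for continual learning: each task is a pair of Gaussian
clusters supported on a small set of informative input dimensions, half of
which (by default) are shared across tasks.  Defaults: 5 tasks, 64 input
dimensions, 16 informative dimensions per task, class-mean distance 1.0,
within-class spread 0.25 (ratio 4: a linear readout exceeds 95% per task,
comparable to an easy digit pair), 500 train / 100 test samples per class,
values clipped to [0, 1] to mirror pixel range.  Domain-incremental
labelling assigns shared labels (the parity analogue); class-incremental
labelling gives every class its own output unit.

What this emulates: cross-task interference through shared informative
features, per-task linear separability, pixel-like input statistics.  What
it does not: multi-scale correlated features, within-class manifold
structure, class imbalance, or anything requiring depth to extract.
Passing orderings on this benchmark show that the mechanisms interact as
designed (sparsity separates representations; gating stabilises them); it
does not certify performance on natural images.

## Desk-scale study conditions

The packaged studies (`dfc_cl.experiments`, also used by
`scripts/acceptance.py`) run the five-task sequence with hidden sizes
32-32, batch size 32, 4 epochs per task, at LR 0.1 — mid-range on the
default grid, inside the regime where sequential training causes
measurable forgetting for backpropagation.  The domain-IL accuracy study
uses ten seeds: the sparse-only variant's final accuracy is by far the
noisiest (seed-to-seed sd ≈ 0.06, several times BP's), so comparing
seed-averaged means needs more replicates there.  The representation
study uses five seeds; its orderings are separated by wide margins.  At
these sizes the full pair of studies completes in under ten minutes on
one CPU core.
Reported quantities: final all-task domain-IL accuracy per variant;
class-IL mean pairwise separation of stable-state targets (recorded right
after each task is learned), effective dimensionality of per-task target
matrices, and the unaltered dimensionality fraction.

## Representation metrics

* **Separation** `1 - cos(a_1, a_2)` on summed absolute activation
  profiles `a_d = sum_j |r_j^d|`; in [0, 1] because profiles are
  nonnegative.  Zero profiles raise rather than return a value.
* **Normalized inter-label separation** — mean separation over
  different-label class pairs minus same-label pairs, each pair counted
  once.
* **Effective dimensionality** — exponential of the Shannon entropy of
  normalised singular values of the *centred* activation matrix (the
  dimensionality of variation, not of the mean offset); singular values
  below 1e-12 of the largest are treated as zero; an empty spectrum
  returns 1 by convention.  A participation-ratio variant is available.
* **Hyperplane alignment** — fraction of a new task's initial stable-state
  targets classified correctly by the previous task's readout snapshot.
* **Hyperplane movement** — decreases in signed distance to the stored
  readout boundary (on each sample's label side), summed and normalised by
  total displacement between checkpoints; 0 when nothing moves.
* **Unaltered dimensionality fraction (gamma)** — previous tasks' pooled
  targets and the new task's targets are each reduced to their leading
  `ceil(ED)` principal components; the shared dimensionality is the
  squared Frobenius norm of the basis inner-product matrix, and
  `gamma = (ED_prev - shared)/ED_prev`, clipped to [0, 1].  The hyperplane
  and gamma formulations are this package's own operationalisations of
  their verbal definitions; their limiting cases (nested, partial,
  orthogonal subspaces; pure toward/orthogonal movement) are pinned by
  tests.

## Known limitations

* Feedback weights are per-sample Jacobians, not learned; spiking or
  hardware-level dynamics are out of scope.
* The Euler integrator is first-order; very stiff gain settings require a
  smaller `dt` (the divergence guard reports, rather than hides, unstable
  settings).
* WTA ties are broken deterministically by index; in the continuous
  dynamics exact ties have measure zero, but hand-crafted equal inputs
  will suppress lower indices first.
* Stochastic ordering results are claims about seed-averaged means under
  the stated conditions, not about every individual seed.
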