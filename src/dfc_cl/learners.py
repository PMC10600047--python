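"""Online learners: DFC variants and a backpropagation baseline.

All learners share the same minimal, task-free surface:

* ``partial_fit(X, y)`` — one update from a minibatch of labelled samples;
* ``predict(X)`` — test-time inference by a pure feedforward pass.

No method takes a task identifier, boundary flag, or reset hook; continual
learning happens simply by feeding batches from successive tasks into
``partial_fit``.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

from .network import (
    DivergenceError,
    DynamicsConfig,
    NetworkParams,
    StableState,
    feedforward_pass,
    get_activation,
    init_params,
)
from .plasticity import (
    UpdateBatch,
    apply_updates,
    forward_update,
    recurrent_update,
    recurrent_update_full,
)
from .sparsity import SparsityConfig
from . import network as _net

__all__ = ["DFCLearner", "BPLearner", "VARIANTS", "make_learner"]

#: canonical ablation names -> (sparse, recurrent) flags
VARIANTS: Dict[str, tuple] = {
    "dfc": (False, False),
    "dfc_sparse": (True, False),
    "dfc_rec": (False, True),
    "dfc_sparse_rec": (True, True),
}


def _default_sparsity(n_hidden: int) -> SparsityConfig:
    # low sparsity early (generic features), high sparsity late (class-
    # specific features)
    levels = [0.4] + [0.8] * (n_hidden - 1) if n_hidden > 1 else [0.8]
    return SparsityConfig(s_ss=levels)


class DFCLearner:
    """Deep-feedback-control learner with optional WTA sparsity and gating.

    Each ``partial_fit`` call simulates the controlled dynamics to a stable
    state for every sample (vectorised over the batch, with per-sample
    feedback weights and per-sample suppression masks), derives the local
    forward/lateral weight deltas from that state, and applies their batch
    average.

    Parameters
    ----------
    layer_sizes : ``[n_in, hidden..., n_out]``.
    lr : learning rate ``eta`` of the local updates.
    sparse, recurrent : which ablation to run (see ``VARIANTS``).
    dynamics : integration/controller constants; defaults are sane for
        tanh networks of a few hundred units.
    sparsity : WTA schedule; defaults to low first-layer / high deeper-layer
        levels when ``sparse`` is on.
    center_updates : zero-mean-centre the deltas; defaults to on whenever
        the sparsity or gating machinery is active.
    """

    def __init__(
        self,
        layer_sizes: Sequence[int],
        lr: float = 1e-3,
        seed: int = 0,
        sparse: bool = False,
        recurrent: bool = False,
        dynamics: Optional[DynamicsConfig] = None,
        sparsity: Optional[SparsityConfig] = None,
        center_updates: Optional[bool] = None,
        weight_scale: float = 1.0,
    ) -> None:
        self.lr = float(lr)
        self.sparse = bool(sparse)
        self.recurrent = bool(recurrent)
        self.dynamics = dynamics or DynamicsConfig()
        n_hidden = len(layer_sizes) - 2
        if self.sparse:
            self.sparsity = sparsity or _default_sparsity(n_hidden)
            if len(self.sparsity.s_ss) != n_hidden:
                raise ValueError("need one sparsity level per hidden layer")
        else:
            self.sparsity = None
        if center_updates is None:
            center_updates = self.sparse or self.recurrent
        self.center_updates = bool(center_updates)
        self.rng = np.random.default_rng(seed)
        self.params = init_params(layer_sizes, self.rng, weight_scale)
        self.n_outputs = layer_sizes[-1]
        self.n_updates = 0
        self.n_diverged = 0

    # -- inference ---------------------------------------------------------

    def forward(self, X: np.ndarray) -> List[np.ndarray]:
        return feedforward_pass(self.params, X, self.dynamics.activation)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[-1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(self.decision_function(X))
        return np.argmax(scores, axis=1)

    # -- learning ----------------------------------------------------------

    def _targets(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        onehot = np.zeros((len(y), self.n_outputs))
        onehot[np.arange(len(y)), y] = 1.0
        lam = self.dynamics.target_nudge
        if lam >= 1.0:
            return onehot
        r_ff = np.atleast_2d(self.forward(X)[-1])
        return (1.0 - lam) * r_ff + lam * onehot

    def compute_stable_state(self, X: np.ndarray, y: np.ndarray) -> StableState:
        """Run the controlled dynamics without touching the weights."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_1d(np.asarray(y))
        return _net.simulate_to_stable_state(
            self.params,
            X,
            self._targets(X, y),
            self.dynamics,
            sparsity_cfg=self.sparsity,
            use_recurrence=self.recurrent,
        )

    def _updates(self, ss: StableState) -> UpdateBatch:
        dW = forward_update(ss, self.lr)
        if self.recurrent:
            if self.sparse:
                dR = recurrent_update(ss, self.lr)
            else:
                dR = recurrent_update_full(ss, self.lr)
        else:
            dR = [np.zeros_like(r) for r in self.params.R]
        if not self.center_updates:
            # undo the zero-mean shift: recompute the raw masked deltas
            dW = _uncentred_forward(ss, self.lr)
            if self.recurrent and not self.sparse:
                dR = _uncentred_recurrent_full(ss, self.lr)
        masks = [np.atleast_2d(m) for m in ss.mask_ss]
        return UpdateBatch(dW=dW, dR=dR, eta=self.lr, masks=masks)

    def partial_fit(self, X: np.ndarray, y: np.ndarray) -> Dict:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_1d(np.asarray(y))
        try:
            ss = self.compute_stable_state(X, y)
        except DivergenceError:
            self.n_diverged += 1
            raise
        upd = self._updates(ss)
        apply_updates(self.params, upd, inplace=True)
        self.n_updates += 1
        err = np.atleast_1d(ss.output_error)
        return {
            "converged": ss.converged,
            "mean_output_error": float(err.mean()),
            "n_steps_run": ss.n_steps_run,
        }


def _uncentred_forward(ss: StableState, eta: float) -> List[np.ndarray]:
    """Masked forward deltas without the zero-mean shift (plain DFC)."""
    out = []
    L = len(ss.r_ss) - 1
    for i in range(1, L + 1):
        r_post = np.atleast_2d(ss.r_ss[i])
        r_ff = np.atleast_2d(ss.r_ff_ss[i])
        r_pre = np.atleast_2d(ss.r_ss[i - 1])
        mask = np.atleast_2d(ss.mask_ss[i - 1])
        diff = eta * (r_post - r_ff) * mask
        out.append(np.einsum("bi,bj->bij", diff, r_pre).mean(axis=0))
    return out


def _uncentred_recurrent_full(ss: StableState, eta: float) -> List[np.ndarray]:
    out = []
    L = len(ss.r_ss) - 1
    for i in range(1, L):
        r_post = np.atleast_2d(ss.r_ss[i])
        r_ff = np.atleast_2d(ss.r_ff_ss[i])
        post = eta * (np.abs(r_post) - np.abs(r_ff))
        raw = np.einsum("bi,bj->bij", post, np.abs(r_post))
        idx = np.arange(raw.shape[1])
        raw[:, idx, idx] = 0.0
        out.append(raw.mean(axis=0))
    return out


class BPLearner:
    """Plain backpropagation baseline: same architecture, MSE to one-hot.

    Minibatch SGD on ``0.5 * ||phi(v_L) - onehot||^2`` with the same tanh
    nonlinearity everywhere, no lateral weights, no controller.
    """

    def __init__(
        self,
        layer_sizes: Sequence[int],
        lr: float = 1e-3,
        seed: int = 0,
        activation: str = "tanh",
        weight_scale: float = 1.0,
    ) -> None:
        self.lr = float(lr)
        self.activation = activation
        self.rng = np.random.default_rng(seed)
        self.params = init_params(layer_sizes, self.rng, weight_scale)
        self.n_outputs = layer_sizes[-1]
        self.n_updates = 0
        self.n_diverged = 0

    def forward(self, X: np.ndarray) -> List[np.ndarray]:
        return feedforward_pass(self.params, X, self.activation)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[-1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(self.decision_function(X))
        return np.argmax(scores, axis=1)

    def partial_fit(self, X: np.ndarray, y: np.ndarray) -> Dict:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_1d(np.asarray(y))
        phi, phi_p = get_activation(self.activation)
        onehot = np.zeros((len(y), self.n_outputs))
        onehot[np.arange(len(y)), y] = 1.0

        # forward, keeping pre-activations
        rs = [X]
        vs = []
        for w in self.params.W:
            vs.append(rs[-1] @ w.T)
            rs.append(phi(vs[-1]))

        B = X.shape[0]
        delta = (rs[-1] - onehot) * phi_p(vs[-1])
        for i in range(len(self.params.W) - 1, -1, -1):
            grad = delta.T @ rs[i] / B
            if i > 0:
                delta = (delta @ self.params.W[i]) * phi_p(vs[i - 1])
            self.params.W[i] -= self.lr * grad
        self.n_updates += 1
        loss = 0.5 * float(np.mean(np.sum((rs[-1] - onehot) ** 2, axis=1)))
        return {"converged": True, "mean_output_error": loss, "n_steps_run": 0}


def make_learner(
    variant: str,
    layer_sizes: Sequence[int],
    lr: float,
    seed: int,
    dynamics: Optional[DynamicsConfig] = None,
    sparsity: Optional[SparsityConfig] = None,
    **kwargs,
):
    """Build a learner for one of ``bp | dfc | dfc_sparse | dfc_rec |
    dfc_sparse_rec``."""
    if variant == "bp":
        act = (dynamics or DynamicsConfig()).activation
        return BPLearner(layer_sizes, lr=lr, seed=seed, activation=act, **kwargs)
    try:
        sparse, recurrent = VARIANTS[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {['bp', *VARIANTS]}"
        ) from None
    return DFCLearner(
        layer_sizes,
        lr=lr,
        seed=seed,
        sparse=sparse,
        recurrent=recurrent,
        dynamics=dynamics,
        sparsity=sparsity,
        **kwargs,
    )
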