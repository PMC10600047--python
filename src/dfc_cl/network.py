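"""Controlled neuronal dynamics for Deep Feedback Control (DFC).

A DFC network is an ordinary multi-layer perceptron at test time.  During
learning, a proportional-integral (PI) output controller injects an error
signal ``u(t)`` into every layer through feedback weights ``Q_i``, and the
leaky-integrator membrane dynamics

    tau_v * dv_i/dt = -v_i + v_i_ff + Q_i u(t)

are integrated (explicit Euler) until the network settles into a stable
state whose activations ("targets") drive the local plasticity rules.

Conventions used throughout the package
---------------------------------------
* ``layer_sizes = [n_0, n_1, ..., n_L]`` — layer 0 is the (clamped) input.
* ``W[i]`` has shape ``(n_{i+1}, n_i)`` and maps layer ``i`` output to layer
  ``i+1`` pre-activations; there are ``L`` forward matrices.
* ``R[i]`` is the square lateral-gating matrix of hidden layer ``i+1``
  (zero diagonal); there are ``L-1`` of them.
* ``Q[i]`` maps the controller signal (dimension ``n_L``) into layer
  ``i+1``; it is recomputed per sample as the transposed Jacobian of the
  network output with respect to that layer's pre-activations.
* All stateful arrays carry a leading batch axis internally; the public
  functions accept single samples (1-D) or batches (2-D) and return values
  of matching rank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "NetworkParams",
    "DynamicsConfig",
    "DynamicsState",
    "StableState",
    "DivergenceError",
    "get_activation",
    "init_params",
    "feedforward_pass",
    "compute_feedback_weights",
    "controller_step",
    "simulate_to_stable_state",
    "save_params",
    "load_params",
]

# activation registry: name -> (phi, phi_prime)
_ACTIVATIONS: dict[str, Tuple[Callable, Callable]] = {
    "tanh": (np.tanh, lambda v: 1.0 - np.tanh(v) ** 2),
    "linear": (lambda v: v, lambda v: np.ones_like(v)),
    "relu": (
        lambda v: np.maximum(v, 0.0),
        # subgradient convention at 0: phi'(0) = 0
        lambda v: (v > 0.0).astype(float),
    ),
}

_CLIP = 1e6  # activation magnitude beyond which we declare divergence


class DivergenceError(RuntimeError):
    """Raised when the Euler integration blows up (NaN/overflow)."""


def get_activation(name: str) -> Tuple[Callable, Callable]:
    """Return ``(phi, phi_prime)`` for a registered nonlinearity name."""
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
        ) from None


@dataclass
class NetworkParams:
    """Forward, lateral and feedback weights of a DFC network.

    ``Q`` is optional: it is re-initialised per sample from the Jacobian of
    the output and is therefore transient state rather than a learned
    parameter.
    """

    layer_sizes: List[int]
    W: List[np.ndarray]
    R: List[np.ndarray]
    Q: Optional[List[np.ndarray]] = None

    def __post_init__(self) -> None:
        ls = self.layer_sizes
        if len(ls) < 2 or any(n <= 0 for n in ls):
            raise ValueError("layer_sizes needs >=2 positive entries")
        if len(self.W) != len(ls) - 1:
            raise ValueError("expected one forward matrix per connection")
        for i, w in enumerate(self.W):
            if w.shape != (ls[i + 1], ls[i]):
                raise ValueError(
                    f"W[{i}] has shape {w.shape}, expected {(ls[i + 1], ls[i])}"
                )
        if len(self.R) != len(ls) - 2:
            raise ValueError("expected one recurrent matrix per hidden layer")
        for i, r in enumerate(self.R):
            n = ls[i + 1]
            if r.shape != (n, n):
                raise ValueError(f"R[{i}] has shape {r.shape}, expected {(n, n)}")
            if np.any(np.diag(r) != 0.0):
                raise ValueError(f"R[{i}] must have a zero diagonal")
        for arrs in (self.W, self.R):
            for a in arrs:
                if not np.all(np.isfinite(a)):
                    raise ValueError("weights must be finite")

    @property
    def n_layers(self) -> int:
        """Number of non-input layers."""
        return len(self.W)

    @property
    def n_hidden(self) -> int:
        return len(self.R)

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            list(self.layer_sizes),
            [w.copy() for w in self.W],
            [r.copy() for r in self.R],
            None if self.Q is None else [q.copy() for q in self.Q],
        )


@dataclass
class DynamicsConfig:
    """Integration and controller constants for the stable-state dynamics.

    The membrane time constant, Euler step, number of steps and the PI
    gains are not fixed by the learning rule itself; the defaults below are
    chosen for stable convergence on small dense networks and are all
    exposed for sweeps.

    Parameters
    ----------
    tau_v : membrane time constant (dimensionless time units).
    dt : Euler step; ``dt / tau_v = 0.2`` by default.
    n_steps : total integration steps; high enough that most samples settle.
    k_p, k_i : proportional and integral controller gains.
    alpha_leak : leakage rate of the integral accumulator.
    target_nudge : ``lambda in (0, 1]``; how far the desired output is pushed
        from the feedforward output toward the one-hot label (1 = full label).
    activation : nonlinearity name (``tanh``, ``linear``, ``relu``).
    convergence_tol : optional tolerance on ``max|dv/dt|``: the integration
        exits early once the dynamics settle below it (after the sparsity
        ramp), and the stable state's ``converged`` flag reports whether the
        final step met it.  ``None`` (default) runs the fixed schedule, as
        saturating nonlinearities under integral control approach their
        stable state with a long slow tail that a tight rate tolerance
        would never certify.
    """

    tau_v: float = 1.0
    dt: float = 0.2
    n_steps: int = 150
    k_p: float = 0.5
    k_i: float = 1.0
    alpha_leak: float = 1e-3
    target_nudge: float = 1.0
    activation: str = "tanh"
    convergence_tol: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tau_v <= 0:
            raise ValueError("dt and tau_v must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (0.0 < self.target_nudge <= 1.0):
            raise ValueError("target_nudge must lie in (0, 1]")
        get_activation(self.activation)

    def to_json(self) -> str:
        return json.dumps(self.__dict__)

    @classmethod
    def from_json(cls, s: str) -> "DynamicsConfig":
        return cls(**json.loads(s))


@dataclass
class DynamicsState:
    """Instantaneous state of the controlled dynamics (one Euler step).

    All per-layer lists run over the non-input layers ``1..L``; arrays have
    shape ``(batch, n_layer)``.
    """

    v: List[np.ndarray]
    v_ff: List[np.ndarray]
    v_fb: List[np.ndarray]
    r: List[np.ndarray]
    u: np.ndarray
    u_int: np.ndarray
    mask: List[np.ndarray]
    t: int = 0


@dataclass
class StableState:
    """Final ("stable state") activations of one controlled simulation.

    ``r_ss[0]`` and ``r_ff_ss[0]`` hold the clamped input so that
    presynaptic activity for layer ``i`` is always ``r_ss[i-1]``.
    ``mask_ss[i]`` corresponds to layer ``i+1``.
    """

    r_ss: List[np.ndarray]
    r_ff_ss: List[np.ndarray]
    mask_ss: List[np.ndarray]
    output_error: np.ndarray
    converged: bool
    n_steps_run: int = 0


def init_params(
    layer_sizes: Sequence[int],
    rng: np.random.Generator,
    weight_scale: float = 1.0,
) -> NetworkParams:
    """Gaussian fan-in-scaled forward weights; lateral weights start at zero.

    Zero ``R`` makes every gate ``sigma(0) = 0.5``, which the activity
    renormalisation cancels exactly, so an untrained network behaves as a
    plain MLP.
    """
    ls = list(layer_sizes)
    W = [
        rng.standard_normal((ls[i + 1], ls[i])) * (weight_scale / np.sqrt(ls[i]))
        for i in range(len(ls) - 1)
    ]
    R = [np.zeros((n, n)) for n in ls[1:-1]]
    return NetworkParams(ls, W, R)


def _as_batch(x: np.ndarray) -> Tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    if x.ndim == 2:
        return x, False
    raise ValueError("input must be a vector or a (batch, dim) matrix")


def feedforward_pass(
    params: NetworkParams, x: np.ndarray, activation: str = "tanh"
) -> List[np.ndarray]:
    """Pure feedforward activations ``[x, r_1, ..., r_L]``.

    This is the test-time inference path: no controller feedback, no
    lateral gating, no winner-take-all suppression.
    """
    phi, _ = get_activation(activation)
    xb, single = _as_batch(x)
    if xb.shape[1] != params.layer_sizes[0]:
        raise ValueError(
            f"input dimension {xb.shape[1]} != layer_sizes[0]={params.layer_sizes[0]}"
        )
    rs = [xb]
    for w in params.W:
        rs.append(phi(rs[-1] @ w.T))
    return [r[0] if single else r for r in rs]


def _feedforward_pre(
    params: NetworkParams, xb: np.ndarray, phi: Callable
) -> List[np.ndarray]:
    """Pre-activations ``[v_1..v_L]`` of the pure feedforward pass (batched)."""
    vs = []
    r = xb
    for w in params.W:
        v = r @ w.T
        vs.append(v)
        r = phi(v)
    return vs


def compute_feedback_weights(
    params: NetworkParams, x: np.ndarray, activation: str = "tanh"
) -> List[np.ndarray]:
    """Per-sample feedback weights ``Q_i = (d r_L / d v_i)^T``.

    The Jacobian of the post-nonlinearity output with respect to each
    layer's pre-activations, evaluated along the pure feedforward pass at
    ``x`` (the controller then steers the output directly, so no explicit
    loss enters).  For the output layer this is ``diag(phi'(v_L))``.

    Returns a list of ``L`` arrays of shape ``(n_i, n_L)`` (single sample)
    or ``(batch, n_i, n_L)``.
    """
    phi, phi_p = get_activation(activation)
    xb, single = _as_batch(x)
    vs = _feedforward_pre(params, xb, phi)
    L = params.n_layers
    n_out = params.layer_sizes[-1]
    # J[i] = d r_L / d v_{i+1}, built top-down: J_L = diag(phi'(v_L)),
    # J_i = J_{i+1} W_{i+1} diag(phi'(v_i)).
    B = xb.shape[0]
    J = np.zeros((B, n_out, n_out))
    idx = np.arange(n_out)
    J[:, idx, idx] = phi_p(vs[-1])
    Qs: List[np.ndarray] = [np.swapaxes(J, 1, 2)]
    for i in range(L - 2, -1, -1):
        J = (J @ params.W[i + 1]) * phi_p(vs[i])[:, None, :]
        Qs.append(np.swapaxes(J, 1, 2))
    Qs.reverse()
    return [q[0] if single else q for q in Qs]


def controller_step(
    u_int: np.ndarray,
    r_L: np.ndarray,
    r_L_star: np.ndarray,
    cfg: DynamicsConfig,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One PI-controller update.

    ``e = r_L* - r_L``; the leaky integral accumulates ``u_int +=
    dt * (e - alpha_leak * u_int)`` and the control signal is
    ``u = k_p e + k_i u_int``.  Returns ``(u, u_int, e)``.
    """
    e = r_L_star - r_L
    u_int = u_int + cfg.dt * (e - cfg.alpha_leak * u_int)
    u = cfg.k_p * e + cfg.k_i * u_int
    return u, u_int, e


def simulate_to_stable_state(
    params: NetworkParams,
    x: np.ndarray,
    r_L_star: np.ndarray,
    cfg: DynamicsConfig,
    sparsity_cfg=None,
    use_recurrence: bool = False,
) -> StableState:
    """Integrate the controlled dynamics and return the stable state.

    At every Euler step the feedforward drive of each layer is recomputed
    from the current (controlled) activity of the layer below — gated by
    the lateral weights when ``use_recurrence`` — the PI controller updates
    ``u`` from the current output error, and the winner-take-all mask from
    ``sparsity_cfg`` (ramped over time) zeroes the lowest-scoring neurons'
    outputs.  The final step's values are taken as the stable state; with
    controller gains zero and no sparsity or recurrence this reduces to the
    plain feedforward fixed point.

    Raises
    ------
    DivergenceError
        if any activation exceeds 1e6 or becomes non-finite, naming the step.
    """
    from . import sparsity as _sp  # local import to avoid a cycle

    phi, _ = get_activation(cfg.activation)
    xb, single = _as_batch(x)
    tb, _ = _as_batch(r_L_star)
    if tb.shape[0] != xb.shape[0]:
        raise ValueError("x and r_L_star batch sizes differ")
    B = xb.shape[0]
    L = params.n_layers
    n_out = params.layer_sizes[-1]

    Q = compute_feedback_weights(params, xb, cfg.activation)
    Q = [q if q.ndim == 3 else q[None] for q in Q]

    # start on the uncontrolled feedforward trajectory
    v = _feedforward_pre(params, xb, phi)
    masks = [np.ones((B, params.layer_sizes[i + 1])) for i in range(L)]
    u_int = np.zeros((B, n_out))
    u = np.zeros((B, n_out))
    v_ff = [vi.copy() for vi in v]
    ramp_done_at = 0
    if sparsity_cfg is not None:
        ramp_done_at = sparsity_cfg.ramp_steps
    steps_run = cfg.n_steps
    vdot_max = np.inf

    def layer_masked(i: int) -> bool:
        if sparsity_cfg is None:
            return False
        if i < L - 1:
            return True
        return bool(sparsity_cfg.apply_to_output)

    masked_layers = [i for i in range(L) if layer_masked(i)]
    beta_fb = sparsity_cfg.beta_fb if sparsity_cfg is not None else 0.0
    check_tol = cfg.convergence_tol is not None
    for t in range(cfg.n_steps):
        r = [phi(v[i]) * masks[i] for i in range(L)]

        # feedforward drives from current controlled activity
        r_below = xb
        for i in range(L):
            if use_recurrence and i < L - 1:
                v_ff[i] = _sp._gated_drive(params.W[i], params.R[i], r_below, r[i])
            else:
                v_ff[i] = r_below @ params.W[i].T
            r_below = r[i]

        u, u_int, e = controller_step(u_int, r[-1], tb, cfg)
        vdot_max = 0.0
        v_fb = [np.einsum("bio,bo->bi", Q[i], u) for i in range(L)]
        last = t == cfg.n_steps - 1
        for i in range(L):
            vdot = (-v[i] + v_ff[i] + v_fb[i]) / cfg.tau_v
            v[i] = v[i] + cfg.dt * vdot
            if check_tol or last:
                vdot_max = max(vdot_max, float(np.max(np.abs(vdot))))

        # divergence is checked periodically; the message names the window
        if (t % 8 == 7 or last) and any(
            not np.all(np.abs(vi) <= _CLIP) for vi in v
        ):
            raise DivergenceError(f"dynamics diverged by step {t}")

        # re-select the suppressed population with the ramped sparsity level
        for i in masked_layers:
            s = _sp.sparsity_schedule(t + 1, sparsity_cfg, min(i, L - 2))
            k = int(np.floor(s * v_ff[i].shape[1]))
            masks[i] = _sp._select_mask(v_ff[i], v_fb[i], k, beta_fb)

        if check_tol and vdot_max < cfg.convergence_tol and t + 1 >= ramp_done_at:
            steps_run = t + 1
            break

    converged = cfg.convergence_tol is None or vdot_max < cfg.convergence_tol
    r = [phi(v[i]) * masks[i] for i in range(L)]
    r_ff = [phi(v_ff[i]) for i in range(L)]
    out_err = np.linalg.norm(tb - r[-1], axis=1)

    def unb(a: np.ndarray) -> np.ndarray:
        return a[0] if single else a

    return StableState(
        r_ss=[unb(xb)] + [unb(ri) for ri in r],
        r_ff_ss=[unb(xb)] + [unb(ri) for ri in r_ff],
        mask_ss=[unb(mi) for mi in masks],
        output_error=out_err[0] if single else out_err,
        converged=converged,
        n_steps_run=steps_run,
    )


def save_params(params: NetworkParams, cfg: DynamicsConfig, path: str | Path) -> None:
    """Write weights to ``<path>.npz`` with a JSON sidecar for the config."""
    path = Path(path)
    arrays = {f"W{i}": w for i, w in enumerate(params.W)}
    arrays.update({f"R{i}": r for i, r in enumerate(params.R)})
    if params.Q is not None:
        arrays.update({f"Q{i}": q for i, q in enumerate(params.Q)})
    np.savez(path.with_suffix(".npz"), layer_sizes=np.array(params.layer_sizes), **arrays)
    path.with_suffix(".json").write_text(cfg.to_json())


def load_params(path: str | Path) -> Tuple[NetworkParams, DynamicsConfig]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as data:
        ls = [int(n) for n in data["layer_sizes"]]
        W = [data[f"W{i}"] for i in range(len(ls) - 1)]
        R = [data[f"R{i}"] for i in range(len(ls) - 2)]
        Q = None
        if "Q0" in data:
            Q = [data[f"Q{i}"] for i in range(len(ls) - 1)]
    cfg = DynamicsConfig.from_json(path.with_suffix(".json").read_text())
    return NetworkParams(ls, W, R, Q), cfg
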