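"""Dynamic winner-take-all sparsity and lateral recurrent gating.

Two distinct but interacting mechanisms live here:

* a WTA schedule that suppresses a growing fraction ``s_i(t)`` of each
  hidden layer's neurons during the controlled dynamics, ranked by a mix
  of feedforward and feedback drive;
* multiplicative lateral gating ``sigma(R_i |r_i|)`` of the feedforward
  drive, renormalised so that gating redistributes activity across the
  layer without changing its total magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy.special import expit

from .network import NetworkParams

__all__ = ["SparsityConfig", "sparsity_schedule", "select_suppressed", "apply_gating"]


@dataclass
class SparsityConfig:
    """WTA suppression schedule and selection mix.

    Parameters
    ----------
    s_ss : stable-state sparsity level per hidden layer, each in ``[0, 1)``
        (fraction of neurons suppressed once the ramp has completed).
    ramp_steps : dynamics steps over which ``s_i(t)`` grows linearly from 0
        to ``s_ss``; suppression starts at zero so the controller first sees
        the dense network.
    beta_fb : fraction of feedback drive in the suppression ranking score
        (0 = feedforward only, 1 = feedback only, 0.5 = equal mix).
    apply_to_output : whether the output layer is also sparsified
        (off by default; the readout is never suppressed).
    """

    s_ss: List[float] = field(default_factory=lambda: [0.4, 0.8])
    ramp_steps: int = 75
    beta_fb: float = 0.5
    apply_to_output: bool = False

    def __post_init__(self) -> None:
        if any(not (0.0 <= s < 1.0) for s in self.s_ss):
            raise ValueError("each stable-state sparsity level must lie in [0, 1)")
        if not (0.0 <= self.beta_fb <= 1.0):
            raise ValueError("beta_fb must lie in [0, 1]")
        if self.ramp_steps < 1:
            raise ValueError("ramp_steps must be >= 1")


def sparsity_schedule(t: int, cfg: SparsityConfig, layer: int) -> float:
    """Ramped sparsity level ``s_i(t) = s_ss * min(1, t / ramp_steps)``.

    Zero at ``t = 0``, grows linearly, saturates at ``s_ss[layer]`` for
    ``t >= ramp_steps``.
    """
    if t < 0:
        raise ValueError("step index must be >= 0")
    return cfg.s_ss[layer] * min(1.0, t / cfg.ramp_steps)


def _select_mask(
    v_ff: np.ndarray, v_fb: np.ndarray, k: int, beta_fb: float, stable: bool = False
) -> np.ndarray:
    """Validation-free batched WTA mask (hot path of the dynamics loop).

    The public wrapper requests a stable sort for the documented tie-break;
    the dynamics loop skips it since continuous drives never tie exactly.
    """
    mask = np.ones_like(v_ff)
    if k > 0:
        score = (1.0 - beta_fb) * np.abs(v_ff) + beta_fb * np.abs(v_fb)
        order = np.argsort(score, axis=1, kind="stable" if stable else None)
        rows = np.arange(v_ff.shape[0])[:, None]
        mask[rows, order[:, :k]] = 0.0
    return mask


def select_suppressed(
    v_ff: np.ndarray, v_fb: np.ndarray, s: float, beta_fb: float
) -> np.ndarray:
    """Binary keep-mask from the mixed-drive winner-take-all rule.

    Each neuron is scored ``(1 - beta_fb)|v_ff| + beta_fb|v_fb|`` and the
    ``floor(s * n)`` lowest-scoring neurons are suppressed (mask 0).  Ties
    are broken by suppressing the lower index first (stable sort).  The mix
    is used only to *select* the suppressed population; the activity that
    flows through the network is the ordinary combined drive.

    Accepts single vectors or ``(batch, n)`` arrays.
    """
    v_ff = np.asarray(v_ff, dtype=float)
    v_fb = np.asarray(v_fb, dtype=float)
    if v_ff.shape != v_fb.shape:
        raise ValueError("v_ff and v_fb must have the same shape")
    if not (0.0 <= s < 1.0):
        raise ValueError("sparsity fraction must lie in [0, 1)")
    single = v_ff.ndim == 1
    vf = v_ff[None] if single else v_ff
    vb = v_fb[None] if single else v_fb
    k = int(np.floor(s * vf.shape[1]))
    mask = _select_mask(vf, vb, k, beta_fb, stable=True)
    return mask[0] if single else mask


def _gated_drive(
    W: np.ndarray, R: np.ndarray, r_prev: np.ndarray, r_self: np.ndarray
) -> np.ndarray:
    """Validation-free batched gated drive with L2 renormalisation."""
    raw = r_prev @ W.T
    gated = raw * expit(np.abs(r_self) @ R.T)
    n_raw = np.sqrt(np.einsum("bi,bi->b", raw, raw))
    n_gated = np.sqrt(np.einsum("bi,bi->b", gated, gated))
    scale = np.where(n_gated > 0.0, n_raw / np.where(n_gated > 0.0, n_gated, 1.0), 1.0)
    return gated * scale[:, None]


def apply_gating(
    params: NetworkParams,
    r_prev: np.ndarray,
    r_self: np.ndarray,
    layer: int,
    norm_ord: int = 2,
) -> np.ndarray:
    """Laterally gated feedforward drive with activity renormalisation.

    ``raw = W_i r_prev`` is multiplied elementwise by the gate
    ``sigma(R_i |r_self|)`` (each gate strictly in (0, 1)), then rescaled by
    a scalar so the gated vector keeps the norm of ``raw`` — gating changes
    the distribution of activity across the layer, never its total level.
    With ``R_i = 0`` the uniform 0.5 gate cancels exactly.

    ``layer`` indexes the hidden layer (0-based, matching ``params.R``).
    """
    r_prev = np.asarray(r_prev, dtype=float)
    r_self = np.asarray(r_self, dtype=float)
    single = r_prev.ndim == 1
    rp = r_prev[None] if single else r_prev
    rs = r_self[None] if single else r_self
    W = params.W[layer]
    R = params.R[layer]
    if rp.shape[1] != W.shape[1] or rs.shape[1] != W.shape[0]:
        raise ValueError("activity vectors inconsistent with layer shapes")
    if norm_ord == 2:
        out = _gated_drive(W, R, rp, rs)
        return out[0] if single else out
    raw = rp @ W.T
    gate = expit(np.abs(rs) @ R.T)
    gated = raw * gate
    norm_raw = np.linalg.norm(raw, ord=norm_ord, axis=1, keepdims=True)
    norm_gated = np.linalg.norm(gated, ord=norm_ord, axis=1, keepdims=True)
    scale = np.where(norm_gated > 0.0, norm_raw / np.where(norm_gated > 0, norm_gated, 1.0), 1.0)
    out = gated * scale
    return out[0] if single else out
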