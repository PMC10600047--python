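"""Local plasticity: masked, zero-mean-centred weight updates.

Forward weights learn from the gap between a neuron's controlled target
activation and its feedforward-driven activation at the stable state,

    dW_i = eta * (r_i_ss - phi(v_i_ff_ss)) r_{i-1,ss}^T,

restricted to neurons left *active* by the winner-take-all mask.  Lateral
gating weights learn an anti-Hebbian rule restricted to *suppressed*
neurons,

    dR_i = -eta * |phi(v_i_ff_ss)| |r_i_ss|^T,

so each weight is only ever touched through one of the two rules on a
given sample.  Both deltas are centred to zero mean over the entries that
are actually eligible for update, which keeps any one neuron from becoming
systematically more excitable and monopolising the WTA competition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .network import NetworkParams, StableState

__all__ = [
    "UpdateBatch",
    "forward_update",
    "recurrent_update",
    "recurrent_update_full",
    "apply_updates",
]


@dataclass
class UpdateBatch:
    """One sample's (or minibatch's averaged) weight deltas."""

    dW: List[np.ndarray]
    dR: List[np.ndarray]
    eta: float
    masks: List[np.ndarray]


def _batched(arr: np.ndarray) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    return a[None] if a.ndim == 1 else a


def forward_update(ss: StableState, eta: float) -> List[np.ndarray]:
    """Forward-weight deltas, masked to active rows and centred.

    Rows of suppressed neurons stay exactly zero; the remaining entries are
    shifted by their scalar mean so the applied update has zero mean.
    Batched stable states return the batch-averaged delta.
    """
    if ss.mask_ss is None:
        raise ValueError("stable state carries no suppression masks")
    L = len(ss.r_ss) - 1
    dWs: List[np.ndarray] = []
    for i in range(1, L + 1):
        r_post = _batched(ss.r_ss[i])
        r_ff = _batched(ss.r_ff_ss[i])
        r_pre = _batched(ss.r_ss[i - 1])
        mask = _batched(ss.mask_ss[i - 1])
        diff = eta * (r_post - r_ff) * mask  # suppressed rows drop out
        raw = np.einsum("bi,bj->bij", diff, r_pre)
        # centre over entries of active rows, per sample
        n_active = mask.sum(axis=1)  # (B,)
        n_pre = r_pre.shape[1]
        total = raw.sum(axis=(1, 2))
        denom = np.maximum(n_active * n_pre, 1.0)
        mean = total / denom
        raw -= mean[:, None, None] * mask[:, :, None]
        dWs.append(raw.mean(axis=0))
    return dWs


def recurrent_update(ss: StableState, eta: float) -> List[np.ndarray]:
    """Suppressed-neuron lateral deltas (anti-Hebbian simplification).

    Only incoming lateral weights of neurons silenced by the WTA mask are
    updated; active rows and the diagonal stay exactly zero.  Centring runs
    over the suppressed rows' off-diagonal entries.
    """
    if ss.mask_ss is None:
        raise ValueError("stable state carries no suppression masks")
    L = len(ss.r_ss) - 1
    dRs: List[np.ndarray] = []
    for i in range(1, L):  # hidden layers only
        r_post = _batched(ss.r_ss[i])
        r_ff = _batched(ss.r_ff_ss[i])
        mask = _batched(ss.mask_ss[i - 1])
        sup = 1.0 - mask  # rows eligible for a lateral update
        post = -eta * np.abs(r_ff) * sup
        raw = np.einsum("bi,bj->bij", post, np.abs(r_post))
        n = raw.shape[1]
        idx = np.arange(n)
        raw[:, idx, idx] = 0.0
        n_sup = sup.sum(axis=1)
        n_entries = np.maximum(n_sup * (n - 1), 1.0)
        mean = raw.sum(axis=(1, 2)) / n_entries
        shift = mean[:, None, None] * sup[:, :, None] * np.ones((1, 1, n))
        shift[:, idx, idx] = 0.0
        raw -= shift
        dRs.append(raw.mean(axis=0))
    return dRs


def recurrent_update_full(ss: StableState, eta: float) -> List[np.ndarray]:
    """Lateral deltas applied to *all* neurons (no-sparsity ablation).

    ``dR_i = eta (|r_ss| - |phi(v_ff_ss)|) |r_ss|^T`` with zero diagonal,
    centred over all off-diagonal entries.  Used by the recurrent-only DFC
    variant, which has no suppressed population to restrict the rule to.
    """
    L = len(ss.r_ss) - 1
    dRs: List[np.ndarray] = []
    for i in range(1, L):
        r_post = _batched(ss.r_ss[i])
        r_ff = _batched(ss.r_ff_ss[i])
        post = eta * (np.abs(r_post) - np.abs(r_ff))
        raw = np.einsum("bi,bj->bij", post, np.abs(r_post))
        n = raw.shape[1]
        idx = np.arange(n)
        raw[:, idx, idx] = 0.0
        mean = raw.sum(axis=(1, 2)) / (n * (n - 1))
        shift = np.ones_like(raw) * mean[:, None, None]
        shift[:, idx, idx] = 0.0
        raw -= shift
        dRs.append(raw.mean(axis=0))
    return dRs


def apply_updates(
    params: NetworkParams, upd: UpdateBatch, inplace: bool = False
) -> NetworkParams:
    """Add the deltas to ``W`` and ``R``; ``Q`` is transient and untouched."""
    if len(upd.dW) != len(params.W) or len(upd.dR) != len(params.R):
        raise ValueError("update lists do not match parameter lists")
    for dw, w in zip(upd.dW, params.W):
        if dw.shape != w.shape:
            raise ValueError(f"dW shape {dw.shape} != W shape {w.shape}")
    for dr, r in zip(upd.dR, params.R):
        if dr.shape != r.shape:
            raise ValueError(f"dR shape {dr.shape} != R shape {r.shape}")
        if np.any(np.diag(dr) != 0.0):
            raise ValueError("dR must have a zero diagonal")
    out = params if inplace else params.copy()
    for w, dw in zip(out.W, upd.dW):
        w += dw
    for r, dr in zip(out.R, upd.dR):
        r += dr
    return out
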