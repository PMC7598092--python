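"""Hebbian plasticity with synaptic normalization.

Inter-region (external) rule, for an existing connection from source region
``j`` to target region ``i`` (row = target, matching the coupling term
``sum_j W_ij E_j(t - del_ij)``):

    dW_ij = c * E_j(t - del_ij) * (E_i(t) - E_i(t - step))

i.e. presynaptic activity as it arrives (delayed by conduction) times the
change of postsynaptic activity over the last solver step.  Updated weights
are clipped at zero (excitatory connections cannot become negative) and each
region's *incoming* weights are then rescaled to sum to one — the synaptic
scaling that keeps total afferent drive constant.  Connections whose weight
is zero are never updated, so the sparsity pattern can only shrink (and in
practice is preserved).

The same rule acts on the seven internal weights of each region,

    dw_k = c * Pre(t) * (Post(t) - Post(t - step)),

with the pre/post populations given by the wiring (E->E, Is-|E, Id-|E,
E->Is, E->Id, Is-|Id, Id-|Id); after an update the plastic internal weights
of a node are jointly rescaled so their sum equals its pre-update value
(conserving total internal weight).

Updates fire every ``update_every`` solver steps (default 10).  A learning
rate of zero makes the whole cycle a strict no-op, so ``c = 0`` runs are
bitwise identical to plasticity-off runs.

Oja's rule is available as a non-validated alternative plugin
(``rule="oja"``): dW = c * post * (pre - post * W).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .model import INTERNAL_PRE_POST

__all__ = [
    "PlasticityConfig",
    "hebbian_update_external",
    "hebbian_delta_external",
    "normalize_weights",
    "hebbian_update_internal",
    "update_internal_weights",
    "apply_plasticity_cycle",
]

ALL_INTERNAL = (1, 2, 3, 4, 5, 6, 7)


@dataclass
class PlasticityConfig:
    """Learning-rule settings.

    c
        learning rate (dimensionless, >= 0; 0 disables all updates).
    update_every
        solver steps between weight updates (default 10).
    external_on / internal_on
        toggles for inter-region and intra-region plasticity.
    plastic_internal_set
        which of w1..w7 are subject to updating (1-based indices).
    rule
        ``"hebbian"`` (validated) or ``"oja"`` (plugin, external only).
    """

    c: float = 0.01
    update_every: int = 10
    external_on: bool = True
    internal_on: bool = True
    plastic_internal_set: Sequence[int] = ALL_INTERNAL
    rule: str = "hebbian"

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("learning rate c must be non-negative")
        if self.update_every < 1:
            raise ValueError("update_every must be >= 1")
        if self.rule not in ("hebbian", "oja"):
            raise ValueError(f"unknown plasticity rule {self.rule!r}")
        bad = [k for k in self.plastic_internal_set if k not in ALL_INTERNAL]
        if bad:
            raise ValueError(f"plastic_internal_set entries must be in 1..7, got {bad}")

    @property
    def is_active(self) -> bool:
        return self.c > 0 and (self.external_on or self.internal_on)


def normalize_weights(W: np.ndarray) -> np.ndarray:
    """Rescale each region's incoming external weights to sum to one.

    Rows (targets) with all-zero incoming weights are left untouched;
    negative entries are rejected (clipping happens upstream).
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("weights must be non-negative before normalization")
    sums = W.sum(axis=1)
    out = W.copy()
    nz = sums > 0
    out[nz] = W[nz] / sums[nz, None]
    return out


def hebbian_delta_external(
    W: np.ndarray,
    E_delayed: np.ndarray,
    E_now: np.ndarray,
    E_prev: np.ndarray,
    c: float,
) -> np.ndarray:
    """Clipped Hebbian update of the external weights, *without*
    normalization.

    ``E_delayed[i, j]`` is the source activity ``E_j(t - del_ij)``; only
    entries with ``W_ij > 0`` are touched.
    """
    delta = c * E_delayed * (E_now - E_prev)[:, None]
    return np.where(W > 0, np.maximum(0.0, W + delta), W)


def _oja_delta_external(W, E_delayed, E_now, c):
    post = E_now[:, None]
    return np.where(W > 0, np.maximum(0.0, W + c * post * (E_delayed - post * W)), W)


def hebbian_update_external(
    W: np.ndarray,
    buffer,
    D: np.ndarray,
    c: float,
    step: float,
    t_now: Optional[float] = None,
    rule: str = "hebbian",
) -> np.ndarray:
    """One external plasticity update read from the history buffer.

    Presynaptic activities are interpolated at ``t_now - D_ij`` for every
    existing connection; postsynaptic change is ``E(t_now) - E(t_now -
    step)``.  Returns the updated, normalized weight matrix.
    """
    if c == 0:
        return W
    n = W.shape[0]
    t = buffer.newest_time if t_now is None else t_now
    rows, cols = np.nonzero(W)
    E_delayed = np.zeros_like(W)
    if rows.size:
        E_delayed[rows, cols] = buffer.interpolate_components(
            t - D[rows, cols], cols
        )
    idx = np.arange(n)
    E_now = buffer.interpolate_components(np.full(n, t), idx)
    E_prev = buffer.interpolate_components(np.full(n, t - step), idx)
    if rule == "oja":
        W_new = _oja_delta_external(W, E_delayed, E_now, c)
    else:
        W_new = hebbian_delta_external(W, E_delayed, E_now, E_prev, c)
    return normalize_weights(W_new)


def hebbian_update_internal(
    w_k: float,
    pre_now: float,
    post_now: float,
    post_prev: float,
    c: float,
) -> float:
    """Scalar internal-weight update (before joint renormalization):
    ``max(0, w_k + c * pre_now * (post_now - post_prev))``."""
    for v in (w_k, pre_now, post_now, post_prev):
        if not np.isfinite(v):
            raise ValueError("activities and weights must be finite")
    return max(0.0, w_k + c * pre_now * (post_now - post_prev))


def update_internal_weights(
    w: np.ndarray,
    act_now: np.ndarray,
    act_prev: np.ndarray,
    c: float,
    plastic_set: Sequence[int] = ALL_INTERNAL,
) -> np.ndarray:
    """Vectorised internal update over all regions.

    ``w`` is (n, 7); ``act_now``/``act_prev`` are (3, n) arrays of
    (E, Is, Id) activities at t and t-step.  The plastic subset of each
    node's weights is renormalized to conserve its pre-update sum.
    """
    if c == 0:
        return w
    w_new = np.array(w, dtype=float, copy=True)
    ks = [k - 1 for k in plastic_set]
    pre_sums = w_new[:, ks].sum(axis=1)
    for k in ks:
        pre_pop, post_pop = INTERNAL_PRE_POST[k]
        delta = c * act_now[pre_pop] * (act_now[post_pop] - act_prev[post_pop])
        w_new[:, k] = np.maximum(0.0, w_new[:, k] + delta)
    post_sums = w_new[:, ks].sum(axis=1)
    scale = np.where(post_sums > 0, pre_sums / np.where(post_sums > 0, post_sums, 1.0), 1.0)
    w_new[:, ks] *= scale[:, None]
    return w_new


def apply_plasticity_cycle(
    buffer,
    t_now: float,
    E_now: np.ndarray,
    W: np.ndarray,
    w_internal: np.ndarray,
    config: PlasticityConfig,
    D: np.ndarray,
    step: float,
    counters=None,
) -> Tuple[np.ndarray, np.ndarray]:
    """One full plasticity cycle: external update + normalization, then
    internal update + renormalization.  With ``c = 0`` both weights are
    returned unchanged (strict no-op)."""
    if not config.is_active:
        return W, w_internal
    n = W.shape[0]
    if config.external_on:
        W = hebbian_update_external(W, buffer, D, config.c, step, t_now=t_now,
                                    rule=config.rule)
        if counters is not None:
            counters.external_updates += 1
    if config.internal_on:
        y_now = buffer.interpolate(t_now)
        y_prev = buffer.interpolate(t_now - step)
        act_now = y_now.reshape(3, n)
        act_prev = y_prev.reshape(3, n)
        w_internal = update_internal_weights(
            w_internal, act_now, act_prev, config.c, config.plastic_internal_set
        )
        if counters is not None:
            counters.internal_updates += 1
    return W, w_internal
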