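"""Node dynamics of the three-population neural mass model.

Each brain region is a modified Wilson-Cowan oscillator with one excitatory
population ``E`` and two inhibitory populations: a *subtractive* one ``Is``
(shifts the input-output function to higher inputs, i.e. raises the effective
threshold) and a *divisive* one ``Id`` (lowers the slope and the maximum of
the input-output function, i.e. gain control).

The population input-output function is a three-argument logistic,

    F_j(x, theta, a) = logistic(a_j/(1+a) * (x - (theta_j + theta)))
                       - logistic(-a_j*theta_j/(1+a)),

where ``x`` is the driving input, ``theta`` the subtractive modulation and
``a`` the divisive modulation; the subtraction of the second term makes
``F_j(0, 0, a) = 0`` so the origin is a fixed point in the absence of drive.
The saturation level ``k_j = lim_{x->inf} F_j`` captures the refractory
fraction of each population.

Region ``i`` obeys the delay differential equations

    tau_e dE_i/dt  = -E_i  + (k_e - E_i)  * F_e(w1*E_i + sum_j W_ij*E_j(t - del_ij) + P_e,
                                                w2*Is_i, w3*Id_i)
    tau_i dIs_i/dt = -Is_i + (k_i - Is_i) * F_i(w4*E_i + P_s, 0, 0)
    tau_i dId_i/dt = -Id_i + (k_i - Id_i) * F_i(w5*E_i + P_d, w6*Is_i + w7*Id_i, 0)

with inter-region weights ``W`` and axonal conduction delays ``del`` supplied
by the connectome, and internal weights w1..w7 wiring the three populations
within a region (E->E, Is-|E, Id-|E, E->Is, E->Id, Is-|Id, Id-|Id).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple, Union

import numpy as np
from scipy.special import expit

__all__ = [
    "PopulationParams",
    "NetworkState",
    "sigmoid_F",
    "refractory_k",
    "coupling_drive",
    "coupling_drive_all",
    "rhs",
]

ArrayLike = Union[float, np.ndarray]

# order of the seven internal connections: (presynaptic, postsynaptic)
# populations coded 0=E, 1=Is, 2=Id
INTERNAL_PRE_POST: Tuple[Tuple[int, int], ...] = (
    (0, 0),  # w1: E -> E
    (1, 0),  # w2: Is -| E (subtractive)
    (2, 0),  # w3: Id -| E (divisive)
    (0, 1),  # w4: E -> Is
    (0, 2),  # w5: E -> Id
    (1, 2),  # w6: Is -| Id (subtractive)
    (2, 2),  # w7: Id -| Id (subtractive)
)


def refractory_k(a_j: float, theta_j: float, a: ArrayLike = 0.0) -> ArrayLike:
    """Saturation constant of the population input-output function.

    ``k_j = exp(a_j*theta_j/(1+a)) / (1 + exp(a_j*theta_j/(1+a)))``, the limit
    of :func:`sigmoid_F` as the drive ``x`` grows without bound.  Lies in
    (0, 1); divisive modulation ``a`` lowers it (for ``theta_j > 0``).
    """
    a = np.asarray(a, dtype=float) if np.ndim(a) else float(a)
    if np.any(np.asarray(a) < 0):
        raise ValueError("divisive modulator a must be non-negative")
    if not a_j > 0:
        raise ValueError("gain constant a_j must be positive")
    return expit(a_j * theta_j / (1.0 + a))


def sigmoid_F(
    x: ArrayLike,
    theta: ArrayLike,
    a: ArrayLike,
    a_j: float,
    theta_j: float,
) -> ArrayLike:
    """Three-argument logistic input-output function.

    Parameters
    ----------
    x : driving input.
    theta : subtractive modulation (raises the effective threshold).
    a : divisive modulation (lowers slope and maximum); must be >= 0.
    a_j, theta_j : gain and threshold constants of the population.

    Evaluated via the overflow-safe logistic, so extreme drives saturate
    cleanly instead of overflowing.
    """
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    a = np.asarray(a, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(theta)) and np.all(np.isfinite(a))):
        raise ValueError("sigmoid_F inputs must be finite")
    if np.any(a < 0):
        raise ValueError("divisive modulator a must be non-negative")
    if not a_j > 0:
        raise ValueError("gain constant a_j must be positive")
    slope = a_j / (1.0 + a)
    out = expit(slope * (x - (theta_j + theta))) - expit(-a_j * theta_j / (1.0 + a))
    return out if out.ndim else float(out)


def _sigmoid_fast(x, theta, a, a_j: float, theta_j: float):
    # validation-free form for the integrator hot loop; inputs are already
    # guaranteed finite by the rhs state check and the stepper
    slope = a_j / (1.0 + a)
    return expit(slope * (x - (theta_j + theta))) - expit(-a_j * theta_j / (1.0 + a))


@dataclass
class PopulationParams:
    """Node-level constants of the three-population model.

    Defaults are package choices that give bounded oscillatory activity in a
    single node; every field is overridable.  ``w1..w7`` may be scalars or
    per-region arrays (plasticity makes internal weights region-specific).

    The saturation constants ``k_e``/``k_i`` are computed once, at
    construction, with zero divisive modulation; set ``dynamic_k=True`` to
    recompute ``k_e`` at every evaluation from the instantaneous divisive
    input instead.
    """

    tau_e: float = 5.0      # excitatory time constant (ms)
    tau_i: float = 10.0     # inhibitory time constant (ms), both Is and Id
    a_e: float = 1.0
    a_i: float = 1.0
    theta_e: float = 4.0
    theta_i: float = 4.0
    w1: ArrayLike = 16.0
    w2: ArrayLike = 10.0
    w3: ArrayLike = 1.0
    w4: ArrayLike = 8.0
    w5: ArrayLike = 2.0
    w6: ArrayLike = 0.5
    w7: ArrayLike = 0.5
    P_e: float = 1.0
    P_s: float = 0.5
    P_d: float = 0.5
    dynamic_k: bool = False
    k_e: float = field(init=False)
    k_i: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.tau_e > 0 or not self.tau_i > 0:
            raise ValueError("time constants tau_e, tau_i must be positive")
        if not self.a_e > 0 or not self.a_i > 0:
            raise ValueError("sigmoid gains a_e, a_i must be positive")
        for name in ("w1", "w2", "w3", "w4", "w5", "w6", "w7"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"internal weight {name} must be non-negative")
        self.k_e = float(refractory_k(self.a_e, self.theta_e, 0.0))
        self.k_i = float(refractory_k(self.a_i, self.theta_i, 0.0))

    def internal_weights(self, n: int) -> np.ndarray:
        """(n, 7) array of internal weights, broadcasting scalars."""
        w = np.empty((n, 7), dtype=float)
        for k, name in enumerate(("w1", "w2", "w3", "w4", "w5", "w6", "w7")):
            w[:, k] = np.asarray(getattr(self, name), dtype=float)
        return w

    def with_internal_weights(self, w: np.ndarray) -> "PopulationParams":
        """Copy of the parameters with per-region internal weights ``w`` (n, 7)."""
        return replace(
            self,
            w1=w[:, 0], w2=w[:, 1], w3=w[:, 2], w4=w[:, 3],
            w5=w[:, 4], w6=w[:, 5], w7=w[:, 6],
        )


@dataclass
class NetworkState:
    """Activities of all regions at one instant.

    ``E``, ``Is``, ``Id`` are dimensionless firing-rate proxies, one entry
    per region.
    """

    t: float
    E: np.ndarray
    Is: np.ndarray
    Id: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.Is = np.asarray(self.Is, dtype=float)
        self.Id = np.asarray(self.Id, dtype=float)
        if not (self.E.shape == self.Is.shape == self.Id.shape):
            raise ValueError("E, Is, Id must have identical shapes")
        for name, v in (("E", self.E), ("Is", self.Is), ("Id", self.Id)):
            if not np.all(np.isfinite(v)):
                bad = int(np.flatnonzero(~np.isfinite(v))[0])
                raise ValueError(f"non-finite activity in population {name}, region {bad}")

    @property
    def n(self) -> int:
        return self.E.shape[0]

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.E, self.Is, self.Id])

    @classmethod
    def from_stacked(cls, t: float, y: np.ndarray) -> "NetworkState":
        n = y.shape[0] // 3
        return cls(t, y[:n], y[n:2 * n], y[2 * n:])


def coupling_drive(
    i: int,
    E: np.ndarray,
    delayed_E_row: np.ndarray,
    W: np.ndarray,
    params: PopulationParams,
) -> float:
    """Driving input to region ``i``'s excitatory population (scalar form).

    ``w1*E_i + sum_{j != i} W_ij * E_j(t - del_ij) + P_e``, accumulated
    left to right exactly as written.
    """
    n = E.shape[0]
    if delayed_E_row.shape[0] != n or W.shape != (n, n):
        raise ValueError("dimension mismatch between state, delayed_E and W")
    w1 = np.asarray(params.w1, dtype=float)
    acc = float(w1[i] if w1.ndim else w1) * E[i]
    row = W[i]
    for j in range(n):
        if j != i:
            acc += row[j] * delayed_E_row[j]
    return acc + params.P_e


def coupling_drive_all(
    E: np.ndarray,
    delayed_E: np.ndarray,
    W: np.ndarray,
    params: PopulationParams,
    out: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Driving input for all regions at once.

    Accumulates column by column so each region's sum is performed in the
    same order as the scalar form — the two agree bit for bit.  ``W`` must
    have a zero diagonal (self-influence enters through ``w1`` only).
    """
    n = E.shape[0]
    if delayed_E.shape != (n, n) or W.shape != (n, n):
        raise ValueError("dimension mismatch between state, delayed_E and W")
    acc = out if out is not None else np.empty(n, dtype=float)
    np.multiply(np.asarray(params.w1, dtype=float), E, out=acc)
    for j in range(n):
        acc += W[:, j] * delayed_E[:, j]
    acc += params.P_e
    return acc


def rhs(
    t: float,
    E: np.ndarray,
    Is: np.ndarray,
    Id: np.ndarray,
    delayed_E: np.ndarray,
    W: np.ndarray,
    params: PopulationParams,
    drive_out: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time derivatives (dE, dIs, dId) of all regions.

    ``delayed_E[i, j]`` holds ``E_j(t - del_ij)``; entries where ``W_ij = 0``
    are irrelevant (multiplied by zero).
    """
    for name, v in (("E", E), ("Is", Is), ("Id", Id)):
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise ValueError(
                f"non-finite activity at t={t}: population {name}, region {bad}"
            )
    p = params
    drive = coupling_drive_all(E, delayed_E, W, p, out=drive_out)
    a_div = np.asarray(p.w3, dtype=float) * Id
    F_e = _sigmoid_fast(drive, np.asarray(p.w2, dtype=float) * Is, a_div, p.a_e, p.theta_e)
    k_e = refractory_k(p.a_e, p.theta_e, a_div) if p.dynamic_k else p.k_e
    dE = (-E + (k_e - E) * F_e) / p.tau_e
    F_s = _sigmoid_fast(np.asarray(p.w4, dtype=float) * E + p.P_s, 0.0, 0.0, p.a_i, p.theta_i)
    dIs = (-Is + (p.k_i - Is) * F_s) / p.tau_i
    F_d = _sigmoid_fast(
        np.asarray(p.w5, dtype=float) * E + p.P_d,
        np.asarray(p.w6, dtype=float) * Is + np.asarray(p.w7, dtype=float) * Id,
        0.0,
        p.a_i,
        p.theta_i,
    )
    dId = (-Id + (p.k_i - Id) * F_d) / p.tau_i
    return dE, dIs, dId


def rhs_state(
    state: NetworkState,
    delayed_E: np.ndarray,
    W: np.ndarray,
    params: PopulationParams,
) -> NetworkState:
    """Convenience wrapper of :func:`rhs` on a :class:`NetworkState`."""
    dE, dIs, dId = rhs(state.t, state.E, state.Is, state.Id, delayed_E, W, params)
    return NetworkState(state.t, dE, dIs, dId)
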