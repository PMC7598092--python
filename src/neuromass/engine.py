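"""Delay differential equation engine.

A fixed-step Bogacki-Shampine (2,3) pair integrates the network equations:
four right-hand-side stages per step yield a third-order solution plus an
embedded second-order estimate whose difference serves as a local error
indicator (logged, not used for step control — the biological regime fixes
the step at 1 ms).  The fourth stage equals the next step's first (FSAL).

Delayed state is read from a circular history buffer holding the most
recent (time, state, derivative) triples; piecewise cubic Hermite
interpolation between stored nodes — the continuous extension matching the
(2,3) pair's accuracy — evaluates the solution at arbitrary past times.
Before the simulation start the history is the constant initial state.

Long runs are chunked: the stepper is driven for ``chunk_steps`` steps
(default 10), then plasticity acts on the weights and snapshots are taken
if due, and integration resumes from the endpoint.  Memory is bounded by
the buffer capacity regardless of the simulated duration; the capacity is
raised automatically to cover the longest conduction delay.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Tuple, Union

import numpy as np

from .model import NetworkState, PopulationParams, rhs
from .connectome import Connectome

__all__ = [
    "EngineConfig",
    "HistoryBuffer",
    "HistoryUnderrunError",
    "DivergenceError",
    "step_rk23",
    "integrate_dde",
    "simulate",
    "SimulationResult",
]

logger = logging.getLogger(__name__)

ERROR_WARN_THRESHOLD = 1e-3


class HistoryUnderrunError(RuntimeError):
    """A delayed lookup reached further back than the buffer retains."""


class DivergenceError(RuntimeError):
    """Activities left the physically meaningful range during integration."""


@dataclass
class EngineConfig:
    """Integration settings.

    step
        solver step in ms (default 1 — the model's temporal resolution).
    chunk_steps
        steps per solver call before control returns for plasticity and
        recording (default 10).
    t_end
        total biological time to simulate, ms.
    initial_state
        a :class:`~neuromass.model.NetworkState`, a constant fill value for
        all populations, or ``"random"`` (uniform in [0, 0.2), seeded by
        ``rng_seed``).
    """

    t_end: float = 0.0
    step: float = 1.0
    chunk_steps: int = 10
    initial_state: Union[NetworkState, float, str] = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError("step must be positive")
        if self.chunk_steps < 1:
            raise ValueError("chunk_steps must be >= 1")
        if self.t_end < 0:
            raise ValueError("t_end must be non-negative")


class HistoryBuffer:
    """Circular buffer of (time, state, derivative) triples.

    The oldest entries are overwritten once ``capacity`` is reached.  Times
    must be pushed in strictly increasing order.  Queries earlier than the
    simulation start return the constant pre-history state; queries between
    the start and the oldest retained entry raise
    :class:`HistoryUnderrunError` with the capacity that would have sufficed.
    """

    def __init__(self, capacity: int, dim: int, t_start: float, y_start: np.ndarray,
                 step_hint: Optional[float] = None):
        if capacity < 2:
            raise ValueError("capacity must be at least 2")
        self.capacity = int(capacity)
        self.dim = int(dim)
        self.t_start = float(t_start)
        self.step_hint = step_hint  # uniform node spacing, enables O(1) bracketing
        self.y_prehistory = np.array(y_start, dtype=float).copy()
        self._t = np.empty(self.capacity)
        self._y = np.empty((self.capacity, self.dim))
        self._dy = np.empty((self.capacity, self.dim))
        self._start = 0
        self.count = 0

    # -- writing ---------------------------------------------------------
    def push(self, t: float, y: np.ndarray, dy: np.ndarray) -> None:
        if self.count > 0 and t <= self.newest_time:
            raise ValueError(f"times must be strictly increasing (got {t} after {self.newest_time})")
        if self.count < self.capacity:
            idx = (self._start + self.count) % self.capacity
            self.count += 1
        else:
            idx = self._start
            self._start = (self._start + 1) % self.capacity
        self._t[idx] = t
        self._y[idx] = y
        self._dy[idx] = dy

    def replace_newest_derivative(self, dy: np.ndarray) -> None:
        """Overwrite the most recent derivative (after a weight update the
        right-limit derivative belongs to the new piecewise-constant weights)."""
        idx = (self._start + self.count - 1) % self.capacity
        self._dy[idx] = dy

    # -- inspection ------------------------------------------------------
    @property
    def oldest_time(self) -> float:
        return float(self._t[self._start])

    @property
    def newest_time(self) -> float:
        return float(self._t[(self._start + self.count - 1) % self.capacity])

    def _ordered_indices(self) -> np.ndarray:
        return (self._start + np.arange(self.count)) % self.capacity

    @property
    def times(self) -> np.ndarray:
        return self._t[self._ordered_indices()]

    # -- reading ---------------------------------------------------------
    def _check_underrun(self, tq: np.ndarray, live: np.ndarray) -> None:
        t_old = self.oldest_time
        tol = 1e-9 * max(1.0, abs(t_old))
        bad = live & (tq < t_old - tol)
        if np.any(bad):
            t_bad = float(np.min(tq[bad]))
            span = self.newest_time - t_bad
            if self.count >= 2:
                h = (self.newest_time - t_old) / (self.count - 1)
                need = math.ceil(span / h) + 2
            else:
                need = self.capacity + 1
            raise HistoryUnderrunError(
                f"history underrun: t={t_bad} predates oldest buffered time "
                f"{t_old}; a capacity of at least {need} entries is required"
            )

    def interpolate_components(self, tq: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Vectorised lookup of component ``cols[k]`` at time ``tq[k]``.

        Cubic Hermite between the bracketing stored nodes; exact at nodes.
        """
        tq = np.asarray(tq, dtype=float)
        cols = np.asarray(cols)
        out = np.empty(tq.shape)
        pre = tq <= self.t_start
        if np.any(pre):
            out[pre] = self.y_prehistory[cols[pre]]
        live = ~pre
        if not np.any(live):
            return out
        self._check_underrun(tq, live)
        order = self._ordered_indices()
        tql = tq[live]
        cl = cols[live]
        if self.step_hint is not None:
            # uniform spacing: direct bracket computation; exact node hits
            # (tq on the grid) give s = 0 just like the searchsorted path
            k = np.floor((tql - self.oldest_time) / self.step_hint).astype(np.intp)
        else:
            k = np.searchsorted(self._t[order], tql, side="right") - 1
        k = np.clip(k, 0, self.count - 2)
        i0 = order[k]
        i1 = order[k + 1]
        t0 = self._t[i0]
        hloc = self._t[i1] - t0
        s = (tql - t0) / hloc
        y0 = self._y[i0, cl]
        y1 = self._y[i1, cl]
        d0 = self._dy[i0, cl]
        d1 = self._dy[i1, cl]
        s2 = s * s
        s3 = s2 * s
        h00 = 2 * s3 - 3 * s2 + 1
        h10 = s3 - 2 * s2 + s
        h01 = -2 * s3 + 3 * s2
        h11 = s3 - s2
        out[live] = h00 * y0 + h10 * hloc * d0 + h01 * y1 + h11 * hloc * d1
        return out

    def interpolate(self, tq: float) -> np.ndarray:
        """Full state vector at time ``tq`` (scalar query)."""
        cols = np.arange(self.dim)
        return self.interpolate_components(np.full(self.dim, float(tq)), cols)

    def __call__(self, tq: float) -> np.ndarray:
        return self.interpolate(tq)


# Bogacki-Shampine (2,3) tableau
_B_HIGH = (2.0 / 9.0, 1.0 / 3.0, 4.0 / 9.0, 0.0)
_E_COEF = (-5.0 / 72.0, 1.0 / 12.0, 1.0 / 9.0, -1.0 / 8.0)  # y_high - y_low


def step_rk23(
    f: Callable[[float, np.ndarray], np.ndarray],
    t: float,
    y: np.ndarray,
    h: float,
    k1: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """One Bogacki-Shampine step from ``(t, y)``.

    Returns ``(y_new, k4, err)`` where ``k4 = f(t+h, y_new)`` is reusable as
    the next step's first stage (FSAL) and ``err`` is the max-norm of the
    difference between the third- and second-order solutions.
    """
    if k1 is None:
        k1 = f(t, y)
    k2 = f(t + 0.5 * h, y + (0.5 * h) * k1)
    k3 = f(t + 0.75 * h, y + (0.75 * h) * k2)
    y_new = y + h * (_B_HIGH[0] * k1 + _B_HIGH[1] * k2 + _B_HIGH[2] * k3)
    if not np.all(np.isfinite(y_new)):
        raise DivergenceError(f"non-finite stage value at t={t + h}")
    k4 = f(t + h, y_new)
    err_vec = h * (_E_COEF[0] * k1 + _E_COEF[1] * k2 + _E_COEF[2] * k3 + _E_COEF[3] * k4)
    return y_new, k4, float(np.max(np.abs(err_vec)))


def integrate_dde(
    f: Callable[[float, np.ndarray, HistoryBuffer], np.ndarray],
    t0: float,
    y0: np.ndarray,
    h: float,
    n_steps: int,
    max_delay: float = 0.0,
    capacity: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Integrate a generic (possibly delayed) system with the fixed-step
    (2,3) pair and a ring-buffer history.

    ``f(t, y, history)`` may call ``history(tq)`` for delayed state;
    pre-history (tq <= t0) is the constant ``y0``.  Returns the node times
    and states, including the initial condition.  Intended for small test
    problems; the network simulator uses the same stepper with a
    specialised delayed-coupling evaluator.
    """
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    cap = capacity if capacity is not None else max(10, math.ceil(max_delay / h) + 4)
    buf = HistoryBuffer(cap, y0.shape[0], t0, y0, step_hint=h)

    def fb(t: float, y: np.ndarray) -> np.ndarray:
        return np.atleast_1d(np.asarray(f(t, y, buf), dtype=float))

    y = y0.copy()
    k1 = fb(t0, y)
    buf.push(t0, y, k1)
    ts = np.empty(n_steps + 1)
    ys = np.empty((n_steps + 1, y0.shape[0]))
    ts[0], ys[0] = t0, y
    for i in range(n_steps):
        t = t0 + i * h
        y, k1, _ = step_rk23(fb, t, y, h, k1)
        t_next = t0 + (i + 1) * h
        buf.push(t_next, y, k1)
        ts[i + 1], ys[i + 1] = t_next, y
    return ts, ys


@dataclass
class SimulationResult:
    """Outcome of :func:`simulate`."""

    series: "object"            # recorder.SnapshotSeries (or None when streaming)
    final_state: NetworkState
    buffer_capacity: int
    max_error_estimate: float
    n_steps: int
    final_external_weights: Optional[np.ndarray] = None
    final_internal_weights: Optional[np.ndarray] = None
    diverged: bool = False


class _NetworkRHS:
    """Stacked-vector right-hand side with delayed-coupling evaluation.

    Holds the (fixed) sparsity pattern of ``W``; delayed excitatory
    activities are interpolated only for connected pairs and scattered into
    a reusable dense matrix (absent connections multiply by zero anyway).
    """

    def __init__(
        self,
        conn_W: np.ndarray,
        delays: np.ndarray,
        params: PopulationParams,
        buffer: HistoryBuffer,
        counters=None,
    ):
        self.params = params
        self.buffer = buffer
        self.n = conn_W.shape[0]
        self.rows, self.cols = np.nonzero(conn_W)
        self.pair_delays = delays[self.rows, self.cols]
        # Fortran order: the exact column-wise accumulation in
        # coupling_drive_all then walks contiguous memory
        self.W = np.asfortranarray(conn_W)
        self.delayed_E = np.zeros((self.n, self.n), order="F")
        self.counters = counters
        self._drive = np.empty(self.n)
        self._dy = np.empty(3 * self.n)

    def set_weights(self, W: np.ndarray) -> None:
        self.W = np.asfortranarray(W)

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        n = self.n
        E, Is, Id = y[:n], y[n:2 * n], y[2 * n:]
        if self.rows.size:
            vals = self.buffer.interpolate_components(t - self.pair_delays, self.cols)
            self.delayed_E[self.rows, self.cols] = vals
        dE, dIs, dId = rhs(t, E, Is, Id, self.delayed_E, self.W, self.params,
                           drive_out=self._drive)
        if self.counters is not None:
            self.counters.rhs_evals += 1
            self.counters.coupling_macs += self.rows.size
        out = self._dy
        out[:n], out[n:2 * n], out[2 * n:] = dE, dIs, dId
        return out.copy()


def _resolve_initial_state(config: EngineConfig, n: int) -> NetworkState:
    init = config.initial_state
    if isinstance(init, NetworkState):
        if init.n != n:
            raise ValueError(f"initial state has {init.n} regions, connectome has {n}")
        return init
    if isinstance(init, str):
        if init != "random":
            raise ValueError(f"unknown initial_state spec {init!r}")
        rng = np.random.default_rng(config.rng_seed)
        return NetworkState(0.0, rng.uniform(0, 0.2, n), rng.uniform(0, 0.2, n),
                            rng.uniform(0, 0.2, n))
    fill = float(init)
    return NetworkState(0.0, np.full(n, fill), np.full(n, fill), np.full(n, fill))


def required_capacity(max_delay: float, step: float, minimum: int = 10) -> int:
    """Buffer capacity covering the longest delay: ceil(max_delay/step) + 4,
    never below ``minimum`` (the historical 10-step ring)."""
    return max(minimum, math.ceil(max_delay / step) + 4)


def simulate(
    conn: Connectome,
    params: PopulationParams,
    config: EngineConfig,
    plasticity_config=None,
    recorder=None,
    snapshot_interval: Optional[float] = None,
    counters=None,
    divergence_limit: float = 1e6,
) -> SimulationResult:
    """Run the whole-brain network for ``config.t_end`` ms.

    The loop alternates chunks of ``chunk_steps`` solver steps with
    plasticity updates (applied at chunk boundaries whose global step index
    is a multiple of ``plasticity_config.update_every``) and snapshot
    recording at multiples of ``snapshot_interval`` (ms).  Weights are
    piecewise constant between plasticity updates.

    ``recorder`` is any object with an ``add(t, state, W, w_internal)``
    method (an in-memory :class:`~neuromass.recorder.SnapshotSeries` or a
    streaming HDF5 writer).  A snapshot at t=0 is always taken.
    """
    from .plasticity import apply_plasticity_cycle  # local import: no cycle at import time
    from .recorder import SnapshotSeries

    n = conn.n
    h = config.step
    n_steps = int(round(config.t_end / h))
    if abs(n_steps * h - config.t_end) > 1e-9 * max(1.0, config.t_end):
        raise ValueError("t_end must be an integer number of steps")

    state0 = _resolve_initial_state(config, n)
    W = conn.W.copy()
    w_int = params.internal_weights(n)
    params_run = params.with_internal_weights(w_int)

    D = conn.D.copy()
    mask = W > 0
    if np.any(mask & (D < h)):
        n_clamped = int(np.count_nonzero(mask & (D < h)))
        logger.warning(
            "%d delays shorter than one step (%g ms) clamped up to the step",
            n_clamped, h,
        )
        D = np.where(mask & (D < h), h, D)
    max_delay = float(D[mask].max()) if mask.any() else 0.0
    capacity = required_capacity(max_delay, h)

    y = state0.stacked()
    buf = HistoryBuffer(capacity, 3 * n, 0.0, y, step_hint=h)
    f = _NetworkRHS(W, D, params_run, buf, counters=counters)
    k1 = f(0.0, y)
    buf.push(0.0, y, k1)

    if recorder is None:
        recorder = SnapshotSeries()
    interval = snapshot_interval
    if interval is not None and interval <= 0:
        raise ValueError("snapshot interval must be positive")
    recorder.add(0.0, NetworkState.from_stacked(0.0, y), W, w_int)
    if counters is not None:
        counters.snapshots += 1
    next_snap = interval if interval is not None else None

    max_err = 0.0
    step_idx = 0
    plast = plasticity_config
    plast_active = plast is not None and plast.is_active
    try:
        while step_idx < n_steps:
            todo = min(config.chunk_steps, n_steps - step_idx)
            for _ in range(todo):
                t = step_idx * h
                y, k1, err = step_rk23(f, t, y, h, k1)
                max_err = max(max_err, err)
                step_idx += 1
                buf.push(step_idx * h, y, k1)
                if np.max(np.abs(y)) > divergence_limit:
                    raise DivergenceError(
                        f"activity exceeded {divergence_limit:g} at t={step_idx * h} ms"
                    )
            t_now = step_idx * h
            if plast_active and step_idx % plast.update_every == 0:
                E_now = y[:n]
                W, w_int = apply_plasticity_cycle(
                    buf, t_now, E_now, W, w_int, plast, D, h, counters=counters
                )
                f.set_weights(W)
                params_run = params.with_internal_weights(w_int)
                f.params = params_run
                # weights changed: the derivative entering the next interval
                # must use the new weights (FSAL + newest buffer slot); this
                # evaluation is plasticity work, not solver work
                f.counters = None
                k1 = f(t_now, y)
                f.counters = counters
                if counters is not None:
                    counters.weight_refresh_evals += 1
                buf.replace_newest_derivative(k1)
            if next_snap is not None and t_now >= next_snap - 0.5 * h:
                recorder.add(t_now, NetworkState.from_stacked(t_now, y), W, w_int)
                if counters is not None:
                    counters.snapshots += 1
                next_snap += interval
    except DivergenceError:
        if hasattr(recorder, "flush"):
            recorder.flush()
        raise
    if max_err > ERROR_WARN_THRESHOLD:
        logger.warning("max embedded error estimate %.3e exceeds %.0e",
                       max_err, ERROR_WARN_THRESHOLD)
    if hasattr(recorder, "flush"):
        recorder.flush()
    final = NetworkState.from_stacked(n_steps * h, y)
    series = recorder if isinstance(recorder, SnapshotSeries) else None
    return SimulationResult(
        series=series,
        final_state=final,
        buffer_capacity=capacity,
        max_error_estimate=max_err,
        n_steps=n_steps,
        final_external_weights=W,
        final_internal_weights=w_int,
    )
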