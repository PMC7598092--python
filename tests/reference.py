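"""Independent reference implementations used as test oracles.

Everything here is deliberately naive: full (unbounded) history kept in
Python lists, linear bracket search, scalar double loops for coupling and
plasticity.  The production engine must reproduce these results; the
oracles never import the engine's buffer, stepper, or plasticity kernels.
"""

from __future__ import annotations

import numpy as np

from neuromass.model import rhs


def hermite(t0, t1, y0, y1, d0, d1, tq):
    """Cubic Hermite interpolation on [t0, t1] (independent derivation)."""
    h = t1 - t0
    s = (tq - t0) / h
    h00 = (1 + 2 * s) * (1 - s) ** 2
    h10 = s * (1 - s) ** 2
    h01 = s * s * (3 - 2 * s)
    h11 = s * s * (s - 1)
    return h00 * y0 + h10 * h * d0 + h01 * y1 + h11 * h * d1


class FullHistoryIntegrator:
    """Monolithic fixed-step Bogacki-Shampine integrator.

    Keeps the complete solution history — the memory-hungry single-call
    scheme the chunked engine must agree with when plasticity is off.
    """

    def __init__(self, t0: float, y0: np.ndarray):
        self.t0 = float(t0)
        self.y0 = np.atleast_1d(np.asarray(y0, dtype=float)).copy()
        self.ts = [self.t0]
        self.ys = [self.y0.copy()]
        self.dys: list = [None]  # filled once f is known

    def interp(self, tq: float) -> np.ndarray:
        if tq <= self.t0:
            return self.y0
        for k in range(len(self.ts) - 1):
            if self.ts[k] <= tq <= self.ts[k + 1]:
                return hermite(self.ts[k], self.ts[k + 1], self.ys[k],
                               self.ys[k + 1], self.dys[k], self.dys[k + 1], tq)
        if abs(tq - self.ts[-1]) < 1e-12:
            return self.ys[-1]
        raise ValueError(f"query {tq} outside recorded history")

    def run(self, f, h: float, n_steps: int, callback=None) -> None:
        """``f(t, y, interp)``; optional ``callback(step_index)`` after each
        step (used to apply plasticity in the reference simulation)."""
        k1 = f(self.t0, self.ys[0], self.interp)
        self.dys[0] = k1
        y = self.ys[0]
        for i in range(n_steps):
            t = self.t0 + i * h
            k2 = f(t + 0.5 * h, y + 0.5 * h * k1, self.interp)
            k3 = f(t + 0.75 * h, y + 0.75 * h * k2, self.interp)
            y = y + h * (2.0 / 9.0 * k1 + 1.0 / 3.0 * k2 + 4.0 / 9.0 * k3)
            t_next = self.t0 + (i + 1) * h
            k1 = f(t_next, y, self.interp)
            self.ts.append(t_next)
            self.ys.append(y.copy())
            self.dys.append(k1)
            if callback is not None:
                new_k1 = callback(i + 1)
                if new_k1 is not None:
                    k1 = new_k1
                    self.dys[-1] = k1


def make_network_f(W, D, params):
    """Network right-hand side with scalar delayed lookups (oracle form)."""
    n = W.shape[0]

    def f(t, y, interp):
        E, Is, Id = y[:n], y[n:2 * n], y[2 * n:]
        delayed_E = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if W[i, j] != 0:
                    delayed_E[i, j] = interp(t - D[i, j])[j]
        dE, dIs, dId = rhs(t, E, Is, Id, delayed_E, W, params)
        return np.concatenate([dE, dIs, dId])

    return f


def scalar_hebbian_external(W, E_delayed, E_now, E_prev, c):
    """Double-loop Hebbian update + incoming normalization (oracle form)."""
    n = W.shape[0]
    W_new = W.copy()
    for i in range(n):
        for j in range(n):
            if W[i, j] > 0:
                dw = c * E_delayed[i, j] * (E_now[i] - E_prev[i])
                W_new[i, j] = max(0.0, W[i, j] + dw)
    for i in range(n):
        s = sum(W_new[i, j] for j in range(n))
        if s > 0:
            for j in range(n):
                W_new[i, j] = W_new[i, j] / s
    return W_new


def scalar_hebbian_internal(w, act_now, act_prev, c, pre_post):
    """Per-node scalar internal updates with sum-conserving renormalization."""
    n = w.shape[0]
    w_new = w.copy()
    for i in range(n):
        before = sum(w[i, k] for k in range(7))
        for k in range(7):
            pre, post = pre_post[k]
            dw = c * act_now[pre][i] * (act_now[post][i] - act_prev[post][i])
            w_new[i, k] = max(0.0, w[i, k] + dw)
        after = sum(w_new[i, k] for k in range(7))
        if after > 0:
            for k in range(7):
                w_new[i, k] = w_new[i, k] * (before / after)
    return w_new
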