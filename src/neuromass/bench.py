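"""Scaling benchmark harness.

The dominant cost of the model is the coupling term: every region's drive
sums over all its afferent connections, so the work per step grows as
O(n^2) with the region count (exactly n(n-1) multiply-adds per stage at
full connectivity).  The harness runs the synthetic network family at a
range of sizes and reports *instrumented operation counts* — deterministic
and hardware-independent — alongside wall time, which is informational
only.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .connectome import count_edges, generate_synthetic_connectome
from .engine import EngineConfig, simulate
from .model import PopulationParams
from .plasticity import PlasticityConfig

__all__ = ["Counters", "benchmark_scaling"]


@dataclass
class Counters:
    """Deterministic operation counters incremented by the engine."""

    rhs_evals: int = 0
    coupling_macs: int = 0       # one per weighted afferent term per rhs evaluation
    external_updates: int = 0
    internal_updates: int = 0
    weight_refresh_evals: int = 0  # derivative refreshes after weight updates
    snapshots: int = 0

    def as_dict(self) -> dict:
        return {
            "rhs_evals": self.rhs_evals,
            "coupling_macs": self.coupling_macs,
            "external_updates": self.external_updates,
            "internal_updates": self.internal_updates,
            "weight_refresh_evals": self.weight_refresh_evals,
            "snapshots": self.snapshots,
        }


def benchmark_scaling(
    sizes: Sequence[int],
    p: float = 0.2,
    plasticity_on: bool = True,
    biological_time: float = 1000.0,
    seed: int = 0,
    params: Optional[PopulationParams] = None,
    step: float = 1.0,
    learning_rate: float = 0.01,
) -> pd.DataFrame:
    """Run the synthetic network family and tabulate cost versus size.

    One row per network size: expected and realised edge counts, rhs
    evaluation count, coupling multiply-add count, plasticity update
    counts, and wall time (seconds; informational, excluded from any
    deterministic comparison).
    """
    if any(n < 1 for n in sizes):
        raise ValueError("network sizes must be >= 1")
    params = params or PopulationParams()
    rows = []
    for i, n in enumerate(sizes):
        conn = generate_synthetic_connectome(n=n, p=p, seed=seed + i)
        counters = Counters()
        plast = PlasticityConfig(c=learning_rate) if plasticity_on else None
        cfg = EngineConfig(t_end=biological_time, step=step)
        t0 = time.perf_counter()
        simulate(conn, params, cfg, plasticity_config=plast, counters=counters)
        wall = time.perf_counter() - t0
        rows.append({
            "n": n,
            "edges_expected": count_edges(n, p),
            "edges_external": conn.n_external,
            "rhs_evals": counters.rhs_evals,
            "coupling_macs": counters.coupling_macs,
            "external_updates": counters.external_updates,
            "internal_updates": counters.internal_updates,
            "weight_refresh_evals": counters.weight_refresh_evals,
            "wall_time_s": wall,
        })
    return pd.DataFrame(rows)


def scaling_exponent(df: pd.DataFrame, column: str = "coupling_macs") -> float:
    """Log-log slope of an operation-count column versus network size."""
    x = np.log(df["n"].to_numpy(dtype=float))
    y = np.log(df[column].to_numpy(dtype=float))
    return float(np.polyfit(x, y, 1)[0])
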