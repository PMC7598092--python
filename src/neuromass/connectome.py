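"""Inter-region structural connectivity.

Weights are initialised from streamline tractography counts,
``W_ij = 0.1 * ln(S_ij)`` for connected pairs and 0 otherwise, and conduction
delays from fiber trajectory lengths divided by a propagation speed of
7 m/s (= 7 mm/ms).  A synthetic generator emulates DTI-derived matrices:
each ordered region pair is connected independently with probability ``p``
(default 0.2, roughly the fraction of inter-region connections present in
the brain), with 82 regions by default.

``W`` is treated as directed: tractography counts are symmetric, but
plasticity makes the weights asymmetric immediately, so the generator
samples each ordered pair independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "init_weights",
    "compute_delays",
    "generate_synthetic_connectome",
    "count_edges",
    "load_connectome",
    "write_connectome",
]

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT_SCALE = 0.1
DEFAULT_VELOCITY_M_PER_S = 7.0
N_INTERNAL_PER_REGION = 7  # w1..w7


@dataclass
class Connectome:
    """Streamline counts ``S``, fiber lengths ``L`` (mm), derived weights
    ``W`` and delays ``D`` (ms) between ``n`` regions.

    Diagonals are zero throughout: self-influence enters the node model via
    the internal weight w1, never through ``W``.
    """

    S: np.ndarray
    L: np.ndarray
    W: np.ndarray
    D: np.ndarray
    labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        mats = {"S": self.S, "L": self.L, "W": self.W, "D": self.D}
        shapes = {m.shape for m in mats.values()}
        if len(shapes) != 1:
            raise ValueError(f"matrices must share one square shape, got {shapes}")
        n = self.S.shape[0]
        if self.S.shape != (n, n):
            raise ValueError("connectome matrices must be square")
        for name, m in mats.items():
            if np.any(np.diag(m) != 0):
                raise ValueError(f"diagonal of {name} must be zero")
            if np.any(m < 0):
                raise ValueError(f"{name} must be non-negative")
        if np.any((self.S == 0) & (self.W != 0)):
            raise ValueError("W must vanish wherever S vanishes")
        if np.any((self.W > 0) & (self.D <= 0)):
            raise ValueError("connected pairs must have positive delay")

    @property
    def n(self) -> int:
        return self.S.shape[0]

    @property
    def n_external(self) -> int:
        """Number of (directed) inter-region connections."""
        return int(np.count_nonzero(self.W))

    @property
    def max_delay(self) -> float:
        mask = self.W > 0
        return float(self.D[mask].max()) if mask.any() else 0.0


def init_weights(
    S: np.ndarray,
    scale: float = DEFAULT_WEIGHT_SCALE,
    log_base: str = "e",
) -> np.ndarray:
    """Weights from streamline counts: ``scale * log(S_ij)`` where ``S_ij > 0``.

    The natural logarithm is the default; ``log_base="10"`` switches to
    log10.  Counts in (0, 1) would produce negative weights and are rejected
    (integer streamline counts can never trigger this).
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("streamline counts must be non-negative")
    if np.any((S > 0) & (S < 1)):
        raise ValueError("streamline counts in (0, 1) would give negative weights")
    logf = np.log if log_base == "e" else np.log10
    if log_base not in ("e", "10"):
        raise ValueError("log_base must be 'e' or '10'")
    W = np.zeros_like(S)
    mask = S > 0
    W[mask] = scale * logf(S[mask])
    return W


def compute_delays(L: np.ndarray, v: float = DEFAULT_VELOCITY_M_PER_S) -> np.ndarray:
    """Delays (ms) from fiber lengths (mm) at propagation speed ``v`` (m/s).

    1 m/s = 1 mm/ms, so the numeric value of ``v`` carries over directly.
    """
    if not v > 0:
        raise ValueError("propagation speed must be positive")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("fiber lengths must be non-negative")
    return L / v


def default_count_law(rng: np.random.Generator, size: int) -> np.ndarray:
    """Streamline counts for synthetic connections: 1 + Geometric(1/49).

    Minimum 2, mean 50 — chosen so 0.1*ln(S) lands in a weight range of
    roughly 0.07-0.6, comparable to log-scaled tractography weights.
    """
    return 1 + rng.geometric(1.0 / 49.0, size=size)


def generate_synthetic_connectome(
    n: int = 82,
    p: float = 0.2,
    seed: Optional[int] = None,
    length_range: Tuple[float, float] = (20.0, 150.0),
    count_law: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    v: float = DEFAULT_VELOCITY_M_PER_S,
    scale: float = DEFAULT_WEIGHT_SCALE,
) -> Connectome:
    """Random connectome emulating DTI-derived matrices.

    Each ordered pair (i, j), i != j, carries a connection independently
    with probability ``p``; connected pairs draw a streamline count from
    ``count_law`` and a fiber length uniformly from ``length_range`` (mm).
    Identical seeds give identical connectomes.
    """
    if n < 1:
        raise ValueError("need at least one region")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"connection probability must lie in [0, 1], got {p}")
    lo, hi = length_range
    if not (0 < lo <= hi):
        raise ValueError("length_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    conn = rng.random((n, n)) < p
    np.fill_diagonal(conn, False)
    m = int(conn.sum())
    law = count_law if count_law is not None else default_count_law
    S = np.zeros((n, n))
    L = np.zeros((n, n))
    S[conn] = law(rng, m)
    L[conn] = rng.uniform(lo, hi, size=m)
    return Connectome(S=S, L=L, W=init_weights(S, scale=scale), D=compute_delays(L, v=v))


def count_edges(n: int, p: float) -> int:
    """Expected total edge count of the synthetic family.

    Seven internal connections per region (w1..w7) plus ``p*n*(n-1)``
    expected directed external connections, rounded to nearest integer.
    """
    if n < 1:
        raise ValueError("need at least one region")
    if not 0.0 <= p <= 1.0:
        raise ValueError("connection probability must lie in [0, 1]")
    return int(round(N_INTERNAL_PER_REGION * n + p * n * (n - 1)))


def _read_matrix(path: Path) -> np.ndarray:
    """Header-less numeric CSV/TSV matrix (separator sniffed).

    Parsed with round-trip float conversion so a matrix written at full
    precision reads back bit-exact.
    """
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    try:
        df = pd.read_csv(path, header=None, sep=sep, float_precision="round_trip")
        m = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric matrix entry ({exc})") from exc
    if np.any(~np.isfinite(m)):
        i, j = np.argwhere(~np.isfinite(m))[0]
        raise ValueError(f"{path}: non-finite entry at row {i}, column {j}")
    return m


def _validate_square(m: np.ndarray, name: str, path: Path) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: {name} matrix is not square (shape {m.shape})")
    if np.any(m < 0):
        i, j = np.argwhere(m < 0)[0]
        raise ValueError(f"{path}: negative {name} entry at row {i}, column {j}")


def load_connectome(
    streamlines_path: str | Path,
    lengths_path: str | Path,
    v: float = DEFAULT_VELOCITY_M_PER_S,
    scale: float = DEFAULT_WEIGHT_SCALE,
) -> Connectome:
    """Build a :class:`Connectome` from streamline-count and length matrices.

    Nonzero diagonals are forced to zero with a warning (self-connections
    are represented by internal weights, not ``W``).
    """
    s_path, l_path = Path(streamlines_path), Path(lengths_path)
    S = _read_matrix(s_path)
    L = _read_matrix(l_path)
    _validate_square(S, "streamline", s_path)
    _validate_square(L, "length", l_path)
    if S.shape != L.shape:
        raise ValueError(
            f"shape mismatch: streamlines {S.shape} vs lengths {L.shape}"
        )
    for name, m, path in (("streamline", S, s_path), ("length", L, l_path)):
        if np.any(np.diag(m) != 0):
            logger.warning("%s: nonzero diagonal in %s matrix forced to zero", path, name)
            np.fill_diagonal(m, 0.0)
    labels = None
    sidecar = s_path.with_suffix(".labels.json")
    if sidecar.exists():
        labels = json.loads(sidecar.read_text())
    return Connectome(
        S=S, L=L, W=init_weights(S, scale=scale), D=compute_delays(L, v=v), labels=labels
    )


def write_connectome(conn: Connectome, out_dir: str | Path) -> dict:
    """Write S, L, W, D as header-less CSVs; round-trips exactly.

    Returns the mapping of matrix name to file path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, m in (("streamlines", conn.S), ("lengths", conn.L),
                    ("weights", conn.W), ("delays", conn.D)):
        path = out / f"{name}.csv"
        np.savetxt(path, m, delimiter=",", fmt="%.17g")
        paths[name] = path
    if conn.labels is not None:
        (out / "streamlines.labels.json").write_text(json.dumps(list(conn.labels)))
    return paths
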