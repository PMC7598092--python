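"""Sparse snapshot recording.

Long simulations record activity and weights only every ``interval`` ms of
biological time (50 s in the original study design), so memory grows with
the snapshot count, never with the step count.  Snapshots can be held in
memory (:class:`SnapshotSeries`) or streamed to HDF5
(:class:`StreamingHDF5Writer`), which keeps at most one snapshot in working
memory.  HDF5 files are written with object timestamps disabled so a
repeated deterministic run produces an identical file.

HDF5 layout::

    /                attrs: format_version, n_snapshots, metadata (JSON)
    /snapshots/000000   attrs: t  — datasets E, Is, Id, W, w_internal
    /snapshots/000001   ...
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import h5py
import numpy as np
import pandas as pd

from .model import NetworkState

__all__ = [
    "SnapshotSeries",
    "SeriesIntegrityError",
    "StreamingHDF5Writer",
    "write_series",
    "read_series",
    "export_csv",
    "snapshot_times",
]

FORMAT_VERSION = 1


class SeriesIntegrityError(RuntimeError):
    """A snapshot file is corrupt, truncated, or inconsistent."""


def snapshot_times(t_end: float, interval: float) -> np.ndarray:
    """Scheduled snapshot times (ms): 0, interval, 2*interval, ... <= t_end."""
    if interval <= 0:
        raise ValueError("snapshot interval must be positive")
    n = int(np.floor(t_end / interval + 1e-9))
    return np.arange(n + 1) * interval


@dataclass
class SnapshotSeries:
    """In-memory record of snapshots: times, activities, and both weight sets.

    ``metadata`` holds whatever is needed to re-run the simulation
    (config hash, seed, package version).
    """

    times: List[float] = field(default_factory=list)
    E: List[np.ndarray] = field(default_factory=list)
    Is: List[np.ndarray] = field(default_factory=list)
    Id: List[np.ndarray] = field(default_factory=list)
    external_weights: List[np.ndarray] = field(default_factory=list)
    internal_weights: List[np.ndarray] = field(default_factory=list)
    metadata: Dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times)

    def add(self, t: float, state: NetworkState, W: np.ndarray,
            w_internal: np.ndarray) -> None:
        """Append a deep-copied snapshot; times must strictly increase."""
        if self.times and t <= self.times[-1]:
            raise ValueError(
                f"snapshots must be recorded in increasing time order "
                f"(got t={t} after t={self.times[-1]})"
            )
        self.times.append(float(t))
        self.E.append(np.array(state.E, copy=True))
        self.Is.append(np.array(state.Is, copy=True))
        self.Id.append(np.array(state.Id, copy=True))
        self.external_weights.append(np.array(W, copy=True))
        self.internal_weights.append(np.array(w_internal, copy=True))

    def state_at(self, idx: int) -> NetworkState:
        return NetworkState(self.times[idx], self.E[idx], self.Is[idx], self.Id[idx])

    def content_hash(self) -> str:
        """SHA-256 over the byte representation of every recorded array —
        two deterministic runs agree iff their hashes agree."""
        hsh = hashlib.sha256()
        hsh.update(np.asarray(self.times, dtype=float).tobytes())
        for group in (self.E, self.Is, self.Id, self.external_weights,
                      self.internal_weights):
            for arr in group:
                hsh.update(np.ascontiguousarray(arr).tobytes())
        return hsh.hexdigest()

    def __eq__(self, other) -> bool:
        if not isinstance(other, SnapshotSeries):
            return NotImplemented
        if self.times != other.times:
            return False
        for a, b in ((self.E, other.E), (self.Is, other.Is), (self.Id, other.Id),
                     (self.external_weights, other.external_weights),
                     (self.internal_weights, other.internal_weights)):
            if len(a) != len(b) or any(not np.array_equal(x, y) for x, y in zip(a, b)):
                return False
        return True


def _write_snapshot_group(grp: h5py.Group, t: float, E, Is, Id, W, w_internal) -> None:
    grp.attrs["t"] = float(t)
    for name, data in (("E", E), ("Is", Is), ("Id", Id), ("W", W),
                       ("w_internal", w_internal)):
        grp.create_dataset(name, data=np.asarray(data), track_times=False)


class StreamingHDF5Writer:
    """Append snapshots to HDF5 one at a time (bounded working memory).

    Usable as the ``recorder`` argument of the engine.  The snapshot count
    attribute is updated and the file flushed after every append, so a
    partially written file is detectable on read.
    """

    def __init__(self, path: str | Path, metadata: Optional[Dict] = None):
        self.path = Path(path)
        self._file = h5py.File(self.path, "w", track_order=True)
        self._file.attrs["format_version"] = FORMAT_VERSION
        self._file.attrs["n_snapshots"] = 0
        self._file.attrs["metadata"] = json.dumps(metadata or {}, sort_keys=True)
        self._grp = self._file.create_group("snapshots", track_order=True)
        self._count = 0
        self._last_t: Optional[float] = None

    def add(self, t: float, state: NetworkState, W: np.ndarray,
            w_internal: np.ndarray) -> None:
        if self._last_t is not None and t <= self._last_t:
            raise ValueError("snapshots must be appended in increasing time order")
        grp = self._grp.create_group(f"{self._count:06d}", track_order=True)
        _write_snapshot_group(grp, t, state.E, state.Is, state.Id, W, w_internal)
        self._count += 1
        self._last_t = t
        self._file.attrs["n_snapshots"] = self._count
        self._file.flush()

    def flush(self) -> None:
        if self._file:
            self._file.flush()

    def close(self) -> None:
        if self._file:
            self._file.close()
            self._file = None

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def write_series(series: SnapshotSeries, path: str | Path) -> Path:
    """Write a whole in-memory series to HDF5 (lossless, reproducible)."""
    path = Path(path)
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["n_snapshots"] = len(series)
        f.attrs["metadata"] = json.dumps(series.metadata, sort_keys=True)
        snaps = f.create_group("snapshots", track_order=True)
        for i, t in enumerate(series.times):
            grp = snaps.create_group(f"{i:06d}", track_order=True)
            _write_snapshot_group(grp, t, series.E[i], series.Is[i], series.Id[i],
                                  series.external_weights[i], series.internal_weights[i])
    return path


def read_series(path: str | Path) -> SnapshotSeries:
    """Read a snapshot file, verifying completeness.

    Raises :class:`SeriesIntegrityError` if the file is unreadable or the
    stored snapshot count disagrees with the groups present, naming the
    last valid snapshot.
    """
    path = Path(path)
    series = SnapshotSeries()
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise SeriesIntegrityError(f"{path}: unreadable snapshot file ({exc})") from exc
    with f:
        declared = int(f.attrs.get("n_snapshots", -1))
        series.metadata = json.loads(f.attrs.get("metadata", "{}"))
        snaps = f.get("snapshots")
        keys = sorted(snaps.keys()) if snaps is not None else []
        if declared != len(keys):
            last = keys[-1] if keys else "none"
            raise SeriesIntegrityError(
                f"{path}: declares {declared} snapshots but contains "
                f"{len(keys)} (last valid: {last})"
            )
        for key in keys:
            grp = snaps[key]
            series.times.append(float(grp.attrs["t"]))
            series.E.append(grp["E"][()])
            series.Is.append(grp["Is"][()])
            series.Id.append(grp["Id"][()])
            series.external_weights.append(grp["W"][()])
            series.internal_weights.append(grp["w_internal"][()])
    return series


def export_csv(series: SnapshotSeries, out_dir: str | Path) -> Dict[str, Path]:
    """CSV export for small runs.

    ``activity.csv`` is one long-format table (time_ms, region, variable,
    value); each snapshot's weight matrices go to ``W_t<t>.csv`` and
    ``w_internal_t<t>.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for i, t in enumerate(series.times):
        n = series.E[i].shape[0]
        for var, arr in (("E", series.E[i]), ("Is", series.Is[i]), ("Id", series.Id[i])):
            frames.append(pd.DataFrame({
                "time_ms": t, "region": np.arange(n), "variable": var, "value": arr,
            }))
    paths = {}
    activity = out / "activity.csv"
    pd.concat(frames, ignore_index=True).to_csv(activity, index=False)
    paths["activity"] = activity
    for i, t in enumerate(series.times):
        wp = out / f"W_t{t:g}.csv"
        np.savetxt(wp, series.external_weights[i], delimiter=",", fmt="%.17g")
        paths[f"W_t{t:g}"] = wp
        ip = out / f"w_internal_t{t:g}.csv"
        np.savetxt(ip, series.internal_weights[i], delimiter=",", fmt="%.17g")
        paths[f"w_internal_t{t:g}"] = ip
    return paths
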