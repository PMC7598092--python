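"""Run configuration and orchestration.

A single YAML file describes a complete simulation: connectome source
(files or the synthetic generator), node parameters, engine settings,
plasticity, and recording.  Every constant of the simulation regime
(step = 1 ms, chunk = 10 steps, update_every = 10 steps, snapshot every
50 s, propagation speed 7 m/s, connection probability 0.2, weight scale
0.1) appears in the config and is overridable.  Unknown keys are rejected
so typos fail before any compute.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from . import __version__
from .bench import Counters
from .connectome import (
    Connectome,
    generate_synthetic_connectome,
    load_connectome,
)
from .engine import EngineConfig, simulate
from .model import PopulationParams
from .plasticity import PlasticityConfig
from .recorder import SnapshotSeries, StreamingHDF5Writer, write_series

__all__ = ["RunConfig", "ConfigError", "load_config", "run_simulation"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown run-configuration content."""


_PARAM_KEYS = {
    "tau_e", "tau_i", "a_e", "a_i", "theta_e", "theta_i",
    "w1", "w2", "w3", "w4", "w5", "w6", "w7",
    "P_e", "P_s", "P_d", "dynamic_k",
}
_ENGINE_KEYS = {"t_end", "step", "chunk_steps", "initial_state", "rng_seed"}
_PLASTICITY_KEYS = {"enabled", "c", "update_every", "external_on", "internal_on",
                    "plastic_internal_set", "rule"}
_RECORDER_KEYS = {"interval", "stream"}
_CONNECTOME_KEYS = {"synthetic", "files", "weight_scale", "log_base", "velocity"}
_SYNTH_KEYS = {"n", "p", "seed", "length_range"}
_FILE_KEYS = {"streamlines", "lengths"}
_TOP_KEYS = {"connectome", "params", "engine", "plasticity", "recorder",
             "log_level", "outdir"}


def _check_keys(section: Dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated, fully resolved simulation configuration."""

    connectome: Dict
    params: PopulationParams
    engine: EngineConfig
    plasticity: Optional[PlasticityConfig]
    snapshot_interval: float = 50_000.0  # ms (50 s)
    stream: bool = False
    log_level: str = "INFO"
    outdir: Path = Path("neuromass_out")
    raw: Dict = field(default_factory=dict)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()

    def build_connectome(self) -> Connectome:
        spec = self.connectome
        if "files" in spec:
            files = spec["files"]
            return load_connectome(
                files["streamlines"], files["lengths"],
                v=spec.get("velocity", 7.0), scale=spec.get("weight_scale", 0.1),
            )
        synth = spec.get("synthetic", {})
        return generate_synthetic_connectome(
            n=synth.get("n", 82),
            p=synth.get("p", 0.2),
            seed=synth.get("seed", 0),
            length_range=tuple(synth.get("length_range", (20.0, 150.0))),
            v=spec.get("velocity", 7.0),
            scale=spec.get("weight_scale", 0.1),
        )


def _parse(raw: Dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("run configuration must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")

    conn = raw.get("connectome", {"synthetic": {}})
    _check_keys(conn, _CONNECTOME_KEYS, "connectome")
    if "synthetic" in conn and "files" in conn:
        raise ConfigError("connectome: give either 'synthetic' or 'files', not both")
    if "synthetic" in conn:
        _check_keys(conn["synthetic"], _SYNTH_KEYS, "connectome.synthetic")
    if "files" in conn:
        _check_keys(conn["files"], _FILE_KEYS, "connectome.files")
        missing = _FILE_KEYS - set(conn["files"])
        if missing:
            raise ConfigError(f"connectome.files missing {sorted(missing)}")

    pdict = raw.get("params", {})
    _check_keys(pdict, _PARAM_KEYS, "params")
    try:
        params = PopulationParams(**pdict)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"params: {exc}") from exc

    edict = dict(raw.get("engine", {}))
    _check_keys(edict, _ENGINE_KEYS, "engine")
    try:
        engine = EngineConfig(**edict)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"engine: {exc}") from exc

    pl = dict(raw.get("plasticity", {}))
    _check_keys(pl, _PLASTICITY_KEYS, "plasticity")
    enabled = pl.pop("enabled", True)
    plasticity = None
    if enabled:
        try:
            plasticity = PlasticityConfig(**pl)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"plasticity: {exc}") from exc

    rec = raw.get("recorder", {})
    _check_keys(rec, _RECORDER_KEYS, "recorder")
    interval = float(rec.get("interval", 50_000.0))
    if interval <= 0:
        raise ConfigError("recorder.interval must be positive (ms)")

    return RunConfig(
        connectome=conn,
        params=params,
        engine=engine,
        plasticity=plasticity,
        snapshot_interval=interval,
        stream=bool(rec.get("stream", False)),
        log_level=str(raw.get("log_level", "INFO")),
        outdir=Path(raw.get("outdir", "neuromass_out")),
        raw=raw,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _parse(raw)


def run_simulation(config: RunConfig, counters: Optional[Counters] = None) -> Dict:
    """Orchestrate connectome -> engine -> plasticity -> recorder.

    Writes the snapshot series to ``<outdir>/snapshots.h5`` and returns a
    summary dict (snapshot count, final time, max embedded error estimate,
    output path).  Configuration errors surface before any compute;
    divergence flushes partial results, then re-raises.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    conn = config.build_connectome()
    config.outdir.mkdir(parents=True, exist_ok=True)
    out_path = config.outdir / "snapshots.h5"
    metadata = {
        "config_hash": config.config_hash(),
        "config": config.raw,
        "version": __version__,
        "n_regions": conn.n,
    }
    counters = counters if counters is not None else Counters()
    if config.stream:
        with StreamingHDF5Writer(out_path, metadata=metadata) as writer:
            result = simulate(
                conn, config.params, config.engine,
                plasticity_config=config.plasticity,
                recorder=writer,
                snapshot_interval=config.snapshot_interval,
                counters=counters,
            )
            n_snapshots = counters.snapshots
    else:
        series = SnapshotSeries(metadata=metadata)
        result = simulate(
            conn, config.params, config.engine,
            plasticity_config=config.plasticity,
            recorder=series,
            snapshot_interval=config.snapshot_interval,
            counters=counters,
        )
        write_series(series, out_path)
        n_snapshots = len(series)
    logger.info(
        "simulated %.0f ms in %d steps, %d snapshots, max error estimate %.2e",
        config.engine.t_end, result.n_steps, n_snapshots, result.max_error_estimate,
    )
    return {
        "output": str(out_path),
        "n_snapshots": n_snapshots,
        "t_end": config.engine.t_end,
        "n_steps": result.n_steps,
        "max_error_estimate": result.max_error_estimate,
        "buffer_capacity": result.buffer_capacity,
        "counters": counters.as_dict(),
    }
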