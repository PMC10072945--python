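"""Artifact I/O: cell-position tables, run summaries, config hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import RunResult, SimulationConfig

__all__ = [
    "config_to_dict",
    "config_hash",
    "write_positions_csv",
    "read_positions_csv",
    "write_summary_json",
    "run_summary",
]

POSITION_COLUMNS = ["id", "type_name", "x_um", "y_um", "z_um", "diameter_um", "alive", "layer"]


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["mechanisms"] = sorted(d["mechanisms"])
    return d


def config_hash(config: SimulationConfig) -> str:
    """Stable short hash of the full configuration (for artifact provenance)."""
    payload = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_positions_csv(result: RunResult, path: str | Path) -> Path:
    """Write the final cell table (one row per cell, dead cells included)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = result.population.to_dataframe(result.types.names)
    df.to_csv(path, index=False)
    return path


def read_positions_csv(path: str | Path, alive_only: bool = True) -> pd.DataFrame:
    """Read a cell-position table written by :func:`write_positions_csv`.

    Plain x/y(/z) tables from other tools are accepted as long as they carry
    ``x_um``/``y_um`` columns (or ``x``/``y``).
    """
    df = pd.read_csv(path)
    rename = {}
    for want, alts in {"x_um": ("x",), "y_um": ("y",), "z_um": ("z",)}.items():
        if want not in df.columns:
            for alt in alts:
                if alt in df.columns:
                    rename[alt] = want
    df = df.rename(columns=rename)
    if "x_um" not in df.columns or "y_um" not in df.columns:
        raise ValueError(f"{path}: no x_um/y_um position columns found")
    if alive_only and "alive" in df.columns:
        df = df[df["alive"].astype(bool)]
    return df.reset_index(drop=True)


def run_summary(result: RunResult) -> dict:
    """JSON-ready per-run summary: config echo, census, per-type stats."""
    stats = result.per_type_stats()
    return {
        "config": config_to_dict(result.config),
        "config_hash": config_hash(result.config),
        "seed": result.config.seed,
        "initial_count": result.initial_count,
        "final_alive": result.population.n_alive,
        "death_rate": result.death_rate,
        "cf_end_step": result.cf_end_step,
        "steps_run": result.steps_run,
        "steady": result.steady,
        "day_log": result.day_log.to_dict("records"),
        "average_ri": result.average_ri(),
        "per_type": stats.where(pd.notna(stats), None).to_dict("records"),
    }


def write_summary_json(summary: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            v = float(o)
            return v if np.isfinite(v) else None
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return str(o)

    path.write_text(json.dumps(summary, indent=2, default=_default, allow_nan=True))
    return path
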