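"""Plain-text I/O: event tables, fraction/count series, YAML scenario configs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .schedule import LightSchedule
from .series import PhaseFractionSeries
from .simulate import CellCountSeries, EventSample, InstrumentModel, Scenario, SimParams

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "write_fractions_tsv",
    "read_fractions_tsv",
    "write_counts_tsv",
    "read_counts_tsv",
    "load_config",
    "save_config",
    "scenario_from_config",
    "config_hash",
    "write_manifest",
]


def write_events_tsv(sample: EventSample, path) -> None:
    df = pd.DataFrame({"time_h": sample.t_abs, "fl_au": sample.events})
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path, condition: str = "") -> EventSample:
    df = pd.read_csv(path, sep=None, engine="python")
    if "fl_au" not in df.columns or "time_h" not in df.columns:
        raise ValueError(f"{path}: expected columns time_h, fl_au")
    t_abs = float(df["time_h"].iloc[0])
    return EventSample(
        t=t_abs % 24.0,
        day=int(t_abs // 24.0),
        events=df["fl_au"].to_numpy(),
        condition=condition,
    )


def write_fractions_tsv(series: PhaseFractionSeries, path) -> None:
    series.to_frame().to_csv(path, sep="\t", index=False)


def read_fractions_tsv(path, condition: str = "") -> PhaseFractionSeries:
    df = pd.read_csv(path, sep="\t")
    return PhaseFractionSeries.from_frame(df, condition=condition)


def write_counts_tsv(counts: CellCountSeries, path) -> None:
    pd.DataFrame({"time_h": counts.t, "cells_per_ml": counts.n}).to_csv(
        path, sep="\t", index=False
    )


def read_counts_tsv(path) -> CellCountSeries:
    df = pd.read_csv(path, sep="\t")
    return CellCountSeries(t=df["time_h"].to_numpy(), n=df["cells_per_ml"].to_numpy())


# ---------------------------------------------------------------------------
# Scenario configuration (YAML)
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def scenario_from_config(cfg: dict, name: Optional[str] = None) -> Scenario:
    """Build a Scenario from a config mapping.

    Expected layout::

        name: HL
        schedule: {t_dawn: 6, photoperiod_h: 12, e_max_par: 875, ...}
        params:   {n0: 10000, s_onset_clock: 16.0, seed: 1, ...}

    Every stochastic stage must receive an explicit seed.
    """
    if "params" not in cfg:
        raise ValueError("config missing 'params' section")
    params_cfg = dict(cfg["params"])
    if "seed" not in params_cfg:
        raise ValueError("config validation error: params.seed is required")
    schedule = LightSchedule(**cfg.get("schedule", {}))
    params = SimParams(**params_cfg)
    return Scenario(name=name or cfg.get("name", "scenario"), schedule=schedule,
                    params=params)


def instrument_from_config(cfg: dict) -> InstrumentModel:
    return InstrumentModel(**cfg.get("instrument", {}))


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, cfg: dict, stage: str, seeds: dict) -> None:
    from . import __version__

    manifest = {
        "stage": stage,
        "config_hash": config_hash(cfg),
        "seeds": seeds,
        "dielcycle_version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
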