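"""Config-file parsing and tabular input/output.

Config files are YAML (JSON is a YAML subset) with keys exactly matching
:class:`ppsim.simulate.SimConfig` field names; unknown keys are rejected so
typos fail loudly.  Trajectories are written as TSV with a JSON manifest
sidecar carrying the full configuration and seed, sufficient to reproduce the
run bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .observables import ObservedTrajectory
from .simulate import _CONFIG_FIELDS, SimConfig, Trajectory

TRAJECTORY_COLUMNS = [
    "generation",
    "cycle",
    "n_cells",
    "n_lysed",
    "pending_virions",
    "mutant_allele_freq",
    "heterozygote_fraction",
    "mean_copy_number",
    "od_proxy",
    "mutant_cell_fraction",
]


def config_from_dict(raw: dict) -> SimConfig:
    """Build a SimConfig from a plain dict, rejecting unknown keys.

    The sentinels ``"off"`` (seed_generation) and ``"none"`` (copy_cap) are
    accepted as spellings of null.  ``initial_classes`` keys may be written
    ``"a,b"`` strings since YAML/JSON mappings cannot key on tuples.
    """
    unknown = set(raw) - set(_CONFIG_FIELDS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cleaned = dict(raw)
    if str(cleaned.get("seed_generation")).lower() == "off":
        cleaned["seed_generation"] = None
    if str(cleaned.get("copy_cap")).lower() == "none":
        cleaned["copy_cap"] = None
    if cleaned.get("initial_classes") is not None:
        classes = {}
        for key, count in cleaned["initial_classes"].items():
            if isinstance(key, str):
                a, b = (int(x) for x in key.split(","))
            else:
                a, b = (int(x) for x in key)
            classes[(a, b)] = int(count)
        cleaned["initial_classes"] = classes
    return SimConfig(**cleaned)


def load_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config_from_dict(raw)


def config_to_dict(config: SimConfig) -> dict:
    """JSON-serialisable dict of a config (tuple keys flattened to 'a,b')."""
    d = asdict(config)
    if d.get("initial_classes") is not None:
        d["initial_classes"] = {f"{a},{b}": c for (a, b), c in d["initial_classes"].items()}
    return d


def write_trajectory_tsv(traj: Trajectory, path: str | Path) -> None:
    df = traj.to_dataframe()[TRAJECTORY_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_trajectory_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_observed_tsv(obs: ObservedTrajectory, path: str | Path) -> None:
    obs.to_dataframe().to_csv(path, sep="\t", index=False)


def read_observed_tsv(path: str | Path) -> ObservedTrajectory:
    df = pd.read_csv(path, sep="\t")
    try:
        return ObservedTrajectory.from_dataframe(df)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_manifest(path: str | Path, **entries) -> None:
    """Write a run manifest (command, config, seed, outputs, timing)."""
    Path(path).write_text(json.dumps(entries, indent=2, default=str) + "\n")
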