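"""File plumbing: CSV/JSON/YAML formats for fixes, observations, draws.

Draws are written as one CSV per fitted model (one column per scalar
parameter plus a ``chain`` id column) with a JSON metadata sidecar carrying
the model id, seed, chain protocol, animal ids and Metropolis acceptance
rates — enough to rebuild the Chain objects exactly.
"""

from __future__ import annotations

from dataclasses import asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mcmc import Chain, McmcConfig, ParamLayout
from .model import MODEL_REGISTRY
from .observations import OBS_COLUMNS
from .preprocessing import FIX_COLUMNS


def read_fixes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: fix CSV is missing columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_fixes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: observation CSV is missing columns {missing}")
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    df[OBS_COLUMNS].to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("animal_id", "timestamp", "x2_km", "x3_km", "x4_km")
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: covariate CSV is missing columns {missing}")
    return df


def write_chains(chains: list[Chain], spec_id: int, config: McmcConfig,
                 draws_path, meta_path) -> None:
    layout = chains[0].layout
    frames = []
    for i, ch in enumerate(chains):
        df = pd.DataFrame(ch.draws, columns=layout.names)
        df.insert(0, "chain", i)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(draws_path, index=False)
    meta = {
        "spec_id": spec_id,
        "animal_ids": [str(a) for a in layout.animal_ids],
        "config": asdict(config),
        "chains": [{"seed": ch.seed, "acceptance_rates": ch.acceptance_rates}
                   for ch in chains],
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_chains(draws_path, meta_path) -> tuple[list[Chain], int]:
    """Rebuild chains written by :func:`write_chains`; returns (chains, spec_id)."""
    with open(meta_path) as fh:
        meta = json.load(fh)
    spec = MODEL_REGISTRY[int(meta["spec_id"])]
    layout = ParamLayout(spec, len(meta["animal_ids"]), meta["animal_ids"])
    df = pd.read_csv(draws_path)
    chains = []
    for i, cm in enumerate(meta["chains"]):
        sub = df[df["chain"] == i]
        draws = sub[layout.names].to_numpy(float)
        chains.append(Chain(layout=layout, draws=draws,
                            acceptance_rates=cm["acceptance_rates"], seed=cm["seed"]))
    return chains, spec.id


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
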