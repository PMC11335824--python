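"""Delimited-text I/O, configuration loading, and run manifests.

Trial-level rating tables are plain UTF-8 delimited text with a header row
and columns ``participant_id, group, trial_id, truth, rating`` (plus an
optional ``replicate`` column for simulated datasets). Truth labels are
``same`` / ``different``, case-insensitive on read; ratings accept decimals.

Group parameters and experiment designs are YAML mappings; every output
directory written by the CLI carries a JSON manifest (tool version, resolved
configuration, root seed, timestamp, input digests) sufficient to reproduce
the run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .classification import DIFFERENT, RATING_COLUMNS, SAME
from .simulate import ExperimentDesign, GroupParams

PathLike = Union[str, os.PathLike]


def read_ratings(path: PathLike, sep: str = ",") -> pd.DataFrame:
    """Read a trial-level rating table, validating columns, labels and ratings.

    Errors name the offending data rows (1-based, excluding the header).
    """
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty (a header row is required)")
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")

    truth = df["truth"].astype(str).str.strip().str.lower()
    bad = ~truth.isin([SAME, DIFFERENT])
    if bad.any():
        rows = (df.index[bad] + 1).tolist()[:10]
        raise ValueError(
            f"{path}: unknown truth labels {sorted(df['truth'][bad].unique())} "
            f"at data rows {rows}"
        )
    df["truth"] = truth
    rating = pd.to_numeric(df["rating"], errors="coerce")
    bad = rating.isna()
    if bad.any():
        rows = (df.index[bad] + 1).tolist()[:10]
        raise ValueError(f"{path}: non-numeric ratings at data rows {rows}")
    df["rating"] = rating.astype(float)
    return df


def write_ratings(df: pd.DataFrame, path: PathLike, sep: str = ",") -> None:
    """Write a trial-level rating table as delimited text."""
    cols = [c for c in ("replicate",) + RATING_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep=sep, index=False)


def load_group_params(path: PathLike) -> Dict[str, GroupParams]:
    """Load per-group rating-distribution parameters from YAML.

    Layout: a mapping ``group -> {mean_same, sd_same, mean_diff, sd_diff}``
    with an optional top-level ``scale: [lo, hi]`` applied to every group.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or not cfg:
        raise ValueError(f"{path}: expected a mapping of groups to parameters")
    scale = tuple(cfg.pop("scale", (1.0, 12.0)))
    out = {}
    for group, vals in cfg.items():
        if not isinstance(vals, dict):
            raise ValueError(f"{path}: group {group!r} must map to parameter fields")
        try:
            out[group] = GroupParams(
                mean_same=float(vals["mean_same"]),
                sd_same=float(vals["sd_same"]),
                mean_diff=float(vals["mean_diff"]),
                sd_diff=float(vals["sd_diff"]),
                scale=tuple(vals.get("scale", scale)),
            )
        except KeyError as e:
            raise ValueError(f"{path}: group {group!r} missing field {e}")
    return out


def load_design(path: PathLike) -> ExperimentDesign:
    """Load an experiment design (participant/trial/replicate counts) from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    allowed = {
        "n_participants_per_group",
        "n_same",
        "n_diff",
        "n_replicates",
        "seed",
        "yoked",
    }
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown design fields {sorted(unknown)}")
    return ExperimentDesign(**cfg)


def _sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: PathLike,
    command: str,
    config: dict,
    seed: Optional[int],
    inputs: Sequence[PathLike] = (),
) -> Path:
    """Write a JSON run manifest into an output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "forensicsdt",
        "version": __version__,
        "command": command,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "inputs": {str(p): _sha256(p) for p in inputs},
    }
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return path


def params_to_config(params_by_group: Dict[str, GroupParams]) -> dict:
    return {g: asdict(p) for g, p in params_by_group.items()}
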