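"""Condition-level summaries with the cell as the unit of replication.

Per-cell metric tables (state fractions, on-rates, lifetimes, mean oligomer
orders, assay responses) are grouped by condition and reduced to
mean +/- SEM across cells, with a run manifest recording config hash, seed
and package version for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["summarize", "write_manifest"]


def summarize(per_cell: pd.DataFrame, metrics: list[str] | None = None) -> pd.DataFrame:
    """Across-cell mean and SEM per condition.

    ``per_cell`` needs columns cell_id, condition plus numeric metric
    columns. SEM with a single cell is reported as NaN ("missing"), never
    fabricated. A cell id appearing under two conditions is an error.
    """
    required = {"cell_id", "condition"}
    if not required <= set(per_cell.columns):
        raise ValueError(f"per-cell table needs columns {sorted(required)}")
    dup = per_cell.groupby("cell_id")["condition"].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index.tolist()
        raise ValueError(f"cell id(s) assigned to multiple conditions: {bad}")
    if metrics is None:
        metrics = [
            c
            for c in per_cell.columns
            if c not in required and pd.api.types.is_numeric_dtype(per_cell[c])
        ]
    rows = []
    for cond, g in per_cell.groupby("condition", sort=True):
        rec = {"condition": cond, "n_cells": g["cell_id"].nunique()}
        for m in metrics:
            v = g.groupby("cell_id")[m].mean()  # one value per cell
            rec[f"{m}_mean"] = float(v.mean())
            rec[f"{m}_sem"] = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def write_manifest(path: str | Path, config: dict, seed: int, extra: dict | None = None) -> dict:
    """Run manifest: config hash, seed, package version."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "smtrack_version": __version__,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
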