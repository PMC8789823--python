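"""Quantification rules for split-luciferase and BRET readouts.

Plate-reader kinetics are normalized to the pre-ligand baseline
(fold change), then averaged over a stated post-ligand window — 13-15 min
for the complementation assays, 27-30 min with per-timepoint vehicle
normalization for the surface-receptor (internalization) assay. The BRET
index is acceptor / (donor + acceptor); per-cell fold change is the index
about 14 min after stimulation over the index before.

t = 0 is the first post-ligand read (manual ligand addition introduces a
lag, so early-responding sensors may already deviate from 1 at t = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AssaySeries",
    "BretFrame",
    "fold_change",
    "window_quantify",
    "vehicle_normalize",
    "bret_index",
    "bret_fold_change",
    "aggregate_replicates",
]


@dataclass
class AssaySeries:
    """One well's luminescence kinetics."""

    times: np.ndarray  # s from ligand addition, strictly increasing
    counts: np.ndarray  # a.u., >= 0
    condition: str = ""
    replicate: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class BretFrame:
    I_nanobit: float  # donor-channel mean intensity
    I_venus: float  # acceptor-channel mean intensity
    time: float = 0.0

    def __post_init__(self):
        if self.I_nanobit < 0 or self.I_venus < 0:
            raise ValueError("intensities must be >= 0")


def fold_change(series: AssaySeries, baseline: float | None = None) -> AssaySeries:
    """Normalize counts to the pre-ligand baseline (defaults to the first read)."""
    b = series.counts[0] if baseline is None else float(baseline)
    if b == 0:
        raise ValueError("zero baseline")
    return AssaySeries(series.times, series.counts / b, series.condition, series.replicate)


def window_quantify(series: AssaySeries, window: tuple[float, float]) -> float:
    """Mean of values with time in [start, end] inclusive."""
    lo, hi = window
    sel = (series.times >= lo) & (series.times <= hi)
    if not sel.any():
        raise ValueError(f"window [{lo}, {hi}] contains no sample")
    return float(series.counts[sel].mean())


def vehicle_normalize(ligand: AssaySeries, vehicle: AssaySeries) -> AssaySeries:
    """Per-timepoint ratio to the vehicle series (surface-receptor rule)."""
    if len(ligand.times) != len(vehicle.times) or not np.allclose(ligand.times, vehicle.times):
        raise ValueError("ligand and vehicle series must share timepoints")
    if (vehicle.counts == 0).any():
        raise ValueError("vehicle series contains zero counts")
    return AssaySeries(
        ligand.times, ligand.counts / vehicle.counts, ligand.condition, ligand.replicate
    )


def bret_index(frame: BretFrame) -> float:
    """Acceptor fraction: I_venus / (I_nanobit + I_venus), in [0, 1]."""
    denom = frame.I_nanobit + frame.I_venus
    if denom == 0:
        raise ValueError("zero total intensity")
    return frame.I_venus / denom


def bret_fold_change(before: BretFrame, after: BretFrame) -> float:
    """Per-cell fold change: index after stimulation / index before."""
    b = bret_index(before)
    if b == 0:
        raise ValueError("zero pre-stimulation BRET index")
    return bret_index(after) / b


def aggregate_replicates(df: pd.DataFrame, value: str = "response") -> pd.DataFrame:
    """Mean across within-experiment duplicates, then mean +/- SE across experiments.

    Expects columns condition, experiment, replicate, <value>.
    """
    per_exp = df.groupby(["condition", "experiment"], sort=True)[value].mean().reset_index()
    out = (
        per_exp.groupby("condition", sort=True)[value]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
             n="count")
        .reset_index()
    )
    return out
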