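"""Track containers and the track-CSV dialect.

One row per localization: ``cell_id, channel, track_id, frame, x_um, y_um,
intensity`` with a mandatory header, 0-based frames and positions in um.
The in-memory container is a canonically sorted :class:`pandas.DataFrame`
wrapped with acquisition metadata (frame interval, pixel size, movie length).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "TRACK_COLUMNS",
    "Track",
    "TrackSet",
    "SchemaError",
    "TrackValidationError",
    "read_tracks",
    "write_tracks",
    "read_ground_truth",
    "write_ground_truth",
]

TRACK_COLUMNS = ["cell_id", "channel", "track_id", "frame", "x_um", "y_um", "intensity"]


class SchemaError(ValueError):
    """The file does not match the track-CSV dialect."""


class TrackValidationError(ValueError):
    """Rows violate a track invariant (ordering, duplicates, non-finite)."""


@dataclass
class Track:
    """One particle's time-ordered positions and intensities in one channel."""

    cell_id: str
    channel: int
    track_id: str
    frames: np.ndarray  # strictly increasing ints
    xy: np.ndarray  # (n, 2) um
    intensity: np.ndarray  # (n,) a.u.

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TrackSet:
    """Tracks grouped by cell and channel, sharing acquisition metadata.

    ``df`` is canonically sorted by (cell_id, channel, track_id, frame);
    ``metadata`` carries ``dt`` (s), ``pixel_size`` (um) and ``n_frames``.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = _canonicalize(self.df)
        if "dt" in self.metadata and not self.metadata["dt"] > 0:
            raise TrackValidationError("metadata dt must be > 0")

    @property
    def dt(self) -> float:
        return float(self.metadata["dt"])

    def channel(self, ch: int) -> "TrackSet":
        return TrackSet(self.df[self.df["channel"] == ch].copy(), dict(self.metadata))

    def cells(self) -> list[str]:
        return sorted(self.df["cell_id"].unique().tolist())

    def n_tracks(self) -> int:
        return self.df.groupby(["cell_id", "channel", "track_id"], sort=False).ngroups

    def tracks(self) -> Iterator[Track]:
        for (cell, ch, tid), g in self.df.groupby(
            ["cell_id", "channel", "track_id"], sort=True
        ):
            yield Track(
                cell_id=str(cell),
                channel=int(ch),
                track_id=str(tid),
                frames=g["frame"].to_numpy(dtype=int),
                xy=g[["x_um", "y_um"]].to_numpy(dtype=float),
                intensity=g["intensity"].to_numpy(dtype=float),
            )

    def total_observation_time(self) -> float:
        """Total particle-observation time (s): one dt per localization."""
        return len(self.df) * self.dt


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, TRACK_COLUMNS].copy()
    df["cell_id"] = df["cell_id"].astype(str)
    df["track_id"] = df["track_id"].astype(str)
    df["channel"] = df["channel"].astype(int)
    df["frame"] = df["frame"].astype(int)
    for c in ("x_um", "y_um", "intensity"):
        df[c] = df[c].astype(float)
    df = df.sort_values(["cell_id", "channel", "track_id", "frame"], kind="mergesort")
    return df.reset_index(drop=True)


def _validate(df: pd.DataFrame) -> None:
    """Validate in file order: frames must already be strictly increasing."""
    bad = ~np.isfinite(df[["x_um", "y_um"]].to_numpy(dtype=float)).all(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise TrackValidationError(f"non-finite coordinate at row {row}")
    if (~df["channel"].astype(int).isin([1, 2])).any():
        raise TrackValidationError("channel must be 1 or 2")
    key = ["cell_id", "channel", "track_id"]
    grp = df.groupby(key, sort=False)["frame"]
    if grp.apply(lambda f: f.duplicated().any()).any():
        raise TrackValidationError("duplicate (track, frame) row")
    if grp.apply(lambda f: (np.diff(f.to_numpy()) <= 0).any()).any():
        raise TrackValidationError("frames must be strictly increasing within a track")


def read_tracks(path: str | Path, metadata: dict | None = None) -> TrackSet:
    """Read and validate a track CSV.

    Raises :class:`SchemaError` for a missing column and
    :class:`TrackValidationError` for invariant breaches (duplicate frames,
    decreasing frame order, non-finite coordinates).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    if len(df):
        _validate(df)
    df = _canonicalize(df)
    return TrackSet(df, dict(metadata or {}))


def write_tracks(ts: TrackSet, path: str | Path) -> None:
    """Write the canonical CSV; write_tracks(read_tracks(f)) is byte-stable."""
    df = ts.df.copy()
    df.to_csv(path, index=False, float_format="%.6f")


# -- ground-truth sidecar (ndjson) ----------------------------------------

def write_ground_truth(gt: dict, path: str | Path) -> None:
    """Ground truth as ndjson: one record per track, then per binding event."""
    with open(path, "w") as fh:
        for rec in gt["tracks"]:
            fh.write(json.dumps({"type": "track", **rec}) + "\n")
        for rec in gt["binding_events"]:
            fh.write(json.dumps({"type": "binding", **rec}) + "\n")


def read_ground_truth(path: str | Path) -> dict:
    tracks, events = [], []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            kind = rec.pop("type")
            (tracks if kind == "track" else events).append(rec)
    return {"tracks": tracks, "binding_events": events}
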