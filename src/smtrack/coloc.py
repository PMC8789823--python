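"""Two-channel colocalization events and their kinetics.

A colocalization event requires, frame by frame, that a channel-1 and a
channel-2 particle lie within ``radius`` (default 0.1 um) of each other AND
carry the same hard diffusion-state label. Candidate pairs in a frame are
made mutually exclusive by greedy nearest-distance assignment; consecutive
matched frames of the same pair merge into one event, with no gap bridging.

Kinetics: the on-event rate is new events per channel-1 particle-second.
The dissociation rate comes from an exponential fit to event durations that
is left-truncated at one frame (the minimum observable duration) and
right-censored at track/movie end; the naive uncensored estimate is
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TrackSet
from .vbhmm import StateAssignment

__all__ = [
    "ColocEvent",
    "ColocSummary",
    "detect_coloc",
    "coloc_kinetics",
    "chance_coloc_baseline",
]


@dataclass
class ColocEvent:
    cell_id: str
    track_ch1: str
    track_ch2: str
    start_frame: int
    end_frame: int  # inclusive
    duration: float  # (end - start + 1) * dt, s
    state: int  # majority label during the event
    censored: bool  # touches either track's last frame or movie end


@dataclass
class ColocSummary:
    on_rate: float  # events per ch1 particle per s
    n_events: int
    durations: np.ndarray  # s
    k_off: float | None  # 1/s, censoring-aware MLE
    k_off_ci: tuple[float, float] | None
    mean_lifetime: float | None  # 1/k_off, s
    k_off_naive: float | None  # ignores censoring/truncation


def events_to_frame(events: list[ColocEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": e.cell_id,
                "track_ch1": e.track_ch1,
                "track_ch2": e.track_ch2,
                "start_frame": e.start_frame,
                "end_frame": e.end_frame,
                "duration_s": e.duration,
                "state": e.state,
                "censored": e.censored,
            }
            for e in events
        ]
    )


def _frame_table(ts: TrackSet, assignment: StateAssignment, channel: int) -> pd.DataFrame:
    lab = assignment.labels[["cell_id", "channel", "track_id", "frame", "state"]]
    df = ts.df[ts.df["channel"] == channel].merge(
        lab, on=["cell_id", "channel", "track_id", "frame"], how="inner"
    )
    return df


def detect_coloc(
    ts: TrackSet,
    assign1: StateAssignment,
    assign2: StateAssignment,
    radius: float = 0.1,
) -> list[ColocEvent]:
    """Detect same-state proximity events between channels 1 and 2."""
    df1 = _frame_table(ts, assign1, 1)
    df2 = _frame_table(ts, assign2, 2)
    n_frames = int(ts.metadata.get("n_frames", ts.df["frame"].max() + 1))
    dt = ts.dt
    events: list[ColocEvent] = []
    track_end1 = df1.groupby("track_id")["frame"].max()
    track_end2 = df2.groupby("track_id")["frame"].max()

    for cell in sorted(set(df1["cell_id"]) & set(df2["cell_id"])):
        c1 = df1[df1["cell_id"] == cell]
        c2 = df2[df2["cell_id"] == cell]
        # per-frame greedy matching
        open_runs: dict[tuple[str, str], list] = {}  # pair -> [start, last, labels]
        closed: list[tuple] = []
        g1 = dict(tuple(c1.groupby("frame", sort=True)))
        g2 = dict(tuple(c2.groupby("frame", sort=True)))
        for f in sorted(set(g1) | set(g2)):
            matched: set[tuple[str, str]] = set()
            if f in g1 and f in g2:
                a, b = g1[f], g2[f]
                xy1 = a[["x_um", "y_um"]].to_numpy()
                xy2 = b[["x_um", "y_um"]].to_numpy()
                s1 = a["state"].to_numpy()
                s2 = b["state"].to_numpy()
                id1 = a["track_id"].to_numpy()
                id2 = b["track_id"].to_numpy()
                d = np.sqrt(((xy1[:, None, :] - xy2[None, :, :]) ** 2).sum(axis=2))
                ok = (d <= radius) & (s1[:, None] == s2[None, :])
                cand = [
                    (d[i, j], str(id1[i]), str(id2[j]), int(s1[i]), i, j)
                    for i, j in zip(*np.nonzero(ok))
                ]
                cand.sort(key=lambda c: (c[0], c[1], c[2]))  # distance, index tie-break
                used1: set[int] = set()
                used2: set[int] = set()
                for dist, t1, t2, st, i, j in cand:
                    if i in used1 or j in used2:
                        continue
                    used1.add(i)
                    used2.add(j)
                    pair = (t1, t2)
                    matched.add(pair)
                    if pair in open_runs and open_runs[pair][1] == f - 1:
                        open_runs[pair][1] = f
                        open_runs[pair][2].append(st)
                    else:
                        if pair in open_runs:
                            closed.append((pair, *open_runs.pop(pair)))
                        open_runs[pair] = [f, f, [st]]
            # close runs that were not continued this frame
            for pair in [p for p, run in open_runs.items() if run[1] < f and p not in matched]:
                closed.append((pair, *open_runs.pop(pair)))
        closed.extend((pair, *run) for pair, run in open_runs.items())

        for (t1, t2), start, end, labels in closed:
            vals, counts = np.unique(labels, return_counts=True)
            majority = int(vals[np.argmax(counts)])
            censored = (
                end >= n_frames - 1
                or end >= int(track_end1.get(t1, -1))
                or end >= int(track_end2.get(t2, -1))
            )
            events.append(
                ColocEvent(
                    cell_id=cell,
                    track_ch1=t1,
                    track_ch2=t2,
                    start_frame=int(start),
                    end_frame=int(end),
                    duration=(end - start + 1) * dt,
                    state=majority,
                    censored=censored,
                )
            )
    events.sort(key=lambda e: (e.cell_id, e.start_frame, e.track_ch1, e.track_ch2))
    return events


def exponential_mle(
    durations: np.ndarray, censored: np.ndarray, truncation: float
) -> tuple[float, tuple[float, float]]:
    """Rate MLE for left-truncated, right-censored exponential durations.

    With all durations >= truncation (memorylessness), k = n_uncensored /
    sum(d_i - truncation). Reduces to 1/(mean - truncation) when nothing is
    censored. Wald CI on log-rate.
    """
    d = np.asarray(durations, dtype=float)
    cens = np.asarray(censored, dtype=bool)
    n_unc = int((~cens).sum())
    total = float((d - truncation).sum())
    if n_unc == 0 or total <= 0:
        raise ValueError("no uncensored duration mass to fit")
    k = n_unc / total
    se_log = 1.0 / np.sqrt(n_unc)
    ci = (k * np.exp(-1.96 * se_log), k * np.exp(1.96 * se_log))
    return k, ci


def coloc_kinetics(
    events: list[ColocEvent], ts_ch1: TrackSet, dt: float | None = None
) -> ColocSummary:
    """On-rate and dissociation-rate summary from detected events."""
    dt = ts_ch1.dt if dt is None else dt
    obs_time = ts_ch1.total_observation_time()
    if obs_time <= 0:
        raise ValueError("total channel-1 observation time must be > 0")
    n = len(events)
    on_rate = n / obs_time
    if n == 0:
        return ColocSummary(on_rate=0.0, n_events=0, durations=np.array([]), k_off=None,
                            k_off_ci=None, mean_lifetime=None, k_off_naive=None)
    durations = np.array([e.duration for e in events])
    censored = np.array([e.censored for e in events])
    try:
        k_off, ci = exponential_mle(durations, censored, truncation=dt)
    except ValueError:
        k_off, ci = None, None
    k_naive = 1.0 / durations.mean() if durations.mean() > 0 else None
    return ColocSummary(
        on_rate=on_rate,
        n_events=n,
        durations=durations,
        k_off=k_off,
        k_off_ci=ci,
        mean_lifetime=(1.0 / k_off) if k_off else None,
        k_off_naive=k_naive,
    )


def chance_coloc_baseline(
    ts: TrackSet,
    assign1: StateAssignment,
    assign2: StateAssignment,
    radius: float = 0.1,
    n_shuffles: int = 10,
    seed: int = 0,
    field: float | None = None,
) -> tuple[float, float]:
    """Chance on-rate from circular shifts of channel-2 tracks.

    Each shuffle displaces every channel-2 track by one random vector,
    wrapped inside the field, breaking real correlations while preserving
    densities and motion statistics. Returns (mean, SD) of the shuffled
    on-rate.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    field = field or ts.metadata.get("field")
    if not field:
        raise ValueError("field size required for circular shifts")
    rng = np.random.default_rng(seed)
    ch1 = ts.channel(1)
    rates = []
    base = ts.df
    ch2_mask = base["channel"] == 2
    for _ in range(n_shuffles):
        df = base.copy()
        for tid, idx in df[ch2_mask].groupby("track_id").groups.items():
            shift = rng.uniform(0, field, size=2)
            df.loc[idx, "x_um"] = (df.loc[idx, "x_um"] + shift[0]) % field
            df.loc[idx, "y_um"] = (df.loc[idx, "y_um"] + shift[1]) % field
        shuffled = TrackSet(df, dict(ts.metadata))
        ev = detect_coloc(shuffled, assign1, assign2, radius=radius)
        rates.append(len(ev) / ch1.total_observation_time())
    rates = np.asarray(rates)
    return float(rates.mean()), float(rates.std(ddof=1)) if len(rates) > 1 else 0.0
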