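"""Synthetic two-channel track sets with known ground truth.

The generator emulates a dual-color TIRF single-molecule acquisition:
particles switch among K diffusion states by a per-frame Markov chain,
diffuse by isotropic Gaussian steps of per-axis variance ``2*D_k*dt``,
are reflected inside an L x L membrane domain while in a confined state
(domain anchored at the state-entry position), carry oligomer-dependent
spot intensities, photobleach geometrically, and are observed with
Gaussian localization noise. Scripted binding tethers channel-2 particles
to channel-1 particles for exponentially distributed lifetimes, providing
ground truth for colocalization-kinetics recovery.

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .io import TRACK_COLUMNS, TrackSet

__all__ = ["simulate_tracks", "simulate_assay_series"]


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect x into [lo, hi] (billiard reflection, handles large excursions)."""
    width = hi - lo
    if width <= 0:
        return lo
    y = (x - lo) % (2.0 * width)
    return lo + (width - abs(y - width))


def _simulate_states(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    """Markov state sequence s_0..s_{n-1} (0-based labels)."""
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(cfg.n_states, p=cfg.pi_arr)
    A = cfg.A_arr
    for t in range(1, n):
        states[t] = rng.choice(cfg.n_states, p=A[states[t - 1]])
    return states


def _track_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    """Frames until photobleach (geometric survival), capped at movie end."""
    if cfg.bleach_rate >= 1.0:
        return cfg.n_frames
    n = 1
    while n < cfg.n_frames and rng.random() < cfg.bleach_rate:
        n += 1
    return n


def _simulate_channel(
    rng: np.random.Generator, cfg: SimulationConfig, cell_id: str, channel: int
):
    """All tracks of one channel; returns (per-track dicts, ground-truth recs)."""
    tracks = []
    step_sd = np.sqrt(2.0 * cfg.D_arr * cfg.dt)  # per-axis step SD per state
    for i in range(cfg.n_tracks):
        tid = f"ch{channel}t{i:04d}"
        n = _track_length(rng, cfg)
        states = _simulate_states(rng, cfg, n)
        pos = np.empty((n, 2))
        pos[0] = rng.uniform(0.0, cfg.field, size=2)
        anchor = pos[0].copy()  # domain anchor while confined
        for t in range(n - 1):
            k = states[t]
            if t > 0 and states[t] != states[t - 1]:
                anchor = pos[t].copy()
            step = rng.normal(0.0, step_sd[k], size=2)
            nxt = pos[t] + step
            L = cfg.confinement[k]
            if L is not None:
                for ax in range(2):
                    nxt[ax] = _reflect(nxt[ax], anchor[ax] - L / 2, anchor[ax] + L / 2)
            pos[t + 1] = nxt

        if cfg.intensity is not None:
            w = np.asarray(cfg.intensity.oligomer_weights[states[0]], dtype=float)
            order = int(rng.choice(len(w), p=w)) + 1
            mu = order * cfg.intensity.mu1
            sd = np.sqrt(order) * cfg.intensity.cv1 * cfg.intensity.mu1
            inten = rng.normal(mu, sd, size=n)
        else:
            order = 1
            inten = np.ones(n)

        tracks.append(
            {
                "cell_id": cell_id,
                "channel": channel,
                "track_id": tid,
                "true_pos": pos,
                "states": states,
                "order": order,
                "intensity": inten,
                "start": 0,
                "n": n,
            }
        )
    return tracks


def _script_binding(rng, cfg: SimulationConfig, cell_id, ch1_tracks, ch2_tracks):
    """Tether ch2 particles to ch1 particles for exponential lifetimes.

    While bound, the ch2 true position is the partner's position plus an
    i.i.d. Gaussian offset each frame; its own diffusion is suspended and
    resumes from the release position.
    """
    b = cfg.binding
    events = []
    if b is None or b.k_on_script <= 0:
        return events
    p_on = 1.0 - np.exp(-b.k_on_script * cfg.dt)  # per-frame binding probability
    n_frames = max(tr["n"] for tr in ch2_tracks)
    free2 = np.zeros(len(ch2_tracks), dtype=int)  # ch2 free again from this frame
    busy1 = np.zeros(len(ch1_tracks), dtype=int)  # ch1 occupied until this frame
    for t in range(n_frames):
        for i2, tr2 in enumerate(ch2_tracks):
            n2 = tr2["n"]
            if t >= n2 or t < free2[i2] or rng.random() >= p_on:
                continue
            # exclusive partners: a ch1 particle holds one ch2 at a time
            candidates = [
                i1 for i1, tr1 in enumerate(ch1_tracks) if tr1["n"] > t and busy1[i1] <= t
            ]
            if not candidates:
                continue
            i1 = candidates[rng.integers(len(candidates))]
            partner = ch1_tracks[i1]
            lifetime = rng.exponential(b.mean_lifetime)
            want = max(1, int(np.ceil(lifetime / cfg.dt)))
            end = min(t + want - 1, n2 - 1, partner["n"] - 1)
            offs = rng.normal(0.0, b.bound_offset_sd, size=(end - t + 1, 2))
            shift = partner["true_pos"][end] + offs[-1] - tr2["true_pos"][end]
            tr2["true_pos"][t : end + 1] = partner["true_pos"][t : end + 1] + offs
            if end + 1 < n2:
                tr2["true_pos"][end + 1 :] += shift  # resume from release point
            tr2["states"][t : end + 1] = partner["states"][t : end + 1]
            censored = end == min(n2 - 1, partner["n"] - 1) and want > end - t + 1
            events.append(
                {
                    "cell_id": cell_id,
                    "track_ch1": partner["track_id"],
                    "track_ch2": tr2["track_id"],
                    "start_frame": int(t),
                    "end_frame": int(end),
                    "lifetime_s": float(lifetime),
                    "censored": bool(censored),
                }
            )
            free2[i2] = end + 2  # a free frame separates scripted events
            busy1[i1] = end + 2
    return events


def _split_at_binding_starts(ch2_tracks, events):
    """Split channel-2 tracks at scripted binding starts.

    Tethering relocates a particle to its partner, so the frame before a
    binding start and the binding start itself are different molecules'
    worth of motion — exactly like a cytosolic protein appearing at the
    membrane on recruitment in TIRF. Splitting there keeps every emitted
    track internally continuous (no teleport displacement enters any
    downstream displacement statistic). Events are remapped to the
    sub-track that carries them.
    """
    starts = {}
    for e in events:
        starts.setdefault(e["track_ch2"], set()).add(e["start_frame"])
    out = []
    for tr in ch2_tracks:
        cuts = sorted(s for s in starts.get(tr["track_id"], ()) if 0 < s < tr["n"])
        if not cuts:
            out.append(tr)
            continue
        bounds = [0, *cuts, tr["n"]]
        pieces = {}
        for j, (s0, s1) in enumerate(zip(bounds[:-1], bounds[1:])):
            sub = dict(
                tr,
                track_id=f"{tr['track_id']}-{j}",
                start=tr["start"] + s0,
                n=s1 - s0,
                true_pos=tr["true_pos"][s0:s1],
                states=tr["states"][s0:s1],
                intensity=tr["intensity"][s0:s1],
            )
            pieces[(s0, s1)] = sub
            out.append(sub)
        for e in events:
            if e["track_ch2"] == tr["track_id"]:
                for (s0, s1), sub in pieces.items():
                    if s0 <= e["start_frame"] < s1:
                        e["track_ch2"] = sub["track_id"]
                        break
    return out


def simulate_tracks(
    cfg: SimulationConfig, n_cells: int = 1, seed: int | None = None
) -> tuple[TrackSet, dict]:
    """Generate a two-channel TrackSet plus its ground truth.

    Returns ``(trackset, ground_truth)`` where ground truth carries the
    per-frame true state label and true oligomer order of every track and
    the scripted binding intervals (with the continuous lifetime draw, for
    distributional checks).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    gt_tracks, gt_events = [], []
    for c in range(n_cells):
        cell_id = f"c{c:02d}"
        ch1 = _simulate_channel(rng, cfg, cell_id, 1)
        ch2 = _simulate_channel(rng, cfg, cell_id, 2)
        cell_events = _script_binding(rng, cfg, cell_id, ch1, ch2)
        ch2 = _split_at_binding_starts(ch2, cell_events)
        gt_events.extend(cell_events)
        for tr in ch1 + ch2:
            obs = tr["true_pos"] + (
                rng.normal(0.0, cfg.sigma_loc, size=tr["true_pos"].shape)
                if cfg.sigma_loc > 0
                else 0.0
            )
            frames = np.arange(tr["start"], tr["start"] + tr["n"])
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": tr["cell_id"],
                        "channel": tr["channel"],
                        "track_id": tr["track_id"],
                        "frame": frames,
                        "x_um": obs[:, 0],
                        "y_um": obs[:, 1],
                        "intensity": tr["intensity"],
                    }
                )
            )
            gt_tracks.append(
                {
                    "cell_id": tr["cell_id"],
                    "channel": tr["channel"],
                    "track_id": tr["track_id"],
                    "start": int(tr["start"]),
                    "states": [int(s) + 1 for s in tr["states"]],  # 1-based labels
                    "order": int(tr["order"]),
                }
            )
    df = pd.concat(rows, ignore_index=True)[TRACK_COLUMNS]
    meta = {"dt": cfg.dt, "pixel_size": 0.067, "n_frames": cfg.n_frames, "field": cfg.field}
    gt = {"tracks": gt_tracks, "binding_events": gt_events}
    return TrackSet(df, meta), gt


def simulate_assay_series(
    baseline: float,
    amplitude: float,
    rate: float,
    times: np.ndarray,
    noise_cv: float = 0.0,
    seed: int = 0,
):
    """Mono-exponential luminescence kinetics with multiplicative noise.

    counts(t) = baseline * (1 + amplitude * (1 - exp(-rate * t))), each read
    multiplied by (1 + noise_cv * eps) with eps ~ N(0, 1). ``amplitude`` may
    be negative (decay). Deterministic under a fixed seed.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    times = np.asarray(times, dtype=float)
    counts = baseline * (1.0 + amplitude * (1.0 - np.exp(-rate * times)))
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        counts = counts * (1.0 + noise_cv * rng.standard_normal(times.shape))
    return pd.DataFrame({"time_s": times, "count": counts})
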