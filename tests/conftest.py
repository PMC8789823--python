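"""Shared fixtures: synthetic track sets with ground truth.

The expensive acquisition-scale fixtures are session-scoped so the
model-selection run is paid for once and reused by the segmentation,
confinement and colocalization checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import smtrack as st
from smtrack.config import SimulationConfig
from smtrack.vbhmm import StateAssignment


def two_state_config(**overrides) -> SimulationConfig:
    """Balanced, well-separated, unconfined two-state model."""
    base = dict(
        n_states=2,
        D=[0.01, 0.3],
        A=[[0.95, 0.05], [0.05, 0.95]],
        pi=[0.5, 0.5],
        confinement=[None, None],
        sigma_loc=0.0,
        dt=0.03,
        n_frames=100,
        n_tracks=150,
        field=30.0,
        bleach_rate=1.0,
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig.model_validate(base)


def truth_assignment(gt: dict, channel: int, dt_dummy: float = 1.0) -> StateAssignment:
    """StateAssignment built from ground-truth labels (oracle labels)."""
    rows = []
    K = 1
    for tr in gt["tracks"]:
        if tr["channel"] != channel:
            continue
        states = tr["states"]
        K = max(K, max(states))
        # per-frame label convention: displacement leaving the frame; the
        # generator's state at frame t drives the step t -> t+1 already
        start = tr.get("start", 0)
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": tr["cell_id"],
                    "channel": tr["channel"],
                    "track_id": tr["track_id"],
                    "frame": np.arange(start, start + len(states)),
                    "state": states,
                }
            )
        )
    labels = pd.concat(rows, ignore_index=True)
    return StateAssignment(labels=labels, K=K)


@pytest.fixture(scope="session")
def default_sim():
    """One cell of the default acquisition-mimicking configuration."""
    cfg = st.default_config()
    ts, gt = st.simulate_tracks(cfg, n_cells=1, seed=1)
    return cfg, ts, gt


@pytest.fixture(scope="session")
def selection_ch1(default_sim):
    """Lower-bound model selection over K = 1..8 on channel 1."""
    cfg, ts, _ = default_sim
    model, assign, table = st.select_model(
        ts.channel(1), range(1, 9), n_restarts=5, seed=1, sigma_loc=cfg.sigma_loc
    )
    return model, assign, table


def binding_sim(k_on, seed, n_tracks=200, field=100.0):
    """Scripted-binding recovery conditions.

    Sparse field (chance coincidences negligible) and fast diffusion
    (released pairs separate within a frame), so detected events are the
    scripted ones.
    """
    cfg = two_state_config(
        n_states=1, D=[0.3], A=[[1.0]], pi=[1.0], confinement=[None],
        n_tracks=n_tracks, n_frames=300, sigma_loc=0.005, seed=seed, field=field,
        binding=dict(k_on_script=k_on, mean_lifetime=0.3, bound_offset_sd=0.01),
    )
    ts, gt = st.simulate_tracks(cfg, seed=seed)
    a1 = truth_assignment(gt, 1)
    a2 = truth_assignment(gt, 2)
    return cfg, ts, gt, a1, a2


@pytest.fixture(scope="session")
def scripted_binding():
    return binding_sim(k_on=0.6, seed=23)


@pytest.fixture(scope="session")
def two_state_fit():
    """K=2 recovery fit on a balanced well-separated simulation."""
    cfg = two_state_config(seed=11)
    ts, gt = st.simulate_tracks(cfg, seed=11)
    model, assign = st.vb_fit(ts.channel(1), 2, n_restarts=3, seed=3, sigma_loc=0.0)
    return cfg, ts, gt, model, assign
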