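"""Colocalization detection rules and dwell-time kinetics."""

import numpy as np
import pandas as pd
import pytest

import smtrack as st
from smtrack.coloc import chance_coloc_baseline, coloc_kinetics, detect_coloc, exponential_mle
from smtrack.io import TrackSet
from smtrack.vbhmm import StateAssignment

from conftest import truth_assignment, two_state_config

DT = 0.03


def build_pair(xy1, xy2, states1=None, states2=None, n_frames=None):
    """Two single-track channels from coordinate arrays."""
    n1, n2 = len(xy1), len(xy2)
    rows = []
    for ch, xy in ((1, np.asarray(xy1, float)), (2, np.asarray(xy2, float))):
        for f, (x, y) in enumerate(xy):
            rows.append({"cell_id": "c00", "channel": ch, "track_id": f"t{ch}",
                         "frame": f, "x_um": x, "y_um": y, "intensity": 1.0})
    ts = TrackSet(pd.DataFrame(rows), {"dt": DT, "n_frames": n_frames or max(n1, n2)})
    assigns = []
    for ch, n, states in ((1, n1, states1), (2, n2, states2)):
        lab = pd.DataFrame({
            "cell_id": "c00", "channel": ch, "track_id": f"t{ch}",
            "frame": np.arange(n), "state": states if states is not None else 1,
        })
        assigns.append(StateAssignment(labels=lab, K=2))
    return ts, assigns[0], assigns[1]


def test_coincident_tracks_give_one_event_with_full_duration():
    xy = np.zeros((10, 2))
    ts, a1, a2 = build_pair(xy, xy, n_frames=20)
    events = detect_coloc(ts, a1, a2, radius=0.1)
    assert len(events) == 1
    e = events[0]
    assert (e.start_frame, e.end_frame) == (0, 9)
    assert np.isclose(e.duration, 10 * DT)


def test_constant_separation_beyond_radius_gives_no_event():
    xy1 = np.zeros((10, 2))
    xy2 = xy1 + [0.15, 0.0]
    ts, a1, a2 = build_pair(xy1, xy2)
    assert detect_coloc(ts, a1, a2, radius=0.1) == []


def test_same_position_different_state_gives_no_event():
    xy = np.zeros((10, 2))
    ts, a1, a2 = build_pair(xy, xy, states1=np.ones(10, int), states2=np.full(10, 2))
    assert detect_coloc(ts, a1, a2, radius=0.1) == []


def test_single_frame_gap_splits_events():
    xy1 = np.zeros((11, 2))
    xy2 = np.zeros((11, 2))
    xy2[5] = [0.5, 0.5]  # out of range for one frame
    ts, a1, a2 = build_pair(xy1, xy2)
    events = detect_coloc(ts, a1, a2, radius=0.1)
    assert [(e.start_frame, e.end_frame) for e in events] == [(0, 4), (6, 10)]


def test_event_touching_track_end_is_censored():
    xy = np.zeros((8, 2))
    ts, a1, a2 = build_pair(xy, xy, n_frames=50)
    (e,) = detect_coloc(ts, a1, a2, radius=0.1)
    assert e.censored


def test_greedy_matching_is_mutually_exclusive():
    # two ch1 particles near one ch2 particle: only the nearest pairs up
    rows = []
    for tid, x in (("a", 0.0), ("b", 0.05)):
        rows += [{"cell_id": "c00", "channel": 1, "track_id": tid, "frame": f,
                  "x_um": x, "y_um": 0.0, "intensity": 1.0} for f in range(5)]
    rows += [{"cell_id": "c00", "channel": 2, "track_id": "z", "frame": f,
              "x_um": 0.04, "y_um": 0.0, "intensity": 1.0} for f in range(5)]
    ts = TrackSet(pd.DataFrame(rows), {"dt": DT, "n_frames": 10})
    lab1 = pd.DataFrame([{"cell_id": "c00", "channel": 1, "track_id": t, "frame": f, "state": 1}
                         for t in ("a", "b") for f in range(5)])
    lab2 = pd.DataFrame([{"cell_id": "c00", "channel": 2, "track_id": "z", "frame": f, "state": 1}
                         for f in range(5)])
    events = detect_coloc(ts, StateAssignment(lab1, 1), StateAssignment(lab2, 1), radius=0.1)
    assert len(events) == 1
    assert events[0].track_ch1 == "b"  # nearest wins


class TestExponentialMLE:
    def test_uncensored_equals_closed_form_mean_minus_truncation(self):
        rng = np.random.default_rng(0)
        d = DT + rng.exponential(0.3, size=400)
        k, ci = exponential_mle(d, np.zeros(400, bool), truncation=DT)
        assert np.isclose(k, 1.0 / (d.mean() - DT), rtol=1e-12)
        assert ci[0] < k < ci[1]

    def test_censoring_aware_estimate_removes_bias(self):
        rng = np.random.default_rng(1)
        true = rng.exponential(0.3, size=4000) + DT
        cutoff = 0.5
        obs = np.minimum(true, cutoff)
        cens = true > cutoff
        k, _ = exponential_mle(obs, cens, truncation=DT)
        assert abs(1.0 / k - 0.3) < 0.03
        k_naive = 1.0 / (obs.mean() - DT)
        assert k_naive > k  # naive overestimates the rate

    def test_all_censored_is_an_error(self):
        with pytest.raises(ValueError):
            exponential_mle(np.array([1.0]), np.array([True]), truncation=DT)


def test_no_events_reports_zero_rate_and_undefined_koff():
    xy1 = np.zeros((10, 2))
    ts, a1, a2 = build_pair(xy1, xy1 + 5.0)
    summ = coloc_kinetics([], ts.channel(1))
    assert summ.on_rate == 0.0
    assert summ.k_off is None and summ.mean_lifetime is None


from conftest import binding_sim  # noqa: E402  (shared recovery conditions)


def test_scripted_lifetime_recovered_within_15pct(scripted_binding):
    cfg, ts, gt, a1, a2 = scripted_binding
    events = detect_coloc(ts, a1, a2, radius=0.1)
    assert len(events) >= 500
    # exclude the 1-frame bin (dominated by chance/post-release coincidences)
    # and fit with the matching truncation: valid by memorylessness
    keep = [e for e in events if e.end_frame - e.start_frame + 1 >= 2]
    k, _ = exponential_mle(
        np.array([e.duration for e in keep]),
        np.array([e.censored for e in keep]),
        truncation=2 * ts.dt,
    )
    assert abs(1.0 / k - 0.3) / 0.3 < 0.15


def test_on_rate_doubles_with_scripted_kon():
    # low scripted rate so the bound duty cycle stays negligible and the
    # event count is linear in k_on
    _, ts1, gt1, a1, b1 = binding_sim(k_on=0.08, seed=27, n_tracks=250, field=130.0)
    ev1 = detect_coloc(ts1, a1, b1, radius=0.1)
    s1 = coloc_kinetics(ev1, ts1.channel(1))
    _, ts2, gt2, a2, b2 = binding_sim(k_on=0.16, seed=29, n_tracks=250, field=130.0)
    ev2 = detect_coloc(ts2, a2, b2, radius=0.1)
    s2 = coloc_kinetics(ev2, ts2.channel(1))
    # Poisson SE on each rate, propagated to the ratio
    se1 = np.sqrt(s1.n_events) / ts1.channel(1).total_observation_time()
    se2 = np.sqrt(s2.n_events) / ts2.channel(1).total_observation_time()
    ratio = s2.on_rate / s1.on_rate
    se_ratio = ratio * np.sqrt((se1 / s1.on_rate) ** 2 + (se2 / s2.on_rate) ** 2)
    assert abs(ratio - 2.0) < 3 * se_ratio


def test_event_durations_bounded_by_co_observation(scripted_binding):
    cfg, ts, gt, a1, a2 = scripted_binding
    events = detect_coloc(ts, a1, a2, radius=0.1)
    lengths = {(ch, tid): n for (ch, tid), n in
               ts.df.groupby(["channel", "track_id"]).size().items()}
    for e in events:
        co = min(lengths[(1, e.track_ch1)], lengths[(2, e.track_ch2)]) * ts.dt
        assert e.duration <= co + 1e-12


class TestChanceBaseline:
    def test_independent_channels_within_3sd_of_shuffled(self):
        cfg = two_state_config(n_tracks=80, n_frames=120, sigma_loc=0.0, seed=31)
        ts, gt = st.simulate_tracks(cfg, seed=31)
        a1 = truth_assignment(gt, 1)
        a2 = truth_assignment(gt, 2)
        obs = coloc_kinetics(detect_coloc(ts, a1, a2, radius=0.1), ts.channel(1)).on_rate
        mean, sd = chance_coloc_baseline(ts, a1, a2, radius=0.1, n_shuffles=8,
                                         seed=1, field=cfg.field)
        assert abs(obs - mean) <= 3 * max(sd, 1e-6)

    def test_scripted_binding_exceeds_baseline(self, scripted_binding):
        cfg, ts, gt, a1, a2 = scripted_binding
        obs = coloc_kinetics(detect_coloc(ts, a1, a2, radius=0.1), ts.channel(1)).on_rate
        mean, sd = chance_coloc_baseline(ts, a1, a2, radius=0.1, n_shuffles=5,
                                         seed=1, field=cfg.field)
        assert obs > mean + 3 * sd

    def test_empty_channel2_gives_zero_baseline(self):
        xy = np.zeros((10, 2))
        ts, a1, a2 = build_pair(xy, xy)
        df = ts.df[ts.df["channel"] == 1]
        ts1 = TrackSet(df, dict(ts.metadata))
        mean, sd = chance_coloc_baseline(ts1, a1, a2, n_shuffles=2, seed=0, field=5.0)
        assert mean == 0.0
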