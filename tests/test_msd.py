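"""MSD curves, confined-diffusion fits, localization precision."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import smtrack as st
from smtrack.msd import MSDCurve, PrecisionParams, _confined, compute_msd, fit_msd, mortensen_precision

from conftest import two_state_config


def test_hand_computed_linear_track():
    # (0,0),(1,0),(2,0) at dt=1: MSD(1)=1, MSD(2)=4
    curve = compute_msd([np.array([[0.0, 0], [1, 0], [2, 0]])], dt=1.0, max_lag=2)
    assert np.allclose(curve.msd, [1.0, 4.0])
    assert curve.n_pairs.tolist() == [2, 1]


def test_stationary_track_msd_is_zero():
    curve = compute_msd([np.zeros((10, 2))], dt=0.5, max_lag=4)
    assert np.allclose(curve.msd, 0.0)


def test_free_diffusion_matches_4Ddt():
    cfg = two_state_config(n_states=1, D=[0.1], A=[[1.0]], pi=[1.0],
                           confinement=[None], n_tracks=300, n_frames=60,
                           field=60.0, seed=17)
    ts, _ = st.simulate_tracks(cfg, seed=17)
    tracks = [tr.xy for tr in ts.channel(1).tracks()]
    curve = compute_msd(tracks, dt=cfg.dt, max_lag=5)
    # SE across per-track time-averaged MSDs
    for lag_i in range(5):
        lag = lag_i + 1
        per_track = [((t[lag:] - t[:-lag]) ** 2).sum(axis=1).mean() for t in tracks]
        se = np.std(per_track, ddof=1) / np.sqrt(len(per_track))
        assert abs(curve.msd[lag_i] - 4 * 0.1 * lag * cfg.dt) < 3 * se


def test_ensemble_equals_pooled_pair_brute_force():
    rng = np.random.default_rng(3)
    segs = [rng.normal(size=(n, 2)) for n in (2, 3, 5, 4, 7)]
    curve = compute_msd(segs, dt=1.0, max_lag=4)
    for i, lag in enumerate(curve.lags.astype(int)):
        pairs = []
        for s in segs:
            for t in range(len(s) - lag):
                pairs.append(((s[t + lag] - s[t]) ** 2).sum())
        assert np.isclose(curve.msd[i], np.mean(pairs))
        assert curve.n_pairs[i] == len(pairs)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    dx=hst.floats(-50, 50), dy=hst.floats(-50, 50),
    theta=hst.floats(0, 2 * np.pi),
)
def test_msd_invariant_under_rigid_motion(dx, dy, theta):
    rng = np.random.default_rng(5)
    xy = rng.normal(size=(12, 2))
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = xy @ R.T + np.array([dx, dy])
    a = compute_msd([xy], dt=1.0, max_lag=5)
    b = compute_msd([moved], dt=1.0, max_lag=5)
    assert np.allclose(a.msd, b.msd, rtol=1e-9, atol=1e-9)


def test_confined_fit_recovers_generating_parameters_exactly():
    lags = np.arange(1, 11) * 0.03
    y = _confined(lags, 0.05, 0.2, 0.0)
    curve = MSDCurve(lags=lags, msd=y, n_pairs=np.full(10, 100))
    fit = fit_msd(curve, model="confined")
    assert abs(fit.D - 0.05) < 1e-6
    assert abs(fit.L - 0.2) < 1e-6
    assert abs(fit.offset) < 1e-8
    assert not fit.unconfined_flag


@pytest.mark.parametrize("D", np.geomspace(0.005, 0.5, 10))
@pytest.mark.parametrize("L", np.linspace(0.09, 0.5, 10))
def test_confined_fit_grid_recovery_within_10pct(D, L):
    lags = np.arange(1, 11) * 0.0305
    y = _confined(lags, D, L, 0.002)
    curve = MSDCurve(lags=lags, msd=y, n_pairs=np.full(10, 500))
    fit = fit_msd(curve, model="confined")
    if 12 * D * lags[0] / L**2 > 3:
        # plateau reached before the first lag: (D, L, c) are not separately
        # identifiable, only the plateau level is
        plateau_true = L**2 / 3 + 0.002
        plateau_fit = fit.L**2 / 3 + fit.offset
        assert abs(plateau_fit - plateau_true) / plateau_true < 0.01
        return
    assert abs(fit.L - L) / L < 0.10
    assert abs(fit.D - D) / D < 0.10


def test_free_curve_under_confined_model_is_flagged_unconfined():
    lags = np.arange(1, 11) * 0.03
    y = 4 * 0.2 * lags  # no plateau in range
    curve = MSDCurve(lags=lags, msd=y, n_pairs=np.full(10, 100))
    fit = fit_msd(curve, model="confined")
    assert fit.unconfined_flag


def test_free_fit_recovers_slope_and_offset():
    lags = np.arange(1, 8) * 0.5
    curve = MSDCurve(lags=lags, msd=4 * 0.07 * lags + 0.01, n_pairs=np.full(7, 10))
    fit = fit_msd(curve, model="free")
    assert abs(fit.D - 0.07) < 1e-10
    assert abs(fit.offset - 0.01) < 1e-10


class TestMortensenPrecision:
    P = dict(a=0.067, b=2.0, sigma_psf=0.1, F_em=2.0)

    def test_precision_vanishes_monotonically_with_photons(self):
        vals = [mortensen_precision(PrecisionParams(N=n, **self.P))
                for n in (50, 500, 5000, 50000)]
        assert all(x > y for x, y in zip(vals, vals[1:]))
        assert vals[-1] < 0.01

    def test_background_free_reduction(self):
        p = PrecisionParams(N=400, a=0.067, b=0.0, sigma_psf=0.1, F_em=1.0)
        sa = np.sqrt(0.1**2 + 0.067**2 / 12)
        assert np.isclose(mortensen_precision(p), sa * np.sqrt(16 / 9 / 400), rtol=1e-12)

    def test_matches_independent_one_line_evaluation(self):
        p = PrecisionParams(N=311.0, a=0.067, b=3.7, sigma_psf=0.123, F_em=2.0)
        sa2 = p.sigma_psf**2 + p.a**2 / 12
        oracle = np.sqrt(p.F_em * sa2 / p.N * (16 / 9 + 8 * np.pi * sa2 * p.b**2 / (p.N * p.a**2)))
        assert abs(mortensen_precision(p) - oracle) < 1e-12

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PrecisionParams(N=0, a=0.067, b=1, sigma_psf=0.1)
        with pytest.raises(ValueError):
            PrecisionParams(N=100, a=0.067, b=-1, sigma_psf=0.1)


def test_errors_on_inadequate_input():
    with pytest.raises(ValueError):
        compute_msd([np.zeros((1, 2))], dt=1.0, max_lag=2)
    lags = np.arange(1, 4) * 0.1
    curve = MSDCurve(lags=lags, msd=lags, n_pairs=np.ones(3, dtype=int))
    with pytest.raises(ValueError):
        fit_msd(curve, model="confined")  # needs >= 4 lags
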