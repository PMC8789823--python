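"""VB-HMM: oracle equivalence, closed-form recovery, model selection."""

import itertools

import numpy as np
import pytest

import smtrack as st
from smtrack.vbhmm import LOG2PI, Priors, _estep_batch, forward_backward, state_fractions

from conftest import two_state_config


# -- brute-force oracle ------------------------------------------------------

def enumerate_posterior(log_pi, log_A, log_B, per_step=False):
    """Exact chain posterior by enumeration over all K^T label sequences."""
    T, K = log_B.shape
    joint = {}
    for z in itertools.product(range(K), repeat=T):
        lp = log_pi[z[0]] + log_B[0, z[0]]
        for t in range(1, T):
            lp += log_A[z[t - 1], z[t]] + log_B[t, z[t]]
        joint[z] = lp
    lps = np.array(list(joint.values()))
    m = lps.max()
    Z = m + np.log(np.exp(lps - m).sum())
    gamma = np.zeros((T, K))
    xi_steps = np.zeros((max(T - 1, 0), K, K))
    for z, lp in joint.items():
        p = np.exp(lp - Z)
        for t in range(T):
            gamma[t, z[t]] += p
        for t in range(T - 1):
            xi_steps[t, z[t], z[t + 1]] += p
    if per_step:
        return gamma, xi_steps, Z
    return gamma, xi_steps.sum(axis=0), Z


def random_tilde_params(rng, K):
    """Unnormalized expected-log parameters, as the VB E-step uses."""
    log_pi = np.log(rng.dirichlet(np.ones(K))) - rng.uniform(0, 0.3)
    log_A = np.log(rng.dirichlet(np.ones(K), size=K)) - rng.uniform(0, 0.3, size=(K, 1))
    return log_pi, log_A


@pytest.mark.parametrize("T,K", [(3, 2), (6, 2), (5, 3)])
def test_forward_backward_matches_enumeration(T, K):
    rng = np.random.default_rng(100 + T + K)
    log_pi, log_A = random_tilde_params(rng, K)
    log_B = rng.normal(0, 1, size=(T, K))
    gamma, xi, ll = forward_backward(log_pi, log_A, log_B)
    g0, xi0, ll0 = enumerate_posterior(log_pi, log_A, log_B)
    assert np.abs(gamma - g0).max() < 1e-10
    assert np.abs(xi - xi0).max() < 1e-10
    assert abs(ll - ll0) < 1e-8


def test_batched_estep_matches_enumeration_on_tiny_chains():
    # three chains x up to six displacements x K=2, against brute force
    rng = np.random.default_rng(7)
    K = 2
    lengths = [6, 4, 3]
    r2 = np.zeros((3, 6))
    mask = np.zeros((3, 6), dtype=bool)
    for i, L in enumerate(lengths):
        r2[i, :L] = rng.exponential(0.05, size=L)
        mask[i, :L] = True
    log_pi, log_A = random_tilde_params(rng, K)
    lam = np.array([5.0, 60.0])
    ln_lam = np.log(lam) + rng.uniform(-0.1, 0, size=K)  # tilde value < log E[lam]
    gamma, stay, xi_sum, n1, ll = _estep_batch(r2, mask, log_pi, log_A, ln_lam, lam)
    g_exp, xi_exp, n1_exp, ll_exp = [], np.zeros((K, K)), np.zeros(K), 0.0
    for i, L in enumerate(lengths):
        logB = ln_lam[None, :] - LOG2PI - 0.5 * lam[None, :] * r2[i, :L, None]
        g0, xi0_steps, ll0 = enumerate_posterior(log_pi, log_A, logB, per_step=True)
        assert np.abs(gamma[i, :L] - g0).max() < 1e-10
        # per-step diagonal transition posteriors (stay probabilities)
        diag = xi0_steps[:, np.arange(K), np.arange(K)]
        assert np.abs(stay[i, : L - 1] - diag).max() < 1e-10
        xi_exp += xi0_steps.sum(axis=0)
        n1_exp += g0[0]
        ll_exp += ll0
    assert np.abs(xi_sum - xi_exp).max() < 1e-10
    assert np.abs(n1 - n1_exp).max() < 1e-10
    assert abs(ll - ll_exp) < 1e-8


# -- recovery ----------------------------------------------------------------

def test_single_state_variance_recovery_within_sampling_error():
    cfg = two_state_config(n_states=1, D=[0.1], A=[[1.0]], pi=[1.0],
                           confinement=[None], dt=1.0, n_tracks=150,
                           n_frames=100, field=200.0, seed=21)
    ts, _ = st.simulate_tracks(cfg, seed=21)
    model, _ = st.vb_fit(ts.channel(1), 1, n_restarts=1, seed=0)
    n = model.n_displacements
    assert n >= 1e4
    target = 2 * 0.1 * 1.0  # per-axis variance
    se = target * np.sqrt(1.0 / n)  # chi^2 SE over 2n axis samples
    assert abs(model.sigma2[0] - target) < 3 * se
    assert abs(model.D[0] - 0.1) < 3 * se / 2.0


def test_two_state_recovery_of_D_and_transition_diagonal(two_state_fit):
    cfg, ts, gt, model, assign = two_state_fit
    assert model.n_displacements >= 1e4
    for k, D_true in enumerate(cfg.D):
        assert abs(model.D[k] - D_true) / D_true < 0.10
    assert abs(model.A[0, 0] - 0.95) < 0.05
    assert abs(model.A[1, 1] - 0.95) < 0.05


def test_recovered_state_fractions_match_truth(two_state_fit):
    cfg, ts, gt, model, assign = two_state_fit
    frac = state_fractions(assign, per_cell=False).iloc[0]
    true_fracs = []
    for tr in gt["tracks"]:
        if tr["channel"] != 1:
            continue
        s = np.asarray(tr["states"][:-1]) - 1  # displacement labels
        true_fracs.append(np.bincount(s, minlength=2) / len(s))
    true_fracs = np.asarray(true_fracs)
    mean_true = true_fracs.mean(axis=0)
    se = true_fracs.std(axis=0, ddof=1) / np.sqrt(len(true_fracs))
    for k in range(2):
        assert abs(frac[f"frac_{k + 1}"] - mean_true[k]) < 3 * se[k]


# -- structural properties ---------------------------------------------------

def test_lower_bound_is_monotone(two_state_fit):
    *_, model, _ = two_state_fit
    trace = model.elbo_trace
    assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[1:]))


def test_states_canonically_ordered_and_rows_stochastic(two_state_fit):
    *_, model, _ = two_state_fit
    assert np.all(np.diff(model.sigma2) > 0)
    assert np.allclose(model.A.sum(axis=1), 1.0, atol=1e-10)
    assert abs(model.pi.sum() - 1.0) < 1e-10


def test_restart_permutation_invariance():
    # different seeds (hence different perturbed initializations) reach the
    # same canonical model
    cfg = two_state_config(n_tracks=60, n_frames=60, seed=31)
    ts, _ = st.simulate_tracks(cfg, seed=31)
    m1, _ = st.vb_fit(ts.channel(1), 2, n_restarts=3, seed=1)
    m2, _ = st.vb_fit(ts.channel(1), 2, n_restarts=3, seed=99)
    assert np.allclose(m1.sigma2, m2.sigma2, rtol=1e-4)
    assert np.allclose(m1.A, m2.A, atol=1e-3)


def test_fractions_sum_to_one_and_unit_vector_case(two_state_fit):
    *_, assign = two_state_fit
    frac = state_fractions(assign, per_cell=False).iloc[0]
    assert abs(frac["frac_1"] + frac["frac_2"] - 1.0) < 1e-12
    one_state = assign.labels.copy()
    one_state["state"] = 1
    frac1 = state_fractions(st.StateAssignment(labels=one_state, K=2), per_cell=False).iloc[0]
    assert frac1["frac_1"] == 1.0 and frac1["frac_2"] == 0.0


def test_responsibilities_sum_to_one_and_argmax_is_label(two_state_fit):
    *_, assign = two_state_fit
    resp = assign.labels[["resp_1", "resp_2"]].to_numpy()
    assert np.allclose(resp.sum(axis=1), 1.0, atol=1e-9)
    assert (resp.argmax(axis=1) + 1 == assign.labels["state"]).all()


# -- model selection ---------------------------------------------------------

def test_selects_one_state_when_truth_is_single_state():
    cfg = two_state_config(n_states=1, D=[0.1], A=[[1.0]], pi=[1.0],
                           confinement=[None], n_tracks=100, n_frames=80,
                           field=60.0, seed=41)
    ts, _ = st.simulate_tracks(cfg, seed=41)
    model, _, table = st.select_model(ts.channel(1), range(1, 4), n_restarts=2, seed=0)
    assert model.K == 1


def test_redundant_identical_states_collapse_to_one():
    cfg = two_state_config(D=[0.1, 0.1], n_tracks=100, n_frames=80, field=60.0, seed=43)
    ts, _ = st.simulate_tracks(cfg, seed=43)
    model, _, table = st.select_model(ts.channel(1), range(1, 4), n_restarts=2, seed=0)
    assert model.K == 1


def test_errors_on_unusable_input():
    import pandas as pd

    from smtrack.io import TrackSet

    df = pd.DataFrame(
        {"cell_id": ["c0"], "channel": [1], "track_id": ["t0"], "frame": [0],
         "x_um": [0.0], "y_um": [0.0], "intensity": [1.0]}
    )
    ts = TrackSet(df, {"dt": 0.03})
    with pytest.raises(ValueError):
        st.vb_fit(ts, 1)
    with pytest.raises(ValueError):
        st.select_model(ts, [])
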