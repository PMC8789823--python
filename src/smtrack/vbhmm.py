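"""Variational-Bayes HMM over per-frame displacements.

Each track contributes an independent chain of 2-D displacement vectors;
the emission for state k is a zero-mean isotropic Gaussian with per-axis
variance ``sigma2_k``. Conjugate priors (Dirichlet on the initial
distribution and transition rows, Gamma on the per-state precision) give
closed-form coordinate-ascent updates; the variational lower bound is the
sum of chain log-normalizers under the expected-log ("tilde") parameters
minus the Dirichlet/Gamma KL terms, and is monotone over iterations.

States are canonically ordered by ascending sigma2, so for a four-state
membrane-protein fit they read immobile, slow, medium, fast. The diffusion
coefficient is recovered from the displacement variance by subtracting the
static localization-noise contribution:
``D_k = max(0, (sigma2_k - 2 sigma_loc^2) / (2 dt))``.

Model selection fits a range of K and keeps the model with the highest
converged lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from .io import TrackSet

__all__ = [
    "Priors",
    "DiffusionStateModel",
    "StateAssignment",
    "vb_fit",
    "select_model",
    "state_fractions",
    "forward_backward",
]

LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class Priors:
    """Weak conjugate defaults; symmetric Dirichlet(1), Gamma(1e-3, 1e-3)."""

    alpha_pi: float = 1.0
    alpha_A: float = 1.0
    a0: float = 1e-3
    b0: float = 1e-3


@dataclass
class DiffusionStateModel:
    K: int
    sigma2: np.ndarray  # per-state per-axis displacement variance (um^2)
    D: np.ndarray  # um^2/s after localization-noise subtraction
    A: np.ndarray  # row-stochastic transition matrix
    pi: np.ndarray
    lower_bound: float
    alpha_pi: np.ndarray  # Dirichlet counts, initial distribution
    alpha_A: np.ndarray  # Dirichlet counts, transition rows
    gamma_a: np.ndarray  # Gamma shape per state precision
    gamma_b: np.ndarray  # Gamma rate per state precision
    dt: float
    sigma_loc: float
    n_displacements: int
    n_tracks_used: int
    n_tracks_excluded: int
    elbo_trace: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "K": int(self.K),
            "sigma2": self.sigma2.tolist(),
            "D": self.D.tolist(),
            "A": self.A.tolist(),
            "pi": self.pi.tolist(),
            "lower_bound": float(self.lower_bound),
            "hyperparameters": {
                "alpha_pi": self.alpha_pi.tolist(),
                "alpha_A": self.alpha_A.tolist(),
                "gamma_a": self.gamma_a.tolist(),
                "gamma_b": self.gamma_b.tolist(),
            },
            "dt": self.dt,
            "sigma_loc": self.sigma_loc,
            "n_displacements": int(self.n_displacements),
            "n_tracks_used": int(self.n_tracks_used),
            "n_tracks_excluded": int(self.n_tracks_excluded),
        }


@dataclass
class StateAssignment:
    """Per-frame hard labels (1-based) with displacement responsibilities.

    ``labels`` has one row per localization: cell_id, channel, track_id,
    frame, state, resp_1..resp_K, stay_1..stay_K. The per-frame label is
    the label of the displacement leaving that frame; a track's last frame
    inherits the previous label. ``stay_k`` at frame t is the smoothed
    conditional probability that the chain remains in state k across the
    transition to the next displacement, so the posterior probability that
    an entire span stayed in k is resp_k at its first frame times the
    product of stay_k over the span (Markov property).
    """

    labels: pd.DataFrame
    K: int


# -- chain extraction -------------------------------------------------------

def _chains(ts: TrackSet):
    """Squared-displacement chains from consecutive-frame steps.

    Tracks are split at frame gaps; chains shorter than one displacement
    are dropped and counted as excluded.
    """
    chains, keys, excluded = [], [], 0
    for tr in ts.tracks():
        if len(tr) < 2:
            excluded += 1
            continue
        gaps = np.flatnonzero(np.diff(tr.frames) != 1)
        bounds = np.concatenate(([0], gaps + 1, [len(tr.frames)]))
        got = False
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e - s < 2:
                continue
            d = np.diff(tr.xy[s:e], axis=0)
            chains.append((d**2).sum(axis=1))
            keys.append((tr.cell_id, tr.channel, tr.track_id, tr.frames[s:e]))
            got = True
        if not got:
            excluded += 1
    return chains, keys, excluded


def _pad(chains):
    C = len(chains)
    T = max(len(c) for c in chains)
    r2 = np.zeros((C, T))
    mask = np.zeros((C, T), dtype=bool)
    for i, c in enumerate(chains):
        r2[i, : len(c)] = c
        mask[i, : len(c)] = True
    return r2, mask


# -- E-step -----------------------------------------------------------------

def _fb_chain(log_pi: np.ndarray, log_A: np.ndarray, log_B: np.ndarray):
    """Scaled forward-backward for one chain; keeps per-step xi."""
    T, K = log_B.shape
    At = np.exp(log_A)
    shift = log_B.max(axis=1)
    B = np.exp(log_B - shift[:, None])
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = np.exp(log_pi) * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ At) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi = np.zeros((max(T - 1, 0), K, K))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = (At @ bb) / c[t + 1]
        xi[t] = alpha[t][:, None] * At * bb[None, :] / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, xi, float(np.log(c).sum() + shift.sum())


def forward_backward(log_pi: np.ndarray, log_A: np.ndarray, log_B: np.ndarray):
    """Scaled forward-backward for a single chain.

    ``log_B`` is (T, K). Returns (gamma (T, K), xi_sum (K, K), log-normalizer).
    Works with unnormalized ("tilde") parameters, as VB requires.
    """
    gamma, xi, ll = _fb_chain(log_pi, log_A, log_B)
    return gamma, xi.sum(axis=0), ll


try:  # numba accelerates the batched forward-backward; numpy path is the fallback
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco


@_njit(cache=True)
def _fb_kernel(r2, lengths, pi, At, ln_lam, lam):  # pragma: no cover - numba
    C, Tmax = r2.shape
    K = lam.shape[0]
    gamma = np.zeros((C, Tmax, K))
    stay = np.zeros((C, Tmax, K))  # unnormalized xi_t(k,k)
    xi_sum = np.zeros((K, K))
    n1 = np.zeros(K)
    loglik = 0.0
    B = np.empty((Tmax, K))
    alpha = np.empty((Tmax, K))
    beta = np.empty((Tmax, K))
    c = np.empty(Tmax)
    for i in range(C):
        T = lengths[i]
        # scaled emission with per-observation max-shift
        for t in range(T):
            m = -1e300
            for k in range(K):
                e = ln_lam[k] - LOG2PI - 0.5 * lam[k] * r2[i, t]
                B[t, k] = e
                if e > m:
                    m = e
            s = 0.0
            for k in range(K):
                B[t, k] = np.exp(B[t, k] - m)
                s += B[t, k]
            loglik += m
        # forward
        s = 0.0
        for k in range(K):
            alpha[0, k] = pi[k] * B[0, k]
            s += alpha[0, k]
        c[0] = s
        for k in range(K):
            alpha[0, k] /= s
        for t in range(1, T):
            s = 0.0
            for k in range(K):
                a = 0.0
                for j in range(K):
                    a += alpha[t - 1, j] * At[j, k]
                a *= B[t, k]
                alpha[t, k] = a
                s += a
            c[t] = s
            for k in range(K):
                alpha[t, k] /= s
        for t in range(T):
            loglik += np.log(c[t])
        # backward with xi accumulation
        for k in range(K):
            beta[T - 1, k] = 1.0
        for t in range(T - 2, -1, -1):
            for j in range(K):
                b = 0.0
                for k in range(K):
                    bb = B[t + 1, k] * beta[t + 1, k]
                    xi = alpha[t, j] * At[j, k] * bb / c[t + 1]
                    b += At[j, k] * bb
                    xi_sum[j, k] += xi
                    if j == k:
                        stay[i, t, k] = xi
                beta[t, j] = b / c[t + 1]
        for t in range(T):
            s = 0.0
            for k in range(K):
                g = alpha[t, k] * beta[t, k]
                gamma[i, t, k] = g
                s += g
            for k in range(K):
                gamma[i, t, k] /= s
        for k in range(K):
            n1[k] += gamma[i, 0, k]
    return gamma, stay, xi_sum, n1, loglik


def _estep_batch(r2, mask, log_pi, log_A, ln_lam, lam):
    """Batched E-step over padded chains.

    Returns responsibilities gamma (C, T, K), per-step diagonal transition
    posteriors stay (C, T, K) with stay[i, t, k] = xi_t(k, k), pooled xi
    counts (K, K), first-frame counts (K,), and the total log-normalizer.
    """
    lengths = mask.sum(axis=1).astype(np.int64)
    if _HAVE_NUMBA:
        gamma, stay, xi_sum, n1, loglik = _fb_kernel(
            r2, lengths, np.exp(log_pi), np.exp(log_A), ln_lam, lam
        )
        return gamma, stay, xi_sum, n1, float(loglik)
    # pure-numpy fallback: per-chain scaled forward-backward
    C, T = r2.shape
    K = len(lam)
    gamma = np.zeros((C, T, K))
    stay = np.zeros((C, T, K))
    xi_sum = np.zeros((K, K))
    n1 = np.zeros(K)
    loglik = 0.0
    for i in range(C):
        Ti = lengths[i]
        logB = ln_lam[None, :] - LOG2PI - 0.5 * lam[None, :] * r2[i, :Ti, None]
        g, xi, ll = _fb_chain(log_pi, log_A, logB)
        gamma[i, :Ti] = g
        if Ti > 1:
            stay[i, : Ti - 1] = xi[:, np.arange(K), np.arange(K)]
        xi_sum += xi.sum(axis=0)
        n1 += g[0]
        loglik += ll
    return gamma, stay, xi_sum, n1, float(loglik)


# -- KL terms ---------------------------------------------------------------

def _kl_dirichlet(alpha_q: np.ndarray, alpha0: float) -> float:
    a0 = np.full_like(alpha_q, alpha0)
    s_q, s_0 = alpha_q.sum(), a0.sum()
    return float(
        gammaln(s_q)
        - gammaln(s_0)
        - (gammaln(alpha_q).sum() - gammaln(a0).sum())
        + ((alpha_q - a0) * (digamma(alpha_q) - digamma(s_q))).sum()
    )


def _kl_gamma(a_q, b_q, a0, b0) -> float:
    return float(
        np.sum(
            (a_q - a0) * digamma(a_q)
            - gammaln(a_q)
            + gammaln(a0)
            + a0 * (np.log(b_q) - np.log(b0))
            + a_q * (b0 - b_q) / b_q
        )
    )


# -- fit --------------------------------------------------------------------

def _init_responsibilities(r2, mask, K, rng, perturb):
    """Quantile split of log squared displacement into K bins."""
    vals = np.log(r2[mask] + 1e-12)
    edges = np.quantile(vals, np.linspace(0, 1, K + 1)[1:-1]) if K > 1 else []
    labels = np.digitize(np.log(r2 + 1e-12), edges) if K > 1 else np.zeros_like(r2, int)
    if perturb > 0:
        flip = rng.random(labels.shape) < perturb
        labels = np.where(flip, rng.integers(0, K, size=labels.shape), labels)
    gamma = np.zeros((*labels.shape, K))
    np.put_along_axis(gamma, labels[:, :, None], 1.0, axis=2)
    return np.where(mask[:, :, None], gamma, 0.0)


def _mstep(gamma, xi_sum, n1, r2, mask, priors: Priors):
    occ = gamma[mask].sum(axis=0)
    alpha_pi = priors.alpha_pi + n1
    alpha_A = priors.alpha_A + xi_sum
    a = priors.a0 + occ  # d/2 = 1 per 2-D displacement
    b = priors.b0 + 0.5 * (gamma * r2[:, :, None])[mask].sum(axis=0)
    return alpha_pi, alpha_A, a, b


def _expected_logs(alpha_pi, alpha_A, a, b):
    log_pi = digamma(alpha_pi) - digamma(alpha_pi.sum())
    log_A = digamma(alpha_A) - digamma(alpha_A.sum(axis=1))[:, None]
    ln_lam = digamma(a) - np.log(b)
    lam = a / b
    return log_pi, log_A, ln_lam, lam


def _run_vb(r2, mask, K, priors, rng, perturb, max_iter, tol):
    gamma = _init_responsibilities(r2, mask, K, rng, perturb)
    xi0 = np.zeros((K, K))
    # transition counts from the hard initialization
    lab = gamma.argmax(axis=2)
    for i in range(r2.shape[0]):
        T = mask[i].sum()
        for t in range(T - 1):
            xi0[lab[i, t], lab[i, t + 1]] += 1
    alpha_pi, alpha_A, a, b = _mstep(gamma, xi0, gamma[:, 0, :].sum(axis=0), r2, mask, priors)
    elbo_prev = -np.inf
    trace = []
    for it in range(max_iter):
        log_pi, log_A, ln_lam, lam = _expected_logs(alpha_pi, alpha_A, a, b)
        gamma, stay, xi_sum, n1, loglik = _estep_batch(r2, mask, log_pi, log_A, ln_lam, lam)
        elbo = (
            loglik
            - _kl_dirichlet(alpha_pi, priors.alpha_pi)
            - sum(_kl_dirichlet(alpha_A[j], priors.alpha_A) for j in range(K))
            - _kl_gamma(a, b, priors.a0, priors.b0)
        )
        if not np.isfinite(elbo):
            raise FloatingPointError(f"non-finite lower bound at iteration {it}")
        trace.append(elbo)
        if it > 0 and abs(elbo - elbo_prev) < tol * abs(elbo):
            break
        elbo_prev = elbo
        alpha_pi, alpha_A, a, b = _mstep(gamma, xi_sum, n1, r2, mask, priors)
    return np.array(trace), gamma, stay, alpha_pi, alpha_A, a, b


def vb_fit(
    ts: TrackSet,
    K: int,
    priors: Priors | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    sigma_loc: float = 0.0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[DiffusionStateModel, StateAssignment]:
    """Fit a K-state displacement VB-HMM; best of ``n_restarts`` restarts.

    The first restart starts from a clean quantile split of log squared
    displacements; later restarts perturb it. Restart ties break by first
    index. States are reported in ascending-sigma2 order.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    priors = priors or Priors()
    chains, keys, excluded = _chains(ts)
    if not chains:
        raise ValueError("no track has >= 2 consecutive frames")
    r2, mask = _pad(chains)
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        perturb = 0.0 if r == 0 else 0.3
        trace, gamma, stay, alpha_pi, alpha_A, a, b = _run_vb(
            r2, mask, K, priors, rng, perturb, max_iter, tol
        )
        if best is None or trace[-1] > best[0][-1]:
            best = (trace, gamma, stay, alpha_pi, alpha_A, a, b)
    trace, gamma, stay, alpha_pi, alpha_A, a, b = best

    sigma2 = b / a
    order = np.argsort(sigma2)
    sigma2 = sigma2[order]
    alpha_pi = alpha_pi[order]
    alpha_A = alpha_A[np.ix_(order, order)]
    a, b = a[order], b[order]
    gamma = gamma[:, :, order]
    stay = stay[:, :, order]
    A_hat = alpha_A / alpha_A.sum(axis=1, keepdims=True)
    pi_hat = alpha_pi / alpha_pi.sum()
    D = np.maximum(0.0, (sigma2 - 2.0 * sigma_loc**2) / (2.0 * ts.dt))

    model = DiffusionStateModel(
        K=K,
        sigma2=sigma2,
        D=D,
        A=A_hat,
        pi=pi_hat,
        lower_bound=float(trace[-1]),
        alpha_pi=alpha_pi,
        alpha_A=alpha_A,
        gamma_a=a,
        gamma_b=b,
        dt=ts.dt,
        sigma_loc=sigma_loc,
        n_displacements=int(mask.sum()),
        n_tracks_used=len(chains),
        n_tracks_excluded=excluded,
        elbo_trace=trace,
    )
    assignment = _assignment(gamma, stay, mask, keys, K)
    return model, assignment


def _assignment(gamma, stay, mask, keys, K) -> StateAssignment:
    rows = []
    for i, (cell, ch, tid, frames) in enumerate(keys):
        T = int(mask[i].sum())  # displacements
        g = gamma[i, :T, :]
        hard = g.argmax(axis=1) + 1
        # per-frame label: displacement leaving the frame; last frame inherits
        frame_labels = np.concatenate([hard, hard[-1:]])
        resp = np.vstack([g, g[-1:]])
        # conditional stay probability P(z_{t+1}=k | z_t=k, data) per
        # displacement transition; last displacement and frame have none
        cond = np.ones((T + 1, K))
        if T > 1:
            cond[: T - 1] = np.clip(stay[i, : T - 1, :] / np.maximum(g[:-1], 1e-300), 0.0, 1.0)
        df = pd.DataFrame(
            {
                "cell_id": cell,
                "channel": ch,
                "track_id": tid,
                "frame": frames,
                "state": frame_labels,
            }
        )
        for k in range(K):
            df[f"resp_{k + 1}"] = resp[:, k]
        for k in range(K):
            df[f"stay_{k + 1}"] = cond[:, k]
        rows.append(df)
    labels = pd.concat(rows, ignore_index=True)
    return StateAssignment(labels=labels, K=K)


def select_model(
    ts: TrackSet,
    K_range=range(1, 9),
    priors: Priors | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    sigma_loc: float = 0.0,
    **fit_kw,
) -> tuple[DiffusionStateModel, StateAssignment, pd.DataFrame]:
    """Fit every K and return the model with the highest lower bound.

    Also returns the full (K, lower_bound) table for reporting.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    results, rows = {}, []
    for K in K_range:
        model, assign = vb_fit(
            ts, K, priors=priors, n_restarts=n_restarts, seed=seed + K, sigma_loc=sigma_loc, **fit_kw
        )
        results[K] = (model, assign)
        rows.append({"K": K, "lower_bound": model.lower_bound})
    table = pd.DataFrame(rows)
    best_K = int(table.loc[table["lower_bound"].idxmax(), "K"])
    model, assign = results[best_K]
    return model, assign, table


def state_fractions(assignment: StateAssignment, per_cell: bool = True) -> pd.DataFrame:
    """Fraction of displacements per state (per cell by default).

    Each track's last frame inherits the previous displacement label, so it
    is dropped here to count displacements exactly once.
    """
    df = assignment.labels
    if df.empty:
        raise ValueError("empty assignment")
    # drop each track's final (inherited) frame
    last = df.groupby(["cell_id", "channel", "track_id"], sort=False)["frame"].transform("max")
    disp = df[df["frame"] < last]
    group = ["cell_id"] if per_cell else []
    out = []
    for keys, g in disp.groupby(group, sort=True) if group else [((), disp)]:
        counts = g["state"].value_counts().reindex(range(1, assignment.K + 1), fill_value=0)
        frac = counts / counts.sum()
        rec = {"cell_id": keys[0] if group else "all"}
        rec.update({f"frac_{k}": float(frac[k]) for k in range(1, assignment.K + 1)})
        rec["n_displacements"] = int(counts.sum())
        out.append(rec)
    return pd.DataFrame(out)
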