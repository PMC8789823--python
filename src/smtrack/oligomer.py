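"""Oligomer-order estimation from spot-intensity histograms.

A diffraction-limited spot containing n independent emitters has mean
intensity ``n * mu1`` and SD ``sqrt(n) * sigma1``, where (mu1, sigma1)
describe the monomer. The intensity histogram is therefore decomposed by a
constrained Gaussian mixture over orders 1..n_max in which only the weights
(and optionally the monomer parameters) are free. The monomer anchor is
normally estimated from the fast-state population, where the molecules are
assumed monomeric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IntensityMixture", "fit_intensity_mixture", "responsibilities", "compare_orders"]


@dataclass
class IntensityMixture:
    mu1: float
    sigma1: float
    n_max: int
    weights: np.ndarray  # simplex over orders 1..n_max
    log_likelihood: float
    converged: bool

    @property
    def mean_order(self) -> float:
        return float(np.sum(np.arange(1, self.n_max + 1) * self.weights))

    def to_dict(self) -> dict:
        return {
            "mu1": self.mu1,
            "sigma1": self.sigma1,
            "n_max": self.n_max,
            "weights": self.weights.tolist(),
            "mean_order": self.mean_order,
            "log_likelihood": self.log_likelihood,
        }


def _component_logpdf(x, mu1, sigma1, n_max):
    """(len(x), n_max) log N(x; n*mu1, n*sigma1^2) without scipy call overhead."""
    n = np.arange(1, n_max + 1, dtype=float)
    var = n * sigma1**2
    return -0.5 * ((x[:, None] - n[None, :] * mu1) ** 2 / var[None, :]) - 0.5 * np.log(
        2.0 * np.pi * var
    )[None, :]


def responsibilities(x: np.ndarray, mu1: float, sigma1: float, weights: np.ndarray) -> np.ndarray:
    """Posterior P(order | intensity) under the constrained mixture (Bayes)."""
    logp = np.log(np.maximum(weights, 1e-300))[None, :] + _component_logpdf(
        np.asarray(x, float), mu1, sigma1, len(weights)
    )
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def _loglik(x, mu1, sigma1, weights):
    comp = np.log(np.maximum(weights, 1e-300))[None, :] + _component_logpdf(
        x, mu1, sigma1, len(weights)
    )
    m = comp.max(axis=1, keepdims=True)
    return float((m.squeeze(1) + np.log(np.exp(comp - m).sum(axis=1))).sum())


def _em(x, mu1, sigma1, w, fix_anchor, max_iter, tol):
    n = np.arange(1, len(w) + 1, dtype=float)
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        comp = np.log(np.maximum(w, 1e-300))[None, :] + _component_logpdf(x, mu1, sigma1, len(w))
        m = comp.max(axis=1, keepdims=True)
        p = np.exp(comp - m)
        tot = p.sum(axis=1, keepdims=True)
        ll = float((m.squeeze(1) + np.log(tot.squeeze(1))).sum())  # at current params
        r = p / tot
        w = r.mean(axis=0)
        if not fix_anchor:
            mu1 = float((r * x[:, None]).sum() / (r * n[None, :]).sum())
            var = float((r * (x[:, None] - n[None, :] * mu1) ** 2 / n[None, :]).sum() / len(x))
            sigma1 = float(np.sqrt(max(var, 1e-300)))
            if sigma1 < 1e-9 * max(abs(mu1), 1.0):
                raise FloatingPointError("degenerate fit: sigma1 collapsed to 0")
        if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_prev = ll
    ll = _loglik(x, mu1, sigma1, w)
    return mu1, sigma1, w, ll, converged


def fit_intensity_mixture(
    intensities: np.ndarray,
    n_max: int = 4,
    monomer_anchor: tuple[float, float] | None = None,
    seed: int = 0,
    n_starts: int = 3,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> IntensityMixture:
    """EM fit of the integer-multiple Gaussian mixture.

    ``monomer_anchor=(mu1, sigma1)`` fixes the monomer component (the
    fast-state convention); when None both are fitted free. Multistart over
    seeded random weight initializations; best log-likelihood wins.
    """
    x = np.asarray(intensities, dtype=float)
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if len(x) < 50:
        raise ValueError(f"need >= 50 intensity samples, got {len(x)}")
    fix = monomer_anchor is not None
    if fix:
        mu0, sig0 = monomer_anchor
        if sig0 <= 0:
            raise ValueError("anchor sigma1 must be > 0")
    else:
        # moment start: treat the lower half as monomer-ish
        mu0 = float(np.percentile(x, 30))
        sig0 = float(max(x.std() / 2, 1e-6 * max(abs(mu0), 1.0)))
    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, n_starts)):
        w0 = np.full(n_max, 1.0 / n_max) if s == 0 else rng.dirichlet(np.ones(n_max))
        try:
            mu1, sigma1, w, ll, conv = _em(x, mu0, sig0, w0, fix, max_iter, tol)
        except FloatingPointError:
            continue
        if best is None or ll > best[3]:
            best = (mu1, sigma1, w, ll, conv)
    if best is None:
        raise FloatingPointError("degenerate fit: sigma1 collapsed to 0 in every start")
    mu1, sigma1, w, ll, conv = best
    return IntensityMixture(
        mu1=float(mu1), sigma1=float(sigma1), n_max=n_max,
        weights=np.asarray(w), log_likelihood=ll, converged=conv,
    )


def compare_orders(
    intensities_a: np.ndarray,
    intensities_b: np.ndarray,
    n_max: int = 4,
    monomer_anchor: tuple[float, float] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Difference in mean oligomer order (A - B) with a bootstrap CI.

    Nonparametric bootstrap over spots; percentile 95% interval. Both point
    fits must converge.
    """
    xa = np.asarray(intensities_a, dtype=float)
    xb = np.asarray(intensities_b, dtype=float)
    if len(xa) < 50 or len(xb) < 50:
        raise ValueError("insufficient samples for comparison (need >= 50 each)")
    fit_a = fit_intensity_mixture(xa, n_max, monomer_anchor, seed=seed)
    fit_b = fit_intensity_mixture(xb, n_max, monomer_anchor, seed=seed)
    if not (fit_a.converged and fit_b.converged):
        raise RuntimeError("point fits did not converge")
    point = fit_a.mean_order - fit_b.mean_order
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        ra = xa[rng.integers(0, len(xa), len(xa))]
        rb = xb[rng.integers(0, len(xb), len(xb))]
        fa = fit_intensity_mixture(ra, n_max, monomer_anchor, seed=seed, n_starts=1, max_iter=200)
        fb = fit_intensity_mixture(rb, n_max, monomer_anchor, seed=seed, n_starts=1, max_iter=200)
        diffs[i] = fa.mean_order - fb.mean_order
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return {
        "difference": float(point),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "mean_order_a": fit_a.mean_order,
        "mean_order_b": fit_b.mean_order,
        "n_boot": n_boot,
    }
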