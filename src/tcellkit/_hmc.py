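"""Hamiltonian Monte Carlo with dual-averaging step-size adaptation.

A compact fixed-path-length HMC sampler for models that supply an
analytic gradient. Chains run in lockstep so the (vectorised)
log-posterior-and-gradient callback is evaluated once per leapfrog step
for all chains. Adaptation follows the usual scheme: Nesterov dual
averaging of the step size toward a target acceptance rate, and a mass
matrix — dense by default, to decorrelate the linear ridges that
hierarchical models with flat fixed-effect priors produce — estimated
from the chain history midway through warmup.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

__all__ = ["sample_hmc"]


class _Metric:
    """Euclidean metric: momentum draws and kinetic-energy products."""

    def __init__(self, D: int):
        self.set_diag(np.ones(D))

    def set_diag(self, var: np.ndarray) -> None:
        # position-space variance `var`; mass = 1/var
        self._dense = False
        self._var = var
        self._sqrt_mass = 1.0 / np.sqrt(var)

    def set_dense(self, cov: np.ndarray) -> None:
        self._dense = True
        self._cov = cov
        # p ~ N(0, cov^{-1}): p = L^{-T} xi with cov = L L'
        self._chol = linalg.cholesky(cov, lower=True)

    def draw_momentum(self, rng, C: int, D: int) -> np.ndarray:
        xi = rng.standard_normal((C, D))
        if self._dense:
            return linalg.solve_triangular(
                self._chol, xi.T, lower=True, trans="T").T
        return xi * self._sqrt_mass

    def velocity(self, p: np.ndarray) -> np.ndarray:
        # dx/dt = M^{-1} p = cov @ p
        if self._dense:
            return p @ self._cov
        return p * self._var

    def kinetic(self, p: np.ndarray) -> np.ndarray:
        return 0.5 * (p * self.velocity(p)).sum(axis=1)


def _regularised_cov(samples: np.ndarray) -> np.ndarray:
    """Stan-style shrinkage of a sample covariance toward its diagonal."""
    n = len(samples)
    cov = np.cov(samples.T)
    w = n / (n + 5.0)
    reg = w * cov + (1 - w) * 1e-3 * np.eye(cov.shape[0])
    return reg


def sample_hmc(logp_and_grad, x0: np.ndarray, *,
               warmup: int = 600, draws: int = 600,
               n_leapfrog: int = 12, target_accept: float = 0.8,
               seed: int = 0, jitter_leapfrog: int = 2,
               init_step: float = 0.05, dense_mass: bool = True):
    """Sample with HMC; returns (draws (S, C, D), info dict).

    ``logp_and_grad(x)`` maps a (C, D) position array to a (C,) log
    density and its (C, D) gradient. ``x0`` is the (C, D) initial
    position of the C chains. Trajectory length is ``n_leapfrog``
    leapfrog steps, uniformly jittered by ±``jitter_leapfrog`` to avoid
    periodicity. Step size is dual-averaged per chain during warmup; the
    metric is re-estimated from the middle half of warmup. Proposals
    with non-finite energy are rejected and counted as divergences.
    """
    rng = np.random.default_rng(seed)
    x = np.array(x0, float)
    C, D = x.shape
    lp, grad = logp_and_grad(x)
    if not np.isfinite(lp).all():
        raise ValueError("non-finite log density at the initial position")

    metric = _Metric(D)
    eps = np.full(C, init_step)
    mu = np.log(10.0 * eps)
    h_bar = np.zeros(C)
    log_eps_bar = np.log(eps)
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_iter = np.zeros(C)

    win_lo, win_hi = warmup // 4, (3 * warmup) // 4
    history: list[np.ndarray] = []

    out = np.empty((draws, C, D))
    accept_sum = 0.0
    n_divergent = 0

    for it in range(warmup + draws):
        p0 = metric.draw_momentum(rng, C, D)
        xn, gn = x.copy(), grad.copy()
        pn = p0 + 0.5 * eps[:, None] * gn
        steps = max(1, n_leapfrog + int(rng.integers(
            -jitter_leapfrog, jitter_leapfrog + 1)))
        for leap in range(steps):
            xn = xn + eps[:, None] * metric.velocity(pn)
            lpn, gn = logp_and_grad(xn)
            if leap < steps - 1:
                pn = pn + eps[:, None] * gn
        pn = pn + 0.5 * eps[:, None] * gn
        with np.errstate(invalid="ignore", over="ignore"):
            dh = (lpn - lp) - (metric.kinetic(pn) - metric.kinetic(p0))
        finite = np.isfinite(dh)
        if it >= warmup:
            n_divergent += int((~finite).sum())
        alpha = np.where(finite, np.exp(np.minimum(dh, 0.0)), 0.0)
        acc = rng.random(C) < alpha
        x[acc], lp[acc], grad[acc] = xn[acc], lpn[acc], gn[acc]

        if it < warmup:
            adapt_iter += 1
            m = adapt_iter + t0
            h_bar = (1 - 1 / m) * h_bar + (target_accept - alpha) / m
            log_eps = mu - np.sqrt(adapt_iter) / gamma * h_bar
            eta = adapt_iter ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = np.exp(log_eps)
            if win_lo <= it < win_hi:
                history.append(x.copy())
            if it == win_hi and len(history) * C > D + 10:
                samples = np.concatenate(history)
                if dense_mass:
                    metric.set_dense(_regularised_cov(samples))
                else:
                    metric.set_diag(np.clip(samples.var(axis=0),
                                            1e-8, None))
                # restart step-size adaptation around the running value
                mu = np.log(10.0 * np.exp(log_eps_bar))
                h_bar[:] = 0.0
                adapt_iter[:] = 0.0
            if it == warmup - 1:
                eps = np.exp(log_eps_bar)  # smoothed final step size
        else:
            out[it - warmup] = x
            accept_sum += float(alpha.mean())

    info = {
        "step_size": eps.copy(),
        "mean_accept": accept_sum / max(draws, 1),
        "n_divergent": n_divergent,
        "dense_mass": dense_mass,
    }
    return out, info
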