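"""A compact Hamiltonian Monte Carlo sampler for smooth, unconstrained posteriors.

Static-trajectory HMC with dual-averaging step-size adaptation (targeting a
configurable acceptance rate) and a dense mass matrix re-estimated at warmup
checkpoints from the warmup draws — the dense metric matters here because intercept
and random-effect parameters are strongly correlated a posteriori.  The number of
leapfrog steps is a fixed trajectory length divided by the current step size,
jittered ±30% to avoid resonances.  All randomness flows from a single ``numpy``
Generator, so runs are reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HMCConfig", "sample_chain"]


@dataclass
class HMCConfig:
    n_warmup: int = 1000
    n_samples: int = 1000
    target_accept: float = 0.95
    trajectory_length: float = 1.5   # epsilon * n_leapfrog, in metric-scaled units
    max_leapfrog: int = 256
    checkpoint_fractions: tuple = (0.3, 0.6, 0.85)
    divergence_energy: float = 1000.0


class _Metric:
    """Dense inverse-mass matrix Sigma with momentum p ~ N(0, Sigma^{-1})."""

    def __init__(self, sigma: np.ndarray):
        self.sigma = sigma
        self.chol = np.linalg.cholesky(sigma)  # Sigma = L L^T

    def sample_momentum(self, rng, dim):
        # p = L^{-T} z  =>  Cov(p) = (L L^T)^{-1} = Sigma^{-1}
        z = rng.standard_normal(dim)
        return np.linalg.solve(self.chol.T, z)

    def kinetic(self, p):
        return 0.5 * p @ (self.sigma @ p)

    def velocity(self, p):
        return self.sigma @ p


def _find_initial_step(logp_and_grad, q, metric: _Metric, rng):
    """Double/halve until a single leapfrog step has acceptance probability ~0.5."""
    eps = 0.1
    lp, grad = logp_and_grad(q)
    p = metric.sample_momentum(rng, q.size)
    h0 = lp - metric.kinetic(p)

    def one_step(eps_):
        p1 = p + 0.5 * eps_ * grad
        q1 = q + eps_ * metric.velocity(p1)
        lp1, g1 = logp_and_grad(q1)
        p1 = p1 + 0.5 * eps_ * g1
        return lp1 - metric.kinetic(p1)

    delta = one_step(eps) - h0
    if not np.isfinite(delta):
        delta = -np.inf
    direction = 1 if delta > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        delta = one_step(eps)
        delta = delta - h0 if np.isfinite(delta) else -np.inf
        if (direction == 1 and delta <= np.log(0.5)) or (direction == -1 and delta >= np.log(0.5)):
            break
    return eps


def _regularized_cov(window: np.ndarray) -> np.ndarray:
    n, dim = window.shape
    cov = np.cov(window, rowvar=False, ddof=1).reshape(dim, dim)
    shrink = n / (n + 5.0)
    cov = shrink * cov + (1.0 - shrink) * np.diag(np.maximum(np.diag(cov), 1e-8))
    cov += 1e-8 * np.eye(dim)
    return cov


def sample_chain(logp_and_grad, init, config: HMCConfig, seed: int):
    """Run one HMC chain; returns (draws, info).

    ``logp_and_grad(theta) -> (float, ndarray)`` must be the log posterior density
    (up to a constant) and its gradient.  ``draws`` has shape (n_samples, dim) and
    contains post-warmup states only.
    """
    rng = np.random.default_rng(seed)
    q = np.array(init, dtype=float)
    dim = q.size
    metric = _Metric(np.eye(dim))

    eps = _find_initial_step(logp_and_grad, q, metric, rng)
    # dual averaging state; t_da restarts whenever the metric changes
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, t_da = np.log(eps), 0.0, 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    cfg = config
    checkpoints = {int(f * cfg.n_warmup) for f in cfg.checkpoint_fractions}
    window: list[np.ndarray] = []
    draws = np.empty((cfg.n_samples, dim))
    lp, grad = logp_and_grad(q)
    n_div = 0
    accept_sum = 0.0

    for it in range(cfg.n_warmup + cfg.n_samples):
        warming = it < cfg.n_warmup
        step = eps  # during warmup eps holds the current dual-averaging iterate
        L_nominal = max(1, int(cfg.trajectory_length / step))
        lo, hi = max(1, int(0.7 * L_nominal)), max(2, int(1.3 * L_nominal) + 1)
        L = int(min(rng.integers(lo, hi), cfg.max_leapfrog))

        p0 = metric.sample_momentum(rng, dim)
        h0 = lp - metric.kinetic(p0)
        qn, pn, gn, lpn = q, p0, grad, lp
        diverged = False
        pn = pn + 0.5 * step * gn
        for leap in range(L):
            qn = qn + step * metric.velocity(pn)
            lpn, gn = logp_and_grad(qn)
            if not np.isfinite(lpn):
                diverged = True
                break
            pn = pn + (step if leap < L - 1 else 0.5 * step) * gn
        if not diverged:
            delta = (lpn - metric.kinetic(pn)) - h0
            if not np.isfinite(delta) or delta < -cfg.divergence_energy:
                diverged = True
        if diverged:
            alpha = 0.0
            n_div += int(not warming)
        else:
            alpha = min(1.0, np.exp(min(delta, 0.0)))
            if rng.random() < alpha:
                q, lp, grad = qn, lpn, gn

        if warming:
            t_da += 1
            frac = 1.0 / (t_da + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (cfg.target_accept - alpha)
            log_eps = mu - np.sqrt(t_da) / gamma * h_bar
            w = t_da ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = np.exp(log_eps)
            window.append(q.copy())
            if it + 1 in checkpoints and len(window) >= 2 * dim:
                metric = _Metric(_regularized_cov(np.asarray(window)))
                window.clear()
                # restart step-size adaptation around a fresh heuristic value
                eps = _find_initial_step(logp_and_grad, q, metric, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, t_da = np.log(eps), 0.0, 0
            if it == cfg.n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            accept_sum += alpha
            draws[it - cfg.n_warmup] = q

    info = {
        "step_size": float(eps),
        "accept_rate": accept_sum / max(cfg.n_samples, 1),
        "divergences": n_div,
    }
    return draws, info
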