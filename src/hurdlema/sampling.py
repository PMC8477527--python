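"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained gradient-based MCMC kernel operating on an arbitrary target
``logp_grad(theta) -> (logp, grad)`` over an unconstrained parameter vector.
The warmup schedule follows the usual three-phase layout: an initial
step-size-only buffer, a sequence of doubling windows that estimate a
diagonal metric from the warmup draws, and a terminal step-size buffer.
Sampling statistics (acceptance probability, tree depth, divergences) are
recorded per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["SamplerConfig", "NutsResult", "nuts_sample", "find_reasonable_epsilon"]

_MAX_DELTA = 1000.0  # divergence threshold on the energy error


@dataclass
class SamplerConfig:
    """MCMC budget: chains, iterations per chain, warmup share, master seed.

    Defaults mirror common practice for hierarchical regression models:
    4 chains of 2000 iterations with the first half used as warmup, leaving
    4 x 1000 retained draws.
    """

    n_chains: int = 4
    n_iter: int = 2000
    n_warmup: int | None = None
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10

    def __post_init__(self) -> None:
        if self.n_warmup is None:
            self.n_warmup = self.n_iter // 2
        if not self.n_warmup < self.n_iter:
            raise ValueError("n_warmup must be < n_iter")
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for Rhat")

    @property
    def n_keep(self) -> int:
        return self.n_iter - self.n_warmup

    def chain_seeds(self) -> list[np.random.Generator]:
        """Deterministic fan-out of the master seed into per-chain generators."""
        return [np.random.Generator(np.random.PCG64(s))
                for s in np.random.SeedSequence(self.seed).spawn(self.n_chains)]


@dataclass
class NutsResult:
    samples: np.ndarray  # (n_keep, dim)
    accept_prob: np.ndarray
    treedepth: np.ndarray
    divergent: np.ndarray
    step_size: float
    inv_mass: np.ndarray


def _kinetic(p, inv_mass):
    with np.errstate(over="ignore", invalid="ignore"):
        return 0.5 * np.dot(p * inv_mass, p)


def _leapfrog(logp_grad, theta, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    theta = theta + eps * (p * inv_mass)
    lp, grad = logp_grad(theta)
    p = p + 0.5 * eps * grad
    return theta, p, lp, grad


def find_reasonable_epsilon(logp_grad, theta, rng, inv_mass) -> float:
    """Heuristic initial step size: double/halve until acceptance crosses 0.5."""
    eps = 1.0
    lp, grad = logp_grad(theta)
    p = rng.standard_normal(len(theta)) / np.sqrt(inv_mass)
    h0 = lp - _kinetic(p, inv_mass)
    _, p1, lp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, inv_mass)
    h1 = lp1 - _kinetic(p1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    a = 1.0 if h1 - h0 > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** a
        _, p1, lp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, inv_mass)
        h1 = lp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if a * (h1 - h0) <= a * np.log(0.5):
            break
    return eps


class _Tree:
    __slots__ = ("theta_minus", "p_minus", "grad_minus", "theta_plus", "p_plus",
                 "grad_plus", "theta_prop", "n_valid", "stop", "alpha", "n_alpha",
                 "divergent")


def _build_tree(logp_grad, theta, p, grad, log_u, v, depth, eps, h0, inv_mass, rng):
    t = _Tree()
    if depth == 0:
        theta1, p1, lp1, grad1 = _leapfrog(logp_grad, theta, p, grad, v * eps, inv_mass)
        h1 = lp1 - _kinetic(p1, inv_mass) if np.isfinite(lp1) else -np.inf
        t.theta_minus = t.theta_plus = t.theta_prop = theta1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = grad1
        t.n_valid = int(log_u <= h1)
        t.divergent = (h1 - log_u) < -_MAX_DELTA or not np.isfinite(h1)
        t.stop = t.divergent
        t.alpha = min(1.0, np.exp(min(0.0, h1 - h0)))
        t.n_alpha = 1
        return t
    # recursively double
    t = _build_tree(logp_grad, theta, p, grad, log_u, v, depth - 1, eps, h0,
                    inv_mass, rng)
    if not t.stop:
        if v == -1:
            t2 = _build_tree(logp_grad, t.theta_minus, t.p_minus, t.grad_minus,
                             log_u, v, depth - 1, eps, h0, inv_mass, rng)
            t.theta_minus, t.p_minus, t.grad_minus = (
                t2.theta_minus, t2.p_minus, t2.grad_minus)
        else:
            t2 = _build_tree(logp_grad, t.theta_plus, t.p_plus, t.grad_plus,
                             log_u, v, depth - 1, eps, h0, inv_mass, rng)
            t.theta_plus, t.p_plus, t.grad_plus = (
                t2.theta_plus, t2.p_plus, t2.grad_plus)
        if t2.n_valid and rng.random() < t2.n_valid / max(t.n_valid + t2.n_valid, 1):
            t.theta_prop = t2.theta_prop
        t.n_valid += t2.n_valid
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
        t.stop = t2.stop or _uturn(t.theta_minus, t.theta_plus, t.p_minus,
                                   t.p_plus, inv_mass)
        t.divergent = t.divergent or t2.divergent
    return t


def _uturn(theta_minus, theta_plus, p_minus, p_plus, inv_mass):
    d = theta_plus - theta_minus
    return (np.dot(d, p_minus * inv_mass) < 0) or (np.dot(d, p_plus * inv_mass) < 0)


def _nuts_step(logp_grad, theta, lp, grad, eps, inv_mass, max_treedepth, rng):
    p0 = rng.standard_normal(len(theta)) / np.sqrt(inv_mass)
    h0 = lp - _kinetic(p0, inv_mass)
    log_u = h0 + np.log(rng.random())
    theta_minus = theta_plus = theta
    p_minus = p_plus = p0
    grad_minus = grad_plus = grad
    theta_new, n_valid, depth = theta, 1, 0
    divergent = False
    alpha_sum, n_alpha = 0.0, 0
    while depth < max_treedepth:
        v = -1 if rng.random() < 0.5 else 1
        if v == -1:
            t = _build_tree(logp_grad, theta_minus, p_minus, grad_minus, log_u,
                            v, depth, eps, h0, inv_mass, rng)
            theta_minus, p_minus, grad_minus = t.theta_minus, t.p_minus, t.grad_minus
        else:
            t = _build_tree(logp_grad, theta_plus, p_plus, grad_plus, log_u,
                            v, depth, eps, h0, inv_mass, rng)
            theta_plus, p_plus, grad_plus = t.theta_plus, t.p_plus, t.grad_plus
        alpha_sum += t.alpha
        n_alpha += t.n_alpha
        divergent = divergent or t.divergent
        if t.stop:
            break
        if t.n_valid and rng.random() < t.n_valid / n_valid:
            theta_new = t.theta_prop
        n_valid += t.n_valid
        depth += 1
        if _uturn(theta_minus, theta_plus, p_minus, p_plus, inv_mass):
            break
    lp_new, grad_new = logp_grad(theta_new)
    return theta_new, lp_new, grad_new, alpha_sum / max(n_alpha, 1), depth, divergent


def _warmup_windows(n_warmup: int):
    """(start, end, adapt_metric) phases: buffers 15%/10%, doubling windows between."""
    init_buf = max(1, int(round(0.15 * n_warmup)))
    term_buf = max(1, int(round(0.10 * n_warmup)))
    windows = [(0, init_buf, False)]
    pos, size = init_buf, 25
    while pos < n_warmup - term_buf:
        end = min(pos + size, n_warmup - term_buf)
        if n_warmup - term_buf - end < size:  # fold the remainder in
            end = n_warmup - term_buf
        windows.append((pos, end, True))
        pos, size = end, size * 2
    windows.append((n_warmup - term_buf, n_warmup, False))
    return windows


def nuts_sample(
    logp_grad: Callable,
    theta0: np.ndarray,
    config_or_warmup,
    n_keep: int | None = None,
    rng: np.random.Generator | None = None,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> NutsResult:
    """Run one NUTS chain. Accepts a SamplerConfig or (n_warmup, n_keep)."""
    if isinstance(config_or_warmup, SamplerConfig):
        cfg = config_or_warmup
        n_warmup, n_keep = cfg.n_warmup, cfg.n_keep
        target_accept, max_treedepth = cfg.target_accept, cfg.max_treedepth
        if rng is None:
            rng = cfg.chain_seeds()[0]
    else:
        n_warmup = int(config_or_warmup)
        assert n_keep is not None and rng is not None

    theta = np.array(theta0, dtype=float)
    dim = len(theta)
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    eps = find_reasonable_epsilon(logp_grad, theta, rng, inv_mass)
    # dual averaging state
    mu = np.log(10 * eps)
    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    samples = np.empty((n_keep, dim))
    accept = np.empty(n_warmup + n_keep)
    depths = np.empty(n_warmup + n_keep, dtype=int)
    divs = np.zeros(n_warmup + n_keep, dtype=bool)

    windows = _warmup_windows(n_warmup)
    win_idx = 0
    win_buf: list[np.ndarray] = []

    for it in range(n_warmup + n_keep):
        theta, lp, grad, a, depth, div = _nuts_step(
            logp_grad, theta, lp, grad, eps, inv_mass, max_treedepth, rng)
        accept[it], depths[it], divs[it] = a, depth, div

        if it < n_warmup:
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - a)
            log_eps = mu - np.sqrt(da_count) / gamma * h_bar
            w = da_count ** -kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = np.exp(log_eps)

            start, end, adapt_metric = windows[win_idx]
            if adapt_metric:
                win_buf.append(theta.copy())
            if it + 1 == end:
                if adapt_metric and len(win_buf) > 4:
                    arr = np.asarray(win_buf)
                    n = len(arr)
                    var = arr.var(axis=0, ddof=1)
                    inv_mass = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
                    eps = find_reasonable_epsilon(logp_grad, theta, rng, inv_mass)
                    mu = np.log(10 * eps)
                    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
                win_buf = []
                win_idx = min(win_idx + 1, len(windows) - 1)
            if it + 1 == n_warmup:
                eps = np.exp(log_eps_bar)
        else:
            samples[it - n_warmup] = theta

    return NutsResult(samples=samples, accept_prob=accept[n_warmup:],
                      treedepth=depths[n_warmup:], divergent=divs[n_warmup:],
                      step_size=float(eps), inv_mass=inv_mass)
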