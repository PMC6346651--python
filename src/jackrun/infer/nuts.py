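"""Hamiltonian Monte Carlo with No-U-Turn trajectory termination.

Multinomial NUTS with dual-averaging step-size adaptation and windowed
diagonal mass-matrix estimation during warmup.  The sampler operates on an
unconstrained parameter vector and needs only a function returning the log
density and its gradient.  Trajectories are grown by doubling until the
no-U-turn criterion fires or the maximum tree depth is reached; leaves are
sampled with multinomial weights, and a leaf whose Hamiltonian error exceeds
the divergence threshold marks the transition divergent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NUTSOptions", "nuts_chain"]


@dataclass
class NUTSOptions:
    max_treedepth: int = 8
    target_accept: float = 0.8
    divergence_threshold: float = 1000.0
    init_jitter: float = 1.0


@dataclass
class _DualAverage:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    mu: float
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    target: float = 0.8
    count: int = 0
    h_bar: float = 0.0
    log_eps_bar: float = 0.0

    def update(self, accept_stat: float) -> float:
        self.count += 1
        eta = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Welford:
    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def push(self, x: np.ndarray) -> None:
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self) -> np.ndarray:
        # regularized toward unit scale, as in Stan's windowed adaptation
        var = self.m2 / max(self.n - 1, 1)
        w = self.n / (self.n + 5.0)
        return w * var + (1 - w) * 1e-3


class _Tree:
    __slots__ = (
        "z_minus", "r_minus", "g_minus", "z_plus", "r_plus", "g_plus",
        "z_prop", "lp_prop", "g_prop", "logw", "sum_accept", "n_leaf",
        "diverged", "turning",
    )


def _leapfrog(logp_grad, z, r, g, eps, inv_mass):
    r1 = r + 0.5 * eps * g
    z1 = z + eps * inv_mass * r1
    lp1, g1 = logp_grad(z1)
    r1 = r1 + 0.5 * eps * g1
    return z1, r1, g1, lp1


def _kinetic(r, inv_mass) -> float:
    return 0.5 * float(np.dot(r * r, inv_mass))


def _is_turning(z_minus, r_minus, z_plus, r_plus, inv_mass) -> bool:
    dz = z_plus - z_minus
    return (
        float(np.dot(dz, inv_mass * r_minus)) < 0
        or float(np.dot(dz, inv_mass * r_plus)) < 0
    )


def _build_tree(logp_grad, z, r, g, depth, direction, eps, h0, inv_mass,
                opts, rng) -> _Tree:
    t = _Tree()
    if depth == 0:
        z1, r1, g1, lp1 = _leapfrog(logp_grad, z, r, g, direction * eps, inv_mass)
        h1 = lp1 - _kinetic(r1, inv_mass) if np.isfinite(lp1) else -np.inf
        logw = h1 - h0
        t.z_minus = t.z_plus = t.z_prop = z1
        t.r_minus = t.r_plus = r1
        t.g_minus = t.g_plus = t.g_prop = g1
        t.lp_prop = lp1
        t.logw = logw
        t.sum_accept = float(min(1.0, np.exp(min(logw, 0.0)))) if np.isfinite(logw) else 0.0
        t.n_leaf = 1
        t.diverged = (not np.isfinite(logw)) or (logw < -opts.divergence_threshold)
        t.turning = False
        return t

    first = _build_tree(logp_grad, z, r, g, depth - 1, direction, eps, h0,
                        inv_mass, opts, rng)
    if first.diverged or first.turning:
        return first
    if direction == 1:
        second = _build_tree(logp_grad, first.z_plus, first.r_plus, first.g_plus,
                             depth - 1, direction, eps, h0, inv_mass, opts, rng)
        first.z_plus, first.r_plus, first.g_plus = (
            second.z_plus, second.r_plus, second.g_plus)
    else:
        second = _build_tree(logp_grad, first.z_minus, first.r_minus, first.g_minus,
                             depth - 1, direction, eps, h0, inv_mass, opts, rng)
        first.z_minus, first.r_minus, first.g_minus = (
            second.z_minus, second.r_minus, second.g_minus)

    first.sum_accept += second.sum_accept
    first.n_leaf += second.n_leaf
    first.diverged = second.diverged
    logw_tot = np.logaddexp(first.logw, second.logw)
    # within-subtree multinomial sampling
    if np.isfinite(second.logw) and np.log(rng.uniform()) < second.logw - logw_tot:
        first.z_prop, first.lp_prop, first.g_prop = (
            second.z_prop, second.lp_prop, second.g_prop)
    first.logw = logw_tot
    first.turning = second.turning or _is_turning(
        first.z_minus, first.r_minus, first.z_plus, first.r_plus, inv_mass
    )
    return first


def _nuts_step(logp_grad, z, lp, g, eps, inv_mass, opts, rng):
    r0 = rng.standard_normal(len(z)) / np.sqrt(inv_mass)
    h0 = lp - _kinetic(r0, inv_mass)

    t = _Tree()
    t.z_minus = t.z_plus = t.z_prop = z
    t.r_minus = t.r_plus = r0
    t.g_minus = t.g_plus = t.g_prop = g
    t.lp_prop = lp
    t.logw = 0.0

    sum_accept = 0.0
    n_leaf = 0
    diverged = False
    depth = 0
    while depth < opts.max_treedepth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(logp_grad, t.z_plus, t.r_plus, t.g_plus, depth,
                              1, eps, h0, inv_mass, opts, rng)
        else:
            sub = _build_tree(logp_grad, t.z_minus, t.r_minus, t.g_minus, depth,
                              -1, eps, h0, inv_mass, opts, rng)
        sum_accept += sub.sum_accept
        n_leaf += sub.n_leaf
        if sub.diverged:
            diverged = True
            break
        if sub.turning:
            break
        # biased progressive sampling toward the new subtree
        if np.log(rng.uniform()) < sub.logw - t.logw:
            t.z_prop, t.lp_prop, t.g_prop = sub.z_prop, sub.lp_prop, sub.g_prop
        t.logw = np.logaddexp(t.logw, sub.logw)
        if direction == 1:
            t.z_plus, t.r_plus, t.g_plus = sub.z_plus, sub.r_plus, sub.g_plus
        else:
            t.z_minus, t.r_minus, t.g_minus = sub.z_minus, sub.r_minus, sub.g_minus
        if _is_turning(t.z_minus, t.r_minus, t.z_plus, t.r_plus, inv_mass):
            depth += 1
            break
        depth += 1

    accept_stat = sum_accept / max(n_leaf, 1)
    energy = -t.lp_prop + _kinetic(r0, inv_mass)  # energy at trajectory start draw
    return t.z_prop, t.lp_prop, t.g_prop, accept_stat, depth, n_leaf, diverged, energy


def _find_reasonable_epsilon(logp_grad, z, lp, g, inv_mass, rng) -> float:
    eps = 1.0
    r = rng.standard_normal(len(z)) / np.sqrt(inv_mass)
    h0 = lp - _kinetic(r, inv_mass)
    _, r1, _, lp1 = _leapfrog(logp_grad, z, r, g, eps, inv_mass)
    h1 = lp1 - _kinetic(r1, inv_mass) if np.isfinite(lp1) else -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, r1, _, lp1 = _leapfrog(logp_grad, z, r, g, eps, inv_mass)
        h1 = lp1 - _kinetic(r1, inv_mass) if np.isfinite(lp1) else -np.inf
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return max(eps, 1e-8)


def _adapt_windows(n_warmup: int) -> list[tuple[int, int]]:
    """(start, end) iteration ranges of the mass-matrix estimation windows."""
    init_buf = max(15, int(0.15 * n_warmup))
    term_buf = max(10, int(0.1 * n_warmup))
    windows = []
    start = init_buf
    size = max(25, int(0.1 * n_warmup))
    while start + size < n_warmup - term_buf:
        end = start + size
        if end + 2 * size >= n_warmup - term_buf:
            end = n_warmup - term_buf
        windows.append((start, end))
        start = end
        size *= 2
    if not windows and n_warmup > init_buf + term_buf + 10:
        windows.append((init_buf, n_warmup - term_buf))
    return windows


def nuts_chain(logp_grad, z0, n_warmup, n_draws, rng, opts: NUTSOptions | None = None):
    """Run one NUTS chain; returns (draws, stats) with warmup discarded."""
    opts = opts or NUTSOptions()
    dim = len(z0)
    inv_mass = np.ones(dim)
    z = np.asarray(z0, dtype=float).copy()
    lp, g = logp_grad(z)
    if not np.isfinite(lp):
        raise RuntimeError("non-finite log density at the initial point")

    eps = _find_reasonable_epsilon(logp_grad, z, lp, g, inv_mass, rng)
    da = _DualAverage(mu=np.log(10.0 * eps), target=opts.target_accept)
    windows = _adapt_windows(n_warmup)
    welford = _Welford(dim)
    win_idx = 0

    draws = np.empty((n_draws, dim))
    stats = {
        "lp": np.empty(n_draws),
        "energy": np.empty(n_draws),
        "accept_stat": np.empty(n_draws),
        "treedepth": np.empty(n_draws, dtype=int),
        "n_leapfrog": np.empty(n_draws, dtype=int),
        "diverging": np.zeros(n_draws, dtype=bool),
        "step_size": np.empty(n_draws),
    }

    for it in range(n_warmup + n_draws):
        z, lp, g, acc, depth, n_leaf, div, energy = _nuts_step(
            logp_grad, z, lp, g, eps, inv_mass, opts, rng
        )
        if it < n_warmup:
            eps = da.update(acc)
            if win_idx < len(windows):
                w0, w1 = windows[win_idx]
                if w0 <= it < w1:
                    welford.push(z)
                if it == w1 - 1:
                    inv_mass = welford.variance()
                    welford = _Welford(dim)
                    win_idx += 1
                    eps = _find_reasonable_epsilon(logp_grad, z, lp, g, inv_mass, rng)
                    da = _DualAverage(mu=np.log(10.0 * eps),
                                      target=opts.target_accept)
            if it == n_warmup - 1:
                eps = da.adapted
        else:
            k = it - n_warmup
            draws[k] = z
            stats["lp"][k] = lp
            stats["energy"][k] = energy
            stats["accept_stat"][k] = acc
            stats["treedepth"][k] = depth
            stats["n_leapfrog"][k] = n_leaf
            stats["diverging"][k] = div
            stats["step_size"][k] = eps

    return draws, stats
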