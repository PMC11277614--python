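"""No-U-Turn Hamiltonian Monte Carlo sampler on an unconstrained space.

A self-contained NUTS implementation (doubling tree with slice sampling,
dual-averaging step-size adaptation toward a target acceptance statistic,
and a diagonal mass matrix estimated during warmup in expanding windows).
The target is supplied as a callable returning the log density and its
gradient; constrained parameters are handled by the model layer through
bijective transforms with Jacobian corrections.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NutsResult", "nuts_chain"]

_MAX_DELTA_ENERGY = 1000.0  # divergence threshold on the energy error


@dataclass
class NutsResult:
    draws: np.ndarray          # (n_draws, dim)
    logp: np.ndarray           # (n_draws,)
    divergences: int           # divergent transitions after warmup
    step_size: float
    inv_mass: np.ndarray       # diagonal inverse mass matrix
    accept_stat: float         # mean acceptance statistic after warmup
    treedepths: np.ndarray     # (n_draws,)


class _Tree:
    __slots__ = (
        "x_minus", "r_minus", "g_minus", "x_plus", "r_plus", "g_plus",
        "x_prop", "logp_prop", "g_prop", "n_valid", "stop", "sum_accept",
        "n_accept", "divergent",
    )


def _leapfrog(logp_grad, x, r, g, eps, inv_mass):
    r1 = r + 0.5 * eps * g
    x1 = x + eps * inv_mass * r1
    logp1, g1 = logp_grad(x1)
    r2 = r1 + 0.5 * eps * g1
    return x1, r2, logp1, g1


def _kinetic(r, inv_mass):
    return 0.5 * float(np.dot(r, inv_mass * r))


def _no_uturn(x_minus, x_plus, r_minus, r_plus, inv_mass):
    dx = x_plus - x_minus
    return (
        float(np.dot(dx, inv_mass * r_minus)) >= 0.0
        and float(np.dot(dx, inv_mass * r_plus)) >= 0.0
    )


def _build_tree(logp_grad, x, r, g, log_u, direction, depth, eps, joint0,
                inv_mass, rng):
    """Recursively double the trajectory; classic slice-sampling NUTS."""
    t = _Tree()
    if depth == 0:
        x1, r1, logp1, g1 = _leapfrog(logp_grad, x, r, g, direction * eps, inv_mass)
        joint = logp1 - _kinetic(r1, inv_mass)
        t.x_minus = t.x_plus = t.x_prop = x1
        t.r_minus = t.r_plus = r1
        t.g_minus = t.g_plus = t.g_prop = g1
        t.logp_prop = logp1
        t.n_valid = int(log_u <= joint)
        t.divergent = not np.isfinite(joint) or (log_u - _MAX_DELTA_ENERGY) > joint
        t.stop = t.divergent
        t.sum_accept = float(np.exp(min(0.0, joint - joint0)))
        t.n_accept = 1
        return t

    left = _build_tree(logp_grad, x, r, g, log_u, direction, depth - 1, eps,
                       joint0, inv_mass, rng)
    if left.stop:
        return left
    if direction == -1:
        right = _build_tree(logp_grad, left.x_minus, left.r_minus, left.g_minus,
                            log_u, direction, depth - 1, eps, joint0, inv_mass, rng)
        left.x_minus, left.r_minus, left.g_minus = (
            right.x_minus, right.r_minus, right.g_minus)
    else:
        right = _build_tree(logp_grad, left.x_plus, left.r_plus, left.g_plus,
                            log_u, direction, depth - 1, eps, joint0, inv_mass, rng)
        left.x_plus, left.r_plus, left.g_plus = (
            right.x_plus, right.r_plus, right.g_plus)

    total = left.n_valid + right.n_valid
    if total > 0 and rng.random() < right.n_valid / total:
        left.x_prop = right.x_prop
        left.logp_prop = right.logp_prop
        left.g_prop = right.g_prop
    left.n_valid = total
    left.sum_accept += right.sum_accept
    left.n_accept += right.n_accept
    left.divergent = left.divergent or right.divergent
    left.stop = (
        right.stop
        or not _no_uturn(left.x_minus, left.x_plus, left.r_minus, left.r_plus,
                         inv_mass)
    )
    return left


def _find_initial_step(logp_grad, x, logp, g, inv_mass, rng):
    """Heuristic: double/halve eps until the one-step accept prob crosses 0.5."""
    eps = 1.0
    r = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    joint0 = logp - _kinetic(r, inv_mass)
    _, r1, logp1, _ = _leapfrog(logp_grad, x, r, g, eps, inv_mass)
    joint1 = logp1 - _kinetic(r1, inv_mass)
    if not np.isfinite(joint1):
        joint1 = -np.inf
    direction = 1 if (joint1 - joint0) > np.log(0.5) else -1
    for _ in range(100):
        eps *= 2.0 ** direction
        _, r1, logp1, _ = _leapfrog(logp_grad, x, r, g, eps, inv_mass)
        joint1 = logp1 - _kinetic(r1, inv_mass)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction * (joint1 - joint0) <= direction * np.log(0.5):
            break
    return eps


def _adapt_windows(n_warmup):
    """Stan-style warmup schedule: init buffer, expanding covariance windows,
    terminal step-size buffer. Returns iterations at which to update the mass."""
    init_buf, term_buf, base = 75, 50, 25
    if n_warmup < init_buf + term_buf + base:
        # short warmup: single window over the middle 70%
        return [int(n_warmup * 0.85)], int(n_warmup * 0.15)
    ends = []
    start = init_buf
    size = base
    while start + size < n_warmup - term_buf:
        if start + 3 * size >= n_warmup - term_buf:
            size = n_warmup - term_buf - start
        ends.append(start + size)
        start += size
        size *= 2
    return ends, init_buf


def nuts_chain(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    progress_label: str | None = None,
) -> NutsResult:
    """Run one NUTS chain and return post-warmup draws."""
    x = np.array(x0, dtype=float)
    dim = x.size
    logp, g = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    inv_mass = np.ones(dim)
    window_ends, init_buf = _adapt_windows(n_warmup)
    window_ends = set(window_ends)

    eps = _find_initial_step(logp_grad, x, logp, g, inv_mass, rng)
    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_iter = 0

    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    depths = np.zeros(n_draws, dtype=int)
    divergences = 0
    accept_sum, accept_n = 0.0, 0

    sys.setrecursionlimit(max(10_000, sys.getrecursionlimit()))
    total = n_warmup + n_draws
    for it in range(total):
        warming = it < n_warmup
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = logp - _kinetic(r0, inv_mass)
        log_u = joint0 + np.log(rng.random())
        x_minus = x_plus = x
        r_minus = r_plus = r0
        g_minus = g_plus = g
        x_prop, logp_prop, g_prop = x, logp, g
        n_valid, depth = 1, 0
        sum_accept, n_accept = 0.0, 0
        divergent = False
        while depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == -1:
                t = _build_tree(logp_grad, x_minus, r_minus, g_minus, log_u,
                                direction, depth, eps, joint0, inv_mass, rng)
                x_minus, r_minus, g_minus = t.x_minus, t.r_minus, t.g_minus
            else:
                t = _build_tree(logp_grad, x_plus, r_plus, g_plus, log_u,
                                direction, depth, eps, joint0, inv_mass, rng)
                x_plus, r_plus, g_plus = t.x_plus, t.r_plus, t.g_plus
            sum_accept += t.sum_accept
            n_accept += t.n_accept
            divergent = divergent or t.divergent
            if t.stop:
                break
            if t.n_valid > 0 and rng.random() < t.n_valid / n_valid:
                x_prop, logp_prop, g_prop = t.x_prop, t.logp_prop, t.g_prop
            n_valid += t.n_valid
            depth += 1
            if not _no_uturn(x_minus, x_plus, r_minus, r_plus, inv_mass):
                break
        x, logp, g = x_prop, logp_prop, g_prop
        accept_prob = sum_accept / max(n_accept, 1)

        if warming:
            da_iter += 1
            h_bar = (1 - 1 / (da_iter + t0)) * h_bar + (
                (target_accept - accept_prob) / (da_iter + t0))
            log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
            w = da_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it >= init_buf:
                welford_n += 1
                delta = x - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (x - welford_mean)
            if (it + 1) in window_ends and welford_n > 4:
                var = welford_m2 / (welford_n - 1)
                # regularize toward unit scale as Stan does
                inv_mass = (welford_n / (welford_n + 5.0)) * var + (
                    1e-3 * 5.0 / (welford_n + 5.0))
                welford_n = 0
                welford_mean[:] = 0.0
                welford_m2[:] = 0.0
                # restart step-size adaptation around the current eps
                eps = _find_initial_step(logp_grad, x, logp, g, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            i = it - n_warmup
            draws[i] = x
            logps[i] = logp
            depths[i] = depth
            divergences += int(divergent)
            accept_sum += accept_prob
            accept_n += 1

    return NutsResult(
        draws=draws,
        logp=logps,
        divergences=divergences,
        step_size=eps,
        inv_mass=inv_mass,
        accept_stat=accept_sum / max(accept_n, 1),
        treedepths=depths,
    )
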