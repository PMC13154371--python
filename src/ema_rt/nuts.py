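"""No-U-Turn sampler (NUTS) over a differentiable log density.

A self-contained gradient-based MCMC backend for the hierarchical RT model:
dynamic Hamiltonian Monte Carlo with slice-based multinomial selection over
the doubling trajectory, a generalized U-turn criterion under a diagonal
metric, dual-averaging step-size adaptation toward a target acceptance
statistic, and windowed estimation of the diagonal mass matrix during
warmup.

The target is supplied as ``logp_and_grad(x) -> (float, ndarray)``; the
sampler never needs the model's structure.  Positions producing non-finite
log density or gradient are treated as divergent leapfrog states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["sample_nuts", "NutsStats"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NutsStats:
    """Per-chain adaptation and trajectory diagnostics."""

    step_size: float
    inv_mass: np.ndarray
    accept_mean: float
    n_divergent: int
    treedepth_mean: float
    max_treedepth_hits: int
    logp: np.ndarray = field(default_factory=lambda: np.empty(0))


def _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass):
    with np.errstate(over="ignore", invalid="ignore"):
        p = p + 0.5 * eps * grad
        q = q + eps * inv_mass * p
    if not np.all(np.isfinite(q)):
        return q, p, -np.inf, grad
    logp, grad_new = logp_and_grad(q)
    if not np.isfinite(logp) or not np.all(np.isfinite(grad_new)):
        return q, p, -np.inf, grad_new
    p = p + 0.5 * eps * grad_new
    return q, p, logp, grad_new


def _kinetic(p, inv_mass):
    with np.errstate(over="ignore", invalid="ignore"):
        k = 0.5 * float(np.dot(p, inv_mass * p))
    return k if math.isfinite(k) else math.inf


def _find_reasonable_epsilon(logp_and_grad, q, rng, inv_mass):
    eps = 1.0
    logp, grad = logp_and_grad(q)
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(p, inv_mass)
    _, p1, logp1, _ = _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass)
    h1 = logp1 - _kinetic(p1, inv_mass) if np.isfinite(logp1) else -np.inf
    direction = 1.0 if (h1 - h0) > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        _, p1, logp1, _ = _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass) if np.isfinite(logp1) else -np.inf
        if direction * (h1 - h0) <= direction * math.log(0.5):
            break
    return eps


class _Tree:
    """Recursive trajectory doubling (slice variant, generalized U-turn)."""

    def __init__(self, logp_and_grad, eps, inv_mass, log_u, h0, rng):
        self.f = logp_and_grad
        self.eps = eps
        self.inv_mass = inv_mass
        self.log_u = log_u
        self.h0 = h0
        self.rng = rng
        self.divergent = False
        self.sum_alpha = 0.0
        self.n_alpha = 0

    def build(self, q, p, grad, v, depth):
        """Returns (q-, p-, grad-, q+, p+, grad+, q_prop, grad_prop,
        logp_prop, n_valid, keep_going)."""
        if depth == 0:
            q1, p1, logp1, grad1 = _leapfrog(
                self.f, q, p, grad, v * self.eps, self.inv_mass)
            h1 = logp1 - _kinetic(p1, self.inv_mass) \
                if np.isfinite(logp1) else -np.inf
            n_valid = 1 if self.log_u <= h1 else 0
            diverged = (h1 - self.log_u) < -_DIVERGENCE_THRESHOLD
            if diverged:
                self.divergent = True
            self.sum_alpha += min(1.0, math.exp(min(0.0, h1 - self.h0)))
            self.n_alpha += 1
            return (q1, p1, grad1, q1, p1, grad1, q1, grad1, logp1,
                    n_valid, not diverged)
        (qm, pm, gm, qp, pp, gp, qprop, gprop, lprop, n1, keep) = \
            self.build(q, p, grad, v, depth - 1)
        if not keep:
            return qm, pm, gm, qp, pp, gp, qprop, gprop, lprop, n1, False
        if v < 0:
            (qm, pm, gm, _, _, _, qprop2, gprop2, lprop2, n2, keep2) = \
                self.build(qm, pm, gm, v, depth - 1)
        else:
            (_, _, _, qp, pp, gp, qprop2, gprop2, lprop2, n2, keep2) = \
                self.build(qp, pp, gp, v, depth - 1)
        if n2 > 0 and self.rng.random() < n2 / max(n1 + n2, 1):
            qprop, gprop, lprop = qprop2, gprop2, lprop2
        dq = qp - qm
        keep = (keep2
                and float(np.dot(dq, self.inv_mass * pm)) >= 0
                and float(np.dot(dq, self.inv_mass * pp)) >= 0)
        return qm, pm, gm, qp, pp, gp, qprop, gprop, lprop, n1 + n2, keep


def _nuts_step(logp_and_grad, q, logp, grad, eps, inv_mass, rng,
               max_treedepth):
    p0 = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(p0, inv_mass)
    log_u = h0 - rng.exponential()
    tree = _Tree(logp_and_grad, eps, inv_mass, log_u, h0, rng)
    qm = qp = q
    pm = pp = p0
    gm = gp = grad
    q_cur, grad_cur, logp_cur = q, grad, logp
    n_valid = 1
    depth = 0
    while depth < max_treedepth:
        v = 1 if rng.random() < 0.5 else -1
        if v < 0:
            (qm, pm, gm, _, _, _, qprop, gprop, lprop, n_new, keep) = \
                tree.build(qm, pm, gm, v, depth)
        else:
            (_, _, _, qp, pp, gp, qprop, gprop, lprop, n_new, keep) = \
                tree.build(qp, pp, gp, v, depth)
        if keep and n_new > 0 and rng.random() < n_new / n_valid:
            q_cur, grad_cur, logp_cur = qprop, gprop, lprop
        n_valid += n_new
        depth += 1
        if not keep:
            break
        dq = qp - qm
        if (float(np.dot(dq, inv_mass * pm)) < 0
                or float(np.dot(dq, inv_mass * pp)) < 0):
            break
    alpha = tree.sum_alpha / max(tree.n_alpha, 1)
    return q_cur, logp_cur, grad_cur, alpha, tree.divergent, depth


def _adaptation_windows(n_warmup):
    """(step-size-only head, list of mass windows, step-size-only tail)."""
    if n_warmup < 60:
        return n_warmup, [], 0
    head = max(int(0.15 * n_warmup), 10)
    tail = max(int(0.10 * n_warmup), 10)
    middle = n_warmup - head - tail
    windows, w = [], max(middle // 8, 25)
    pos = 0
    while pos < middle:
        if pos + 3 * w >= middle:
            windows.append(middle - pos)
            break
        windows.append(w)
        pos += w
        w *= 2
    return head, windows, tail


def sample_nuts(
    logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.95,
    max_treedepth: int = 10,
) -> tuple[np.ndarray, NutsStats]:
    """Run one chain; returns post-warmup draws ``(n_draws, dim)`` + stats."""
    q = np.array(x0, dtype=float)
    dim = q.size
    logp, grad = logp_and_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    inv_mass = np.ones(dim)

    eps = _find_reasonable_epsilon(logp_and_grad, q, rng, inv_mass)
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    head, windows, tail = _adaptation_windows(n_warmup)
    boundaries = []
    pos = head
    for w in windows:
        pos += w
        boundaries.append(pos)
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    accepts, depths = [], []
    n_div = 0
    max_hits = 0

    for it in range(n_warmup + n_draws):
        q, logp, grad, alpha, div, depth = _nuts_step(
            logp_and_grad, q, logp, grad, eps, inv_mass, rng, max_treedepth)
        in_warmup = it < n_warmup
        if in_warmup:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - alpha)
            log_eps = mu - math.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = math.exp(log_eps)
            if boundaries and it >= head:
                welford_n += 1
                delta = q - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (q - welford_mean)
                if it + 1 == boundaries[0]:
                    boundaries.pop(0)
                    if welford_n > 1:
                        var = welford_m2 / (welford_n - 1)
                        w = welford_n / (welford_n + 5.0)
                        inv_mass = w * var + (1 - w) * 1e-3
                        welford_n = 0
                        welford_mean[:] = 0.0
                        welford_m2[:] = 0.0
                        eps = _find_reasonable_epsilon(
                            logp_and_grad, q, rng, inv_mass)
                        mu = math.log(10.0 * eps)
                        h_bar, log_eps_bar, adapt_count = 0.0, 0.0, 0
            if it + 1 == n_warmup:
                eps = math.exp(log_eps_bar) if adapt_count > 0 else eps
        else:
            j = it - n_warmup
            draws[j] = q
            logps[j] = logp
            accepts.append(alpha)
            depths.append(depth)
            n_div += int(div)
            max_hits += int(depth >= max_treedepth)

    stats = NutsStats(
        step_size=eps, inv_mass=inv_mass,
        accept_mean=float(np.mean(accepts)) if accepts else float("nan"),
        n_divergent=n_div,
        treedepth_mean=float(np.mean(depths)) if depths else float("nan"),
        max_treedepth_hits=max_hits,
        logp=logps,
    )
    return draws, stats
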