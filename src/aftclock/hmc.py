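"""An adaptive Hamiltonian Monte Carlo sampler with NUTS-style trajectories.

Each draw builds a binary leapfrog tree that doubles in a random direction
until the trajectory makes a U-turn (the No-U-Turn criterion) or hits a
depth cap, then samples a point from it with multinomial weights.  Warmup
adapts the step size by dual averaging toward a target acceptance rate and
estimates a diagonal mass matrix over two expanding windows, Stan-style.

The sampler is generic: it only needs a callable returning the log target
density and its gradient.  Determinism is guaranteed by the caller-supplied
numpy Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_DIVERGENCE_ENERGY = 1000.0


@dataclass
class ChainResult:
    draws: np.ndarray          # (n_draws, dim)
    accept_rate: float
    divergences: int
    step_size: float
    n_leapfrog: int            # mean leapfrog steps per iteration


class _Tree:
    """One NUTS trajectory; mutable state shared across subtree builds."""

    __slots__ = (
        "f", "eps", "inv_mass", "rng", "h0", "x_prop", "logp_prop",
        "grad_prop", "log_w", "sum_accept", "n_leaves", "divergent",
        "n_grad",
    )

    def __init__(self, f, eps, inv_mass, rng, h0):
        self.f = f
        self.eps = eps
        self.inv_mass = inv_mass
        self.rng = rng
        self.h0 = h0
        self.log_w = -np.inf
        self.sum_accept = 0.0
        self.n_leaves = 0
        self.divergent = False
        self.n_grad = 0

    def leaf(self, x, p, grad, logp, direction):
        """One leapfrog step; returns (state, log weight) or None on divergence."""
        eps = direction * self.eps
        p1 = p + 0.5 * eps * grad
        x1 = x + eps * self.inv_mass * p1
        logp1, grad1 = self.f(x1)
        self.n_grad += 1
        if not np.isfinite(logp1):
            self.divergent = True
            return None
        p1 = p1 + 0.5 * eps * grad1
        h = -logp1 + 0.5 * float(np.sum(self.inv_mass * p1 * p1))
        log_w = self.h0 - h
        self.sum_accept += min(1.0, math.exp(min(0.0, log_w)))
        self.n_leaves += 1
        if -log_w > _DIVERGENCE_ENERGY:
            self.divergent = True
            return None
        return (x1, p1, logp1, grad1), log_w


def _build(tree: _Tree, state, depth, direction):
    """Recursively build a subtree; returns (minus, plus, proposal, log_w, ok)
    where proposal is (x, logp, grad) sampled multinomially from the subtree."""
    if depth == 0:
        out = tree.leaf(state[0], state[1], state[3], state[2], direction)
        if out is None:
            return None
        st, log_w = out
        prop = (st[0], st[2], st[3])
        return st, st, prop, log_w

    first = _build(tree, state, depth - 1, direction)
    if first is None:
        return None
    minus, plus, prop, log_w = first
    edge = plus if direction > 0 else minus
    second = _build(tree, edge, depth - 1, direction)
    if second is None:
        return None
    minus2, plus2, prop2, log_w2 = second
    if direction > 0:
        plus = plus2
    else:
        minus = minus2
    total = np.logaddexp(log_w, log_w2)
    if math.log(tree.rng.uniform() + 1e-300) < log_w2 - total:
        prop = prop2
    if _uturn(minus, plus, tree.inv_mass):
        return None
    return minus, plus, prop, total


def _uturn(minus, plus, inv_mass) -> bool:
    dx = plus[0] - minus[0]
    return (
        float(dx @ (inv_mass * minus[1])) < 0.0
        or float(dx @ (inv_mass * plus[1])) < 0.0
    )


def nuts_draw(f, x, logp, grad, eps, inv_mass, rng, max_depth=8):
    """One NUTS draw; returns (x, logp, grad, accept_stat, n_grad, divergent)."""
    dim = x.size
    p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
    h0 = -logp + 0.5 * float(np.sum(inv_mass * p0 * p0))
    tree = _Tree(f, eps, inv_mass, rng, h0)
    minus = plus = (x, p0, logp, grad)
    prop = (x, logp, grad)
    log_w = 0.0   # the initial point carries weight exp(h0 - h0) = 1

    for depth in range(max_depth):
        direction = 1 if rng.uniform() < 0.5 else -1
        edge = plus if direction > 0 else minus
        sub = _build(tree, edge, depth, direction)
        if sub is None:
            break
        minus2, plus2, prop2, log_w2 = sub
        if direction > 0:
            plus = plus2
        else:
            minus = minus2
        # progressive multinomial sampling between old tree and new subtree
        if math.log(rng.uniform() + 1e-300) < log_w2 - np.logaddexp(log_w, log_w2):
            prop = prop2
        log_w = np.logaddexp(log_w, log_w2)
        if _uturn(minus, plus, inv_mass):
            break

    accept_stat = tree.sum_accept / max(1, tree.n_leaves)
    return prop[0], prop[1], prop[2], accept_stat, tree.n_grad, tree.divergent


def find_reasonable_epsilon(f, x, logp, grad, inv_mass, rng) -> float:
    """Double/halve a unit step until the one-step acceptance probability
    crosses 0.5 (the classic step-size initializer)."""
    dim = x.size
    eps = 1.0
    p = rng.standard_normal(dim) / np.sqrt(inv_mass)
    h0 = -logp + 0.5 * float(np.sum(inv_mass * p * p))

    def delta_h(eps):
        p1 = p + 0.5 * eps * grad
        x1 = x + eps * inv_mass * p1
        logp1, grad1 = f(x1)
        if not np.isfinite(logp1):
            return -np.inf
        p2 = p1 + 0.5 * eps * grad1
        with np.errstate(over="ignore"):
            h = -logp1 + 0.5 * float(np.sum(inv_mass * p2 * p2))
        return h0 - h if np.isfinite(h) else -np.inf

    dh = delta_h(eps)
    direction = 1.0 if dh > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        dh = delta_h(eps)
        if (direction > 0 and dh <= math.log(0.5)) or (
            direction < 0 and dh >= math.log(0.5)
        ):
            break
        if eps < 1e-10 or eps > 1e7:
            break
    return float(eps)


def sample_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    rng: np.random.Generator,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    target_accept: float = 0.8,
    max_depth: int = 8,
    init_step: float | None = None,
) -> ChainResult:
    """Run one NUTS chain and return post-warmup draws."""
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    logp, grad = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    inv_mass = np.ones(dim)
    if init_step is None:
        init_step = find_reasonable_epsilon(logp_grad, x, logp, grad, inv_mass, rng)
    eps = init_step
    # dual averaging state (Hoffman & Gelman defaults)
    mu = math.log(10.0 * init_step)
    log_eps_bar, h_bar = math.log(init_step), 0.0
    da_iter = 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    windows = [
        (int(0.15 * n_warmup), int(0.40 * n_warmup)),
        (int(0.40 * n_warmup), int(0.85 * n_warmup)),
    ]
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    accept_sum = 0.0
    divergences = 0
    total_grad = 0
    n_total = n_warmup + n_draws

    for it in range(n_total):
        x, logp, grad, accept_stat, n_grad, divergent = nuts_draw(
            logp_grad, x, logp, grad, eps, inv_mass, rng, max_depth
        )
        total_grad += n_grad
        if it >= n_warmup:
            accept_sum += accept_stat
            if divergent:
                divergences += 1
            draws[it - n_warmup] = x
            continue

        da_iter += 1
        m = da_iter
        h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept_stat) / (m + t0)
        log_eps = mu - math.sqrt(m) / gamma * h_bar
        w = m ** (-kappa)
        log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
        eps = float(np.exp(log_eps))
        if any(lo <= it < hi for lo, hi in windows):
            welford_n += 1
            delta = x - welford_mean
            welford_mean += delta / welford_n
            welford_m2 += delta * (x - welford_mean)
        if any(it == hi - 1 for _, hi in windows) and welford_n > 10:
            var = welford_m2 / (welford_n - 1)
            # regularize toward unit scale as Stan does for short windows
            var = (welford_n / (welford_n + 5.0)) * var + 1e-3 * (5.0 / (welford_n + 5.0))
            inv_mass = np.maximum(var, 1e-10)
            welford_n = 0
            welford_mean = np.zeros(dim)
            welford_m2 = np.zeros(dim)
            eps = find_reasonable_epsilon(logp_grad, x, logp, grad, inv_mass, rng)
            mu = math.log(10.0 * max(eps, 1e-10))
            log_eps_bar, h_bar = math.log(max(eps, 1e-10)), 0.0
            da_iter = 0
        if it == n_warmup - 1:
            eps = float(np.exp(log_eps_bar))

    return ChainResult(
        draws=draws,
        accept_rate=accept_sum / max(1, n_draws),
        divergences=divergences,
        step_size=eps,
        n_leapfrog=int(total_grad / n_total),
    )
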