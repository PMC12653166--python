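"""A compact No-U-Turn sampler with dual-averaging step-size adaptation and
diagonal mass-matrix estimation.

Multinomial NUTS (Betancourt 2017 formulation) with the generalized
no-U-turn criterion, a Stan-like three-phase warmup schedule and divergence
tracking.  Works on any target exposing ``logp_grad(q) -> (logp, grad)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NUTSResult", "nuts_sample"]

_MAX_DELTA_H = 1000.0  # energy error treated as a divergence


@dataclass
class NUTSResult:
    positions: np.ndarray  # (draws, dim) post-warmup positions
    step_size: float
    inv_mass: np.ndarray
    accept_rate: float
    n_divergent: int
    treedepths: np.ndarray = field(repr=False, default=None)


class _Target:
    def __init__(self, logp_grad):
        self._fn = logp_grad
        self.n_evals = 0

    def __call__(self, q):
        self.n_evals += 1
        logp, grad = self._fn(q)
        if not np.isfinite(logp):
            logp = -np.inf
            grad = np.zeros_like(q)
        return logp, grad


def _leapfrog(target, q, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    logp, grad = target(q)
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def _kinetic(p, inv_mass):
    return 0.5 * float(p @ (inv_mass * p))


class _Tree:
    """State accumulated while doubling a trajectory."""

    __slots__ = (
        "q_minus", "p_minus", "grad_minus",
        "q_plus", "p_plus", "grad_plus",
        "q_prop", "logp_prop", "log_sum_weight",
        "sum_p", "divergent", "sum_accept", "n_leapfrog",
    )


def _build_tree(target, tree_depth, q, p, grad, direction, eps, inv_mass, h0, rng):
    """Recursively build one subtree; returns (_Tree, valid) where valid is
    False when the subtree contains a divergence or an internal U-turn."""
    if tree_depth == 0:
        q1, p1, logp1, grad1 = _leapfrog(target, q, p, grad, direction * eps, inv_mass)
        h1 = -logp1 + _kinetic(p1, inv_mass)
        delta_h = h1 - h0
        t = _Tree()
        t.q_minus = t.q_plus = t.q_prop = q1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = grad1
        t.logp_prop = logp1
        t.log_sum_weight = -delta_h if np.isfinite(delta_h) else -np.inf
        t.sum_p = p1.copy()
        t.divergent = bool(delta_h > _MAX_DELTA_H or not np.isfinite(delta_h))
        t.sum_accept = float(np.exp(min(0.0, -delta_h))) if np.isfinite(delta_h) else 0.0
        t.n_leapfrog = 1
        return t, not t.divergent

    inner, ok = _build_tree(
        target, tree_depth - 1, q, p, grad, direction, eps, inv_mass, h0, rng
    )
    if not ok:
        return inner, False
    if direction == 1:
        outer, ok = _build_tree(
            target, tree_depth - 1, inner.q_plus, inner.p_plus, inner.grad_plus,
            direction, eps, inv_mass, h0, rng,
        )
        inner.q_plus = outer.q_plus
        inner.p_plus = outer.p_plus
        inner.grad_plus = outer.grad_plus
    else:
        outer, ok = _build_tree(
            target, tree_depth - 1, inner.q_minus, inner.p_minus, inner.grad_minus,
            direction, eps, inv_mass, h0, rng,
        )
        inner.q_minus = outer.q_minus
        inner.p_minus = outer.p_minus
        inner.grad_minus = outer.grad_minus

    total = np.logaddexp(inner.log_sum_weight, outer.log_sum_weight)
    if np.isfinite(outer.log_sum_weight) and np.log(rng.uniform()) < (
        outer.log_sum_weight - total
    ):
        inner.q_prop = outer.q_prop
        inner.logp_prop = outer.logp_prop
    inner.log_sum_weight = total
    inner.sum_p = inner.sum_p + outer.sum_p
    inner.divergent = inner.divergent or outer.divergent
    inner.sum_accept += outer.sum_accept
    inner.n_leapfrog += outer.n_leapfrog
    if not ok:
        return inner, False

    # generalized no-U-turn condition across the merged subtree
    turning = (
        float(inner.sum_p @ (inv_mass * inner.p_minus)) <= 0
        or float(inner.sum_p @ (inv_mass * inner.p_plus)) <= 0
    )
    return inner, not turning


def _nuts_step(target, q, logp, grad, eps, inv_mass, max_treedepth, rng):
    dim = q.shape[0]
    p = rng.standard_normal(dim) / np.sqrt(inv_mass)
    h0 = -logp + _kinetic(p, inv_mass)

    t = _Tree()
    t.q_minus = t.q_plus = t.q_prop = q
    t.p_minus = t.p_plus = p
    t.grad_minus = t.grad_plus = grad
    t.logp_prop = logp
    t.log_sum_weight = 0.0
    t.sum_p = p.copy()
    t.divergent = False
    t.sum_accept = 0.0
    t.n_leapfrog = 0

    depth = 0
    while depth < max_treedepth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub, ok = _build_tree(
                target, depth, t.q_plus, t.p_plus, t.grad_plus,
                direction, eps, inv_mass, h0, rng,
            )
            t.q_plus, t.p_plus, t.grad_plus = sub.q_plus, sub.p_plus, sub.grad_plus
        else:
            sub, ok = _build_tree(
                target, depth, t.q_minus, t.p_minus, t.grad_minus,
                direction, eps, inv_mass, h0, rng,
            )
            t.q_minus, t.p_minus, t.grad_minus = sub.q_minus, sub.p_minus, sub.grad_minus

        t.sum_accept += sub.sum_accept
        t.n_leapfrog += sub.n_leapfrog
        t.divergent = t.divergent or sub.divergent
        if not ok:
            break
        # biased progressive sampling toward the new subtree
        if np.isfinite(sub.log_sum_weight) and np.log(rng.uniform()) < (
            sub.log_sum_weight - t.log_sum_weight
        ):
            t.q_prop = sub.q_prop
            t.logp_prop = sub.logp_prop
        t.log_sum_weight = np.logaddexp(t.log_sum_weight, sub.log_sum_weight)
        t.sum_p = t.sum_p + sub.sum_p
        depth += 1
        turning = (
            float(t.sum_p @ (inv_mass * t.p_minus)) <= 0
            or float(t.sum_p @ (inv_mass * t.p_plus)) <= 0
        )
        if turning:
            break

    accept_stat = t.sum_accept / max(t.n_leapfrog, 1)
    return t.q_prop, t.logp_prop, accept_stat, t.divergent, depth


def _find_initial_step(target, q, logp, grad, inv_mass, rng):
    eps = 1.0
    p = rng.standard_normal(q.shape[0]) / np.sqrt(inv_mass)
    h0 = -logp + _kinetic(p, inv_mass)
    _, p1, logp1, _ = _leapfrog(target, q, p, grad, eps, inv_mass)
    h1 = -logp1 + _kinetic(p1, inv_mass)
    delta = h0 - h1 if np.isfinite(h1) else -np.inf
    direction = 1.0 if delta > np.log(0.8) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, logp1, _ = _leapfrog(target, q, p, grad, eps, inv_mass)
        h1 = -logp1 + _kinetic(p1, inv_mass)
        delta = h0 - h1 if np.isfinite(h1) else -np.inf
        if direction == 1.0 and delta <= np.log(0.8):
            break
        if direction == -1.0 and delta >= np.log(0.8):
            break
    return max(eps, 1e-8)


def _adaptation_windows(warmup: int) -> list[int]:
    """Iteration indices at which the mass matrix is re-estimated."""
    if warmup < 20:
        return []
    init = max(int(0.15 * warmup), 1)
    term = max(int(0.1 * warmup), 1)
    ends = []
    start, size = init, max(int(0.0625 * warmup), 5)
    while start + size < warmup - term:
        ends.append(start + size)
        start += size
        size *= 2
    ends.append(warmup - term)
    return ends


def nuts_sample(
    logp_grad,
    init: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> NUTSResult:
    """Run one NUTS chain; returns post-warmup positions and diagnostics."""
    target = _Target(logp_grad)
    q = np.array(init, dtype=float)
    dim = q.shape[0]
    logp, grad = target(q)
    if not np.isfinite(logp):
        raise ValueError("non-finite log density at the initial point")

    inv_mass = np.ones(dim)
    eps = _find_initial_step(target, q, logp, grad, inv_mass, rng)

    # dual averaging state; m_da restarts whenever the metric changes
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar, m_da = 0.0, 0.0, 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    window_ends = _adaptation_windows(n_warmup)
    win_sum = np.zeros(dim)
    win_sumsq = np.zeros(dim)
    win_count = 0

    n_divergent = 0
    accept_sum = 0.0
    positions = np.empty((n_draws, dim))
    treedepths = np.empty(n_draws, dtype=np.int8)

    for it in range(n_warmup + n_draws):
        q, logp, accept_stat, divergent, depth = _nuts_step(
            target, q, logp, grad, eps, inv_mass, max_treedepth, rng
        )
        _, grad = target(q)
        if it < n_warmup:
            # dual averaging (Hoffman & Gelman 2014, Algorithm 6)
            m_da += 1
            m = m_da
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept_stat) / (m + t0)
            log_eps = mu_da - np.sqrt(m) / gamma * h_bar
            w = m**-kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))

            win_sum += q
            win_sumsq += q * q
            win_count += 1
            if window_ends and it + 1 == window_ends[0]:
                window_ends.pop(0)
                if win_count >= 10:
                    mean = win_sum / win_count
                    var = win_sumsq / win_count - mean**2
                    # regularize toward unit metric as Stan does
                    var = (win_count / (win_count + 5.0)) * var + 1e-3 * (
                        5.0 / (win_count + 5.0)
                    )
                    inv_mass = np.maximum(var, 1e-10)
                win_sum[:] = 0.0
                win_sumsq[:] = 0.0
                win_count = 0
                eps = _find_initial_step(target, q, logp, grad, inv_mass, rng)
                mu_da = np.log(10.0 * eps)
                log_eps_bar, h_bar, m_da = 0.0, 0.0, 0
            if it + 1 == n_warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            if divergent:
                n_divergent += 1
            accept_sum += accept_stat
            positions[it - n_warmup] = q
            treedepths[it - n_warmup] = depth

    return NUTSResult(
        positions=positions,
        step_size=eps,
        inv_mass=inv_mass,
        accept_rate=accept_sum / max(n_draws, 1),
        n_divergent=n_divergent,
        treedepths=treedepths,
    )
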