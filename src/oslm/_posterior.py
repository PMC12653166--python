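"""Unconstrained-space joint posterior with analytic gradients.

This is the bridge between the model family and the HMC sampler: it flattens
all active parameters into one real vector, evaluates the joint log density
(likelihood + priors + change-of-variable Jacobians) and its exact gradient.

Transforms used
---------------
* random-effect SDs: ``sigma = exp(ls)`` with the ``+ls`` log-Jacobian;
* correlation Cholesky factors: canonical partial correlations via ``tanh``
  (the Stan transform), with its log-Jacobian, and the LKJ density expressed
  on the Cholesky factor;
* random effects themselves: non-centered, ``effect_i = mu + diag(sigma) L z_i``
  with ``z_i`` standard normal, so the implied distribution is exactly
  MVN(mu, diag(sigma) Omega diag(sigma)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit

from .design import PracticeMatrix, TestDesign
from .models import (
    FIXED_EFFECT_SD,
    LKJ_ETA,
    SIGMA_CAUCHY_SCALE,
    ModelSpec,
    ResponseData,
)

_LOG_2PI = float(np.log(2.0 * np.pi))


# unconstrained correlation parameters are clipped here; tanh(15) differs
# from 1 by ~1e-13 and the density out there is astronomically small, so the
# clip only prevents floating-point blow-ups on wild leapfrog excursions.
_Y_CLIP = 15.0


def _chol_from_cpc(y: np.ndarray, R: int) -> tuple[np.ndarray, float, float]:
    """Build a correlation Cholesky factor L from unconstrained params.

    Returns (L, log_jacobian_of_transform, lkj_log_density_term).  The LKJ
    term is the non-constant part of the LKJ(eta) density on L.
    """
    L = np.zeros((R, R))
    L[0, 0] = 1.0
    y = np.clip(y, -_Y_CLIP, _Y_CLIP)
    z = np.tanh(y)
    # log(1 - z^2) = 2*log(sech y), computed without cancellation
    log1mz2 = 2.0 * (np.log(2.0) - np.abs(y) - np.log1p(np.exp(-2.0 * np.abs(y))))
    logjac = 0.0
    lkj = 0.0
    pos = 0
    for r in range(1, R):
        logc = 0.0
        for j in range(r):
            zj = z[pos + j]
            L[r, j] = zj * np.exp(0.5 * logc)
            logjac += 0.5 * logc + log1mz2[pos + j]
            logc += log1mz2[pos + j]
        L[r, r] = np.exp(0.5 * logc)
        lkj += (R - r - 1 + 2.0 * LKJ_ETA - 2.0) * 0.5 * logc
        pos += r
    return L, logjac, lkj


def _chol_from_cpc_backward(
    y: np.ndarray, R: int, g_L: np.ndarray
) -> np.ndarray:
    """Gradient of (log-density contributions + upstream g_L . L) w.r.t. y.

    Re-runs the forward recursion per row and reverse-accumulates through
    the partial-correlation construction, the transform Jacobian and the
    LKJ density term.  Outside the clip region the gradient is zero, which
    matches the (clipped) forward density.
    """
    inside = np.abs(y) < _Y_CLIP
    y = np.clip(y, -_Y_CLIP, _Y_CLIP)
    z = np.tanh(y)
    log1mz2 = 2.0 * (np.log(2.0) - np.abs(y) - np.log1p(np.exp(-2.0 * np.abs(y))))
    gy = np.zeros_like(y)
    pos = 0
    for r in range(1, R):
        zr = z[pos : pos + r]
        l1z = log1mz2[pos : pos + r]
        logc = np.empty(r + 1)
        logc[0] = 0.0
        for j in range(r):
            logc[j + 1] = logc[j] + l1z[j]
        c = np.exp(logc)
        gc = np.zeros(r + 1)
        # diagonal L[r,r] = sqrt(c_r) feeds the upstream grad and LKJ term
        kappa = R - r - 1 + 2.0 * LKJ_ETA - 2.0
        gc[r] = g_L[r, r] * 0.5 * np.exp(-0.5 * logc[r]) + kappa * 0.5 / c[r]
        gc[:r] += 0.5 / c[:r]  # transform Jacobian 0.5*log(c_j) terms
        gz = np.zeros(r)
        for j in range(r - 1, -1, -1):
            zj = zr[j]
            omz2 = np.exp(l1z[j])  # 1 - z_j^2, >= exp(-2*_Y_CLIP) > 0
            gz[j] += gc[j + 1] * c[j] * (-2.0 * zj)
            gc[j] += gc[j + 1] * omz2
            gz[j] += g_L[r, j] * np.exp(0.5 * logc[j])
            gc[j] += g_L[r, j] * zj * 0.5 * np.exp(-0.5 * logc[j])
            gz[j] += -2.0 * zj / omz2  # Jacobian log1p(-z^2)
        gy[pos : pos + r] = gz * np.exp(l1z)  # tanh' = 1 - z^2
        pos += r
    return gy * inside


@dataclass
class _RandomBlock:
    """Index bookkeeping for one random-effect block (practice or difficulty)."""

    names: list[str]
    sign: float  # +1 if the block enters the logit additively, -1 if subtracted
    loading: np.ndarray  # (J, R) columns of V (practice) or W (difficulty)
    sl_z: slice
    sl_mu: slice
    sl_ls: slice
    sl_y: slice

    @property
    def R(self) -> int:
        return len(self.names)


class Posterior:
    """Joint log posterior of one model spec on one data set."""

    def __init__(
        self,
        spec: ModelSpec,
        design: TestDesign,
        practice: PracticeMatrix,
        data: ResponseData,
        loglik_weights: np.ndarray | None = None,
    ) -> None:
        if data.J != design.J:
            raise ValueError("data and design disagree on the number of items")
        self.spec = spec
        self.design = design
        self.practice = practice
        self.data = data
        self.n = data.n
        self.X = data.X.astype(float)
        # per-cell weights let leave-one-out refits drop single observations
        self.wts = None if loglik_weights is None else np.asarray(loglik_weights, float)

        comps = spec.components
        idx = {c: m for m, c in enumerate(comps)}
        self.fixed_diff = [c for c in comps if spec.difficulty_mode[c] == "fixed"]
        self.rand_diff = [c for c in comps if spec.difficulty_mode[c] == "random"]
        self.fixed_prac = [c for c in comps if spec.practice_mode[c] == "fixed"]
        self.rand_prac = [c for c in comps if spec.practice_mode[c] == "random"]

        self.Wf = design.W[:, [idx[c] for c in self.fixed_diff]]
        self.Wr = design.W[:, [idx[c] for c in self.rand_diff]]
        self.Vf = practice.V[:, [idx[c] for c in self.fixed_prac]]
        self.Vr = practice.V[:, [idx[c] for c in self.rand_prac]]

        # ---- layout of the flat unconstrained vector
        pos = 0

        def take(k: int) -> slice:
            nonlocal pos
            sl = slice(pos, pos + k)
            pos += k
            return sl

        self.sl_theta = take(self.n)
        self.sl_afix = take(len(self.fixed_diff))
        self.sl_dfix = take(len(self.fixed_prac))
        self.blocks: list[_RandomBlock] = []
        for names, sign, loading in (
            (self.rand_prac, +1.0, self.Vr),
            (self.rand_diff, -1.0, self.Wr),
        ):
            if not names:
                continue
            R = len(names)
            self.blocks.append(
                _RandomBlock(
                    names=list(names),
                    sign=sign,
                    loading=loading,
                    sl_z=take(self.n * R),
                    sl_mu=take(R),
                    sl_ls=take(R),
                    sl_y=take(R * (R - 1) // 2),
                )
            )
        self.dim = pos

    # ------------------------------------------------------------------
    def _forward(self, q: np.ndarray):
        """Shared forward pass: logits plus per-block intermediates."""
        theta = q[self.sl_theta]
        afix = q[self.sl_afix]
        dfix = q[self.sl_dfix]
        logits = theta[:, None] - afix @ self.Wf.T + dfix @ self.Vf.T

        inter = []
        for b in self.blocks:
            z = q[b.sl_z].reshape(self.n, b.R)
            mu = q[b.sl_mu]
            ls = q[b.sl_ls]
            sigma = np.exp(ls)
            L, logjac, lkj = _chol_from_cpc(q[b.sl_y], b.R)
            T = sigma[:, None] * L
            eff = mu + z @ T.T  # (n, R)
            logits = logits + b.sign * (eff @ b.loading.T)
            inter.append((z, mu, ls, sigma, L, logjac, lkj, T, eff))
        return theta, afix, dfix, logits, inter

    def pointwise_loglik(self, q: np.ndarray) -> np.ndarray:
        """Full-data pointwise log-likelihood (never weighted, so held-out
        cells of a weighted refit still get their predictive density)."""
        _, _, _, logits, _ = self._forward(q)
        return self.X * logits + log_expit(-logits)

    def logp(self, q: np.ndarray) -> float:
        return self.logp_grad(q)[0]

    def logp_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        theta, afix, dfix, logits, inter = self._forward(q)
        # X*l + log sigma(-l) == X log sigma(l) + (1-X) log sigma(-l)
        ll = self.X * logits + log_expit(-logits)
        resid = self.X - expit(logits)
        if self.wts is not None:
            ll = ll * self.wts
            resid = resid * self.wts
        lp = float(ll.sum())
        grad = np.zeros_like(q)

        # theta ~ N(0,1)
        lp += float(-0.5 * (theta @ theta) - 0.5 * self.n * _LOG_2PI)
        grad[self.sl_theta] = resid.sum(axis=1) - theta

        sd2 = FIXED_EFFECT_SD**2
        lp += float(
            -0.5 * (afix @ afix) / sd2
            - afix.size * (0.5 * _LOG_2PI + np.log(FIXED_EFFECT_SD))
        )
        grad[self.sl_afix] = -(resid.sum(axis=0) @ self.Wf) - afix / sd2
        lp += float(
            -0.5 * (dfix @ dfix) / sd2
            - dfix.size * (0.5 * _LOG_2PI + np.log(FIXED_EFFECT_SD))
        )
        grad[self.sl_dfix] = resid.sum(axis=0) @ self.Vf - dfix / sd2

        for b, (z, mu, ls, sigma, L, logjac, lkj, T, _eff) in zip(self.blocks, inter):
            deff = b.sign * (resid @ b.loading)  # (n, R)
            # z ~ N(0,1), mu ~ N(0,1)
            lp += float(-0.5 * (z**2).sum() - 0.5 * z.size * _LOG_2PI)
            lp += float(-0.5 * (mu @ mu) - 0.5 * b.R * _LOG_2PI)
            # sigma ~ half-Cauchy(0, 5), plus exp-transform Jacobian
            lp += float(
                (
                    np.log(2.0 / (np.pi * SIGMA_CAUCHY_SCALE))
                    - np.log1p((sigma / SIGMA_CAUCHY_SCALE) ** 2)
                    + ls
                ).sum()
            )
            lp += logjac + lkj

            grad[b.sl_z] = (deff @ T - z).ravel()
            grad[b.sl_mu] = deff.sum(axis=0) - mu
            dT = deff.T @ z  # (R, R); only lower triangle of L is active
            dsigma = (dT * L).sum(axis=1)
            grad[b.sl_ls] = dsigma * sigma + (
                1.0 - 2.0 * sigma**2 / (SIGMA_CAUCHY_SCALE**2 + sigma**2)
            )
            if b.R > 1:
                # backward only reads the lower triangle of g_L
                grad[b.sl_y] = _chol_from_cpc_backward(
                    q[b.sl_y], b.R, dT * sigma[:, None]
                )
        return lp, grad

    # ------------------------------------------------------------------
    def constrain(self, q: np.ndarray) -> dict[str, np.ndarray]:
        """Map an unconstrained vector to named natural parameters."""
        theta, afix, dfix, _logits, inter = self._forward(q)
        out: dict[str, np.ndarray] = {"theta": theta}
        if self.fixed_diff:
            out["alpha"] = afix
        if self.fixed_prac:
            out["delta_fixed"] = dfix
        for b, (z, mu, ls, sigma, L, _lj, _lk, T, eff) in zip(self.blocks, inter):
            tag = "delta" if b.sign > 0 else "eta"
            out[tag] = eff
            out[f"mu_{tag}"] = mu
            out[f"sigma_{tag}"] = sigma
            out[f"Omega_{tag}"] = L @ L.T
        return out

    def param_shapes(self) -> dict[str, tuple[int, ...]]:
        shapes: dict[str, tuple[int, ...]] = {"theta": (self.n,)}
        if self.fixed_diff:
            shapes["alpha"] = (len(self.fixed_diff),)
        if self.fixed_prac:
            shapes["delta_fixed"] = (len(self.fixed_prac),)
        for b in self.blocks:
            tag = "delta" if b.sign > 0 else "eta"
            shapes[tag] = (self.n, b.R)
            shapes[f"mu_{tag}"] = (b.R,)
            shapes[f"sigma_{tag}"] = (b.R,)
            shapes[f"Omega_{tag}"] = (b.R, b.R)
        return shapes

    def component_labels(self) -> dict[str, list[str]]:
        labels = {
            "alpha": list(self.fixed_diff),
            "delta_fixed": list(self.fixed_prac),
        }
        for b in self.blocks:
            tag = "delta" if b.sign > 0 else "eta"
            labels[tag] = list(b.names)
        return labels
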