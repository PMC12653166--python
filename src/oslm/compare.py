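"""Model comparison: WAIC, PSIS-LOO, posterior predictive checks with the
pairwise odds-ratio statistic, and the side-by-side comparison table.

The scalar OR statistic aggregates association over all J(J-1)/2 unordered
item pairs as the *sum* of pairwise odds ratios; a continuity correction of
0.5 is added to every cell of a 2x2 table that contains a zero.  The
aggregation is a documented choice isolated in :func:`or_statistic` so
alternatives stay pluggable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .inference import PosteriorDraws, data_fingerprint
from .models import ResponseData

__all__ = [
    "InformationCriteria",
    "PPMCResult",
    "waic",
    "psis_loo",
    "or_statistic",
    "ppmc",
    "compare",
]


@dataclass
class InformationCriteria:
    """WAIC and/or PSIS-LOO estimates with pointwise contributions."""

    n_obs: int
    n_draws: int
    elpd_waic: float | None = None
    p_waic: float | None = None
    waic: float | None = None
    pointwise_elpd_waic: np.ndarray | None = field(default=None, repr=False)
    elpd_loo: float | None = None
    p_loo: float | None = None
    looic: float | None = None
    pointwise_elpd_loo: np.ndarray | None = field(default=None, repr=False)
    pareto_k: np.ndarray | None = field(default=None, repr=False)

    def merged_with(self, other: "InformationCriteria") -> "InformationCriteria":
        out = InformationCriteria(n_obs=self.n_obs, n_draws=self.n_draws)
        for src in (self, other):
            for name in (
                "elpd_waic", "p_waic", "waic", "pointwise_elpd_waic",
                "elpd_loo", "p_loo", "looic", "pointwise_elpd_loo", "pareto_k",
            ):
                val = getattr(src, name)
                if val is not None:
                    setattr(out, name, val)
        return out


def _as_loglik_matrix(ll) -> np.ndarray:
    if isinstance(ll, PosteriorDraws):
        ll = ll.stacked_log_lik()
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2:
        raise ValueError("expected a (draws, observations) log-likelihood matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("log-likelihood matrix contains non-finite entries")
    return ll


def waic(loglik) -> InformationCriteria:
    """Widely applicable information criterion from pointwise log-likelihood
    draws (shape ``(draws, observations)`` or a :class:`PosteriorDraws`).

    lppd uses log-mean-exp with log-sum-exp stabilization; the effective
    number of parameters is the sum of pointwise posterior variances.
    """
    ll = _as_loglik_matrix(loglik)
    S, N = ll.shape
    if S < 2:
        raise ValueError("WAIC needs at least 2 draws (pointwise variance)")
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    elpd = float(elpd_i.sum())
    return InformationCriteria(
        n_obs=N,
        n_draws=S,
        elpd_waic=elpd,
        p_waic=float(p_i.sum()),
        waic=-2.0 * elpd,
        pointwise_elpd_waic=elpd_i,
    )


def psis_loo(loglik, reff: float = 1.0) -> InformationCriteria:
    """PSIS-LOO estimate of expected log pointwise predictive density.

    Importance weights are Pareto-smoothed with arviz's ``psislw``;
    per-observation Pareto-k diagnostics are reported.
    """
    ll = _as_loglik_matrix(loglik)
    S, N = ll.shape
    if S < 2:
        raise ValueError("PSIS-LOO needs at least 2 draws")
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, k = az.psislw(-ll.T, reff=reff)  # (obs, draws), normalized
    lw = np.asarray(lw)
    k = np.asarray(k)
    elpd_i = logsumexp(lw + ll.T, axis=1)
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    elpd = float(elpd_i.sum())
    if np.any(k > 0.7):
        warnings.warn(
            f"{int((k > 0.7).sum())} of {N} observations have Pareto k > 0.7; "
            "PSIS-LOO may be unreliable for them",
            stacklevel=2,
        )
    return InformationCriteria(
        n_obs=N,
        n_draws=S,
        elpd_loo=elpd,
        p_loo=float(lppd_i.sum() - elpd),
        looic=-2.0 * elpd,
        pointwise_elpd_loo=elpd_i,
        pareto_k=k,
    )


def information_criteria(loglik) -> InformationCriteria:
    """Both WAIC and PSIS-LOO on the same log-likelihood draws."""
    ll = _as_loglik_matrix(loglik)
    return waic(ll).merged_with(psis_loo(ll))


# ---------------------------------------------------------------------------
# Odds-ratio statistic and PPMC


def pairwise_odds_ratio(n11: float, n10: float, n01: float, n00: float) -> float:
    """Odds ratio of one 2x2 item-pair table, continuity-corrected (all four
    cells +0.5) whenever any cell is zero."""
    if min(n11, n10, n01, n00) == 0:
        n11, n10, n01, n00 = n11 + 0.5, n10 + 0.5, n01 + 0.5, n00 + 0.5
    return (n11 * n00) / (n10 * n01)


def or_statistic(data: ResponseData | np.ndarray) -> float:
    """Sum of pairwise odds ratios over all unordered item pairs."""
    X = data.X if isinstance(data, ResponseData) else np.asarray(data)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a person x item matrix with at least two items")
    if X.shape[0] < 1:
        raise ValueError("need at least one person")
    Xf = X.astype(float)
    n11 = Xf.T @ Xf
    n10 = Xf.T @ (1.0 - Xf)
    n01 = n10.T
    ones = np.ones_like(Xf)
    n00 = (1.0 - Xf).T @ (1.0 - Xf)
    del ones
    J = X.shape[1]
    iu = np.triu_indices(J, k=1)
    a, b, c, d = n11[iu], n10[iu], n01[iu], n00[iu]
    corr = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0) * 0.5
    a, b, c, d = a + corr, b + corr, c + corr, d + corr
    return float(((a * d) / (b * c)).sum())


@dataclass
class PPMCResult:
    """Posterior predictive check of one fit with a scalar test statistic."""

    observed: float
    replicates: np.ndarray = field(repr=False)
    p_post: float
    statistic: str = "sum of pairwise odds ratios"

    @property
    def n_replicates(self) -> int:
        return self.replicates.size

    @property
    def replicate_mean(self) -> float:
        return float(self.replicates.mean())

    @property
    def replicate_sd(self) -> float:
        return float(self.replicates.std(ddof=1)) if self.n_replicates > 1 else 0.0


def draw_logits(draws: PosteriorDraws, s: int) -> np.ndarray:
    """(n, J) success logits implied by stacked posterior draw ``s``."""
    spec, design, practice = draws.spec, draws.design, draws.practice
    n = draws.data.n
    theta = draws.stacked("theta")[s]
    logits = np.tile(theta[:, None], (1, design.J)).astype(float)
    comp_idx = {c: m for m, c in enumerate(spec.components)}
    if "alpha" in draws.draws:
        av = draws.stacked("alpha")[s]
        idx = [comp_idx[c] for c in draws.labels["alpha"]]
        logits -= av @ design.W[:, idx].T
    if "eta" in draws.draws:
        ev = draws.stacked("eta")[s]
        idx = [comp_idx[c] for c in draws.labels["eta"]]
        logits -= ev @ design.W[:, idx].T
    if "delta_fixed" in draws.draws:
        dv = draws.stacked("delta_fixed")[s]
        idx = [comp_idx[c] for c in draws.labels["delta_fixed"]]
        logits += dv @ practice.V[:, idx].T
    if "delta" in draws.draws:
        dv = draws.stacked("delta")[s]
        idx = [comp_idx[c] for c in draws.labels["delta"]]
        logits += dv @ practice.V[:, idx].T
    return logits


def ppmc(
    draws: PosteriorDraws,
    n_replicates: int = 500,
    seed: int = 0,
    thin: int = 5,
    statistic=or_statistic,
) -> PPMCResult:
    """Posterior predictive check: simulate replicate response matrices from
    every ``thin``-th saved draw (up to ``n_replicates``), compute the test
    statistic on each, and report ``p_post = P(T_rep >= T_obs)``."""
    total = draws.n_chains * draws.n_draws
    idx = np.arange(0, total, thin)[:n_replicates]
    if idx.size > total:
        raise ValueError("n_replicates exceeds the number of available draws")
    if idx.size < 2:
        raise ValueError("need at least two replicates")
    rng = np.random.default_rng(seed)
    observed = float(statistic(draws.data))
    reps = np.empty(idx.size)
    for r, s in enumerate(idx):
        p = expit(draw_logits(draws, int(s)))
        X_rep = (rng.random(p.shape) < p).astype(np.int8)
        reps[r] = statistic(X_rep)
    return PPMCResult(
        observed=observed,
        replicates=reps,
        p_post=float(np.mean(reps >= observed)),
    )


# ---------------------------------------------------------------------------


def compare(
    fits: list[PosteriorDraws],
    names: list[str] | None = None,
    run_ppmc: bool = False,
    ppmc_seed: int = 0,
    n_replicates: int = 500,
) -> pd.DataFrame:
    """Goodness-of-fit table across models fit to the same data, sorted by
    LOOIC (lower is a better fit-parsimony balance); the best model is
    flagged.  Raises when the fits were not computed on identical data."""
    if not fits:
        raise ValueError("no fits given")
    names = names or [f.spec.variant for f in fits]
    if len(names) != len(fits):
        raise ValueError("names and fits length mismatch")
    prints = {data_fingerprint(f.data) for f in fits}
    if len(prints) > 1:
        raise ValueError("fits were computed on different data sets")

    rows = []
    for name, f in zip(names, fits):
        ic = information_criteria(f)
        row = {
            "model": name,
            "elpd_waic": ic.elpd_waic,
            "p_waic": ic.p_waic,
            "waic": ic.waic,
            "elpd_loo": ic.elpd_loo,
            "p_loo": ic.p_loo,
            "looic": ic.looic,
        }
        if run_ppmc:
            res = ppmc(f, n_replicates=n_replicates, seed=ppmc_seed)
            row.update(
                {
                    "or_observed": res.observed,
                    "or_simulated": res.replicate_mean,
                    "or_simulated_sd": res.replicate_sd,
                    "p_post": res.p_post,
                }
            )
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("looic", kind="stable").reset_index(drop=True)
    best = table["looic"] <= table["looic"].min() + 1e-9
    table["best"] = best
    if best.sum() > 1:
        warnings.warn("tie for the lowest LOOIC", stacklevel=2)
    return table
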