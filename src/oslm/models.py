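"""Unified likelihood and prior structure for the LLTM / RWLLTM / OSLM /
RWOSLM model family.

All variants share the linear logit

    logit P(X_ij = 1) = theta_i - sum_m w_jm * (difficulty term)
                                 + sum_m v_jm * (practice term)

and differ only in which terms are present and whether they are fixed across
persons or person-varying (random effects).  Positive practice effects mean
the component gets *easier* with accumulated practice; negative means harder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, gammaln, log_expit

from .design import TestDesign, PracticeMatrix

__all__ = [
    "VARIANTS",
    "ModelSpec",
    "ParameterSet",
    "PracticeHyperparameters",
    "ResponseData",
    "success_logit",
    "rule_difficulty_trajectory",
    "log_likelihood",
    "log_prior",
    "lkj_logpdf",
]

VARIANTS = ("LLTM", "RWLLTM", "OSLM", "RWOSLM", "RWOSLM_const")

#: prior scale for fixed-effect coefficients: N(0, 100) read as variance 100.
FIXED_EFFECT_SD = 10.0
#: half-Cauchy scale for random-effect standard deviations.
SIGMA_CAUCHY_SCALE = 5.0
#: LKJ shape for random-effect correlation matrices.
LKJ_ETA = 2.0

#: components whose practice effects stay random in the default constrained
#: RWOSLM.
DEFAULT_CONST_RANDOM = ("A/S", "distortion")


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to fit, and the per-component effect modes.

    ``difficulty_mode[name]`` is ``"fixed"`` or ``"random"``;
    ``practice_mode[name]`` is ``"none"``, ``"fixed"`` or ``"random"``.
    The named constructors enforce the variant definitions; the generic
    constructor validates consistency.
    """

    variant: str
    difficulty_mode: Mapping[str, str]
    practice_mode: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        object.__setattr__(self, "difficulty_mode", dict(self.difficulty_mode))
        object.__setattr__(self, "practice_mode", dict(self.practice_mode))
        if set(self.difficulty_mode) != set(self.practice_mode):
            raise ValueError("difficulty_mode and practice_mode must cover the same components")
        for name, mode in self.difficulty_mode.items():
            if mode not in ("fixed", "random"):
                raise ValueError(f"bad difficulty mode {mode!r} for {name!r}")
        for name, mode in self.practice_mode.items():
            if mode not in ("none", "fixed", "random"):
                raise ValueError(f"bad practice mode {mode!r} for {name!r}")
        dm = set(self.difficulty_mode.values())
        pm = set(self.practice_mode.values())
        constraints = {
            "LLTM": (dm == {"fixed"} and pm == {"none"}),
            "RWLLTM": (dm == {"random"} and pm == {"none"}),
            "OSLM": (dm == {"fixed"} and pm == {"fixed"}),
            "RWOSLM": (dm == {"fixed"} and pm == {"random"}),
            "RWOSLM_const": (dm == {"fixed"} and pm <= {"fixed", "random"}),
        }
        if not constraints[self.variant]:
            raise ValueError(
                f"effect modes inconsistent with variant {self.variant}: "
                f"difficulty={sorted(dm)}, practice={sorted(pm)}"
            )

    # -- named constructors -------------------------------------------------

    @classmethod
    def lltm(cls, components: Sequence[str]) -> "ModelSpec":
        return cls("LLTM", {c: "fixed" for c in components}, {c: "none" for c in components})

    @classmethod
    def rwlltm(cls, components: Sequence[str]) -> "ModelSpec":
        return cls("RWLLTM", {c: "random" for c in components}, {c: "none" for c in components})

    @classmethod
    def oslm(cls, components: Sequence[str]) -> "ModelSpec":
        return cls("OSLM", {c: "fixed" for c in components}, {c: "fixed" for c in components})

    @classmethod
    def rwoslm(cls, components: Sequence[str]) -> "ModelSpec":
        return cls("RWOSLM", {c: "fixed" for c in components}, {c: "random" for c in components})

    @classmethod
    def rwoslm_const(
        cls,
        components: Sequence[str],
        random: Sequence[str] = DEFAULT_CONST_RANDOM,
    ) -> "ModelSpec":
        random = [r for r in random if r in components]
        if not random:
            raise ValueError("constrained RWOSLM needs at least one random-practice component")
        return cls(
            "RWOSLM_const",
            {c: "fixed" for c in components},
            {c: "random" if c in random else "fixed" for c in components},
        )

    @classmethod
    def from_name(
        cls, name: str, components: Sequence[str], random: Sequence[str] | None = None
    ) -> "ModelSpec":
        key = name.replace("-", "_").replace(".", "").lower()
        if key == "lltm":
            return cls.lltm(components)
        if key == "rwlltm":
            return cls.rwlltm(components)
        if key == "oslm":
            return cls.oslm(components)
        if key == "rwoslm":
            return cls.rwoslm(components)
        if key in ("rwoslm_const", "rwoslmconst"):
            return cls.rwoslm_const(components, random or DEFAULT_CONST_RANDOM)
        raise ValueError(f"unknown model name {name!r}")

    # -- component bookkeeping ----------------------------------------------

    @property
    def components(self) -> list[str]:
        return list(self.difficulty_mode)

    @property
    def random_difficulty(self) -> list[str]:
        return [c for c, m in self.difficulty_mode.items() if m == "random"]

    @property
    def fixed_practice(self) -> list[str]:
        return [c for c, m in self.practice_mode.items() if m == "fixed"]

    @property
    def random_practice(self) -> list[str]:
        return [c for c, m in self.practice_mode.items() if m == "random"]

    @property
    def has_practice(self) -> bool:
        return any(m != "none" for m in self.practice_mode.values())


@dataclass(frozen=True)
class PracticeHyperparameters:
    """Hyper-parameters of the multivariate-normal random-effect distribution."""

    mu: np.ndarray
    sigma: np.ndarray
    Omega: np.ndarray

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        Omega = np.atleast_2d(np.asarray(self.Omega, dtype=float))
        R = mu.shape[0]
        if sigma.shape != (R,) or Omega.shape != (R, R):
            raise ValueError("mu, sigma and Omega dimensions disagree")
        if np.any(sigma <= 0):
            raise ValueError("sigma must be elementwise positive")
        if not np.allclose(Omega, Omega.T):
            raise ValueError("Omega must be symmetric")
        if not np.allclose(np.diag(Omega), 1.0):
            raise ValueError("Omega must have a unit diagonal")
        try:
            np.linalg.cholesky(Omega)
        except np.linalg.LinAlgError:
            raise ValueError("Omega must be positive definite") from None
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "Omega", Omega)

    @property
    def Sigma(self) -> np.ndarray:
        """Implied covariance diag(sigma) @ Omega @ diag(sigma)."""
        return self.Omega * np.outer(self.sigma, self.sigma)


@dataclass
class ResponseData:
    """Binary person-by-item outcomes with optional response latencies."""

    X: np.ndarray
    person_ids: np.ndarray | None = None
    latencies: np.ndarray | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D person x item matrix")
        if np.any(np.isnan(X.astype(float))):
            raise ValueError("missing responses are not supported")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("responses must be binary (0/1)")
        self.X = X.astype(np.int8)
        if self.person_ids is None:
            self.person_ids = np.arange(1, self.n + 1)
        else:
            self.person_ids = np.asarray(self.person_ids)
            if self.person_ids.shape != (self.n,):
                raise ValueError("person_ids length must match number of rows")
        if self.latencies is not None:
            self.latencies = np.asarray(self.latencies, dtype=float)
            if self.latencies.shape != self.X.shape:
                raise ValueError("latencies must have the same shape as X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def J(self) -> int:
        return self.X.shape[1]

    # -- I/O ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.X, columns=[f"item_{j}" for j in range(1, self.J + 1)]
        )
        df.insert(0, "person", self.person_ids)
        return df

    @classmethod
    def from_csv(cls, path) -> "ResponseData":
        """Read responses from wide (``person,item_1..item_J``) or long
        (``person,item,response[,latency]``) CSV."""
        df = pd.read_csv(path)
        cols = set(df.columns)
        if {"person", "item", "response"} <= cols:
            wide = df.pivot(index="person", columns="item", values="response")
            wide = wide.sort_index(axis=1)
            lat = None
            if "latency" in cols and df["latency"].notna().all():
                lat = (
                    df.pivot(index="person", columns="item", values="latency")
                    .sort_index(axis=1)
                    .to_numpy(dtype=float)
                )
            return cls(
                X=wide.to_numpy(),
                person_ids=wide.index.to_numpy(),
                latencies=lat,
            )
        item_cols = [c for c in df.columns if c != "person"]
        ids = df["person"].to_numpy() if "person" in cols else None
        return cls(X=df[item_cols].to_numpy(), person_ids=ids)


@dataclass
class ParameterSet:
    """One concrete parameter configuration for a model spec.

    Per-component entries are scalars for fixed effects and length-n arrays
    for random effects; ``practice`` entries are absent (or None) for
    components without a practice term.
    """

    theta: np.ndarray
    difficulty: dict[str, np.ndarray | float]
    practice: dict[str, np.ndarray | float] = field(default_factory=dict)

    def difficulty_matrix(self, spec: ModelSpec, n: int) -> np.ndarray:
        """(n, M) per-person component difficulty coefficients."""
        cols = []
        for name in spec.components:
            val = np.asarray(self.difficulty[name], dtype=float)
            cols.append(np.broadcast_to(val, (n,)))
        return np.column_stack(cols)

    def practice_matrix(self, spec: ModelSpec, n: int) -> np.ndarray:
        """(n, M) per-person practice coefficients; zero where mode is none."""
        cols = []
        for name in spec.components:
            if spec.practice_mode[name] == "none":
                cols.append(np.zeros(n))
            else:
                val = np.asarray(self.practice[name], dtype=float)
                cols.append(np.broadcast_to(val, (n,)))
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Likelihood


def linear_predictor(
    theta: np.ndarray,
    difficulty: np.ndarray,
    practice: np.ndarray,
    W: np.ndarray,
    V: np.ndarray,
) -> np.ndarray:
    """(n, J) success logits from per-person coefficient matrices."""
    return theta[:, None] - difficulty @ W.T + practice @ V.T


def success_logit(
    theta_i: float,
    w_row: np.ndarray,
    v_row: np.ndarray,
    spec: ModelSpec,
    *,
    alpha: Mapping[str, float] | None = None,
    delta_i: Mapping[str, float] | None = None,
    delta_fixed: Mapping[str, float] | None = None,
) -> float:
    """Success logit for one person on one item.

    ``alpha`` carries the per-component difficulty term (alpha_m or eta);
    ``delta_i`` the person's random practice effects; ``delta_fixed`` the
    shared fixed practice effects.
    """
    alpha = alpha or {}
    delta_i = delta_i or {}
    delta_fixed = delta_fixed or {}
    w_row = np.asarray(w_row, dtype=float)
    v_row = np.asarray(v_row, dtype=float)
    if w_row.shape != (len(spec.components),) or v_row.shape != w_row.shape:
        raise ValueError("w_row/v_row length must equal the number of components")
    logit = float(theta_i)
    for m, name in enumerate(spec.components):
        logit -= w_row[m] * float(alpha[name])
        mode = spec.practice_mode[name]
        if mode == "random":
            logit += v_row[m] * float(delta_i[name])
        elif mode == "fixed":
            logit += v_row[m] * float(delta_fixed[name])
    return logit


def rule_difficulty_trajectory(
    alpha_m: float, delta_im: float, W_column: np.ndarray, j: int
) -> float:
    """Difficulty of one component for one person at item ``j`` (1-based):
    initial difficulty minus the practice effect scaled by accumulated prior
    weight."""
    W_column = np.asarray(W_column, dtype=float)
    if not 1 <= j <= W_column.shape[0]:
        raise ValueError(f"item index {j} outside 1..{W_column.shape[0]}")
    return float(alpha_m - delta_im * W_column[: j - 1].sum())


def pointwise_loglik(X: np.ndarray, logits: np.ndarray) -> np.ndarray:
    """Bernoulli log-likelihood per cell, numerically stable for large |logit|."""
    return np.where(X == 1, log_expit(logits), log_expit(-logits))


def log_likelihood(
    data: ResponseData,
    params: ParameterSet,
    design: TestDesign,
    practice: PracticeMatrix,
    spec: ModelSpec,
) -> tuple[np.ndarray, float]:
    """Pointwise (n, J) log-likelihood and its total."""
    n = data.n
    logits = linear_predictor(
        np.asarray(params.theta, dtype=float),
        params.difficulty_matrix(spec, n),
        params.practice_matrix(spec, n),
        design.W,
        practice.V,
    )
    ll = pointwise_loglik(data.X, logits)
    return ll, float(ll.sum())


# ---------------------------------------------------------------------------
# Priors


def lkj_logpdf(Omega: np.ndarray, eta: float = LKJ_ETA) -> float:
    """Exact LKJ log density (including the normalizing constant) of a
    correlation matrix."""
    Omega = np.atleast_2d(np.asarray(Omega, dtype=float))
    R = Omega.shape[0]
    if R == 1:
        return 0.0
    sign, logdet = np.linalg.slogdet(Omega)
    if sign <= 0:
        raise ValueError("Omega must be positive definite")
    # normalizer c_R(eta) from Lewandowski, Kurowicka & Joe (2009)
    log_c = 0.0
    for k in range(1, R):
        log_c += (2.0 * eta - 2.0 + R - k) * (R - k) * np.log(2.0)
        a = eta + (R - k - 1) / 2.0
        log_c += (R - k) * betaln(a, a)
    return float((eta - 1.0) * logdet - log_c)


def _halfcauchy_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("half-Cauchy variates must be positive")
    return np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2)


def _norm_logpdf(x: np.ndarray, sd: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * (x / sd) ** 2


def _mvn_logpdf(x: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(x)
    R = x.shape[1]
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        raise ValueError("covariance must be symmetric positive definite") from None
    z = np.linalg.solve(L, (x - mu).T).T
    return (
        -0.5 * R * np.log(2 * np.pi)
        - np.log(np.diag(L)).sum()
        - 0.5 * (z**2).sum(axis=1)
    )


def log_prior(
    params: ParameterSet,
    spec: ModelSpec,
    hyper: PracticeHyperparameters | None = None,
    difficulty_hyper: PracticeHyperparameters | None = None,
) -> float:
    """Joint log prior for a parameter configuration.

    theta ~ N(0, 1); fixed-effect coefficients ~ N(0, sd=10); random effects
    ~ MVN(mu, Sigma); hyper-priors mu ~ N(0, 1), sigma ~ half-Cauchy(0, 5),
    Omega ~ LKJ(2).  ``hyper`` covers the random practice block and
    ``difficulty_hyper`` the random difficulty block (RWLLTM).
    """
    lp = float(_norm_logpdf(np.asarray(params.theta, dtype=float), 1.0).sum())

    fixed_diff = [c for c, m in spec.difficulty_mode.items() if m == "fixed"]
    for name in fixed_diff:
        lp += float(_norm_logpdf(params.difficulty[name], FIXED_EFFECT_SD))
    for name in spec.fixed_practice:
        lp += float(_norm_logpdf(params.practice[name], FIXED_EFFECT_SD))

    for names, block_hyper, values in (
        (spec.random_practice, hyper, params.practice),
        (spec.random_difficulty, difficulty_hyper, params.difficulty),
    ):
        if not names:
            continue
        if block_hyper is None:
            raise ValueError("hyper-parameters required for random-effect block")
        draws = np.column_stack([np.asarray(values[name], dtype=float) for name in names])
        lp += float(_mvn_logpdf(draws, block_hyper.mu, block_hyper.Sigma).sum())
        lp += float(_norm_logpdf(block_hyper.mu, 1.0).sum())
        lp += float(_halfcauchy_logpdf(block_hyper.sigma, SIGMA_CAUCHY_SCALE).sum())
        lp += lkj_logpdf(block_hyper.Omega, LKJ_ETA)
    return lp
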