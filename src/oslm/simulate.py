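"""Synthetic-data generation: ART-like designs, person parameters, binary
responses with latencies, the sub-second latency exclusion filter, and
external person-level measures with target correlations.

Every generator is seed-deterministic and the simulated-responses writer
emits provenance metadata (seed and generating parameters) alongside data.
The default generating values are packaged as a versioned fixture at
realistic ART-scale magnitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import (
    ComponentSpec,
    PracticeMatrix,
    TestDesign,
    build_practice_matrix,
    check_identification,
)
from .models import ModelSpec, ResponseData

__all__ = [
    "ART_COMPONENTS",
    "PracticeConfig",
    "GeneratingParameters",
    "PersonTruth",
    "ExternalMeasureSpec",
    "ExclusionReport",
    "table2_generating_parameters",
    "generate_design",
    "generate_persons",
    "simulate_responses",
    "latency_filter",
    "generate_external_measures",
]

ART_COMPONENTS = (
    ComponentSpec("CR", "rule"),
    ComponentSpec("PP", "rule"),
    ComponentSpec("A/S", "rule"),
    ComponentSpec("D3", "rule"),
    ComponentSpec("D2", "rule"),
    ComponentSpec("overlay", "figural"),
    ComponentSpec("distortion", "figural"),
    ComponentSpec("fusion", "figural"),
)


@dataclass(frozen=True)
class PracticeConfig:
    """Generating practice effect of one component: absent, shared, or
    person-varying."""

    mode: str  # none | fixed | random
    value: float = 0.0  # fixed-effect value
    mu: float = 0.0  # random-effect mean
    sigma: float = 0.0  # random-effect SD

    def __post_init__(self) -> None:
        if self.mode not in ("none", "fixed", "random"):
            raise ValueError(f"bad practice mode {self.mode!r}")
        if self.mode == "random" and self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass
class GeneratingParameters:
    """True parameter values driving the forward model."""

    alpha: dict[str, float]
    practice: dict[str, PracticeConfig]
    Omega: np.ndarray | None = None  # correlation of the random components

    def __post_init__(self) -> None:
        if set(self.alpha) != set(self.practice):
            raise ValueError("alpha and practice must cover the same components")
        R = len(self.random_components)
        if self.Omega is None:
            self.Omega = np.eye(R)
        self.Omega = np.atleast_2d(np.asarray(self.Omega, dtype=float))
        if R and self.Omega.shape != (R, R):
            raise ValueError("Omega shape must match the number of random components")
        if R:
            if not np.allclose(self.Omega, self.Omega.T) or not np.allclose(
                np.diag(self.Omega), 1.0
            ):
                raise ValueError("Omega must be a symmetric correlation matrix")
            if np.any(np.linalg.eigvalsh(self.Omega) <= 0):
                raise ValueError("Omega must be positive definite")

    @property
    def components(self) -> list[str]:
        return list(self.alpha)

    @property
    def random_components(self) -> list[str]:
        return [c for c, p in self.practice.items() if p.mode == "random"]

    def model_spec(self) -> ModelSpec:
        """The model variant matching this generating configuration."""
        modes = {c: p.mode for c, p in self.practice.items()}
        vals = set(modes.values())
        comps = self.components
        if vals == {"none"}:
            return ModelSpec.lltm(comps)
        if vals == {"fixed"}:
            return ModelSpec.oslm(comps)
        if vals == {"random"}:
            return ModelSpec.rwoslm(comps)
        return ModelSpec.rwoslm_const(comps, random=self.random_components)

    def scaled_sigma(self, factor: float) -> "GeneratingParameters":
        """Copy with all random-effect SDs multiplied by ``factor``."""
        practice = {
            c: (
                PracticeConfig("random", mu=p.mu, sigma=p.sigma * factor)
                if p.mode == "random"
                else p
            )
            for c, p in self.practice.items()
        }
        return GeneratingParameters(dict(self.alpha), practice, self.Omega.copy())

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "practice": {
                c: (
                    {"mode": "random", "mu": p.mu, "sigma": p.sigma}
                    if p.mode == "random"
                    else {"mode": p.mode, "value": p.value}
                )
                for c, p in self.practice.items()
            },
            "Omega": self.Omega.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_mapping(cls, payload: dict) -> "GeneratingParameters":
        practice = {}
        for c, p in payload["practice"].items():
            mode = p["mode"]
            if mode == "random":
                practice[c] = PracticeConfig("random", mu=p["mu"], sigma=p["sigma"])
            elif mode == "fixed":
                practice[c] = PracticeConfig("fixed", value=p["value"])
            else:
                practice[c] = PracticeConfig("none")
        return cls(
            alpha=dict(payload["alpha"]),
            practice=practice,
            Omega=np.asarray(payload["Omega"], dtype=float)
            if payload.get("Omega") is not None
            else None,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratingParameters":
        return cls.from_mapping(json.loads(Path(path).read_text()))


def table2_generating_parameters() -> GeneratingParameters:
    """Packaged default generating values at realistic ART magnitudes."""
    text = (
        resources.files("oslm").joinpath("fixtures/art_generating_params.json").read_text()
    )
    return GeneratingParameters.from_mapping(json.loads(text))


# ---------------------------------------------------------------------------
# Design generation


def generate_design(
    J: int = 34,
    components: tuple[ComponentSpec, ...] = ART_COMPONENTS,
    seed: int = 0,
    generating: GeneratingParameters | None = None,
    ordering: str = "by_predicted_difficulty",
    max_tries: int = 200,
) -> TestDesign:
    """Random Carpenter-style design: 1-3 rules per item with weights up to
    2, figural properties 0/1, items ordered easiest-first by predicted
    difficulty, rejection-resampled until identification passes.
    """
    components = tuple(
        c if isinstance(c, ComponentSpec) else ComponentSpec(c) for c in components
    )
    M = len(components)
    if J < 2 * M + 1:
        raise ValueError(
            f"J={J} items cannot identify practice effects for M={M} components "
            f"(need 2M+1={2 * M + 1} <= J)"
        )
    rng = np.random.default_rng(seed)
    names = [c.name for c in components]
    if generating is None:
        gen_names = set(table2_generating_parameters().alpha)
        if set(names) <= gen_names:
            generating = table2_generating_parameters()
    if generating is not None:
        alpha = np.array([generating.alpha[c] for c in names])
    else:
        alpha = rng.standard_normal(M)

    rule_idx = [m for m, c in enumerate(components) if c.kind == "rule"]
    fig_idx = [m for m, c in enumerate(components) if c.kind == "figural"]
    if not rule_idx:
        rule_idx = list(range(M))
        fig_idx = []

    for _ in range(max_tries):
        W = np.zeros((J, M))
        for j in range(J):
            k = rng.integers(1, min(3, len(rule_idx)) + 1)
            chosen = rng.choice(rule_idx, size=k, replace=False)
            W[j, chosen] = rng.integers(1, 3, size=k)
            for m in fig_idx:
                W[j, m] = rng.random() < 0.4
        if np.any(W.sum(axis=0) == 0):
            continue
        if ordering == "by_predicted_difficulty":
            W = W[np.argsort(W @ alpha, kind="stable")]
        design = TestDesign(components, W)
        report = check_identification(design, build_practice_matrix(design))
        if report.passed:
            return design
    raise RuntimeError(
        f"could not generate an identified design in {max_tries} attempts"
    )


# ---------------------------------------------------------------------------
# Person parameters and responses


@dataclass
class PersonTruth:
    """Generating person-level values: ability and the full practice matrix."""

    theta: np.ndarray
    practice: np.ndarray  # (n, M) per-person practice coefficients
    components: list[str]
    random_components: list[str]

    @property
    def n(self) -> int:
        return self.theta.shape[0]

    def random_effects(self) -> np.ndarray:
        """(n, R) person draws for the random components only."""
        idx = [self.components.index(c) for c in self.random_components]
        return self.practice[:, idx]


def generate_persons(
    n: int, generating: GeneratingParameters, seed: int = 0
) -> PersonTruth:
    """theta i.i.d. standard normal; random practice effects i.i.d.
    MVN(mu, diag(sigma) Omega diag(sigma)); fixed effects broadcast."""
    rng = np.random.default_rng(seed)
    comps = generating.components
    theta = rng.standard_normal(n)
    practice = np.zeros((n, len(comps)))
    rand = generating.random_components
    if rand:
        mu = np.array([generating.practice[c].mu for c in rand])
        sigma = np.array([generating.practice[c].sigma for c in rand])
        L = sigma[:, None] * np.linalg.cholesky(generating.Omega)
        z = rng.standard_normal((n, len(rand)))
        deltas = mu + z @ L.T
        for r, c in enumerate(rand):
            practice[:, comps.index(c)] = deltas[:, r]
    for c in comps:
        p = generating.practice[c]
        if p.mode == "fixed":
            practice[:, comps.index(c)] = p.value
    return PersonTruth(
        theta=theta, practice=practice, components=list(comps), random_components=rand
    )


#: lognormal latency model: exp(N(log 5, 0.4)) seconds, essentially never
#: below the 1-second involuntary-response threshold.
LATENCY_LOG_MEAN = float(np.log(5.0))
LATENCY_LOG_SD = 0.4


def true_logits(
    design: TestDesign, practice: PracticeMatrix, persons: PersonTruth,
    generating: GeneratingParameters,
) -> np.ndarray:
    alpha = np.array([generating.alpha[c.name] for c in design.components])
    return (
        persons.theta[:, None]
        - np.tile(alpha @ design.W.T, (persons.n, 1))
        + persons.practice @ practice.V.T
    )


def simulate_responses(
    design: TestDesign,
    practice: PracticeMatrix,
    persons: PersonTruth,
    generating: GeneratingParameters,
    seed: int = 0,
    with_latencies: bool = True,
    contamination: float = 0.0,
) -> ResponseData:
    """Bernoulli responses from the forward model, with optional lognormal
    latencies; a ``contamination`` fraction of persons receives at least one
    sub-second latency so the exclusion filter has work to do."""
    rng = np.random.default_rng(seed)
    p = expit(true_logits(design, practice, persons, generating))
    X = (rng.random(p.shape) < p).astype(np.int8)
    latencies = None
    if with_latencies:
        latencies = np.exp(
            LATENCY_LOG_MEAN + LATENCY_LOG_SD * rng.standard_normal(p.shape)
        )
        if contamination > 0:
            bad = rng.random(persons.n) < contamination
            for i in np.flatnonzero(bad):
                k = rng.integers(1, 4)
                items = rng.choice(design.J, size=k, replace=False)
                latencies[i, items] = rng.uniform(0.2, 0.99, size=k)
    return ResponseData(X=X, latencies=latencies)


@dataclass
class ExclusionReport:
    n_total: int
    n_excluded: int
    excluded_ids: np.ndarray
    threshold_seconds: float

    @property
    def fraction_excluded(self) -> float:
        return self.n_excluded / self.n_total if self.n_total else 0.0


def latency_filter(
    data: ResponseData, threshold_seconds: float = 1.0
) -> tuple[ResponseData, ExclusionReport]:
    """Drop every person with any item latency below the threshold
    (interpreted as an involuntary response)."""
    if data.latencies is None:
        raise ValueError(
            "no latencies present; re-run without the latency filter (--no-filter)"
        )
    bad = (data.latencies < threshold_seconds).any(axis=1)
    keep = ~bad
    filtered = ResponseData(
        X=data.X[keep],
        person_ids=data.person_ids[keep],
        latencies=data.latencies[keep],
    )
    report = ExclusionReport(
        n_total=data.n,
        n_excluded=int(bad.sum()),
        excluded_ids=data.person_ids[bad],
        threshold_seconds=threshold_seconds,
    )
    return filtered, report


# ---------------------------------------------------------------------------
# External measures


@dataclass
class ExternalMeasureSpec:
    """Linear-Gaussian external measures with target population correlations.

    ``targets[measure][param]`` is the desired correlation of the measure
    with a person parameter named ``"theta"`` or ``"delta[<component>]"``.
    """

    targets: dict[str, dict[str, float]]

    @classmethod
    def table3_defaults(cls) -> "ExternalMeasureSpec":
        """Measure structure mirroring a GTB-like ability battery and
        NEO-PI-R-like dimensions at realistic magnitudes."""
        return cls(
            targets={
                "GTB": {"theta": 0.513, "delta[A/S]": 0.254, "delta[distortion]": 0.221},
                "Openness": {"theta": 0.175, "delta[A/S]": 0.075, "delta[distortion]": 0.097},
                "Conscientiousness": {"theta": -0.098, "delta[A/S]": -0.103, "delta[distortion]": -0.079},
                "Extraversion": {"theta": 0.014, "delta[A/S]": -0.065, "delta[distortion]": -0.085},
                "Agreeableness": {"theta": -0.076, "delta[A/S]": -0.094, "delta[distortion]": -0.091},
                "Neuroticism": {"theta": -0.071, "delta[A/S]": -0.040, "delta[distortion]": -0.005},
            }
        )


def generate_external_measures(
    persons: PersonTruth,
    spec: ExternalMeasureSpec,
    generating: GeneratingParameters,
    seed: int = 0,
) -> pd.DataFrame:
    """Person-level measures whose population correlations with the
    standardized true parameters equal the targets.

    With predictor correlation matrix C (theta independent of the random
    effects, which correlate via Omega) the weights solve C b = r and the
    residual variance is 1 - r' C^-1 r; infeasible targets raise.
    """
    rng = np.random.default_rng(seed)
    rand = persons.random_components
    param_names = ["theta"] + [f"delta[{c}]" for c in rand]
    # standardized predictors
    cols = [persons.theta]
    for c in rand:
        p = generating.practice[c]
        if p.sigma <= 0:
            raise ValueError(
                f"component {c!r} has zero generating SD; cannot target correlations"
            )
        cols.append((persons.practice[:, persons.components.index(c)] - p.mu) / p.sigma)
    Z = np.column_stack(cols)
    R = len(rand)
    C = np.eye(1 + R)
    if R:
        C[1:, 1:] = generating.Omega

    out = pd.DataFrame({"person": np.arange(1, persons.n + 1)})
    for measure, tmap in spec.targets.items():
        unknown = set(tmap) - set(param_names)
        if unknown:
            raise KeyError(f"unknown parameters in targets for {measure!r}: {unknown}")
        r = np.array([tmap.get(p, 0.0) for p in param_names])
        b = np.linalg.solve(C, r)
        explained = float(r @ b)
        if explained > 1.0 + 1e-12:
            raise ValueError(
                f"target correlations for {measure!r} are infeasible "
                f"(implied variance {explained:.3f} > 1)"
            )
        noise_sd = float(np.sqrt(max(1.0 - explained, 0.0)))
        out[measure] = Z @ b + noise_sd * rng.standard_normal(persons.n)
    return out
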