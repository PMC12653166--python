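"""Posterior sampling, convergence diagnostics and posterior summaries.

``fit`` runs NUTS chains on the joint posterior of any model spec and
returns :class:`PosteriorDraws`; ``summarize`` produces the EAP / SD /
2.5--97.5% / R-hat table; the remaining helpers answer the individual-level
questions (posterior sign probabilities, per-person practice-effect
classification, difficulty trajectories).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._nuts import nuts_sample
from ._posterior import Posterior
from .design import PracticeMatrix, TestDesign, build_practice_matrix, check_identification
from .models import ModelSpec, ResponseData, rule_difficulty_trajectory

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "fit",
    "summarize",
    "posterior_probability",
    "classify_individuals",
    "trajectories",
]

RHAT_THRESHOLD = 1.01


def _rhat(x: np.ndarray) -> float:
    """Rank-normalized split R-hat (delegated to arviz)."""
    import arviz as az

    if x.ndim != 2:
        raise ValueError("expected (chains, draws)")
    if np.allclose(x, x.ravel()[0]):
        warnings.warn("constant draws: R-hat undefined", stacklevel=2)
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.asarray(az.rhat(az.convert_to_dataset(x[..., None]))["x"]).item())


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run configuration.

    The default mirrors the reference setting of four chains of 5000
    iterations with the first half discarded as burn-in; ``fast()`` is a
    desk-scale profile for tests and demos.
    """

    chains: int = 4
    iterations: int = 5000
    warmup_fraction: float = 0.5
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not 0 < self.warmup_fraction < 1:
            raise ValueError("warmup_fraction must be in (0, 1)")
        if self.warmup_fraction == 0.5 and self.iterations % 2:
            raise ValueError("iterations must be even when warmup is half")

    @property
    def n_warmup(self) -> int:
        return int(round(self.iterations * self.warmup_fraction))

    @property
    def n_draws(self) -> int:
        return self.iterations - self.n_warmup

    @classmethod
    def fast(cls, seed: int = 0, chains: int = 2, iterations: int = 1000) -> "SamplerConfig":
        return cls(chains=chains, iterations=iterations, seed=seed)


@dataclass
class PosteriorDraws:
    """Post-warmup draws of all active parameters plus pointwise log-likelihoods.

    ``draws[name]`` has shape ``(chains, draws, *param_shape)``; ``log_lik``
    has shape ``(chains, draws, n, J)``.
    """

    spec: ModelSpec
    design: TestDesign
    practice: PracticeMatrix
    data: ResponseData
    config: SamplerConfig
    draws: dict[str, np.ndarray]
    log_lik: np.ndarray
    labels: dict[str, list[str]]
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.log_lik.shape[0]

    @property
    def n_draws(self) -> int:
        return self.log_lik.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one parameter with chains concatenated: (S, *shape)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def stacked_log_lik(self) -> np.ndarray:
        """(S, n*J) pointwise log-likelihood matrix."""
        ll = self.log_lik
        return ll.reshape(ll.shape[0] * ll.shape[1], -1).astype(float)

    # -- flat scalar access -------------------------------------------------

    def _flat_index(self, name: str) -> tuple[str, tuple[int, ...]]:
        """Resolve e.g. 'mu_delta[distortion]', 'alpha[CR]', 'theta[3]',
        'delta[3,A/S]' to an array key plus index."""
        m = re.fullmatch(r"([A-Za-z_]+)(?:\[(.*)\])?", name.strip())
        if not m:
            raise KeyError(f"cannot parse parameter name {name!r}")
        key, idx_str = m.group(1), m.group(2)
        if key not in self.draws:
            raise KeyError(f"unknown parameter {key!r}; have {sorted(self.draws)}")
        if idx_str is None:
            if self.draws[key].ndim != 2:
                raise KeyError(f"{key!r} is not scalar; give an index")
            return key, ()
        idx: list[int] = []
        parts = [p.strip() for p in idx_str.split(",")]
        shape = self.draws[key].shape[2:]
        lab = self.labels.get(key if key not in ("mu_delta", "sigma_delta") else "delta")
        if key in ("mu_eta", "sigma_eta"):
            lab = self.labels.get("eta")
        for d, part in enumerate(parts):
            if part.lstrip("-").isdigit():
                i = int(part)
                # person axes are 1-based in user-facing names
                idx.append(i - 1 if (key in ("theta", "delta", "eta") and d == 0) else i)
            else:
                if lab is None or part not in lab:
                    raise KeyError(f"unknown component label {part!r} for {key!r}")
                idx.append(lab.index(part))
        if len(idx) != len(shape):
            raise KeyError(f"{key!r} expects {len(shape)} indices, got {len(idx)}")
        return key, tuple(idx)

    def scalar_draws(self, name: str) -> np.ndarray:
        """All post-warmup draws of one scalar parameter, chains stacked."""
        key, idx = self._flat_index(name)
        arr = self.stacked(key)
        for i in idx:
            arr = arr[:, i]
        return arr

    # -- persistence --------------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            out_dir / "draws.npz", log_lik=self.log_lik.astype(np.float32), **self.draws
        )
        from .design import write_design

        write_design(self.design, out_dir / "design.json")
        meta = {
            "variant": self.spec.variant,
            "difficulty_mode": dict(self.spec.difficulty_mode),
            "practice_mode": dict(self.spec.practice_mode),
            "labels": self.labels,
            "config": {
                "chains": self.config.chains,
                "iterations": self.config.iterations,
                "warmup_fraction": self.config.warmup_fraction,
                "seed": self.config.seed,
                "target_accept": self.config.target_accept,
                "max_treedepth": self.config.max_treedepth,
            },
            "diagnostics": self.diagnostics,
            "data_fingerprint": data_fingerprint(self.data),
        }
        (out_dir / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
        self.data.to_frame().to_csv(out_dir / "responses.csv", index=False)

    @classmethod
    def load(cls, out_dir: str | Path) -> "PosteriorDraws":
        from .design import read_design

        out_dir = Path(out_dir)
        meta = json.loads((out_dir / "meta.json").read_text())
        design = read_design(out_dir / "design.json")
        spec = ModelSpec(
            meta["variant"], meta["difficulty_mode"], meta["practice_mode"]
        )
        data = ResponseData.from_csv(out_dir / "responses.csv")
        with np.load(out_dir / "draws.npz") as npz:
            arrays = {k: npz[k] for k in npz.files}
        log_lik = arrays.pop("log_lik")
        return cls(
            spec=spec,
            design=design,
            practice=build_practice_matrix(design),
            data=data,
            config=SamplerConfig(**meta["config"]),
            draws=arrays,
            log_lik=log_lik,
            labels={k: list(v) for k, v in meta["labels"].items()},
            diagnostics=meta.get("diagnostics", {}),
        )


def data_fingerprint(data: ResponseData) -> str:
    import hashlib

    return hashlib.sha256(np.ascontiguousarray(data.X).tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------


def fit(
    spec: ModelSpec,
    design: TestDesign,
    practice: PracticeMatrix | None,
    data: ResponseData,
    config: SamplerConfig | None = None,
    check: bool = True,
    loglik_weights: np.ndarray | None = None,
) -> PosteriorDraws:
    """Sample the posterior of ``spec`` on ``data`` with NUTS.

    Runs ``config.chains`` independent chains sequentially (seeded from
    ``config.seed``), discards warmup, and stores named natural-parameter
    draws plus the pointwise log-likelihood of every saved draw.
    Sampling problems (divergences, R-hat failures) are surfaced through the
    ``diagnostics`` dict and warnings, never silently dropped.
    """
    config = config or SamplerConfig()
    if practice is None:
        practice = build_practice_matrix(design)
    if check:
        report = check_identification(design, practice, spec)
        if not report.passed:
            raise ValueError(f"identification failed: {report.messages}")
    post = Posterior(spec, design, practice, data, loglik_weights=loglik_weights)

    seed_seq = np.random.SeedSequence(config.seed)
    chain_seeds = seed_seq.spawn(config.chains)

    shapes = post.param_shapes()
    draws = {
        k: np.empty((config.chains, config.n_draws, *shape))
        for k, shape in shapes.items()
    }
    log_lik = np.empty((config.chains, config.n_draws, data.n, data.J), dtype=np.float32)
    diag = {"divergences": [], "step_size": [], "accept_rate": [], "treedepth_mean": []}

    for c, ss in enumerate(chain_seeds):
        rng = np.random.default_rng(ss)
        init = 0.1 * rng.standard_normal(post.dim)
        res = nuts_sample(
            post.logp_grad,
            init,
            n_warmup=config.n_warmup,
            n_draws=config.n_draws,
            rng=rng,
            target_accept=config.target_accept,
            max_treedepth=config.max_treedepth,
        )
        for d in range(config.n_draws):
            q = res.positions[d]
            for k, v in post.constrain(q).items():
                draws[k][c, d] = v
            log_lik[c, d] = post.pointwise_loglik(q)
        diag["divergences"].append(int(res.n_divergent))
        diag["step_size"].append(float(res.step_size))
        diag["accept_rate"].append(float(res.accept_rate))
        diag["treedepth_mean"].append(float(res.treedepths.mean()))

    total_div = sum(diag["divergences"])
    if total_div:
        warnings.warn(
            f"{total_div} divergent transitions after warmup; "
            "posterior summaries may be biased",
            stacklevel=2,
        )
    return PosteriorDraws(
        spec=spec,
        design=design,
        practice=practice,
        data=data,
        config=config,
        draws=draws,
        log_lik=log_lik,
        labels=post.component_labels(),
        diagnostics=diag,
    )


# ---------------------------------------------------------------------------


def _summary_row(x2d: np.ndarray) -> dict[str, float]:
    flat = x2d.reshape(-1)
    return {
        "EAP": float(flat.mean()),
        "SD": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
        "2.5%": float(np.quantile(flat, 0.025)),
        "97.5%": float(np.quantile(flat, 0.975)),
        "Rhat": _rhat(x2d),
    }


def summarize(draws: PosteriorDraws, include_persons: bool = False) -> pd.DataFrame:
    """EAP, posterior SD, central 2.5--97.5% interval and R-hat per parameter.

    Person-level parameters (theta, per-person random effects) are omitted
    unless ``include_persons`` — the table then mirrors the fixed-effect /
    hyper-parameter layout of the reference analysis.
    """
    rows: dict[str, dict[str, float]] = {}

    def label_for(key: str, j: int) -> str:
        base = key
        for prefix in ("mu_", "sigma_", "Omega_"):
            if key.startswith(prefix):
                base = key[len(prefix):]
        lab = draws.labels.get(base)
        return lab[j] if lab and j < len(lab) else str(j + 1)

    for key, arr in draws.draws.items():
        if key in ("theta", "delta", "eta"):
            if not include_persons:
                continue
            for i in range(arr.shape[2]):
                if arr.ndim == 3:
                    rows[f"{key}[{i + 1}]"] = _summary_row(arr[:, :, i])
                else:
                    for j in range(arr.shape[3]):
                        rows[f"{key}[{i + 1},{label_for(key, j)}]"] = _summary_row(
                            arr[:, :, i, j]
                        )
        elif arr.ndim == 3:
            for j in range(arr.shape[2]):
                rows[f"{key}[{label_for(key, j)}]"] = _summary_row(arr[:, :, j])
        elif arr.ndim == 4:  # correlation matrices: report lower off-diagonal
            for a in range(arr.shape[2]):
                for b in range(a):
                    rows[f"{key}[{label_for(key, a)},{label_for(key, b)}]"] = (
                        _summary_row(arr[:, :, a, b])
                    )
        else:
            rows[key] = _summary_row(arr)

    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "parameter"
    bad = df.index[df["Rhat"] > RHAT_THRESHOLD].tolist()
    if bad:
        warnings.warn(f"R-hat above {RHAT_THRESHOLD} for: {bad}", stacklevel=2)
    return df


def posterior_probability(
    draws: PosteriorDraws, parameter: str, direction: str = ">", value: float = 0.0
) -> float:
    """Posterior probability of a sign/threshold event, e.g.
    ``posterior_probability(fit, "delta_fixed[D3]", ">")`` for P(delta > 0 | x)."""
    x = draws.scalar_draws(parameter)
    if direction == ">":
        return float(np.mean(x > value))
    if direction == "<":
        return float(np.mean(x < value))
    raise ValueError("direction must be '>' or '<'")


def classify_individuals(
    draws: PosteriorDraws, component: str
) -> tuple[pd.DataFrame, float]:
    """Per-person EAP of a random practice effect and the fraction positive."""
    lab = draws.labels.get("delta", [])
    if component not in lab:
        raise ValueError(
            f"component {component!r} does not have a random practice effect"
        )
    j = lab.index(component)
    eap = draws.stacked("delta")[:, :, j].mean(axis=0)
    table = pd.DataFrame(
        {
            "person": draws.data.person_ids,
            "component": component,
            "eap_delta": eap,
            "positive": eap > 0,
        }
    )
    return table, float(np.mean(eap > 0))


def trajectories(
    draws: PosteriorDraws,
    persons: np.ndarray | list | None = None,
    components: list[str] | None = None,
) -> pd.DataFrame:
    """Component-difficulty-vs-practice curves evaluated at EAP estimates.

    For fixed-practice components the curve is shared by all persons
    (person is reported as NA); for random-practice components one curve is
    produced per requested person.  Output is a tidy table with columns
    component, person, item, accumulated_weight, difficulty.
    """
    design = draws.design
    spec = draws.spec
    comp_names = components or spec.components
    alpha_lab = draws.labels.get("alpha", [])
    alpha_eap = draws.stacked("alpha").mean(axis=0) if "alpha" in draws.draws else None
    dfix_lab = draws.labels.get("delta_fixed", [])
    dfix_eap = (
        draws.stacked("delta_fixed").mean(axis=0)
        if "delta_fixed" in draws.draws
        else None
    )
    rand_lab = draws.labels.get("delta", [])
    delta_eap = (
        draws.stacked("delta").mean(axis=0) if "delta" in draws.draws else None
    )
    eta_lab = draws.labels.get("eta", [])
    eta_eap = draws.stacked("eta").mean(axis=0) if "eta" in draws.draws else None

    if persons is None:
        persons = list(draws.data.person_ids)
    pid_to_row = {pid: i for i, pid in enumerate(draws.data.person_ids)}

    records = []
    for name in comp_names:
        m = design.component_index(name)
        col = design.W[:, m]
        if name in alpha_lab:
            a = float(alpha_eap[alpha_lab.index(name)])
        elif name in eta_lab:
            a = None  # person-specific difficulty handled below
        else:
            a = None
        mode = spec.practice_mode[name]
        if mode == "random":
            for pid in persons:
                d = float(delta_eap[pid_to_row[pid], rand_lab.index(name)])
                for j in range(1, design.J + 1):
                    records.append(
                        {
                            "component": name,
                            "person": pid,
                            "item": j,
                            "accumulated_weight": float(col[: j - 1].sum()),
                            "difficulty": rule_difficulty_trajectory(a, d, col, j),
                        }
                    )
        else:
            d = (
                float(dfix_eap[dfix_lab.index(name)])
                if (mode == "fixed" and name in dfix_lab)
                else 0.0
            )
            if a is None and name in eta_lab:
                # RWLLTM: flat per-person difficulty curves at eta EAPs
                for pid in persons:
                    ai = float(eta_eap[pid_to_row[pid], eta_lab.index(name)])
                    for j in range(1, design.J + 1):
                        records.append(
                            {
                                "component": name,
                                "person": pid,
                                "item": j,
                                "accumulated_weight": float(col[: j - 1].sum()),
                                "difficulty": rule_difficulty_trajectory(ai, 0.0, col, j),
                            }
                        )
                continue
            for j in range(1, design.J + 1):
                records.append(
                    {
                        "component": name,
                        "person": pd.NA,
                        "item": j,
                        "accumulated_weight": float(col[: j - 1].sum()),
                        "difficulty": rule_difficulty_trajectory(a, d, col, j),
                    }
                )
    return pd.DataFrame.from_records(records)
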