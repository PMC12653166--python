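"""Downstream analysis and artifact rendering: correlations of person-level
EAPs with external measures, the Rasch-difficulty variance-explained
regression (including the item-position check), and table/figure exports."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .design import TestDesign
from .inference import PosteriorDraws, SamplerConfig, fit, summarize, trajectories
from .models import ModelSpec, ResponseData

__all__ = [
    "person_eap_table",
    "correlate_effects",
    "pivot_correlation_table",
    "rasch_difficulties",
    "variance_explained",
    "VarianceExplainedReport",
    "render_reports",
]


def person_eap_table(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-person EAP estimates of ability and each random practice effect."""
    out = pd.DataFrame({"person": draws.data.person_ids})
    out["theta"] = draws.stacked("theta").mean(axis=0)
    if "delta" in draws.draws:
        eap = draws.stacked("delta").mean(axis=0)
        for j, name in enumerate(draws.labels["delta"]):
            out[f"delta[{name}]"] = eap[:, j]
    return out


def correlate_effects(
    person_eaps: pd.DataFrame, external: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations of EAP columns with external measures.

    Two-tailed p-values come from the exact t transform of r with n-2
    degrees of freedom.  Returns a tidy table with significance flags at
    the .05 and .01 levels; persons are aligned on the ``person`` column.
    """
    if "person" not in person_eaps.columns or "person" not in external.columns:
        raise ValueError("both tables need a 'person' column")
    merged = person_eaps.merge(external, on="person", how="inner", validate="1:1")
    if len(merged) < len(person_eaps) or len(merged) < len(external):
        raise ValueError("person IDs do not align between EAPs and external measures")
    eap_cols = [c for c in person_eaps.columns if c != "person"]
    measure_cols = [c for c in external.columns if c != "person"]
    n = len(merged)
    rows = []
    for meas in measure_cols:
        for par in eap_cols:
            r, p = stats.pearsonr(merged[meas], merged[par])
            rows.append(
                {
                    "measure": meas,
                    "parameter": par,
                    "r": float(r),
                    "p": float(p),
                    "n": n,
                    "sig_05": bool(p < 0.05),
                    "sig_01": bool(p < 0.01),
                }
            )
    return pd.DataFrame(rows)


def pivot_correlation_table(corr: pd.DataFrame) -> pd.DataFrame:
    """Wide measures-by-parameters view with significance stars."""

    def fmt(row):
        stars = "**" if row.sig_01 else ("*" if row.sig_05 else "")
        return f"{row.r:.3f}{stars}"

    tmp = corr.assign(cell=corr.apply(fmt, axis=1))
    return tmp.pivot(index="measure", columns="parameter", values="cell")


def rasch_difficulties(
    data: ResponseData, config: SamplerConfig | None = None
) -> pd.DataFrame:
    """Rasch item difficulties as EAPs from the model family itself.

    The Rasch model is the practice-free special case with W = identity:
    each item is its own component.  Degenerate items (all-0 or all-1
    columns) are rejected.
    """
    means = data.X.mean(axis=0)
    degenerate = np.flatnonzero((means == 0) | (means == 1))
    if degenerate.size:
        raise ValueError(
            f"items with only one observed outcome: {(degenerate + 1).tolist()}"
        )
    J = data.J
    names = [f"item_{j}" for j in range(1, J + 1)]
    design = TestDesign(
        components=[{"name": nm, "kind": "rule"} for nm in names], W=np.eye(J)
    )
    spec = ModelSpec.lltm(names)
    config = config or SamplerConfig.fast()
    draws = fit(spec, design, None, data, config)
    stacked = draws.stacked("alpha")
    return pd.DataFrame(
        {
            "item": np.arange(1, J + 1),
            "difficulty": stacked.mean(axis=0),
            "sd": stacked.std(axis=0, ddof=1),
        }
    )


@dataclass
class VarianceExplainedReport:
    """OLS decomposition of item difficulty into component weights, with the
    incremental contribution of raw item position."""

    r2_components: float
    r2_with_position: float
    incremental_r2: float
    f_statistic: float
    p_value: float
    n_items: int
    coefficients: dict[str, float]

    @property
    def position_significant(self) -> bool:
        return self.p_value < 0.05


def variance_explained(
    difficulties: np.ndarray | pd.DataFrame,
    design: TestDesign,
    positions: np.ndarray | None = None,
) -> VarianceExplainedReport:
    """Regress item difficulties on the design's component weights; then add
    item position and F-test its incremental contribution."""
    if isinstance(difficulties, pd.DataFrame):
        difficulties = difficulties["difficulty"].to_numpy()
    y = np.asarray(difficulties, dtype=float)
    J, M = design.J, design.M
    if y.shape != (J,):
        raise ValueError("one difficulty per item required")
    if J <= M + 2:
        raise ValueError(f"need J > M + 2 items for the regression (J={J}, M={M})")
    if positions is None:
        positions = np.arange(1, J + 1, dtype=float)
    X0 = np.column_stack([np.ones(J), design.W])
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise ValueError("rank-deficient regression matrix (intercept + W)")
    X1 = np.column_stack([X0, positions])

    def ols_rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return beta, float(resid @ resid)

    beta0, rss0 = ols_rss(X0)
    _, rss1 = ols_rss(X1)
    tss = float(((y - y.mean()) ** 2).sum())
    r2_0 = 1.0 - rss0 / tss
    r2_1 = 1.0 - rss1 / tss
    df2 = J - X1.shape[1]
    f = ((rss0 - rss1) / 1.0) / (rss1 / df2) if rss1 > 0 else np.inf
    p = float(stats.f.sf(f, 1, df2))
    coefs = {"intercept": float(beta0[0])}
    coefs.update({c.name: float(b) for c, b in zip(design.components, beta0[1:])})
    return VarianceExplainedReport(
        r2_components=float(r2_0),
        r2_with_position=float(r2_1),
        incremental_r2=float(max(r2_1 - r2_0, 0.0)),
        f_statistic=float(f),
        p_value=p,
        n_items=J,
        coefficients=coefs,
    )


def render_reports(
    draws: PosteriorDraws,
    out_dir: str | Path,
    comparison: pd.DataFrame | None = None,
    correlations: pd.DataFrame | None = None,
    extra_meta: dict | None = None,
) -> list[Path]:
    """Write the standard output bundle of one analysis run.

    Produces a fit-summary CSV (EAP / SD / 2.5% / 97.5% / R-hat), a tidy
    trajectory table for difficulty-vs-practice plots, optional model
    comparison and correlation CSVs, and a deterministic markdown run
    report.  Returns the written paths.
    """
    import oslm

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary = summarize(draws)
    p = out_dir / "fit_summary.csv"
    summary.to_csv(p)
    written.append(p)

    traj = trajectories(draws, persons=list(draws.data.person_ids[:25]))
    p = out_dir / "trajectories.csv"
    traj.to_csv(p, index=False)
    written.append(p)

    if comparison is not None:
        p = out_dir / "model_comparison.csv"
        comparison.to_csv(p, index=False)
        written.append(p)
    if correlations is not None:
        p = out_dir / "external_correlations.csv"
        correlations.to_csv(p, index=False)
        written.append(p)

    lines = [
        "# Analysis run report",
        "",
        f"- package version: {oslm.__version__}",
        f"- model: {draws.spec.variant}",
        f"- persons: {draws.data.n}, items: {draws.data.J}",
        f"- chains: {draws.config.chains}, iterations: {draws.config.iterations}, "
        f"warmup fraction: {draws.config.warmup_fraction}",
        f"- seed: {draws.config.seed}",
        f"- divergences per chain: {draws.diagnostics.get('divergences')}",
        f"- max R-hat (reported parameters): {summary['Rhat'].max():.4f}",
        "",
        "## Files",
    ]
    for w in written:
        lines.append(f"- {w.name}")
    if extra_meta:
        lines += ["", "## Configuration", "", "```json",
                  json.dumps(extra_meta, indent=2, sort_keys=True), "```"]
    p = out_dir / "report.md"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)
    return written
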