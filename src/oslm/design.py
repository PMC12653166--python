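"""Test-design structures: component weight matrix W, cumulative-practice
matrix V, and model-identification checks.

The item-by-component weight matrix ``W`` (J items x M components) is part of
the hypothesized test structure and is never estimated.  The practice matrix
``V`` accumulates, for each item, the weight of each component over all
*previous* items, so that ``v[j, m]`` scales the practice effect acting on
item ``j``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ComponentSpec",
    "TestDesign",
    "PracticeMatrix",
    "IdentificationReport",
    "build_practice_matrix",
    "check_identification",
    "read_design",
    "write_design",
]

COMPONENT_KINDS = ("rule", "figural")

#: component names treated as figural properties when reading a CSV design,
#: which carries no explicit kind column.
DEFAULT_FIGURAL_NAMES = frozenset({"overlay", "distortion", "fusion"})


@dataclass(frozen=True)
class ComponentSpec:
    """A named difficulty component: an abstract rule or a figural property."""

    name: str
    kind: str = "rule"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("component name must be non-empty")
        if self.kind not in COMPONENT_KINDS:
            raise ValueError(
                f"component kind must be one of {COMPONENT_KINDS}, got {self.kind!r}"
            )


@dataclass(frozen=True)
class TestDesign:
    """Items-in-administration-order design with its weight matrix.

    Parameters
    ----------
    components:
        Component definitions; order matches the columns of ``W``.
    W:
        (J, M) array of nonnegative component weights (counts of component
        applications per item).  Rows are items in administration order.
    """

    __test__ = False  # class name looks like a pytest collection target

    components: tuple[ComponentSpec, ...]
    W: np.ndarray

    def __init__(self, components: Iterable[ComponentSpec], W: np.ndarray) -> None:
        components = tuple(
            c if isinstance(c, ComponentSpec) else ComponentSpec(**c)
            for c in components
        )
        W = np.asarray(W, dtype=float)
        if W.ndim != 2:
            raise ValueError("W must be a 2-D matrix")
        J, M = W.shape
        if J < 1:
            raise ValueError("design must contain at least one item")
        if M != len(components):
            raise ValueError(
                f"W has {M} columns but {len(components)} components were given"
            )
        names = [c.name for c in components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        if not np.all(np.isfinite(W)):
            raise ValueError("W contains non-finite entries")
        if np.any(W < 0):
            raise ValueError("W contains negative weights")
        if np.any(W.sum(axis=0) == 0):
            dead = [names[m] for m in np.flatnonzero(W.sum(axis=0) == 0)]
            raise ValueError(f"components never used by any item: {dead}")
        if not np.allclose(W, np.round(W)):
            warnings.warn(
                "W contains non-integer weights; weights are conventionally "
                "counts of component applications",
                stacklevel=2,
            )
        object.__setattr__(self, "components", components)
        object.__setattr__(self, "W", W)
        self.W.setflags(write=False)

    @property
    def J(self) -> int:
        return self.W.shape[0]

    @property
    def M(self) -> int:
        return self.W.shape[1]

    @property
    def component_names(self) -> list[str]:
        return [c.name for c in self.components]

    def component_index(self, name: str) -> int:
        try:
            return self.component_names.index(name)
        except ValueError:
            raise KeyError(f"unknown component {name!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TestDesign):
            return NotImplemented
        return self.components == other.components and np.array_equal(self.W, other.W)


@dataclass(frozen=True)
class PracticeMatrix:
    """Cumulative-practice weights ``V`` and the augmented ``V_plus = (V, 1)``."""

    V: np.ndarray
    V_plus: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        if np.any(V[0] != 0):
            raise ValueError("first row of V must be all zeros (no prior practice)")
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "V_plus", np.hstack([V, np.ones((V.shape[0], 1))]))
        self.V.setflags(write=False)
        self.V_plus.setflags(write=False)


def build_practice_matrix(design: TestDesign) -> PracticeMatrix:
    """Derive the practice matrix from a design.

    ``v[j, m] = w[j, m] * sum_{k < j} w[k, m]`` — item j's weight on component
    m scaled by the total weight of m over all earlier items.  Row 1 is zero.
    """
    W = design.W
    prior = np.vstack([np.zeros((1, design.M)), np.cumsum(W, axis=0)[:-1]])
    return PracticeMatrix(V=W * prior)


@dataclass
class IdentificationReport:
    """Outcome of the identification checks for a (design, model) pair."""

    rank_W_ok: bool
    rank_Vplus_ok: bool
    rank_concat_ok: bool
    effect_count_ok: bool
    messages: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return (
            self.rank_W_ok
            and self.rank_Vplus_ok
            and self.rank_concat_ok
            and self.effect_count_ok
        )


def _full_column_rank(A: np.ndarray) -> bool:
    # numerical rank with threshold max(dims) * eps * sigma_max
    return np.linalg.matrix_rank(A) == A.shape[1]


def check_identification(
    design: TestDesign,
    practice: PracticeMatrix | None = None,
    model=None,
) -> IdentificationReport:
    """Verify the rank and effect-count conditions for estimability.

    With practice effects in the model, ``W``, ``V_plus`` and their
    column-concatenation must all have full column rank, and the number of
    effects must not exceed the number of items (``2M + 1 <= J``).  For
    practice-free models (LLTM / RWLLTM) only the ``W`` rank and ``M <= J``
    matter; the practice-related flags are reported as vacuously true.
    """
    J, M = design.J, design.M
    msgs: list[str] = []

    has_practice = True
    if model is not None:
        has_practice = any(m != "none" for m in model.practice_mode.values())

    rank_W_ok = _full_column_rank(design.W)
    if not rank_W_ok:
        msgs.append("W does not have full column rank")

    if not has_practice:
        effect_count_ok = M <= J
        if not effect_count_ok:
            msgs.append(f"number of effects exceeds item count: M={M} > J={J}")
        msgs.append("practice-free model: V-related rank checks not applicable")
        return IdentificationReport(
            rank_W_ok=rank_W_ok,
            rank_Vplus_ok=True,
            rank_concat_ok=True,
            effect_count_ok=effect_count_ok,
            messages=msgs,
        )

    if practice is None:
        practice = build_practice_matrix(design)
    if practice.V.shape != design.W.shape:
        raise ValueError(
            f"practice matrix shape {practice.V.shape} does not match W {design.W.shape}"
        )

    rank_Vplus_ok = _full_column_rank(practice.V_plus)
    if not rank_Vplus_ok:
        msgs.append("V+ = (V, 1) does not have full column rank")
    rank_concat_ok = _full_column_rank(np.hstack([design.W, practice.V_plus]))
    if not rank_concat_ok:
        msgs.append("concatenation (W, V+) does not have full column rank")
    effect_count_ok = 2 * M + 1 <= J
    if not effect_count_ok:
        msgs.append(f"number of effects exceeds item count: 2M+1={2 * M + 1} > J={J}")
    return IdentificationReport(
        rank_W_ok=rank_W_ok,
        rank_Vplus_ok=rank_Vplus_ok,
        rank_concat_ok=rank_concat_ok,
        effect_count_ok=effect_count_ok,
        messages=msgs,
    )


# ---------------------------------------------------------------------------
# I/O


def write_design(design: TestDesign, path: str | Path) -> None:
    """Write a design to CSV (weights only) or JSON (full fidelity).

    The format is chosen from the file extension.  The CSV layout is
    ``item,<component names...>`` with one row per item (1-based item ids);
    component kinds are not stored in CSV and are re-inferred on read.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "components": [{"name": c.name, "kind": c.kind} for c in design.components],
            "W": design.W.tolist(),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif path.suffix.lower() == ".csv":
        df = pd.DataFrame(design.W, columns=design.component_names)
        df.insert(0, "item", np.arange(1, design.J + 1))
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported design format: {path.suffix!r}")


def _infer_kind(name: str) -> str:
    return "figural" if name.lower() in DEFAULT_FIGURAL_NAMES else "rule"


def read_design(
    path: str | Path, kinds: dict[str, str] | None = None
) -> TestDesign:
    """Read a design written by :func:`write_design`.

    For CSV input, component kinds are taken from ``kinds`` when given and
    otherwise inferred by name (overlay/distortion/fusion are figural, all
    other components are rules).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        comps = []
        for entry in payload.get("components", []):
            if "name" not in entry:
                raise ValueError("design JSON component missing field 'name'")
            if "kind" not in entry:
                raise ValueError(
                    f"design JSON component {entry.get('name')!r} missing field 'kind'"
                )
            comps.append(ComponentSpec(name=entry["name"], kind=entry["kind"]))
        if "W" not in payload:
            raise ValueError("design JSON missing field 'W'")
        return TestDesign(components=comps, W=np.asarray(payload["W"], dtype=float))
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if "item" in df.columns:
            df = df.drop(columns=["item"])
        names = list(df.columns)
        kinds = kinds or {}
        comps = [
            ComponentSpec(name=n, kind=kinds.get(n, _infer_kind(n))) for n in names
        ]
        W = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(W)):
            raise ValueError("design CSV contains non-numeric weight cells")
        return TestDesign(components=comps, W=W)
    raise ValueError(f"unsupported design format: {path.suffix!r}")
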