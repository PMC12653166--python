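"""Shared fixtures.

Expensive MCMC fits are session-scoped and reused across test modules; the
scaled study (4 components, 20 items, 100 persons) keeps them desk-fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from oslm.design import ComponentSpec, TestDesign, build_practice_matrix
from oslm.inference import SamplerConfig, fit
from oslm.models import ModelSpec, ResponseData
from oslm.simulate import (
    ART_COMPONENTS,
    GeneratingParameters,
    generate_design,
    generate_persons,
    simulate_responses,
    table2_generating_parameters,
)

SCALED_NAMES = ["CR", "PP", "A/S", "distortion"]


def scaled_generating_parameters(sigma_factor: float = 1.0) -> GeneratingParameters:
    """Four-component version of the packaged generating values (two fixed
    practice effects, two random)."""
    full = table2_generating_parameters()
    gen = GeneratingParameters(
        alpha={c: full.alpha[c] for c in SCALED_NAMES},
        practice={c: full.practice[c] for c in SCALED_NAMES},
        Omega=full.Omega,
    )
    return gen.scaled_sigma(sigma_factor) if sigma_factor != 1.0 else gen


def scaled_components() -> tuple[ComponentSpec, ...]:
    return tuple(c for c in ART_COMPONENTS if c.name in SCALED_NAMES)


@pytest.fixture(scope="session")
def art_gen() -> GeneratingParameters:
    return table2_generating_parameters()


@pytest.fixture(scope="session")
def art_design(art_gen) -> TestDesign:
    return generate_design(J=34, seed=101, generating=art_gen)


@pytest.fixture(scope="session")
def scaled_gen() -> GeneratingParameters:
    return scaled_generating_parameters()


@pytest.fixture(scope="session")
def scaled_design(scaled_gen) -> TestDesign:
    return generate_design(
        J=20, components=scaled_components(), seed=11, generating=scaled_gen
    )


@pytest.fixture(scope="session")
def scaled_data(scaled_design, scaled_gen) -> ResponseData:
    practice = build_practice_matrix(scaled_design)
    persons = generate_persons(100, scaled_gen, seed=12)
    return simulate_responses(scaled_design, practice, persons, scaled_gen, seed=13)


@pytest.fixture(scope="session")
def rwoslm_fit(scaled_design, scaled_data, scaled_gen):
    """Session RWOSLM_const fit on data simulated from itself."""
    return fit(
        scaled_gen.model_spec(),
        scaled_design,
        None,
        scaled_data,
        SamplerConfig.fast(seed=42, chains=2, iterations=500),
    )


@pytest.fixture(scope="session")
def lltm_fit(scaled_design, scaled_data):
    return fit(
        ModelSpec.lltm(SCALED_NAMES),
        scaled_design,
        None,
        scaled_data,
        SamplerConfig.fast(seed=43, chains=2, iterations=500),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250905)
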