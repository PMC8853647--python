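"""Shared fixtures: the self-fabricating cell model, its EGMs, EGVs at
representative growth rates, and one full growth-rate sweep (session-scoped;
the sweep is the most expensive computation in the suite)."""

from fractions import Fraction as F

import pytest

from egrowth import (
    CapacityParams,
    build_minimal_model,
    build_self_fabricating_model,
    capacity_constraints,
    enumerate_egms,
    enumerate_egvs,
    sweep_mu,
)

MU_LOW = F(1, 2)  # regime L
MU_HIGH = F(5, 4)  # regime H


@pytest.fixture(scope="session")
def model():
    return build_self_fabricating_model()


@pytest.fixture(scope="session")
def minimal_model():
    return build_minimal_model()


@pytest.fixture(scope="session")
def params():
    return CapacityParams.defaults()


@pytest.fixture(scope="session")
def egms(model):
    """EGMs normalised to mu = 1."""
    return enumerate_egms(model, normalize_mu=1)


@pytest.fixture(scope="session")
def egm_by_species(model, egms):
    out = {}
    for rec in egms:
        (sp,) = rec.produced_species
        out[sp] = rec
    return out


@pytest.fixture(scope="session")
def egvs_low(model, params):
    return enumerate_egvs(model, capacity_constraints(model, params, MU_LOW), MU_LOW)


@pytest.fixture(scope="session")
def egvs_high(model, params):
    return enumerate_egvs(model, capacity_constraints(model, params, MU_HIGH), MU_HIGH)


@pytest.fixture(scope="session")
def sweep(model, params):
    return sweep_mu(model, lambda mu: capacity_constraints(model, params, mu))
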