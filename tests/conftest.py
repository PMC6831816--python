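"""Shared fixtures: polymorph specs, solvent conditions, rate model."""

import pytest

from zippersim import SolventConditions, default_polymorph_specs
from zippersim.gillespie_engine import RateModel


@pytest.fixture(scope="session")
def specs():
    return default_polymorph_specs()


@pytest.fixture(scope="session")
def ap_spec(specs):
    return specs["AP"]


@pytest.fixture(scope="session")
def p_spec(specs):
    return specs["P"]


@pytest.fixture(scope="session")
def cond():
    return SolventConditions(temperature=300.0, viscosity=0.89e-3)


@pytest.fixture(scope="session")
def model(specs, cond):
    """A rate model shared across the whole session: its channel cache makes
    repeated engine tests cheap."""
    return RateModel(specs, cond)
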