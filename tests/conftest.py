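"""Shared fixtures: the toy community pipeline, solved once per session."""

from __future__ import annotations

import pytest

from syntroflux.community import build_community
from syntroflux.medium import apply_medium, recipe_to_bounds
from syntroflux.reactor import OperatingPoint, apply_operating_point
from syntroflux.solver import cooperative_tradeoff
from syntroflux.synthetic import make_toy_community, make_toy_medium


@pytest.fixture(scope="session")
def toy_models_and_table():
    return make_toy_community()


@pytest.fixture(scope="session")
def toy_models(toy_models_and_table):
    return toy_models_and_table[0]


@pytest.fixture(scope="session")
def toy_abundances(toy_models_and_table):
    table = toy_models_and_table[1]
    return dict(zip(table["species_id"], table["fraction"]))


@pytest.fixture(scope="session")
def toy_community(toy_models, toy_abundances):
    return build_community(toy_models, toy_abundances)


@pytest.fixture(scope="session")
def toy_medium_bounds():
    return recipe_to_bounds(make_toy_medium())


@pytest.fixture(scope="session")
def medium_community(toy_community, toy_medium_bounds):
    return apply_medium(toy_community, toy_medium_bounds)


@pytest.fixture(scope="session")
def op_community(medium_community):
    return apply_operating_point(medium_community, OperatingPoint())


@pytest.fixture(scope="session")
def op_solution(op_community):
    sol = cooperative_tradeoff(op_community, 0.5)
    assert sol.status == "optimal"
    return sol


@pytest.fixture(scope="session")
def medium_solution(medium_community):
    sol = cooperative_tradeoff(medium_community, 0.5)
    assert sol.status == "optimal"
    return sol
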