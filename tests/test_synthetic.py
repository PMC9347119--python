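"""Structure and determinism of the synthetic community, medium and
coverage generators."""

from __future__ import annotations

import json

import numpy as np
import pytest

from syntroflux.community import build_community
from syntroflux.medium import apply_medium
from syntroflux.model import validate_model
from syntroflux.model_io import _model_to_dict
from syntroflux.solver import _assemble, cooperative_tradeoff, fba
from syntroflux.synthetic import (AMINO_ACIDS, CommunityBlueprint,
                                  CoverageBlueprint, make_coverage_matrix,
                                  make_toy_community)


def test_default_community_shape(toy_models, toy_abundances):
    assert [m.species_id for m in toy_models] == [
        "acetogen", "methanogen", "vfa_consumer", "fermenter_a",
        "fermenter_b"]
    assert list(toy_abundances.values()) == [0.33, 0.26, 0.20, 0.11, 0.10]
    for m in toy_models:
        assert validate_model(m) == []


def test_methanogen_is_sole_ch4_exporter_and_formate_importer(toy_models):
    for m in toy_models:
        has_ch4 = any("ch4" in r.stoichiometry for r in m.reactions
                      if r.is_exchange)
        can_import_formate = any(
            r.stoichiometry.get("formate") and r.lower_bound < 0
            for r in m.reactions if r.is_exchange)
        if m.species_id == "methanogen":
            assert has_ch4
            assert can_import_formate
        else:
            assert not has_ch4
            assert not can_import_formate


def test_acetogen_exchanges_all_seven_amino_acids(toy_models):
    acetogen = next(m for m in toy_models if m.species_id == "acetogen")
    ex_mets = {next(iter(r.stoichiometry)) for r in acetogen.reactions
               if r.is_exchange}
    assert set(AMINO_ACIDS) <= ex_mets


def test_fermenters_export_their_vfa(toy_models):
    by_id = {m.species_id: m for m in toy_models}
    fa = by_id["fermenter_a"].reaction("EX_butyrate")
    assert fa.lower_bound == 0.0 and fa.upper_bound > 0
    fb = by_id["fermenter_b"].reaction("EX_propionate")
    assert fb.lower_bound == 0.0 and fb.upper_bound > 0
    vfa = by_id["vfa_consumer"]
    assert vfa.reaction("EX_acetate").lower_bound < 0
    assert vfa.reaction("EX_propionate").lower_bound < 0


def test_same_blueprint_gives_bit_identical_models():
    bp = CommunityBlueprint(seed=42)
    models1, table1 = make_toy_community(bp)
    models2, table2 = make_toy_community(CommunityBlueprint(seed=42))
    for m1, m2 in zip(models1, models2):
        assert json.dumps(_model_to_dict(m1), sort_keys=True) == \
            json.dumps(_model_to_dict(m2), sort_keys=True)
    assert table1.equals(table2)


def test_bad_blueprints_rejected():
    with pytest.raises(ValueError, match="sum"):
        CommunityBlueprint(abundances=(0.5, 0.2, 0.1, 0.1, 0.05))
    with pytest.raises(ValueError, match="methanogen"):
        CommunityBlueprint(
            archetypes=["methanogen", "methanogen"], abundances=(0.5, 0.5))
    with pytest.raises(ValueError, match="length"):
        CommunityBlueprint(abundances=(0.5, 0.5))


def test_two_species_community_feasible_on_medium(toy_medium_bounds):
    """Acetogen + methanogen alone grow on the mineral medium: the acetogen
    covers the methanogen's amino-acid need and vice versa for threonine."""
    bp = CommunityBlueprint(archetypes=["acetogen", "methanogen"],
                            abundances=(0.56, 0.44))
    models, table = make_toy_community(bp)
    com = build_community(models,
                          dict(zip(table["species_id"], table["fraction"])))
    com = apply_medium(com, toy_medium_bounds)
    sol = cooperative_tradeoff(com, 0.5)
    assert sol.status == "optimal"
    assert sol.mu_c_max > 0
    assert all(mu > 0 for mu in sol.mu.values())


def test_community_feasible_with_positive_growth(medium_solution):
    assert medium_solution.mu_c_max > 0
    assert all(mu > 1e-6 for mu in medium_solution.mu.values())


def test_carbon_bookkeeping_at_solution(op_community, op_solution):
    """CH4 carbon export never exceeds total carbon uptake (CO2, formate,
    acetate carry 1, 1 and 2 carbons)."""
    carbons = {"co2": 1, "formate": 1, "acetate": 2}
    uptake = 0.0
    for met, n_c in carbons.items():
        rid = op_community.community_exchanges.get(met)
        if rid is not None:
            v = op_solution.fluxes[rid]
            if v < 0:
                uptake += -v * n_c
    ch4 = op_solution.fluxes[op_community.community_exchanges["ch4"]]
    assert ch4 <= uptake + 1e-6


def test_stoichiometry_scale_lowers_growth(toy_medium_bounds):
    """Doubling the biomass energy cost halves-ish the community optimum."""
    cheap_models, table = make_toy_community(CommunityBlueprint())
    costly_models, _ = make_toy_community(
        CommunityBlueprint(stoichiometry_scale=2.0))
    ab = dict(zip(table["species_id"], table["fraction"]))
    mu_cheap = fba(apply_medium(build_community(cheap_models, ab),
                                toy_medium_bounds)).objective_value
    mu_costly = fba(apply_medium(build_community(costly_models, ab),
                                 toy_medium_bounds)).objective_value
    assert mu_costly < mu_cheap


class TestCoverageGenerator:
    def test_planted_high_correlation_recovered(self):
        bp = CoverageBlueprint(n_mags=6, n_samples=500,
                               correlation_blocks=[([0, 1], 0.96)],
                               noise_sd=0.1, seed=7, n_experiments=None)
        cov = make_coverage_matrix(bp)
        r = np.corrcoef(cov.values.iloc[0], cov.values.iloc[1])[0, 1]
        assert 0.91 <= r <= 1.0

    def test_independent_rows_uncorrelated(self):
        bp = CoverageBlueprint(n_mags=4, n_samples=500,
                               correlation_blocks=[], noise_sd=0.1, seed=3,
                               n_experiments=None)
        cov = make_coverage_matrix(bp)
        r = np.corrcoef(cov.values.iloc[0], cov.values.iloc[1])[0, 1]
        assert abs(r) < 0.2

    def test_seeded_determinism(self):
        a = make_coverage_matrix(CoverageBlueprint(seed=11))
        b = make_coverage_matrix(CoverageBlueprint(seed=11))
        assert a.values.equals(b.values)
        c = make_coverage_matrix(CoverageBlueprint(seed=12))
        assert not a.values.equals(c.values)

    def test_values_non_negative_default_shape(self):
        cov = make_coverage_matrix()
        assert cov.values.shape == (59, 134)
        assert (cov.values.values >= 0).all()
        assert len(set(cov.replicate_map.values())) == 67

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            make_coverage_matrix(CoverageBlueprint(
                correlation_blocks=[([0, 1], 0.99)], noise_sd=1.0))

    def test_target_consistency_with_sample_size(self):
        """Recovered correlation approaches the planted one as the number
        of samples grows."""
        err = {}
        for n in (50, 500):
            bp = CoverageBlueprint(n_mags=4, n_samples=n,
                                   correlation_blocks=[([0, 1], 0.7)],
                                   noise_sd=0.2, seed=5, n_experiments=None)
            cov = make_coverage_matrix(bp)
            r = np.corrcoef(cov.values.iloc[0], cov.values.iloc[1])[0, 1]
            err[n] = abs(r - 0.7)
        assert err[500] < 0.06
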