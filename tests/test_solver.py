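"""FBA and cooperative-tradeoff correctness against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syntroflux.community import build_community
from syntroflux.model import Metabolite, Reaction, SpeciesModel
from syntroflux.solver import (_assemble, cooperative_tradeoff, fba,
                               growth_sweep)
from syntroflux.synthetic import make_capped_species

from .oracles import lp_vertex_enumeration, qp_mu_grid_search


def chain_model(cap: float = 10.0) -> SpeciesModel:
    """A -> B -> C with export of C capped."""
    return SpeciesModel(
        species_id="chain",
        metabolites=[Metabolite(m, compartment="internal") for m in "ab"]
        + [Metabolite("c", compartment="env")],
        reactions=[
            Reaction("SRC", {"a": 1.0}, 0.0, 1000.0),
            Reaction("R1", {"a": -1.0, "b": 1.0}, 0.0, 1000.0),
            Reaction("R2", {"b": -1.0, "c": 1.0}, 0.0, 1000.0,
                     objective_coefficient=1.0),
            Reaction("EX_c", {"c": -1.0}, 0.0, cap, is_exchange=True),
        ],
    )


class TestFBA:
    def test_linear_chain_capped_at_export(self):
        sol = fba(chain_model(cap=10.0))
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=1e-8)

    def test_fixed_zero_biomass_gives_zero(self):
        m = chain_model()
        m.reaction("R2").lower_bound = 0.0
        m.reaction("R2").upper_bound = 0.0
        sol = fba(m)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-10)

    def test_objective_override(self):
        sol = fba(chain_model(), objective_reaction="SRC")
        assert sol.objective_value == pytest.approx(10.0, abs=1e-8)

    def test_matches_vertex_enumeration_oracle(self):
        m = chain_model(cap=7.5)
        S, lb, ub, c, _ = _assemble(m)
        oracle = lp_vertex_enumeration(S.toarray(), lb.copy(), ub.copy(), c)
        assert fba(m).objective_value == pytest.approx(oracle, abs=1e-6)

    def test_matches_cobra_glpk(self):
        """Independent cross-check of the LP path against cobrapy."""
        from syntroflux.model_io import to_cobra
        from syntroflux.synthetic import make_acetogen

        model = make_acetogen()
        ours = fba(model).objective_value
        theirs = to_cobra(model).optimize().objective_value
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_infeasible_reported_not_silent(self):
        m = chain_model()
        m.reaction("SRC").lower_bound = 5.0   # force production
        m.reaction("EX_c").upper_bound = 1.0  # but forbid the outlet
        m.reaction("R2").upper_bound = 1.0
        sol = fba(m)
        assert sol.status == "infeasible"
        assert sol.objective_value is None


class TestCooperativeTradeoff:
    def test_closed_form_two_species(self):
        """With individually capped, otherwise uncoupled species the stage-2
        optimum is mu_i = f * mu* * a_i / ||a||^2."""
        com = build_community([make_capped_species("sp1", cap=1.0),
                               make_capped_species("sp2", cap=1.0)],
                              {"sp1": 0.3, "sp2": 0.7})
        sol = cooperative_tradeoff(com, 0.5)
        assert sol.mu_c_max == pytest.approx(1.0, abs=1e-8)
        assert sol.mu["sp1"] == pytest.approx(0.5 * 0.3 / 0.58, abs=1e-5)
        assert sol.mu["sp2"] == pytest.approx(0.5 * 0.7 / 0.58, abs=1e-5)

    def test_full_fraction_achieves_maximum(self):
        com = build_community([make_capped_species("sp1", cap=2.0),
                               make_capped_species("sp2", cap=2.0)],
                              {"sp1": 0.4, "sp2": 0.6})
        sol = cooperative_tradeoff(com, 1.0)
        assert sol.community_growth == pytest.approx(sol.mu_c_max, abs=1e-6)

    def test_fraction_out_of_range_rejected(self):
        com = build_community([make_capped_species("sp1")], {"sp1": 1.0})
        for f in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                cooperative_tradeoff(com, f)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(raw=st.lists(st.floats(min_value=0.05, max_value=1.0),
                        min_size=2, max_size=5))
    def test_growth_proportional_to_abundance(self, raw):
        """In symmetric communities with no shared limiting resource the
        stage-2 growth rates are proportional to abundances."""
        total = sum(raw)
        abundances = {f"s{i}": v / total for i, v in enumerate(raw)}
        com = build_community(
            [make_capped_species(sp, cap=1.0) for sp in abundances],
            abundances)
        sol = cooperative_tradeoff(com, 0.5)
        ratios = [sol.mu[sp] / abundances[sp] for sp in abundances]
        assert max(ratios) - min(ratios) < 1e-5

    def test_permutation_reproducibility(self, toy_models, toy_abundances):
        fwd = cooperative_tradeoff(
            build_community(toy_models, toy_abundances), 0.5)
        rev = cooperative_tradeoff(
            build_community(list(reversed(toy_models)), toy_abundances), 0.5)
        for sp in toy_abundances:
            assert fwd.mu[sp] == pytest.approx(rev.mu[sp], abs=1e-7)

    def test_stage2_matches_grid_search_oracle(self):
        """Dense grid search over the mu-simplex agrees with the QP."""
        com = build_community([make_capped_species("sp1", cap=1.0),
                               make_capped_species("sp2", cap=1.0)],
                              {"sp1": 0.4, "sp2": 0.6})
        sol = cooperative_tradeoff(com, 0.5)
        a = np.array([0.4, 0.6])

        def feasible(mu):
            return np.all(mu <= 1.0 + 1e-12)

        oracle = qp_mu_grid_search(feasible, a, 0.5 * sol.mu_c_max,
                                   np.array([1.0, 1.0]))
        assert sol.mu["sp1"] == pytest.approx(oracle[0], abs=1e-3)
        assert sol.mu["sp2"] == pytest.approx(oracle[1], abs=1e-3)
        # objective values agree much tighter than the grid spacing
        ours = sol.mu["sp1"] ** 2 + sol.mu["sp2"] ** 2
        assert ours <= oracle @ oracle + 1e-6

    def test_relaxing_bound_never_decreases_optimum(self, medium_community):
        base = cooperative_tradeoff(medium_community, 0.5)
        relaxed = medium_community.copy()
        relaxed.reaction(
            relaxed.community_exchanges["h2"]).lower_bound *= 2.0
        more = cooperative_tradeoff(relaxed, 0.5)
        assert more.mu_c_max >= base.mu_c_max - 1e-8


class TestGrowthSweep:
    def test_empty_grid_rejected(self, medium_community):
        with pytest.raises(ValueError, match="empty"):
            growth_sweep(medium_community, grid=[])

    def test_unsorted_grid_rejected(self, medium_community):
        with pytest.raises(ValueError, match="sorted"):
            growth_sweep(medium_community, grid=[10.0, 5.0])

    def test_single_point_grid(self, medium_community):
        res = growth_sweep(medium_community, grid=[40.0])
        assert len(res.mu_c) == 1
        assert res.plateau_onset_index is None

    def test_monotone_and_zero_at_origin(self, medium_community):
        res = growth_sweep(medium_community, grid=[0.0, 10.0, 40.0])
        assert res.mu_c[0] == pytest.approx(0.0, abs=1e-8)
        assert all(b >= a - 1e-6 for a, b in zip(res.mu_c, res.mu_c[1:]))

    def test_gas_ratio_mode_scales_per_gas(self, medium_community):
        """A 4:1 H2:CO2 ratio sweep gives at most the growth of the
        equal-bounds sweep at the H2 bound (CO2 is tighter)."""
        equal = growth_sweep(medium_community, grid=[8.0])
        ratio = growth_sweep(medium_community, grid=[2.0],
                             gas_ratios=(4.0, 1.0))
        assert ratio.mu_c[0] <= equal.mu_c[0] + 1e-6
        with pytest.raises(ValueError, match="gas_ratios"):
            growth_sweep(medium_community, grid=[1.0], gas_ratios=(1.0,))
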