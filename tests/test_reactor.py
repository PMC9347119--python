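"""Gas-to-flux conversion and operating-point constraints."""

from __future__ import annotations

import pytest

from syntroflux.community import build_community
from syntroflux.medium import apply_medium
from syntroflux.reactor import (GasMeasurements, OperatingPoint,
                                apply_operating_point, gas_to_flux,
                                molar_volume)
from syntroflux.solver import cooperative_tradeoff
from syntroflux.synthetic import CommunityBlueprint, make_toy_community


def measurements(q_in=1.0, h2=1.0, ch4=0.0, co2=0.0, **kw):
    return GasMeasurements(q_in=q_in,
                           fractions={"h2": h2, "ch4": ch4, "co2": co2}, **kw)


class TestMolarVolume:
    def test_standard_temperature(self):
        # 0.082057 * 273.15 = 22.41 (hand arithmetic)
        assert molar_volume(273.15, 1.0) == pytest.approx(22.41, abs=0.005)

    def test_reference_state_truncates_to_24_46(self):
        assert int(molar_volume(298.15, 1.0) * 100) / 100 == 24.46

    def test_inverse_pressure_scaling(self):
        assert molar_volume(300.0, 2.0) == pytest.approx(
            molar_volume(300.0, 1.0) / 2)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            molar_volume(-1.0, 1.0)
        with pytest.raises(ValueError):
            molar_volume(298.0, 0.0)


class TestGasToFlux:
    def test_unit_rate_with_defaults(self):
        # 1000 / (24.46 * 1.17 * 24) = 1.456 (hand arithmetic)
        assert gas_to_flux(measurements(), "h2") == pytest.approx(1.456,
                                                                  abs=0.001)

    def test_zero_rate(self):
        assert gas_to_flux(measurements(q_in=0.0), "h2") == 0.0

    def test_linearity_in_rate_and_fraction(self):
        f1 = gas_to_flux(measurements(q_in=1.0), "h2")
        assert gas_to_flux(measurements(q_in=2.0), "h2") == pytest.approx(
            2 * f1)
        mixed = measurements(h2=0.62, ch4=0.23, co2=0.15)
        assert gas_to_flux(mixed, "h2") == pytest.approx(0.62 * f1)

    def test_components_sum_to_total(self):
        m = measurements(h2=0.62, ch4=0.23, co2=0.15)
        total = sum(gas_to_flux(m, g) for g in ("h2", "ch4", "co2"))
        assert total == pytest.approx(gas_to_flux(measurements(), "h2"))

    def test_unknown_gas_rejected(self):
        with pytest.raises(KeyError, match="n2"):
            gas_to_flux(measurements(), "n2")

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            GasMeasurements(q_in=1.0, fractions={"h2": 0.5, "ch4": 0.2,
                                                 "co2": 0.2})


class TestOperatingPoint:
    def test_default_bounds_applied(self, medium_community):
        m = apply_operating_point(medium_community, OperatingPoint())
        co2 = m.reaction(m.community_exchanges["co2"])
        assert (co2.lower_bound, co2.upper_bound) == (-1.20, -1.20)
        h2 = m.reaction(m.community_exchanges["h2"])
        assert (h2.lower_bound, h2.upper_bound) == (-5.11, -5.11)
        ch4 = m.reaction(m.community_exchanges["ch4"])
        assert ch4.lower_bound == 1.15
        for vfa in ("acetate", "propionate", "butyrate"):
            r = m.reaction(m.community_exchanges[vfa])
            assert (r.lower_bound, r.upper_bound) == (0.0, 0.0)

    def test_input_model_unmodified(self, medium_community):
        before = medium_community.reaction(
            medium_community.community_exchanges["co2"]).lower_bound
        apply_operating_point(medium_community, OperatingPoint())
        after = medium_community.reaction(
            medium_community.community_exchanges["co2"]).lower_bound
        assert before == after

    def test_zero_rates_pin_gases_only(self, medium_community):
        op = OperatingPoint(co2_uptake=0.0, h2_uptake=0.0,
                            ch4_min_export=0.0, vfa_ids=())
        m = apply_operating_point(medium_community, op)
        co2 = m.reaction(m.community_exchanges["co2"])
        assert (co2.lower_bound, co2.upper_bound) == (0.0, 0.0)
        ac = m.reaction(m.community_exchanges["acetate"])
        ref = medium_community.reaction(
            medium_community.community_exchanges["acetate"])
        assert (ac.lower_bound, ac.upper_bound) == (ref.lower_bound,
                                                    ref.upper_bound)

    def test_missing_exchange_lists_candidates(self, medium_community):
        with pytest.raises(KeyError, match="available"):
            apply_operating_point(medium_community,
                                  OperatingPoint(ch4_id="methane"))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            OperatingPoint(co2_uptake=-1.0)

    def test_solution_respects_pinned_gases(self, op_community, op_solution):
        fluxes = op_solution.fluxes
        assert fluxes[op_community.community_exchanges["co2"]] == \
            pytest.approx(-1.20, abs=1e-6)
        assert fluxes[op_community.community_exchanges["h2"]] == \
            pytest.approx(-5.11, abs=1e-6)
        assert fluxes[op_community.community_exchanges["ch4"]] >= 1.15 - 1e-6

    def test_community_without_methanogen_is_infeasible(self, toy_medium_bounds):
        """The CH4 export demand cannot be met when no species can make
        methane."""
        bp = CommunityBlueprint(
            archetypes=["acetogen", "vfa_consumer", "fermenter", "fermenter"],
            abundances=(0.4, 0.3, 0.16, 0.14))
        models, table = make_toy_community(bp)
        com = build_community(models,
                              dict(zip(table["species_id"], table["fraction"])))
        com = apply_medium(com, toy_medium_bounds)
        with pytest.raises(KeyError):
            # no CH4 exchange even exists at community level
            apply_operating_point(com, OperatingPoint())
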