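"""Reactor gas measurements -> specific flux constraints.

The biofilm reactors are fed a H2/CH4/CO2 gas mix at a volumetric rate q_in
(liters of gas per liter of reactor per day).  Converting a gas stream to a
biomass-specific flux uses the ideal-gas molar volume at the reactor
reference state (24.46 L/mol at 298.15 K, 1 atm) and the measured community
dry mass density (1.17 gDW/L):

    flux [mmol/gDW/h] = q_in * fraction * 1000 / (V_m * rho_X * 24)

The experimental operating point pins the community model: CO2 and H2 uptake
fixed at 1.20 and 5.11 mmol/gDW/h, CH4 export at least 1.15 mmol/gDW/h, and
zero net accumulation of volatile fatty acids in the medium (interspecies
VFA transfer through the shared pool stays free).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .community import CommunityModel

R_GAS = 0.082057  # L atm / (mol K)
MOLAR_VOLUME_298K = 24.46  # L/mol, ideal gas at 298.15 K and 1 atm
BIOMASS_DENSITY = 1.17  # gDW per liter of reactor

GASES = ("h2", "ch4", "co2")


def molar_volume(temperature_K: float = 298.15,
                 pressure_atm: float = 1.0) -> float:
    """Ideal-gas molar volume R*T/P in L/mol."""
    if temperature_K <= 0 or pressure_atm <= 0:
        raise ValueError("temperature and pressure must be positive")
    return R_GAS * temperature_K / pressure_atm


@dataclass
class GasMeasurements:
    q_in: float                      # L gas / L reactor / day
    fractions: dict[str, float]      # {"h2": .., "ch4": .., "co2": ..}
    molar_volume: float = MOLAR_VOLUME_298K   # L/mol
    biomass_density: float = BIOMASS_DENSITY  # gDW/L

    def __post_init__(self) -> None:
        if self.q_in < 0:
            raise ValueError("q_in must be non-negative")
        if self.molar_volume <= 0 or self.biomass_density <= 0:
            raise ValueError("molar volume and biomass density must be positive")
        for gas, frac in self.fractions.items():
            if frac < 0:
                raise ValueError(f"negative gas fraction for '{gas}'")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"gas fractions sum to {total}, expected 1")


def gas_to_flux(measurements: GasMeasurements, gas: str) -> float:
    """Specific flux of one gas component, mmol/gDW/h.

    Linear in q_in and in the gas fraction; the three components sum to the
    total gas flux.
    """
    if gas not in measurements.fractions:
        raise KeyError(
            f"unknown gas '{gas}' (measured: {sorted(measurements.fractions)})"
        )
    return (measurements.q_in * measurements.fractions[gas] * 1000.0
            / (measurements.molar_volume * measurements.biomass_density * 24.0))


@dataclass
class OperatingPoint:
    """Experimentally measured community operating point (magnitudes)."""
    co2_uptake: float = 1.20       # mmol/gDW/h, fixed
    h2_uptake: float = 5.11        # mmol/gDW/h, fixed
    ch4_min_export: float = 1.15   # mmol/gDW/h, lower bound
    vfa_ids: tuple[str, ...] = ("acetate", "propionate", "butyrate")
    co2_id: str = "co2"
    h2_id: str = "h2"
    ch4_id: str = "ch4"

    def __post_init__(self) -> None:
        for v in (self.co2_uptake, self.h2_uptake, self.ch4_min_export):
            if v < 0:
                raise ValueError("operating-point rates must be non-negative")


def apply_operating_point(community: CommunityModel,
                          op_point: OperatingPoint) -> CommunityModel:
    """Pin the community exchanges to the operating point.

    Uptake-negative convention: CO2 and H2 community exchange get lower =
    upper = -uptake (forced uptake); the CH4 exchange lower bound is the
    minimum export; each listed VFA gets community exchange bounds (0, 0) so
    no net accumulation occurs while species-level exchange stays free.
    Returns a new model.
    """
    out = community.copy()

    def _exchange(met_id: str):
        if met_id not in out.community_exchanges:
            candidates = sorted(out.community_exchanges)
            raise KeyError(
                f"no community exchange for '{met_id}'; available: {candidates}"
            )
        return out.reaction(out.community_exchanges[met_id])

    r = _exchange(op_point.co2_id)
    r.lower_bound = r.upper_bound = -op_point.co2_uptake
    r = _exchange(op_point.h2_id)
    r.lower_bound = r.upper_bound = -op_point.h2_uptake
    r = _exchange(op_point.ch4_id)
    r.lower_bound = op_point.ch4_min_export
    for vfa in op_point.vfa_ids:
        if vfa in out.community_exchanges:
            r = out.reaction(out.community_exchanges[vfa])
            r.lower_bound = r.upper_bound = 0.0
    return out
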