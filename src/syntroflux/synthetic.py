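"""Parameterized toy inputs: species models, medium, coverage matrices.

The toy community mirrors the core of a CO2-methanating biofilm: one
hydrogenotrophic methanogen (the only CH4 exporter and the only formate
importer), one versatile acetogen (Wood-Ljungdahl acetate production,
formate production, amino-acid prototrophy except threonine), one
acetate/propionate consumer, and two fermenters (butyrate and propionate
producers, threonine prototrophs).  Cross-fed amino acids are l-Glutamate,
l-Aspartate, l-Glutamine, l-Serine, l-Threonine, l-Alanine and glycine.

Design notes (full discussion in docs/methods.md):

* Reactions are lumped and carbon/nitrogen balanced; hydrogen and oxygen are
  only loosely tracked, as is usual for toy networks.  The carbon ledger is
  what the bookkeeping invariants rely on.
* The methanogen's H2 uptake is capped per gDW, so meeting the reactor CH4
  demand forces methanogenesis from formate - the formate shuttle the
  community is known for.
* The acetogen's formate export is capped, so part of the formate supply
  must flow through acetate-fed bacteria (acetate -> formate conversion),
  which guarantees interspecies acetate cross-feeding at zero net VFA
  accumulation.
* Sulfate reduction in the acetate/propionate consumer absorbs electron
  surplus when H2 is supplied above the 4:1 stoichiometric ratio to CO2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cooccurrence import CoverageMatrix
from .medium import MediumComponent, MediumRecipe
from .model import ENV, INTERNAL, Metabolite, Reaction, SpeciesModel

ARCHETYPES = ("methanogen", "acetogen", "fermenter", "vfa_consumer")

# the seven cross-fed amino acids with carbon and nitrogen atom counts
AMINO_ACIDS: dict[str, tuple[str, int, int]] = {
    "glu_L": ("l-Glutamate", 5, 1),
    "asp_L": ("l-Aspartate", 4, 1),
    "gln_L": ("l-Glutamine", 5, 2),
    "ser_L": ("l-Serine", 3, 1),
    "thr_L": ("l-Threonine", 4, 1),
    "ala_L": ("l-Alanine", 3, 1),
    "gly": ("glycine", 2, 1),
}

DEFAULT_ABUNDANCES = {
    "acetogen": 0.33,
    "methanogen": 0.26,
    "vfa_consumer": 0.20,
    "fermenter_a": 0.11,
    "fermenter_b": 0.10,
}

# species-level transport capacities, mmol/gDW/h
METHANOGEN_H2_CAP = 2.0
BACTERIA_H2_CAP = 20.0
ACETOGEN_FORMATE_CAP = 2.0

_ENV_METS = {
    "h2": "hydrogen", "co2": "carbon dioxide", "ch4": "methane",
    "formate": "formate", "acetate": "acetate", "propionate": "propionate",
    "butyrate": "butyrate", "nh4": "ammonium", "h2o": "water",
    "pi": "phosphate", "so4": "sulfate", "h2s": "hydrogen sulfide",
    "fe2": "Fe(II)", "ni2": "Ni(II)", "cobalt2": "Co(II)", "mg2": "Mg(II)",
    "k": "potassium", "na": "sodium", "cl": "chloride", "ca2": "Ca(II)",
    "zn2": "Zn(II)", "mn2": "Mn(II)", "cu2": "Cu(II)", "mobd": "molybdate",
}


@dataclass
class CommunityBlueprint:
    """Recipe for a toy community.

    ``archetypes`` lists one entry per species; ``abundances`` must match its
    length and sum to 1.  ``stoichiometry_scale`` multiplies the biomass ATP
    requirement, uniformly rescaling all energy-linked fluxes.
    """
    archetypes: list[str] = field(default_factory=lambda: [
        "acetogen", "methanogen", "vfa_consumer", "fermenter", "fermenter"])
    abundances: tuple[float, ...] = (0.33, 0.26, 0.20, 0.11, 0.10)
    seed: int = 0
    stoichiometry_scale: float = 1.0
    allow_multiple_methanogens: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.archetypes) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if len(self.abundances) != len(self.archetypes):
            raise ValueError("abundances must match archetypes in length")
        if any(a < 0 for a in self.abundances):
            raise ValueError("abundances must be non-negative")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError(
                f"abundances sum to {sum(self.abundances)}, expected 1")
        n_meth = self.archetypes.count("methanogen")
        if n_meth > 1 and not self.allow_multiple_methanogens:
            raise ValueError("at most one methanogen unless configured otherwise")
        if self.stoichiometry_scale <= 0:
            raise ValueError("stoichiometry_scale must be positive")


def _met_name(mid: str) -> str:
    if mid in AMINO_ACIDS:
        return AMINO_ACIDS[mid][0]
    return _ENV_METS[mid]


def _mets(ids: list[str], internal: list[str]) -> list[Metabolite]:
    out = [Metabolite(id=m, name=_met_name(m), compartment=ENV) for m in ids]
    out += [Metabolite(id=m, compartment=INTERNAL) for m in internal]
    return out


def _ex(met: str, lb: float, ub: float) -> Reaction:
    return Reaction(f"EX_{met}", {met: -1.0}, lb, ub, is_exchange=True)


def _aa_synthesis(aa: str) -> Reaction:
    _, n_c, n_n = AMINO_ACIDS[aa]
    return Reaction(f"SYN_{aa}",
                    {"co2": -float(n_c), "h2": -2.0 * n_c,
                     "nh4": -float(n_n), "atp": -1.0, aa: 1.0},
                    0.0, 1000.0)


def _biomass(atp: float, carbon: dict[str, float],
             aux_aa: list[str], trace: dict[str, float]) -> Reaction:
    stoich = {"atp": -atp, "h2": -2.0, "nh4": -0.5, "pi": -0.05}
    stoich.update({k: -v for k, v in carbon.items()})
    stoich.update({aa: -0.1 for aa in aux_aa})
    stoich.update({k: -v for k, v in trace.items()})
    return Reaction("BIOMASS", stoich, 0.0, 1000.0, objective_coefficient=1.0)


def make_methanogen(species_id: str = "methanogen",
                    atp_cost: float = 20.0) -> SpeciesModel:
    """Hydrogenotrophic/formatotrophic methanogen (M. wolfeii analogue).

    Sole CH4 exporter and sole formate importer; H2 uptake is transport
    limited, auxotrophic for l-Glutamate, threonine prototroph.
    """
    env = ["h2", "co2", "ch4", "formate", "h2o", "nh4", "pi", "ni2",
           "glu_L", "thr_L"]
    rxns = [
        # CO2 reduction: 4 H2 + CO2 -> CH4
        Reaction("MTG", {"h2": -4.0, "co2": -1.0, "ch4": 1.0, "h2o": 2.0,
                         "atp": 1.0}, 0.0, 1000.0),
        # formate disproportionation: 4 HCOO- -> CH4 + 3 CO2
        Reaction("FMTG", {"formate": -4.0, "ch4": 1.0, "co2": 3.0,
                          "h2o": 2.0, "atp": 1.0}, 0.0, 1000.0),
        Reaction("SYN_thr_L", {"co2": -4.0, "h2": -8.0, "nh4": -1.0,
                               "atp": -1.0, "thr_L": 1.0}, 0.0, 1000.0),
        Reaction("ATPM", {"atp": -1.0}, 0.0, 1000.0),
        _biomass(atp_cost, {"co2": 0.5}, ["glu_L"], {"ni2": 0.001}),
        _ex("h2", -METHANOGEN_H2_CAP, 0.0),
        _ex("co2", -1000.0, 1000.0),
        _ex("ch4", 0.0, 1000.0),
        _ex("formate", -1000.0, 0.0),
        _ex("h2o", -1000.0, 1000.0),
        _ex("nh4", -1000.0, 0.0),
        _ex("pi", -1000.0, 0.0),
        _ex("ni2", -1000.0, 0.0),
        _ex("glu_L", -1000.0, 0.0),
        _ex("thr_L", -1000.0, 1000.0),
    ]
    return SpeciesModel(species_id=species_id,
                        label="toy hydrogenotrophic methanogen",
                        metabolites=_mets(env, ["atp"]),
                        reactions=rxns, biomass_reaction_id="BIOMASS")


def make_acetogen(species_id: str = "acetogen",
                  atp_cost: float = 20.0) -> SpeciesModel:
    """Versatile homoacetogen (Limnochordia analogue).

    Fixes CO2 through a lumped Wood-Ljungdahl reaction, produces formate
    (export transport-capped) and acetate, salvages butyrate, synthesizes six
    of the seven cross-fed amino acids but is auxotrophic for l-Threonine.
    """
    env = ["h2", "co2", "formate", "acetate", "butyrate", "h2o", "nh4", "pi",
           "cobalt2", "so4", "fe2", "mg2", "k", "na", "cl", "ca2", "zn2",
           "mn2", "cu2", "mobd"] + list(AMINO_ACIDS)
    synth = ["glu_L", "asp_L", "gln_L", "ser_L", "ala_L", "gly"]
    rxns = [
        # lumped Wood-Ljungdahl: 2 H2 + 2 CO2 -> acetate
        Reaction("WLP", {"h2": -2.0, "co2": -2.0, "acetate": 1.0,
                         "h2o": 2.0, "atp": 1.0}, 0.0, 1000.0),
        # hydrogen-dependent CO2 reduction to formate
        Reaction("FHL", {"h2": -1.0, "co2": -1.0, "formate": 1.0,
                         "atp": 0.25}, 0.0, 1000.0),
        # butyrate salvage to acetate (carbon only, no energy gain)
        Reaction("BUTDEG", {"butyrate": -1.0, "h2o": -2.0, "acetate": 2.0},
                 0.0, 1000.0),
        Reaction("ATPM", {"atp": -1.0}, 0.0, 1000.0),
        _biomass(atp_cost, {"acetate": 0.5}, ["thr_L"], {"cobalt2": 0.001}),
        *[_aa_synthesis(aa) for aa in synth],
        _ex("h2", -BACTERIA_H2_CAP, 0.0),
        _ex("co2", -1000.0, 1000.0),
        _ex("formate", 0.0, ACETOGEN_FORMATE_CAP),
        _ex("acetate", -1000.0, 1000.0),
        _ex("butyrate", -1000.0, 0.0),
        _ex("h2o", -1000.0, 1000.0),
        _ex("nh4", -1000.0, 0.0),
        _ex("pi", -1000.0, 0.0),
        _ex("cobalt2", -1000.0, 0.0),
        *[_ex(m, -1000.0, 0.0) for m in
          ("so4", "fe2", "mg2", "k", "na", "cl", "ca2", "zn2", "mn2",
           "cu2", "mobd")],
        *[_ex(aa, -1000.0, 1000.0) for aa in AMINO_ACIDS],
    ]
    return SpeciesModel(species_id=species_id,
                        label="toy versatile acetogen",
                        metabolites=_mets(env, ["atp"]),
                        reactions=rxns, biomass_reaction_id="BIOMASS")


def make_vfa_consumer(species_id: str = "vfa_consumer",
                      atp_cost: float = 20.0) -> SpeciesModel:
    """Acetate/propionate consumer (Acetomicrobium analogue).

    Converts acetate to formate, degrades propionate, reduces sulfate (the
    community's electron overflow valve), exports l-Alanine, l-Glutamine and
    l-Glutamate; auxotrophic for glycine.
    """
    env = ["h2", "co2", "formate", "acetate", "propionate", "h2o", "nh4",
           "pi", "so4", "h2s", "glu_L", "gln_L", "ala_L", "gly"]
    rxns = [
        # acetate cleavage to 2 formate (carbon-conserving)
        Reaction("ACFOR", {"acetate": -1.0, "formate": 2.0, "atp": 0.25},
                 0.0, 1000.0),
        # propionate oxidation to acetate + CO2
        Reaction("PRODEG", {"propionate": -1.0, "h2o": -2.0, "acetate": 1.0,
                            "co2": 1.0}, 0.0, 1000.0),
        # dissimilatory sulfate reduction: 4 H2 + SO4 -> H2S
        Reaction("SRED", {"so4": -1.0, "h2": -4.0, "h2s": 1.0, "h2o": 4.0,
                          "atp": 0.25}, 0.0, 1000.0),
        Reaction("ATPM", {"atp": -1.0}, 0.0, 1000.0),
        _biomass(atp_cost, {"acetate": 0.5}, ["gly"], {}),
        *[_aa_synthesis(aa) for aa in ("glu_L", "gln_L", "ala_L")],
        _ex("h2", -BACTERIA_H2_CAP, 0.0),
        _ex("co2", -1000.0, 1000.0),
        _ex("formate", 0.0, 1000.0),
        _ex("acetate", -1000.0, 0.0),
        _ex("propionate", -1000.0, 0.0),
        _ex("h2o", -1000.0, 1000.0),
        _ex("nh4", -1000.0, 0.0),
        _ex("pi", -1000.0, 0.0),
        _ex("so4", -1000.0, 0.0),
        _ex("h2s", 0.0, 1000.0),
        *[_ex(aa, -1000.0, 1000.0) for aa in ("glu_L", "gln_L", "ala_L")],
        _ex("gly", -1000.0, 0.0),
    ]
    return SpeciesModel(species_id=species_id,
                        label="toy acetate/propionate consumer",
                        metabolites=_mets(env, ["atp"]),
                        reactions=rxns, biomass_reaction_id="BIOMASS")


def make_fermenter(species_id: str, variant: str = "a",
                   atp_cost: float = 20.0) -> SpeciesModel:
    """Fermenter archetype (Firmicutes analogue).

    Variant "a" chain-elongates acetate to butyrate, variant "b" carboxylates
    acetate to propionate; both convert acetate to formate, synthesize
    l-Threonine, and are auxotrophic for one or two amino acids.
    """
    if variant == "a":
        vfa_rxn = Reaction("CE_BUT", {"acetate": -2.0, "h2": -2.0,
                                      "butyrate": 1.0, "h2o": 2.0,
                                      "atp": 0.5}, 0.0, 1000.0)
        vfa_ex = _ex("butyrate", 0.0, 1000.0)
        aux = ["ser_L"]
    elif variant == "b":
        vfa_rxn = Reaction("CE_PROP", {"acetate": -1.0, "co2": -1.0,
                                       "h2": -3.0, "propionate": 1.0,
                                       "h2o": 2.0, "atp": 0.5}, 0.0, 1000.0)
        vfa_ex = _ex("propionate", 0.0, 1000.0)
        aux = ["ala_L", "gln_L"]
    else:
        raise ValueError(f"unknown fermenter variant '{variant}'")
    vfa_met = "butyrate" if variant == "a" else "propionate"
    env = ["h2", "co2", "formate", "acetate", vfa_met, "h2o", "nh4", "pi",
           "thr_L"] + aux
    rxns = [
        Reaction("ACFOR", {"acetate": -1.0, "formate": 2.0, "atp": 0.25},
                 0.0, 1000.0),
        vfa_rxn,
        Reaction("SYN_thr_L", {"co2": -4.0, "h2": -8.0, "nh4": -1.0,
                               "atp": -1.0, "thr_L": 1.0}, 0.0, 1000.0),
        Reaction("ATPM", {"atp": -1.0}, 0.0, 1000.0),
        _biomass(atp_cost, {"acetate": 0.5}, aux, {}),
        _ex("h2", -BACTERIA_H2_CAP, 0.0),
        _ex("co2", -1000.0, 1000.0),
        _ex("formate", 0.0, 1000.0),
        _ex("acetate", -1000.0, 0.0),
        vfa_ex,
        _ex("h2o", -1000.0, 1000.0),
        _ex("nh4", -1000.0, 0.0),
        _ex("pi", -1000.0, 0.0),
        _ex("thr_L", -1000.0, 1000.0),
        *[_ex(aa, -1000.0, 0.0) for aa in aux],
    ]
    return SpeciesModel(species_id=species_id,
                        label=f"toy fermenter ({vfa_met} producer)",
                        metabolites=_mets(env, ["atp"]),
                        reactions=rxns, biomass_reaction_id="BIOMASS")


def make_toy_community(
    blueprint: CommunityBlueprint | None = None,
) -> tuple[list[SpeciesModel], pd.DataFrame]:
    """Build the toy species models and their abundance table.

    The output is fully determined by the blueprint (bit-identical across
    calls with the same blueprint).
    """
    if blueprint is None:
        blueprint = CommunityBlueprint()
    atp = 20.0 * blueprint.stoichiometry_scale
    models: list[SpeciesModel] = []
    counters: dict[str, int] = {}
    for arch in blueprint.archetypes:
        counters[arch] = counters.get(arch, 0) + 1
        n = counters[arch]
        total = blueprint.archetypes.count(arch)
        if arch == "fermenter":
            variant = "a" if n == 1 else "b"
            sid = f"fermenter_{chr(ord('a') + n - 1)}"
            models.append(make_fermenter(sid, variant=variant, atp_cost=atp))
        else:
            sid = arch if total == 1 else f"{arch}_{n}"
            maker = {"methanogen": make_methanogen,
                     "acetogen": make_acetogen,
                     "vfa_consumer": make_vfa_consumer}[arch]
            models.append(maker(sid, atp_cost=atp))
    table = pd.DataFrame({
        "species_id": [m.species_id for m in models],
        "fraction": list(blueprint.abundances),
    })
    return models, table


def make_capped_species(species_id: str, cap: float = 1.0) -> SpeciesModel:
    """Minimal self-sufficient species whose growth is capped at ``cap``.

    Useful for communities where species couple only through the abundance
    weighting (no shared limiting resource), where the cooperative tradeoff
    has a closed-form solution.
    """
    return SpeciesModel(
        species_id=species_id,
        label="capped toy species",
        metabolites=[Metabolite("x", compartment=INTERNAL),
                     Metabolite("s", name="substrate", compartment=ENV)],
        reactions=[
            _ex("s", -1000.0, 1000.0),
            Reaction("UPT", {"s": -1.0, "x": 1.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"x": -1.0}, 0.0, cap,
                     objective_coefficient=1.0),
        ],
        biomass_reaction_id="BIOMASS",
    )


# ---------------------------------------------------------------------------
# medium
# ---------------------------------------------------------------------------

_BA_MEDIUM = [
    # (id, name, mmol/L) -- basal anaerobic mineral medium, no organic carbon
    ("h2o", "water", 55000.0),
    ("co2", "dissolved CO2 / bicarbonate", 50.0),
    ("cl", "chloride", 40.0),
    ("na", "sodium", 25.0),
    ("nh4", "ammonium", 18.0),
    ("k", "potassium", 8.0),
    ("pi", "phosphate", 5.0),
    ("mg2", "magnesium", 2.0),
    ("so4", "sulfate", 2.0),
    ("h2", "dissolved hydrogen", 1.5),
    ("ca2", "calcium", 1.5),
    ("fe2", "iron(II)", 0.05),
    ("ni2", "nickel(II)", 0.005),
    ("zn2", "zinc(II)", 0.004),
    ("cobalt2", "cobalt(II)", 0.004),
    ("mn2", "manganese(II)", 0.003),
    ("cu2", "copper(II)", 0.0008),
    ("mobd", "molybdate", 0.0005),
]


def make_toy_medium() -> MediumRecipe:
    """Basal anaerobic (BA) style mineral medium.

    Water plus 17 inorganic components spanning five orders of magnitude in
    concentration; dissolved CO2 is the only carbon source.  Deterministic.
    """
    return MediumRecipe(
        components=[MediumComponent(i, n, c) for i, n, c in _BA_MEDIUM],
        water_id="h2o",
    )


# ---------------------------------------------------------------------------
# coverage matrices
# ---------------------------------------------------------------------------

@dataclass
class CoverageBlueprint:
    """Recipe for a MAG x sample coverage matrix with planted correlations.

    ``correlation_blocks`` plant a target Pearson correlation between the
    listed MAG indices; remaining MAGs are independent.  ``noise_sd`` is the
    standard deviation of independent latent noise relative to the unit
    signal; the latent correlations are pre-amplified so the delivered
    correlation matches the target after attenuation.
    """
    n_mags: int = 59
    n_samples: int = 134
    correlation_blocks: list[tuple[list[int], float]] = field(
        default_factory=lambda: [([0, 1], 0.96), ([2, 3], 0.71)])
    noise_sd: float = 0.2
    seed: int = 0
    shape_sigma: float = 0.25   # lognormal shape of the coverage marginals
    n_experiments: int | None = 67

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for ids, r in self.correlation_blocks:
            if abs(r) > 1:
                raise ValueError(f"|target r| must be <= 1, got {r}")
            if any(i >= self.n_mags or i < 0 for i in ids):
                raise ValueError(f"block member out of range: {ids}")


def _latent_correlation(r: float, noise_sd: float, sigma: float) -> float:
    """Latent normal correlation that delivers Pearson ``r`` after adding
    independent noise and passing through the lognormal transform."""
    attenuated = r * (1.0 + noise_sd**2)
    # invert the lognormal correlation map r_ln(r_n)
    target = np.log1p(attenuated * np.expm1(sigma**2)) / sigma**2
    if abs(target) > 1.0:
        raise ValueError(
            f"target r={r} infeasible with noise_sd={noise_sd}")
    return float(target)


def make_coverage_matrix(blueprint: CoverageBlueprint | None = None) -> CoverageMatrix:
    """Non-negative coverage matrix with planted correlation blocks.

    Correlated standard normals (Gaussian copula) are pushed through an
    exponential so coverages are non-negative and right-skewed, like read
    coverages; per-MAG depth scales differ by orders of magnitude.  Planted
    blocks land within about +-0.05 of their target Pearson r once the
    number of samples reaches ~100.  Seeded and deterministic.
    """
    if blueprint is None:
        blueprint = CoverageBlueprint()
    bp = blueprint
    rng = np.random.default_rng(bp.seed)
    sigma = bp.shape_sigma

    corr = np.eye(bp.n_mags)
    for ids, r in bp.correlation_blocks:
        latent = _latent_correlation(r, bp.noise_sd, sigma)
        for i in ids:
            for j in ids:
                if i != j:
                    corr[i, j] = latent
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation blocks are jointly infeasible") from exc

    z = chol @ rng.standard_normal((bp.n_mags, bp.n_samples))
    z = z + bp.noise_sd * rng.standard_normal(z.shape)
    z = z / np.sqrt(1.0 + bp.noise_sd**2)
    depth = np.exp(rng.normal(1.0, 1.0, size=bp.n_mags))
    values = depth[:, None] * np.exp(sigma * z)

    mag_ids = [f"mag{i + 1:03d}" for i in range(bp.n_mags)]
    sample_ids = [f"sample{j + 1:03d}" for j in range(bp.n_samples)]
    n_exp = bp.n_experiments or bp.n_samples
    replicate_map = {
        sample_ids[j]: f"exp{(j % n_exp) + 1:03d}" for j in range(bp.n_samples)
    }
    return CoverageMatrix(
        values=pd.DataFrame(values, index=mag_ids, columns=sample_ids),
        replicate_map=replicate_map,
    )
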