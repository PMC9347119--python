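"""Abundance-weighted merge of species models into one community model.

Each species keeps its own namespaced copy of every metabolite, including a
private boundary copy of each environment metabolite.  A species exchange
reaction moves metabolite from the species boundary into the shared
environment pool, scaled by the species' relative abundance ``a_i``; one
community exchange reaction per pool metabolite moves it across the outer
boundary.  The pool steady state then enforces the coupling

    v_EX(community, m) = sum_i a_i * v_EX(species i, m)

so species fluxes stay in per-gDW-of-that-species units while community
exchanges are per gDW of community.  Community growth is the
abundance-weighted sum of the species biomass fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import ENV, Metabolite, Reaction, SpeciesModel, require_valid

SEP = "__"
DROP_THRESHOLD = 1e-6


def normalize_abundances(abundances: dict[str, float],
                         drop_threshold: float = DROP_THRESHOLD) -> dict[str, float]:
    """Validate, drop species below the threshold, renormalize to sum 1."""
    for sp, a in abundances.items():
        if a < 0:
            raise ValueError(f"negative abundance for '{sp}': {a}")
    total = sum(abundances.values())
    if total <= 0:
        raise ValueError("abundances sum to zero")
    kept = {sp: a / total for sp, a in abundances.items()
            if a / total >= drop_threshold}
    total = sum(kept.values())
    return {sp: a / total for sp, a in kept.items()}


def species_namespace(species_id: str, element_id: str) -> str:
    return f"{species_id}{SEP}{element_id}"


def community_exchange_id(met_id: str) -> str:
    return f"EX_c{SEP}{met_id}"


@dataclass
class CommunityModel:
    """A merged community model; structurally a flat constraint-based model
    plus the bookkeeping needed to reweight it."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    species_ids: list[str]
    abundances: dict[str, float]
    biomass_ids: dict[str, str]                       # species -> reaction id
    species_exchanges: dict[str, dict[str, str]]      # species -> {met -> rxn}
    community_exchanges: dict[str, str]               # met -> reaction id
    species_id: str = "community"
    label: str = "community model"
    biomass_reaction_id: str | None = None            # none: mu_c is weighted

    _rxn_lookup: dict[str, Reaction] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._rxn_lookup = {r.id: r for r in self.reactions}

    def reaction(self, rid: str) -> Reaction:
        return self._rxn_lookup[rid]

    def copy(self) -> "CommunityModel":
        return CommunityModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            species_ids=list(self.species_ids),
            abundances=dict(self.abundances),
            biomass_ids=dict(self.biomass_ids),
            species_exchanges={s: dict(d) for s, d in self.species_exchanges.items()},
            community_exchanges=dict(self.community_exchanges),
            species_id=self.species_id,
            label=self.label,
        )

    def community_growth(self, fluxes: dict[str, float]) -> float:
        return sum(self.abundances[sp] * fluxes.get(rid, 0.0)
                   for sp, rid in self.biomass_ids.items())

    def species_growth(self, fluxes: dict[str, float]) -> dict[str, float]:
        return {sp: fluxes.get(rid, 0.0) for sp, rid in self.biomass_ids.items()}


def build_community(models: list[SpeciesModel],
                    abundances: dict[str, float],
                    drop_threshold: float = DROP_THRESHOLD) -> CommunityModel:
    """Merge validated species models under an abundance profile.

    Construction is deterministic: species are processed in species_id order.
    """
    ids = [m.species_id for m in models]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate species_id among models: {sorted(ids)}")
    unknown = set(abundances) - set(ids)
    if unknown:
        raise ValueError(f"abundance given for unknown species: {sorted(unknown)}")
    missing = set(ids) - set(abundances)
    if missing:
        raise ValueError(f"no abundance for species: {sorted(missing)}")

    profile = normalize_abundances(abundances, drop_threshold)
    models = sorted([m for m in models if m.species_id in profile],
                    key=lambda m: m.species_id)

    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    biomass_ids: dict[str, str] = {}
    species_exchanges: dict[str, dict[str, str]] = {}
    pool_mets: dict[str, Metabolite] = {}

    for model in models:
        require_valid(model)
        sp = model.species_id
        a = profile[sp]
        env_ids = {m.id for m in model.metabolites if m.compartment == ENV}
        exchange_ids = {r.id for r in model.exchange_reactions()}
        species_exchanges[sp] = {}

        def ns_met(mid: str) -> str:
            if mid in env_ids:
                return species_namespace(sp, mid) + f"{SEP}bnd"
            return species_namespace(sp, mid)

        for m in model.metabolites:
            metabolites.append(Metabolite(id=ns_met(m.id), name=m.name,
                                          compartment="internal",
                                          formula=m.formula))
            if m.compartment == ENV and m.id not in pool_mets:
                pool_mets[m.id] = Metabolite(id=m.id, name=m.name,
                                             compartment=ENV, formula=m.formula)

        for r in model.reactions:
            rid = species_namespace(sp, r.id)
            if r.id in exchange_ids:
                (met_id, coef), = r.stoichiometry.items()
                stoich = {ns_met(met_id): coef, met_id: -coef * a}
                species_exchanges[sp][met_id] = rid
            else:
                stoich = {ns_met(k): v for k, v in r.stoichiometry.items()}
            obj = a if r.id == model.biomass_reaction_id else 0.0
            reactions.append(Reaction(id=rid, stoichiometry=stoich,
                                      lower_bound=r.lower_bound,
                                      upper_bound=r.upper_bound,
                                      is_exchange=False,
                                      objective_coefficient=obj,
                                      name=r.name))
            if r.id == model.biomass_reaction_id:
                biomass_ids[sp] = rid

    metabolites.extend(pool_mets[m] for m in sorted(pool_mets))

    community_exchanges: dict[str, str] = {}
    for mid in sorted(pool_mets):
        rid = community_exchange_id(mid)
        community_exchanges[mid] = rid
        reactions.append(Reaction(id=rid, stoichiometry={mid: -1.0},
                                  lower_bound=-1000.0, upper_bound=1000.0,
                                  is_exchange=True))

    return CommunityModel(
        metabolites=metabolites,
        reactions=reactions,
        species_ids=[m.species_id for m in models],
        abundances=profile,
        biomass_ids=biomass_ids,
        species_exchanges=species_exchanges,
        community_exchanges=community_exchanges,
    )


def set_abundances(community: CommunityModel,
                   abundances: dict[str, float],
                   drop_threshold: float = 0.0) -> CommunityModel:
    """Reweight an existing community without re-parsing the models.

    Only the abundance-scaled coupling coefficients and the community growth
    weights change; species below the drop threshold keep their reactions but
    contribute nothing to community exchanges or growth.
    """
    unknown = set(abundances) - set(community.species_ids)
    if unknown:
        raise ValueError(f"unknown species: {sorted(unknown)}")
    for sp, a in abundances.items():
        if a < 0:
            raise ValueError(f"negative abundance for '{sp}': {a}")
    total = sum(abundances.values())
    if total <= 0:
        raise ValueError("abundances sum to zero")
    profile = {sp: (abundances.get(sp, 0.0) / total)
               for sp in community.species_ids}
    profile = {sp: (0.0 if a < drop_threshold else a) for sp, a in profile.items()}
    total = sum(profile.values())
    profile = {sp: a / total for sp, a in profile.items()}

    out = community.copy()
    out.abundances = profile
    for sp in out.species_ids:
        a = profile[sp]
        for met_id, rid in out.species_exchanges[sp].items():
            r = out.reaction(rid)
            bnd_key = [k for k in r.stoichiometry if k != met_id]
            coef = r.stoichiometry[bnd_key[0]]
            r.stoichiometry[met_id] = -coef * a
        bio = out.reaction(out.biomass_ids[sp])
        bio.objective_coefficient = a
    return out
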