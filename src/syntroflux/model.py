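"""Constraint-based model containers.

A :class:`SpeciesModel` is a minimal genome-scale-model stand-in: metabolites,
reactions with flux bounds, and a biomass objective.  Two compartments exist:
``internal`` (species cytoplasm, lumped) and ``env`` (the shared extracellular
environment).  Exchange reactions move a single environment metabolite across
the model boundary; positive flux is export to the environment, negative flux
is uptake.  All fluxes are in mmol/gDW/h (biomass flux in 1/h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

ENV = "env"
INTERNAL = "internal"

DEFAULT_BOUND = 1000.0


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = INTERNAL
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    is_exchange: bool = False
    objective_coefficient: float = 0.0
    name: str = ""

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            is_exchange=self.is_exchange,
            objective_coefficient=self.objective_coefficient,
            name=self.name,
        )


@dataclass
class SpeciesModel:
    species_id: str
    label: str = ""
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    biomass_reaction_id: str | None = None

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def exchange_reactions(self) -> list[Reaction]:
        """Exchange reactions, using the flag or the single-environment-
        metabolite autodetection rule when no flag is set anywhere."""
        flagged = [r for r in self.reactions if r.is_exchange]
        if flagged:
            return flagged
        env = {m.id for m in self.metabolites if m.compartment == ENV}
        out = []
        for r in self.reactions:
            keys = list(r.stoichiometry)
            if len(keys) == 1 and keys[0] in env:
                out.append(r)
        return out

    def copy(self) -> "SpeciesModel":
        return SpeciesModel(
            species_id=self.species_id,
            label=self.label,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            biomass_reaction_id=self.biomass_reaction_id,
        )


def validate_model(model: SpeciesModel) -> list[str]:
    """Check every container invariant; violations are returned, not raised.

    Each entry names the offending element and the rule it breaks.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for m in model.metabolites:
        if m.id in seen:
            violations.append(f"metabolite '{m.id}': duplicate id")
        seen.add(m.id)
        if m.compartment not in (ENV, INTERNAL):
            violations.append(
                f"metabolite '{m.id}': unknown compartment '{m.compartment}'"
            )
    met_ids = {m.id for m in model.metabolites}
    env_ids = {m.id for m in model.metabolites if m.compartment == ENV}

    seen_r: set[str] = set()
    for r in model.reactions:
        if r.id in seen_r:
            violations.append(f"reaction '{r.id}': duplicate id")
        seen_r.add(r.id)
        if not (r.lower_bound <= r.upper_bound):
            violations.append(
                f"reaction '{r.id}': lower_bound {r.lower_bound} > "
                f"upper_bound {r.upper_bound}"
            )
        for mid in r.stoichiometry:
            if mid not in met_ids:
                violations.append(
                    f"reaction '{r.id}': references undeclared metabolite '{mid}'"
                )
        for mid, coef in r.stoichiometry.items():
            if not math.isfinite(coef):
                violations.append(
                    f"reaction '{r.id}': non-finite coefficient for '{mid}'"
                )
        if r.is_exchange:
            keys = list(r.stoichiometry)
            if len(keys) != 1:
                violations.append(
                    f"reaction '{r.id}': exchange must touch exactly one "
                    f"metabolite, touches {len(keys)}"
                )
            elif keys[0] not in env_ids and keys[0] in met_ids:
                violations.append(
                    f"reaction '{r.id}': exchange metabolite '{keys[0]}' is "
                    "not in the environment compartment"
                )

    if model.biomass_reaction_id is not None:
        hits = [r for r in model.reactions if r.id == model.biomass_reaction_id]
        if len(hits) != 1:
            violations.append(
                f"biomass_reaction_id '{model.biomass_reaction_id}' resolves "
                f"to {len(hits)} reactions (expected exactly 1)"
            )
    return violations


class ValidationError(ValueError):
    """A model violated a container invariant."""


def require_valid(model: SpeciesModel) -> SpeciesModel:
    violations = validate_model(model)
    if violations:
        raise ValidationError("; ".join(violations))
    return model
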