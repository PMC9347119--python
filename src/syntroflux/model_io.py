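"""Read and write species models.

Two dialects are supported:

``toy-json``
    One JSON document with ``metabolites``, ``reactions`` and ``biomass``
    keys.  Schema::

        {
          "species_id": "m1", "label": "toy methanogen",
          "metabolites": [{"id": "h2", "name": "...", "compartment": "env",
                           "formula": "H2"}, ...],
          "reactions":   [{"id": "MTG", "stoich": {"h2": -4.0, ...},
                           "lb": 0.0, "ub": 1000.0,
                           "exchange": false, "objective": 0.0}, ...],
          "biomass": "BIOMASS"
        }

    ``lb``/``ub`` may be omitted: reactions then default to (-1000, 1000)
    when marked reversible (``"reversible": true``) and (0, 1000) otherwise.

``sbml-subset``
    SBML Level 3 with the flux-bounds (fbc) extension, restricted to the
    constraint-based subset (species, reactions, stoichiometry, bounds,
    objective).  Serialization is delegated to cobrapy; groups and
    annotations are ignored with a logged notice.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .model import (
    DEFAULT_BOUND,
    ENV,
    INTERNAL,
    Metabolite,
    Reaction,
    SpeciesModel,
    ValidationError,
    require_valid,
)

logger = logging.getLogger(__name__)

DIALECTS = ("toy-json", "sbml-subset")

# cobra compartment codes <-> our two-compartment scheme
_COMPARTMENT_TO_COBRA = {INTERNAL: "c", ENV: "e"}
_COBRA_TO_COMPARTMENT = {"c": INTERNAL, "e": ENV}


class ParseError(ValueError):
    """File could not be parsed in the declared dialect."""


# ---------------------------------------------------------------------------
# toy-json
# ---------------------------------------------------------------------------

def _model_to_dict(model: SpeciesModel) -> dict:
    return {
        "species_id": model.species_id,
        "label": model.label,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": dict(r.stoichiometry),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "exchange": r.is_exchange,
                "objective": r.objective_coefficient,
            }
            for r in model.reactions
        ],
        "biomass": model.biomass_reaction_id,
    }


def _model_from_dict(doc: dict) -> SpeciesModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", INTERNAL),
                formula=m.get("formula"),
            )
            for m in doc["metabolites"]
        ]
        rxns = []
        for r in doc["reactions"]:
            if "lb" in r or "ub" in r:
                lb = float(r.get("lb", -DEFAULT_BOUND))
                ub = float(r.get("ub", DEFAULT_BOUND))
            elif r.get("reversible", False):
                lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
            else:
                lb, ub = 0.0, DEFAULT_BOUND
            rxns.append(
                Reaction(
                    id=r["id"],
                    stoichiometry={k: float(v) for k, v in r["stoich"].items()},
                    lower_bound=lb,
                    upper_bound=ub,
                    is_exchange=bool(r.get("exchange", False)),
                    objective_coefficient=float(r.get("objective", 0.0)),
                )
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed toy-json model: {exc!r}") from exc
    return SpeciesModel(
        species_id=doc.get("species_id", "species"),
        label=doc.get("label", ""),
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=doc.get("biomass"),
    )


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------

def to_cobra(model: SpeciesModel):
    """Convert to a cobra.Model (used for SBML serialization and as an
    independent FBA cross-check)."""
    import cobra

    cm = cobra.Model(model.species_id, name=model.label or model.species_id)
    cmets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id,
            name=m.name,
            compartment=_COMPARTMENT_TO_COBRA[m.compartment],
            formula=m.formula,
        )
        cmets[m.id] = cmet
    cm.add_metabolites(list(cmets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(
            r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound
        )
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {cmets[k]: v for k, v in r.stoichiometry.items()}
        )
    objective = {
        cm.reactions.get_by_id(r.id): r.objective_coefficient
        for r in model.reactions
        if r.objective_coefficient
    }
    if not objective and model.biomass_reaction_id:
        objective = {cm.reactions.get_by_id(model.biomass_reaction_id): 1.0}
    if objective:
        cm.objective = cm.problem.Objective(
            sum(c * rx.flux_expression for rx, c in objective.items()),
            direction="max",
        )
    return cm


def from_cobra(cm, species_id: str | None = None) -> SpeciesModel:
    from cobra.util.solver import linear_reaction_coefficients

    coeffs = {r.id: c for r, c in linear_reaction_coefficients(cm).items()}
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=_COBRA_TO_COMPARTMENT.get(m.compartment, INTERNAL),
            formula=m.formula or None,
        )
        for m in cm.metabolites
    ]
    exchange_ids = {r.id for r in cm.exchanges}
    rxns = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: v for m, v in r.metabolites.items()},
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            is_exchange=r.id in exchange_ids,
            objective_coefficient=coeffs.get(r.id, 0.0),
        )
        for r in cm.reactions
    ]
    biomass = None
    if len(coeffs) >= 1:
        biomass = max(coeffs, key=lambda k: abs(coeffs[k]))
    return SpeciesModel(
        species_id=species_id or cm.id or "species",
        label=cm.name or "",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=biomass,
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_model(path: str | Path, dialect: str = "toy-json") -> SpeciesModel:
    """Read and validate a species model.

    Raises :class:`ParseError` for malformed files and
    :class:`~syntroflux.model.ValidationError` for violated invariants.
    """
    path = Path(path)
    if dialect == "toy-json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        model = _model_from_dict(doc)
    elif dialect == "sbml-subset":
        import cobra.io

        logger.info("SBML groups/annotations outside the constraint-based "
                    "subset are ignored")
        try:
            cm = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # cobra raises several libsbml error types
            raise ParseError(f"{path}: SBML parse failed: {exc}") from exc
        model = from_cobra(cm)
    else:
        raise ValueError(f"unknown dialect '{dialect}' (choose from {DIALECTS})")
    return require_valid(model)


def write_model(model: SpeciesModel, path: str | Path,
                dialect: str = "toy-json") -> Path:
    """Serialize a validated model; the file re-reads with full fidelity."""
    require_valid(model)
    path = Path(path)
    if dialect == "toy-json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1, sort_keys=True))
    elif dialect == "sbml-subset":
        import cobra.io

        cobra.io.write_sbml_model(to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown dialect '{dialect}' (choose from {DIALECTS})")
    return path
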