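"""Growth-medium construction: chemical recipe -> community uptake bounds.

A recipe lists component concentrations (mmol/L).  Concentrations act only as
relative weights: the most concentrated non-water solute gets the maximal
uptake bound of 100 mmol/gDW/h, every other solute is scaled linearly by its
concentration relative to that maximum and clamped into [1, 100].  Water
alone is allowed 1000 mmol/gDW/h.  Metabolites absent from the medium cannot
be imported (export stays permitted), mimicking a nutrient-depleted digestate
that supplies trace elements but no organic carbon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .community import CommunityModel

logger = logging.getLogger(__name__)

WATER_BOUND = 1000.0
MAX_BOUND = 100.0
MIN_BOUND = 1.0


@dataclass(frozen=True)
class MediumComponent:
    id: str
    name: str
    concentration: float  # mmol/L


@dataclass
class MediumRecipe:
    components: list[MediumComponent]
    water_id: str = "h2o"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.components]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate component ids in recipe")
        if self.water_id not in ids:
            raise ValueError(f"water component '{self.water_id}' missing")
        for c in self.components:
            if not c.concentration > 0:
                raise ValueError(
                    f"component '{c.id}' has non-positive concentration "
                    f"{c.concentration}"
                )

    def component(self, cid: str) -> MediumComponent:
        for c in self.components:
            if c.id == cid:
                return c
        raise KeyError(cid)


@dataclass
class MediumBounds:
    """Maximum uptake flux per component, mmol/gDW/h."""
    bounds: dict[str, float]
    water_id: str = "h2o"

    def __getitem__(self, cid: str) -> float:
        return self.bounds[cid]

    def items(self):
        return self.bounds.items()


def recipe_to_bounds(recipe: MediumRecipe) -> MediumBounds:
    """Scale a recipe into uptake bounds.

    water -> 1000; non-water component i -> clamp(100 * c_i / c_max, 1, 100)
    with c_max the largest non-water concentration.  The mapping is invariant
    to rescaling all concentrations by a common factor.
    """
    non_water = [c for c in recipe.components if c.id != recipe.water_id]
    if not non_water:
        raise ValueError("recipe needs at least one non-water component")
    c_max = max(c.concentration for c in non_water)
    bounds = {recipe.water_id: WATER_BOUND}
    for c in non_water:
        raw = MAX_BOUND * c.concentration / c_max
        bounds[c.id] = min(MAX_BOUND, max(MIN_BOUND, raw))
    return MediumBounds(bounds=bounds, water_id=recipe.water_id)


def load_recipe(path, water_id: str = "h2o") -> MediumRecipe:
    """Read a recipe table (TSV/CSV with columns compound_id, name,
    concentration_mmol_per_L; separator inferred from the extension)."""
    import pandas as pd

    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep)
    cid, name, conc = frame.columns[:3]
    return MediumRecipe(
        components=[MediumComponent(str(r[cid]), str(r[name]), float(r[conc]))
                    for _, r in frame.iterrows()],
        water_id=water_id,
    )


def load_bounds_maxflux(path, water_id: str = "h2o") -> MediumBounds:
    """Read uptake bounds verbatim from a table whose third column already
    holds maximum fluxes (mmol/gDW/h), bypassing concentration scaling."""
    import pandas as pd

    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep)
    cid, _, flux = frame.columns[:3]
    bounds = {str(r[cid]): float(r[flux]) for _, r in frame.iterrows()}
    return MediumBounds(bounds=bounds, water_id=water_id)


def apply_medium(community: CommunityModel, bounds: MediumBounds) -> CommunityModel:
    """Impose medium uptake bounds on the community exchanges.

    Components present in the medium get their scaled uptake bound; every
    other environment metabolite gets import bound 0 while export stays free.
    Returns a new model; applying twice equals applying once.
    """
    out = community.copy()
    for met_id, rid in out.community_exchanges.items():
        r = out.reaction(rid)
        if met_id in bounds.bounds:
            r.lower_bound = -bounds.bounds[met_id]
        else:
            r.lower_bound = 0.0
        r.upper_bound = max(r.upper_bound, 0.0)
    missing = [cid for cid in bounds.bounds if cid not in out.community_exchanges]
    for cid in missing:
        logger.warning(
            "medium component '%s' has no environment exchange in the "
            "community; ignored", cid
        )
    return out
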