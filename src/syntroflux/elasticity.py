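"""Elasticity analysis: log-log sensitivity of exchange fluxes to
univariate interventions.

An effector is either a medium metabolite (its community import bound is
multiplied by a step factor) or a species abundance (scaled, then the
profile is renormalized, since abundances are compositional).  The response
is a community exchange flux under the cooperative tradeoff.  The
coefficient is a one-sided multiplicative finite difference on log scale,

    E = [ln(|v'| + eps) - ln(|v| + eps)] / ln(step_factor),

positive when the intervention increases production.  Fluxes below
tolerance in both states give a coefficient of exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import CommunityModel, set_abundances
from .solver import OPTIMAL, cooperative_tradeoff

EPS = 1e-8
FLUX_TOL = 1e-6

MEDIUM_METABOLITE = "medium_metabolite"
SPECIES_ABUNDANCE = "species_abundance"


@dataclass(frozen=True)
class ElasticityRecord:
    effector_kind: str      # medium_metabolite | species_abundance
    effector_id: str
    response: str           # community exchange reaction id
    coefficient: float
    direction: int          # sign(coefficient)
    status: str = "ok"      # "ok" | "infeasible"


def _perturb(community: CommunityModel, kind: str, effector_id: str,
             step_factor: float) -> CommunityModel:
    if kind == MEDIUM_METABOLITE:
        if effector_id not in community.community_exchanges:
            raise KeyError(f"no community exchange for medium metabolite "
                           f"'{effector_id}'")
        out = community.copy()
        r = out.reaction(out.community_exchanges[effector_id])
        r.lower_bound = r.lower_bound * step_factor  # import bound scales
        return out
    if kind == SPECIES_ABUNDANCE:
        if effector_id not in community.species_ids:
            raise KeyError(f"unknown species '{effector_id}'")
        scaled = dict(community.abundances)
        scaled[effector_id] *= step_factor
        return set_abundances(community, scaled)
    raise ValueError(f"unknown effector kind '{kind}'")


def elasticity(community: CommunityModel,
               effector: tuple[str, str],
               responses: list[str] | None = None,
               step_factor: float = 2.0,
               fraction: float = 0.5,
               baseline=None) -> list[ElasticityRecord]:
    """Elasticity of community exchange fluxes w.r.t. one intervention.

    ``effector`` is (kind, id); ``responses`` defaults to every community
    exchange reaction.  A precomputed baseline tradeoff solution may be
    passed to avoid re-solving it for each effector.
    """
    if step_factor <= 1.0:
        raise ValueError("step_factor must exceed 1")
    kind, effector_id = effector
    if responses is None:
        responses = sorted(community.community_exchanges.values())

    base = baseline if baseline is not None else cooperative_tradeoff(
        community, fraction)
    if base.status != OPTIMAL:
        raise ValueError(f"baseline solve is {base.status}")
    perturbed_model = _perturb(community, kind, effector_id, step_factor)
    pert = cooperative_tradeoff(perturbed_model, fraction)

    records = []
    dlog = np.log(step_factor)
    for resp in responses:
        if pert.status != OPTIMAL:
            records.append(ElasticityRecord(kind, effector_id, resp,
                                            float("nan"), 0, "infeasible"))
            continue
        v0 = abs(base.fluxes.get(resp, 0.0))
        v1 = abs(pert.fluxes.get(resp, 0.0))
        if v0 < FLUX_TOL and v1 < FLUX_TOL:
            coef = 0.0
        else:
            coef = float((np.log(v1 + EPS) - np.log(v0 + EPS)) / dlog)
        sign = 0 if coef == 0.0 else (1 if coef > 0 else -1)
        records.append(ElasticityRecord(kind, effector_id, resp, coef, sign))
    return records


def elasticity_matrix(community: CommunityModel,
                      effectors: list[tuple[str, str]],
                      responses: list[str] | None = None,
                      step_factor: float = 2.0,
                      fraction: float = 0.5):
    """Effectors x responses elasticity table (pandas DataFrame)."""
    import pandas as pd

    base = cooperative_tradeoff(community, fraction)
    rows = {}
    for eff in effectors:
        recs = elasticity(community, eff, responses, step_factor, fraction,
                          baseline=base)
        rows[f"{eff[0]}:{eff[1]}"] = {r.response: r.coefficient for r in recs}
    return pd.DataFrame(rows).T
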