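"""Cross-feeding network extraction from a tradeoff solution.

FBA only defines species <-> shared-pool fluxes; species-to-species arrows
are inferred by proportional allocation through the pool: for each
metabolite, the edge from producer p to consumer c carries
export_p * import_c / max(total export, total import), and the residual is
routed to or from a distinguished medium node.  This conserves flow exactly
and is deterministic.  Edges at or below the plotting threshold
(0.3 mmol/gDW/h by default) are dropped.  Edge fluxes are reported in
abundance-weighted community units so arrow magnitudes are comparable
across species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .community import CommunityModel
from .solver import OPTIMAL, TradeoffSolution

MEDIUM_NODE = "medium"
DEFAULT_THRESHOLD = 0.3  # mmol/gDW/h

METHANOGENESIS_SET = frozenset({
    "co2", "h2", "ch4", "acetate", "pyruvate", "formate",
    # common alternative ids
    "ac", "for", "pyr", "h2_e", "co2_e", "ch4_e",
})

AMINO_ACID_SET = frozenset({
    "ala_L", "arg_L", "asn_L", "asp_L", "cys_L", "gln_L", "glu_L", "gly",
    "his_L", "ile_L", "leu_L", "lys_L", "met_L", "phe_L", "pro_L", "ser_L",
    "thr_L", "trp_L", "tyr_L", "val_L",
})


@dataclass(frozen=True)
class ExchangeEdge:
    source: str
    metabolite: str
    target: str
    flux: float          # mmol/gDW(community)/h
    category: str


@dataclass
class ExchangeNetwork:
    edges: list[ExchangeEdge]
    threshold: float = DEFAULT_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.source, e.metabolite, e.target, e.flux, e.category)
             for e in self.edges],
            columns=["source", "metabolite", "target", "flux", "category"],
        )

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for e in self.edges:
            g.add_edge(e.source, e.target, key=e.metabolite,
                       metabolite=e.metabolite, flux=e.flux,
                       category=e.category)
        return g

    def edges_for(self, metabolite: str) -> list[ExchangeEdge]:
        return [e for e in self.edges if e.metabolite == metabolite]


def classify_metabolite(metabolite_id: str) -> str:
    """Categorize a metabolite as methanogenesis-related, amino acid, or
    other (mirrors the usual cross-feeding figure legend split)."""
    mid = metabolite_id
    for prefix in ("EX_c__", "EX_", "M_"):
        if mid.startswith(prefix):
            mid = mid[len(prefix):]
    if mid in METHANOGENESIS_SET or mid.lower() in METHANOGENESIS_SET:
        return "methanogenesis"
    if mid in AMINO_ACID_SET:
        return "amino_acid"
    # tolerate style variants like "L-serine"/"ser__L"
    canon = mid.replace("__", "_").replace("-", "_").lower()
    for aa in AMINO_ACID_SET:
        if canon == aa.lower() or canon == aa.lower().replace("_l", ""):
            return "amino_acid"
    return "other"


def extract_exchanges(solution: TradeoffSolution,
                      community: CommunityModel) -> pd.DataFrame:
    """Per-species exchange table from an optimal tradeoff solution.

    Columns: species, metabolite, flux (per gDW of that species) and
    flux_weighted (abundance-weighted community units).  Export positive.
    Rows with exactly zero flux are omitted.
    """
    if solution.status != OPTIMAL:
        raise ValueError(f"solution status is '{solution.status}', not optimal")
    rows = []
    for sp in community.species_ids:
        a = community.abundances[sp]
        for met, rid in community.species_exchanges[sp].items():
            v = solution.fluxes.get(rid, 0.0)
            if v != 0.0:
                rows.append((sp, met, v, a * v))
    return pd.DataFrame(rows, columns=["species", "metabolite", "flux",
                                       "flux_weighted"])


def build_network(table: pd.DataFrame,
                  threshold: float = DEFAULT_THRESHOLD,
                  flux_column: str = "flux_weighted",
                  zero_tol: float = 1e-9) -> ExchangeNetwork:
    """Thresholded producer -> consumer flow graph from an exchange table.

    Producers of each metabolite are paired with consumers by proportional
    allocation; imbalance is routed through the medium node.  Edges with
    flux <= threshold are dropped.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    edges: list[ExchangeEdge] = []
    if table.empty:
        return ExchangeNetwork(edges=[], threshold=threshold)
    for met, sub in table.groupby("metabolite", sort=True):
        producers = [(row["species"], row[flux_column])
                     for _, row in sub.iterrows() if row[flux_column] > zero_tol]
        consumers = [(row["species"], -row[flux_column])
                     for _, row in sub.iterrows() if row[flux_column] < -zero_tol]
        total_exp = sum(f for _, f in producers)
        total_imp = sum(f for _, f in consumers)
        denom = max(total_exp, total_imp)
        category = classify_metabolite(met)
        if denom <= zero_tol:
            continue
        for p, fe in producers:
            for c, fi in consumers:
                flux = fe * fi / denom
                if flux > threshold:
                    edges.append(ExchangeEdge(p, met, c, flux, category))
        if total_exp > total_imp + zero_tol:
            # surplus flows into the medium, shared among producers
            for p, fe in producers:
                flux = fe * (total_exp - total_imp) / denom
                if flux > threshold:
                    edges.append(ExchangeEdge(p, met, MEDIUM_NODE, flux,
                                              category))
        elif total_imp > total_exp + zero_tol:
            for c, fi in consumers:
                flux = fi * (total_imp - total_exp) / denom
                if flux > threshold:
                    edges.append(ExchangeEdge(MEDIUM_NODE, met, c, flux,
                                              category))
    return ExchangeNetwork(edges=edges, threshold=threshold)
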