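"""End-to-end pipelines: the three in-silico experiments.

Each run chains: synthetic (or on-disk) models -> medium bounds -> reactor
operating point -> community assembly -> cooperative tradeoff, then the
stage-specific analysis (cross-feeding network, gas-bound growth sweep, or
intervention elasticities).  Every intermediate is serialized under the
output directory together with a manifest (config, seed, package version)
sufficient to reproduce the outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .community import CommunityModel, build_community
from .elasticity import MEDIUM_METABOLITE, SPECIES_ABUNDANCE, elasticity_matrix
from .exchanges import (DEFAULT_THRESHOLD, ExchangeNetwork, build_network,
                        extract_exchanges)
from .medium import apply_medium, recipe_to_bounds
from .model_io import read_model, write_model
from .reactor import OperatingPoint, apply_operating_point
from .solver import (OPTIMAL, SweepResult, TradeoffSolution,
                     cooperative_tradeoff, growth_sweep)
from .synthetic import CommunityBlueprint, make_toy_community, make_toy_medium

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a pipeline run; the defaults reproduce the reference
    reactor conditions (tradeoff fraction 0.5, exchange threshold 0.3
    mmol/gDW/h, nine-point 0-160 gas sweep, CO2/H2 uptake 1.20/5.11 and CH4
    minimum export 1.15 mmol/gDW/h)."""
    models_dir: str | None = None          # None -> synthetic community
    abundances_path: str | None = None
    out_dir: str = "results/run"
    fraction: float = 0.5
    exchange_threshold: float = DEFAULT_THRESHOLD
    sweep_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 161, 20))
    elasticity_step: float = 2.0
    seed: int = 0
    apply_reactor_constraints: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat key=value config file; unknown keys are rejected."""
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise KeyError(f"unknown config key '{key}'")
            ftype = fields[key].type
            if key == "sweep_grid":
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif "float" in str(ftype):
                kwargs[key] = float(value)
            elif "int" in str(ftype):
                kwargs[key] = int(value)
            elif "bool" in str(ftype):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = value if value.lower() != "none" else None
        return cls(**kwargs)

    def manifest(self) -> dict:
        doc = dataclasses.asdict(self)
        blob = json.dumps(doc, sort_keys=True).encode()
        return {"config": doc,
                "config_hash": hashlib.sha256(blob).hexdigest(),
                "package_version": __version__,
                "seed": self.seed}


def _load_community(config: RunConfig, out: Path) -> CommunityModel:
    if config.models_dir is None:
        blueprint = CommunityBlueprint(seed=config.seed)
        models, table = make_toy_community(blueprint)
    else:
        models_dir = Path(config.models_dir)
        models = [read_model(p, "toy-json")
                  for p in sorted(models_dir.glob("*.json"))]
        table = pd.read_csv(config.abundances_path, sep="\t")
    models_out = out / "models"
    models_out.mkdir(parents=True, exist_ok=True)
    for m in models:
        write_model(m, models_out / f"{m.species_id}.json", "toy-json")
    table.to_csv(out / "abundances.tsv", sep="\t", index=False)
    abundances = dict(zip(table["species_id"], table["fraction"]))
    return build_community(models, abundances)


def _prepare(config: RunConfig, with_operating_point: bool):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("stage: community assembly")
    community = _load_community(config, out)
    logger.info("stage: medium")
    recipe = make_toy_medium()
    bounds = recipe_to_bounds(recipe)
    pd.DataFrame(sorted(bounds.items()),
                 columns=["component", "max_uptake"]).to_csv(
        out / "medium_bounds.tsv", sep="\t", index=False)
    community = apply_medium(community, bounds)
    if with_operating_point and config.apply_reactor_constraints:
        logger.info("stage: reactor operating point")
        community = apply_operating_point(community, OperatingPoint())
    (out / "manifest.json").write_text(json.dumps(config.manifest(), indent=1))
    return community, out


def run_simulation(config: RunConfig) -> tuple[TradeoffSolution, ExchangeNetwork]:
    """Cross-feeding experiment: tradeoff solve + thresholded exchange
    network, all intermediates serialized."""
    try:
        community, out = _prepare(config, with_operating_point=True)
        logger.info("stage: cooperative tradeoff (f=%.2f)", config.fraction)
        solution = cooperative_tradeoff(community, config.fraction)
        if solution.status != OPTIMAL:
            raise RuntimeError(f"tradeoff solve returned {solution.status}")
        table = extract_exchanges(solution, community)
        table.to_csv(out / "exchanges.tsv", sep="\t", index=False)
        network = build_network(table, threshold=config.exchange_threshold)
        network.to_frame().to_csv(out / "network.tsv", sep="\t", index=False)
        growth = pd.DataFrame(
            {"species_id": list(solution.mu),
             "mu": [solution.mu[s] for s in solution.mu]})
        growth.to_csv(out / "growth_rates.tsv", sep="\t", index=False)
        return solution, network
    except Exception as exc:
        raise RuntimeError(f"[simulate] {exc}") from exc


def run_sweep(config: RunConfig) -> SweepResult:
    """Gas-availability sweep on the medium-constrained community (no fixed
    reactor gas bounds, which the sweep itself varies)."""
    try:
        community, out = _prepare(config, with_operating_point=False)
        logger.info("stage: growth sweep over %d thresholds",
                    len(config.sweep_grid))
        result = growth_sweep(community, grid=list(config.sweep_grid),
                              fraction=config.fraction)
        rows = []
        for i, t in enumerate(result.thresholds):
            for sp, mus in result.mu_species.items():
                rows.append((t, sp, mus[i], result.mu_c[i]))
        pd.DataFrame(rows, columns=["threshold", "species_id", "mu", "mu_c"]) \
            .to_csv(out / "sweep.tsv", sep="\t", index=False)
        (out / "plateau.json").write_text(json.dumps({
            "plateau_value": result.plateau_value,
            "plateau_onset_index": result.plateau_onset_index}))
        return result
    except Exception as exc:
        raise RuntimeError(f"[sweep] {exc}") from exc


def run_interventions(config: RunConfig,
                      effectors: list[tuple[str, str]] | None = None,
                      responses: list[str] | None = None) -> pd.DataFrame:
    """Intervention experiment: elasticity of exports to medium availability
    and species abundance shifts."""
    try:
        # interventions vary feedstock availability, so the fixed reactor
        # gas uptake is not pinned here (it would null most responses)
        community, out = _prepare(config, with_operating_point=False)
        if effectors is None:
            effectors = [(MEDIUM_METABOLITE, m)
                         for m in sorted(community.community_exchanges)]
            effectors += [(SPECIES_ABUNDANCE, sp)
                          for sp in community.species_ids]
        if responses is None:
            from .exchanges import classify_metabolite
            responses = [rid for met, rid
                         in sorted(community.community_exchanges.items())
                         if classify_metabolite(met) != "other"
                         or met in ("h2s",)]
        logger.info("stage: elasticity (%d effectors x %d responses)",
                    len(effectors), len(responses))
        matrix = elasticity_matrix(community, effectors, responses,
                                   step_factor=config.elasticity_step,
                                   fraction=config.fraction)
        matrix.to_csv(out / "elasticity.tsv", sep="\t")
        return matrix
    except Exception as exc:
        raise RuntimeError(f"[interventions] {exc}") from exc
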