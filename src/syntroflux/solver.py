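"""FBA linear programs and the two-stage cooperative-tradeoff problem.

Stage 1 maximizes community growth mu_c = sum_i a_i mu_i (an LP).  Stage 2
fixes a fraction ``f`` of that optimum as a floor and minimizes the squared
sum of the species growth rates, a strictly convex QP in the mu_i whose
optimum is therefore unique; with otherwise unconstrained species this gives
growth rates proportional to abundances.  Stage 3 pins the species growth
rates and minimizes the squared sum of all exchange fluxes so the reported
cross-feeding fluxes are reproducible despite flux degeneracy.

LPs are solved with HiGHS (scipy.optimize.linprog); the QPs with a
trust-region interior method (scipy.optimize.minimize, ``trust-constr``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog, minimize

from .community import CommunityModel

FEASIBILITY_TOL = 1e-6
OPTIMALITY_TOL = 1e-8

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
FAILED = "failed"

_LINPROG_STATUS = {0: OPTIMAL, 1: FAILED, 2: INFEASIBLE, 3: UNBOUNDED, 4: FAILED}


@dataclass
class FluxSolution:
    status: str
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)


@dataclass
class TradeoffSolution:
    status: str
    mu_c_max: float | None = None
    fraction: float = 0.5
    mu: dict[str, float] = field(default_factory=dict)     # per-species 1/h
    community_growth: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)


@dataclass
class SweepResult:
    thresholds: list[float]
    mu_c: list[float]
    mu_species: dict[str, list[float]]
    plateau_value: float | None = None
    plateau_onset_index: int | None = None


# ---------------------------------------------------------------------------
# problem assembly
# ---------------------------------------------------------------------------

def _assemble(model):
    """Stoichiometric matrix, bounds and objective from any model exposing
    ``metabolites`` and ``reactions``."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rxns = model.reactions
    rows, cols, vals = [], [], []
    for j, r in enumerate(rxns):
        for mid, coef in r.stoichiometry.items():
            if coef != 0.0:
                rows.append(met_index[mid])
                cols.append(j)
                vals.append(coef)
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_index), len(rxns))
    )
    lb = np.array([r.lower_bound for r in rxns])
    ub = np.array([r.upper_bound for r in rxns])
    c = np.array([r.objective_coefficient for r in rxns])
    rxn_ids = [r.id for r in rxns]
    return S, lb, ub, c, rxn_ids


def _solve_lp(S, lb, ub, c):
    """max c.v s.t. S v = 0, lb <= v <= ub."""
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": OPTIMALITY_TOL,
                 "dual_feasibility_tolerance": OPTIMALITY_TOL},
    )
    status = _LINPROG_STATUS.get(res.status, FAILED)
    if status != OPTIMAL:
        return status, None, None
    return OPTIMAL, float(-res.fun), res.x


def _solve_qp(S, lb, ub, quad_idx, x0,
              floor_row: np.ndarray | None = None,
              floor_rhs: float | None = None,
              ridge: float = 1e-9):
    """min sum_{j in quad_idx} v_j^2 s.t. S v = 0, bounds, optional linear
    floor constraint.  A tiny ridge regularizes flux directions outside the
    quadratic objective.  Solved with SLSQP (problems here are small)."""
    n = S.shape[1]
    w = np.full(n, ridge)
    w[quad_idx] = 1.0
    Sd = S.toarray()

    constraints = [
        {"type": "eq", "fun": lambda x: Sd @ x, "jac": lambda x: Sd},
    ]
    if floor_row is not None:
        constraints.append({
            "type": "ineq",
            "fun": lambda x: float(floor_row @ x) - floor_rhs,
            "jac": lambda x: floor_row,
        })
    res = minimize(
        lambda x: float(np.dot(w * x, x)),
        x0,
        jac=lambda x: 2.0 * w * x,
        method="SLSQP",
        bounds=np.column_stack([lb, ub]),
        constraints=constraints,
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    violation = float(np.abs(Sd @ res.x).max()) if n else 0.0
    ok = res.success or violation < FEASIBILITY_TOL
    ok = ok and violation < FEASIBILITY_TOL
    ok = ok and np.all(res.x >= lb - FEASIBILITY_TOL)
    ok = ok and np.all(res.x <= ub + FEASIBILITY_TOL)
    if floor_row is not None and ok:
        ok = float(floor_row @ res.x) >= floor_rhs - FEASIBILITY_TOL
    return (OPTIMAL if ok else FAILED), res.x


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def fba(model, objective_reaction: str | None = None) -> FluxSolution:
    """Plain flux balance analysis: max c.v s.t. S v = 0 and bounds.

    If ``objective_reaction`` is given it overrides the model's objective
    coefficients.
    """
    S, lb, ub, c, rxn_ids = _assemble(model)
    if objective_reaction is not None:
        if objective_reaction not in rxn_ids:
            raise KeyError(objective_reaction)
        c = np.zeros(len(rxn_ids))
        c[rxn_ids.index(objective_reaction)] = 1.0
    status, obj, x = _solve_lp(S, lb, ub, c)
    if status != OPTIMAL:
        return FluxSolution(status=status, objective_value=None)
    return FluxSolution(status=OPTIMAL, objective_value=obj,
                        fluxes=dict(zip(rxn_ids, x.tolist())))


def cooperative_tradeoff(community: CommunityModel,
                         fraction: float = 0.5) -> TradeoffSolution:
    """Two-stage cooperative tradeoff with stage-3 flux regularization.

    1. LP: maximize mu_c, giving mu_c_max.
    2. QP: minimize sum_i mu_i^2 subject to sum_i a_i mu_i >= fraction *
       mu_c_max and all stage-1 constraints; the mu_i are unique.
    3. QP: with the mu_i pinned, minimize the squared sum of all species and
       community exchange fluxes for a reproducible flux vector.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    S, lb, ub, c, rxn_ids = _assemble(community)
    idx = {rid: j for j, rid in enumerate(rxn_ids)}

    status, mu_c_max, x1 = _solve_lp(S, lb, ub, c)
    if status != OPTIMAL:
        return TradeoffSolution(status=status, fraction=fraction)

    bio_idx = np.array([idx[community.biomass_ids[sp]]
                        for sp in community.species_ids])
    a_vec = np.array([community.abundances[sp] for sp in community.species_ids])

    floor_row = np.zeros(len(rxn_ids))
    floor_row[bio_idx] = a_vec
    status, x2 = _solve_qp(S, lb, ub, bio_idx, x1,
                           floor_row=floor_row,
                           floor_rhs=fraction * mu_c_max - 1e-9)
    if status != OPTIMAL:
        return TradeoffSolution(status=FAILED, mu_c_max=mu_c_max,
                                fraction=fraction)
    mu = {sp: float(x2[idx[community.biomass_ids[sp]]])
          for sp in community.species_ids}

    # stage 3: pin growth, regularize exchange fluxes
    ex_ids = [rid for d in community.species_exchanges.values()
              for rid in d.values()]
    ex_ids += list(community.community_exchanges.values())
    ex_idx = np.array(sorted(idx[rid] for rid in ex_ids))
    lb3, ub3 = lb.copy(), ub.copy()
    slack = 1e-7
    for sp, rid in community.biomass_ids.items():
        j = idx[rid]
        lb3[j] = max(lb[j], mu[sp] - slack)
        ub3[j] = min(ub[j], mu[sp] + slack)
    status3, x3 = _solve_qp(S, lb3, ub3, ex_idx, x2)
    x = x3 if status3 == OPTIMAL else x2

    fluxes = dict(zip(rxn_ids, x.tolist()))
    return TradeoffSolution(
        status=OPTIMAL,
        mu_c_max=float(mu_c_max),
        fraction=fraction,
        mu=mu,
        community_growth=float(np.dot(a_vec, [mu[sp] for sp in community.species_ids])),
        fluxes=fluxes,
    )


def growth_sweep(community: CommunityModel,
                 gas_ids: tuple[str, ...] = ("h2", "co2"),
                 grid: list[float] | None = None,
                 fraction: float = 0.5,
                 plateau_rel_tol: float = 1e-3,
                 gas_ratios: tuple[float, ...] | None = None) -> SweepResult:
    """Cooperative tradeoff across a grid of gas uptake upper bounds.

    For each threshold t the community uptake of every gas in ``gas_ids`` is
    allowed in [0, t] (exchange lower bound -t); growth rates are recorded.
    ``gas_ratios`` optionally scales the threshold per gas (e.g. (4, 1) for
    a 4:1 H2:CO2 feed); the default applies the same bound to every gas.
    The plateau value is the last-point mu_c, with onset at the first grid
    point where the relative change drops below ``plateau_rel_tol``.
    """
    if gas_ratios is None:
        gas_ratios = tuple(1.0 for _ in gas_ids)
    if len(gas_ratios) != len(gas_ids):
        raise ValueError("gas_ratios must match gas_ids in length")
    if grid is None:
        grid = list(np.linspace(0.0, 160.0, 9))
    if len(grid) == 0:
        raise ValueError("empty sweep grid")
    if sorted(grid) != list(grid):
        raise ValueError("sweep grid must be sorted ascending")
    for gas in gas_ids:
        if gas not in community.community_exchanges:
            raise KeyError(f"no community exchange for gas '{gas}'")

    mu_c: list[float] = []
    mu_species: dict[str, list[float]] = {sp: [] for sp in community.species_ids}
    for t in grid:
        m = community.copy()
        for gas, ratio in zip(gas_ids, gas_ratios):
            r = m.reaction(m.community_exchanges[gas])
            r.lower_bound = -float(t) * ratio
            r.upper_bound = max(r.upper_bound, 0.0)
        sol = cooperative_tradeoff(m, fraction)
        if sol.status == OPTIMAL:
            mu_c.append(sol.community_growth)
            for sp in community.species_ids:
                mu_species[sp].append(sol.mu[sp])
        else:
            mu_c.append(float("nan"))
            for sp in community.species_ids:
                mu_species[sp].append(float("nan"))

    plateau_value = mu_c[-1] if mu_c else None
    onset = None
    for i in range(1, len(mu_c)):
        denom = max(abs(mu_c[i]), 1e-12)
        if abs(mu_c[i] - mu_c[i - 1]) / denom < plateau_rel_tol:
            onset = i
            break
    return SweepResult(thresholds=list(grid), mu_c=mu_c,
                       mu_species=mu_species,
                       plateau_value=plateau_value,
                       plateau_onset_index=onset if len(grid) > 1 else None)
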