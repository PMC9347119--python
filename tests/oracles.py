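"""Independent brute-force oracles for the optimization stages.

These deliberately avoid the package's solver path: the LP oracle
enumerates basic feasible solutions (vertices) directly, and the QP oracle
scans a dense grid over the species-growth simplex, checking feasibility of
each candidate with an LP in which the growth rates are pinned.
"""

from __future__ import annotations

import itertools

import numpy as np


def lp_vertex_enumeration(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                          c: np.ndarray, tol: float = 1e-9) -> float:
    """Maximize c.v over {S v = 0, lb <= v <= ub} by enumerating vertices.

    A vertex fixes n - rank(S) variables at one of their bounds and solves
    the equality system for the rest.  Exponential; tiny systems only.
    """
    m, n = S.shape
    rank = np.linalg.matrix_rank(S)
    n_fixed = n - rank
    best = -np.inf
    for free_cols in itertools.combinations(range(n), rank):
        fixed_cols = [j for j in range(n) if j not in free_cols]
        B = S[:, list(free_cols)]
        if np.linalg.matrix_rank(B) < rank:
            continue
        for pattern in itertools.product(*[(lb[j], ub[j]) for j in fixed_cols]):
            v = np.empty(n)
            for j, val in zip(fixed_cols, pattern):
                v[j] = val
            rhs = -S[:, fixed_cols] @ np.array(pattern) if fixed_cols \
                else np.zeros(m)
            sol, residual, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            if np.linalg.norm(B @ sol - rhs) > tol:
                continue
            for j, val in zip(free_cols, sol):
                v[j] = val
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                best = max(best, float(c @ v))
        if n_fixed == 0:
            break
    return best


def qp_mu_grid_search(feasible, a: np.ndarray, mu_floor: float,
                      mu_max_individual: np.ndarray,
                      resolution: int = 60, zoom_rounds: int = 5) -> np.ndarray:
    """Minimize sum(mu^2) over a dense grid of per-species growth vectors.

    ``feasible(mu)`` must report whether the community supports the growth
    vector; candidates failing ``a . mu >= mu_floor`` are skipped.  After
    each round the grid zooms in around the incumbent, so the final
    quantization error is (range / resolution) * (4 / resolution)^rounds.
    """
    lo = np.zeros_like(mu_max_individual, dtype=float)
    hi = np.array(mu_max_individual, dtype=float)
    best = None
    for _ in range(zoom_rounds + 1):
        axes = [np.linspace(l, h, resolution + 1) for l, h in zip(lo, hi)]
        best_obj = np.inf if best is None else float(best @ best)
        for mu in itertools.product(*axes):
            mu = np.array(mu)
            if a @ mu < mu_floor - 1e-12:
                continue
            obj = float(mu @ mu)
            if obj < best_obj and feasible(mu):
                best, best_obj = mu, obj
        if best is None:
            return None
        step = (hi - lo) / resolution
        lo = np.maximum(best - 2 * step, 0.0)
        hi = np.minimum(best + 2 * step, mu_max_individual)
    return best
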