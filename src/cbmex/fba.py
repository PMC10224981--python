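"""Flux balance analysis, parsimonious FBA, and flux-consistency detection.

All optimization runs through scipy's HiGHS backend (``linprog`` for LPs,
``milp`` for mixed-integer programs elsewhere in the package), which is
deterministic for a fixed problem. The steady-state constraint S v = 0 with
lb <= v <= ub defines the flux polytope; FBA maximizes (or minimizes) one
flux, pFBA additionally minimizes total absolute flux at the growth optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel

#: any |v| below this is treated as zero when reading flux support
FLUX_ZERO_TOL = 1e-6


@dataclass
class SolverContract:
    """Numerical policy shared by LP/MILP solves."""

    feasibility_tol: float = 1e-9
    flux_zero_tol: float = FLUX_ZERO_TOL
    time_limit: float = 7200.0
    mip_gap: float = 1e-4
    seed: int | None = None


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | timeout | error
    objective_value: float = float("nan")
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def support(self, tol: float = FLUX_ZERO_TOL) -> set[str]:
        return {r for r, v in self.fluxes.items() if abs(v) > tol}


_STATUS = {0: "optimal", 1: "timeout", 2: "infeasible", 3: "error", 4: "error"}


def _bounds(model: MetabolicModel) -> list[tuple[float, float]]:
    return [(r.lower_bound, r.upper_bound) for r in model.reactions]


def _solve_lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    return linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                   bounds=bounds, method="highs")


def solve_fba(model: MetabolicModel, objective_id: str | None = None,
              sense: str = "max") -> FluxSolution:
    """Optimize one reaction's flux over the steady-state polytope."""
    objective_id = objective_id or model.biomass_id
    n = len(model.reactions)
    c = np.zeros(n)
    j = model.reaction_ids.index(objective_id)
    c[j] = -1.0 if sense == "max" else 1.0
    S = model.S
    res = _solve_lp(c, S, np.zeros(S.shape[0]), _bounds(model))
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return FluxSolution(status)
    fluxes = dict(zip(model.reaction_ids, res.x))
    return FluxSolution("optimal", float(res.x[j]), fluxes)


def solve_pfba(model: MetabolicModel, objective_id: str | None = None,
               growth_slack: float = 1e-9
               ) -> tuple[float, FluxSolution, float]:
    """Parsimonious FBA: fix growth at its maximum, then minimize sum |v|.

    Returns ``(max_growth, solution, total_flux)`` where ``total_flux`` is
    the minimal sum of absolute fluxes over all reactions. The growth
    fixation allows a relative slack of ``growth_slack`` below the optimum
    to avoid numerical infeasibility.
    """
    objective_id = objective_id or model.biomass_id
    fba = solve_fba(model, objective_id, "max")
    if not fba.optimal:
        return float("nan"), fba, float("nan")
    mu = fba.objective_value

    # split v = v_plus - v_minus; both halves nonnegative
    n = len(model.reactions)
    S = model.S
    A_eq = np.hstack([S, -S])
    bounds = []
    for rxn in model.reactions:
        bounds.append((max(0.0, rxn.lower_bound), max(0.0, rxn.upper_bound)))
    for rxn in model.reactions:
        bounds.append((max(0.0, -rxn.upper_bound), max(0.0, -rxn.lower_bound)))
    j = model.reaction_ids.index(objective_id)
    growth_row = np.zeros(2 * n)
    growth_row[j] = 1.0
    growth_row[n + j] = -1.0
    # mu*(1-slack) <= v_obj <= mu (two inequality rows)
    lo = mu * (1.0 - growth_slack) if mu >= 0 else mu * (1.0 + growth_slack)
    A_ub = np.vstack([-growth_row, growth_row])
    b_ub = np.array([-lo, mu if mu >= 0 else mu * (1.0 - growth_slack)])
    c = np.ones(2 * n)
    res = _solve_lp(c, A_eq, np.zeros(S.shape[0]), bounds, A_ub, b_ub)
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return mu, FluxSolution(status), float("nan")
    v = res.x[:n] - res.x[n:]
    fluxes = dict(zip(model.reaction_ids, v))
    total = float(np.sum(np.abs(v)))
    return mu, FluxSolution("optimal", float(v[j]), fluxes), total


def flux_range(model: MetabolicModel, rxn_id: str) -> tuple[float, float]:
    """Min and max attainable flux of one reaction (FVA for one reaction)."""
    lo = solve_fba(model, rxn_id, "min")
    hi = solve_fba(model, rxn_id, "max")
    if not (lo.optimal and hi.optimal):
        return 0.0, 0.0
    return lo.objective_value, hi.objective_value


def consistent_reactions_fva(model: MetabolicModel,
                             eps: float = 1e-4) -> set[str]:
    """Brute-force consistency oracle: per-reaction maximize/minimize.

    A reaction is flux-consistent iff it can carry |v| >= eps in some
    steady-state solution. Quadratic in model size; used as the independent
    reference for the block algorithm below.
    """
    out = set()
    slack = 1e-6 * eps
    for rxn in model.reactions:
        lo, hi = flux_range(model, rxn.id)
        if hi >= eps - slack or lo <= -eps + slack:
            out.add(rxn.id)
    return out


def consistent_reactions(model: MetabolicModel, eps: float = 1e-4) -> set[str]:
    """Flux-consistent reactions via block LPs with per-reaction fallback.

    Repeatedly solves the LP ``max sum z_j`` with ``0 <= z_j <= eps`` and
    ``z_j <= sign * v_j`` over the not-yet-confirmed set (both signs), adding
    every reaction whose flux reaches eps in any block solution; reactions
    still unconfirmed are then settled individually. Agrees with
    :func:`consistent_reactions_fva` by construction.
    """
    n = len(model.reactions)
    if n == 0:
        return set()
    S = model.S
    ids = model.reaction_ids
    idx = {r: i for i, r in enumerate(ids)}
    consistent: set[str] = set()
    unconfirmed = set(ids)
    thresh = 0.99 * eps

    for sign in (1.0, -1.0):
        stalled = False
        while unconfirmed and not stalled:
            J = sorted(unconfirmed)
            m = len(J)
            # variables: [v (n), z (m)]
            c = np.concatenate([np.zeros(n), -np.ones(m)])
            A_eq = np.hstack([S, np.zeros((S.shape[0], m))])
            # z_j - sign*v_j <= 0
            A_ub = np.zeros((m, n + m))
            for k, rid in enumerate(J):
                A_ub[k, idx[rid]] = -sign
                A_ub[k, n + k] = 1.0
            bounds = _bounds(model) + [(0.0, eps)] * m
            res = _solve_lp(c, A_eq, np.zeros(S.shape[0]), bounds,
                            A_ub, np.zeros(m))
            if res.status != 0:
                break  # infeasible polytope: nothing can carry flux
            v = res.x[:n]
            newly = {rid for rid in unconfirmed if abs(v[idx[rid]]) >= thresh}
            if not newly:
                stalled = True
            consistent |= newly
            unconfirmed -= newly

    for rid in sorted(unconfirmed):
        lo, hi = flux_range(model, rid)
        if hi >= thresh or lo <= -thresh:
            consistent.add(rid)
    return consistent


def max_growth(model: MetabolicModel) -> float:
    """Maximal biomass flux; NaN when the model is infeasible."""
    sol = solve_fba(model, model.biomass_id, "max")
    return sol.objective_value if sol.optimal else float("nan")


def can_grow(model: MetabolicModel, biomass_lb: float = 1.0,
             tol: float = 1e-6) -> bool:
    """Whether the model attains at least ``biomass_lb`` biomass flux."""
    mu = max_growth(model)
    return bool(np.isfinite(mu) and mu >= biomass_lb - tol)
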