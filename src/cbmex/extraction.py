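"""Model-extraction methods (MEMs).

Six algorithms reduce a generic constraint-based model to a context-specific
submodel using per-reaction activity levels derived from transcriptomics:

* GIMME   — LP: minimize flux through inactive reactions while preserving a
            fraction of maximal growth.
* iMAT    — MILP: maximize the number of active reactions carrying flux plus
            inactive reactions shut off.
* INIT    — MILP: maximize the sum of activity-derived weights over reactions
            kept (positive weight rewards activity, negative rewards removal).
* FASTCORE— LP sequence (LP7/LP10) finding a compact flux-consistent
            superset of a high-activity core.
* MBA     — greedy randomized pruning that preserves a high-confidence core
            entirely and a medium-confidence core approximately.
* mCADRE  — evidence-ranked sequential pruning with protected core and
            growth requirement; infeasible removals are skipped.

The template is prepared once (exchanges open at +/-1000, internal bounds at
+/-1000 by reversibility, biomass lower bound fixed at a nominal rate) and
the biomass reaction is protected by every method: in the core set
(FASTCORE, MBA, mCADRE), in the high-activity set (GIMME, iMAT), or with a
large positive weight (INIT).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .fba import FLUX_ZERO_TOL, can_grow, consistent_reactions, max_growth
from .model import MetabolicModel
from .model_io import OPEN_BOUND, open_exchanges
from .scoring import ACTIVITY_CUTOFF, ReactionActivity

METHODS = ("GIMME", "iMAT", "INIT", "FASTCORE", "MBA", "mCADRE")


@dataclass
class ExtractionConfig:
    method: str = "GIMME"
    activity_cutoff: float = ACTIVITY_CUTOFF
    gimme_growth_fraction: float = 0.9
    imat_eps: float = 1.0
    fastcore_eps: float = 1e-4
    mba_medium_cutoff: float | None = None  # default 0.5 * activity_cutoff
    mba_eps: float = 0.5
    mba_orderings: int = 1
    mcadre_core_cutoff: float = 0.9
    init_biomass_weight: float | None = None  # default 2*max|w| + 1
    biomass_lb: float = 1.0
    flux_zero_tol: float = FLUX_ZERO_TOL
    consistency_eps: float = 1e-4
    time_limit: float = 7200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gimme_growth_fraction <= 1.0):
            raise ValueError("gimme_growth_fraction must be in (0, 1]")
        if self.activity_cutoff < 0 or self.imat_eps <= 0 or self.fastcore_eps <= 0:
            raise ValueError("cutoffs must be >= 0 and eps > 0")

    @property
    def medium_cutoff(self) -> float:
        return (self.mba_medium_cutoff if self.mba_medium_cutoff is not None
                else 0.5 * self.activity_cutoff)


@dataclass
class ContextModel:
    """An extracted submodel plus provenance."""

    model: MetabolicModel
    sample: str
    method: str
    config: ExtractionConfig
    seconds: float = 0.0
    functional: bool = True
    status: str = "optimal"
    objective_value: float | None = None  # MILP objective where applicable

    @property
    def reaction_ids(self) -> set[str]:
        return set(self.model.reaction_ids)


class TemplateError(ValueError):
    """Raised when the template cannot satisfy the biomass requirement."""


def prepare_template(model: MetabolicModel,
                     biomass_lb: float = 1.0) -> MetabolicModel:
    """Open exchanges, reset internal bounds to +/-1000 by reversibility,
    and fix the biomass lower bound. Idempotent."""
    out = open_exchanges(model)
    for rxn in out.reactions:
        if rxn.is_exchange:
            continue
        rxn.lower_bound = -OPEN_BOUND if rxn.lower_bound < 0 else 0.0
        rxn.upper_bound = OPEN_BOUND
    bio = out.biomass
    bio.lower_bound = biomass_lb
    bio.upper_bound = OPEN_BOUND
    if not can_grow(out, biomass_lb):
        raise TemplateError(
            f"template cannot attain biomass flux {biomass_lb}")
    return out


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _ral_of(ral: ReactionActivity, template: MetabolicModel,
            cfg: ExtractionConfig) -> dict[str, float]:
    """Scored activity per reaction; biomass is pinned above the cutoff."""
    out = dict(ral.ral)
    out[template.biomass_id] = max(out.get(template.biomass_id, 0.0),
                                   2.0 * cfg.activity_cutoff + 1.0)
    return out


def _finish(template: MetabolicModel, keep: set[str], sample: str,
            cfg: ExtractionConfig, status: str = "optimal",
            objective: float | None = None) -> ContextModel:
    sub = template.subnetwork(keep, model_id=f"{template.model_id}:{sample}:{cfg.method}")
    functional = can_grow(sub, cfg.biomass_lb)
    return ContextModel(sub, sample, cfg.method, cfg, functional=functional,
                        status=status, objective_value=objective)


# ---------------------------------------------------------------------------
# GIMME
# ---------------------------------------------------------------------------

def extract_gimme(template: MetabolicModel, ral: ReactionActivity,
                  cfg: ExtractionConfig) -> ContextModel:
    """Minimize penalized flux subject to a growth requirement.

    Penalty c_r = max(0, cutoff - RAL_r) for scored reactions; the LP
    minimizes sum c_r |v_r| subject to growth >= fraction * max growth.
    Retained: active reactions (RAL >= cutoff), unscored reactions, all
    exchanges, biomass, and penalized reactions carrying flux at the
    optimum.
    """
    mu = max_growth(template)
    if not np.isfinite(mu):
        raise TemplateError("GIMME requires a growing template")
    scores = _ral_of(ral, template, cfg)
    ids = template.reaction_ids
    n = len(ids)
    penalty = np.zeros(n)
    for j, rid in enumerate(ids):
        if rid in scores:
            penalty[j] = max(0.0, cfg.activity_cutoff - scores[rid])

    S = template.S
    A_eq = np.hstack([S, -S])
    bounds = ([(max(0.0, r.lower_bound), max(0.0, r.upper_bound))
               for r in template.reactions]
              + [(max(0.0, -r.upper_bound), max(0.0, -r.lower_bound))
                 for r in template.reactions])
    j_bio = ids.index(template.biomass_id)
    growth_row = np.zeros(2 * n)
    growth_row[j_bio] = -1.0
    growth_row[n + j_bio] = 1.0
    res = linprog(np.concatenate([penalty, penalty]),
                  A_ub=growth_row[None, :],
                  b_ub=[-cfg.gimme_growth_fraction * mu],
                  A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
                  bounds=bounds, method="highs")
    if res.status != 0:
        raise TemplateError(f"GIMME LP failed with status {res.status}")
    v = res.x[:n] - res.x[n:]

    keep: set[str] = set()
    for j, (rid, rxn) in enumerate(zip(ids, template.reactions)):
        if rid not in scores:  # unscored
            keep.add(rid)
        elif scores[rid] >= cfg.activity_cutoff:
            keep.add(rid)
        elif abs(v[j]) > cfg.flux_zero_tol:  # penalized but used
            keep.add(rid)
        if rxn.is_exchange:
            keep.add(rid)
    keep.add(template.biomass_id)
    return _finish(template, keep, ral.sample, cfg,
                   objective=float(res.fun))


# ---------------------------------------------------------------------------
# iMAT
# ---------------------------------------------------------------------------

def _milp_solve(c, constraints, integrality, bounds, cfg: ExtractionConfig):
    res = milp(c=c, constraints=constraints, integrality=integrality,
               bounds=bounds,
               options={"time_limit": cfg.time_limit,
                        "mip_rel_gap": 0.0})
    return res


def extract_imat(template: MetabolicModel, ral: ReactionActivity,
                 cfg: ExtractionConfig) -> ContextModel:
    """MILP maximizing activated high-activity and shut low-activity
    reactions; see module docstring.

    RH = scored reactions with RAL >= cutoff plus biomass; RL = remaining
    scored reactions. After solving, low-activity reactions with zero flux
    are dropped and the model is restored to flux consistency.
    """
    scores = _ral_of(ral, template, cfg)
    ids = template.reaction_ids
    n = len(ids)
    RH = [r for r in ids if r in scores and scores[r] >= cfg.activity_cutoff]
    RL = [r for r in ids if r in scores and scores[r] < cfg.activity_cutoff]
    idx = {r: j for j, r in enumerate(ids)}
    eps = cfg.imat_eps

    nv = n
    cols: list[tuple[str, str]] = []  # (kind, rxn)
    for r in RH:
        cols.append(("y+", r))
        if template.reaction(r).lower_bound < 0:
            cols.append(("y-", r))
    for r in RL:
        cols.append(("y0", r))
    ny = len(cols)
    col_at = {kc: nv + k for k, kc in enumerate(cols)}

    S = template.S
    rows: list[tuple[dict[int, float], float, float]] = []
    obj = np.zeros(nv + ny)

    def add_row(entries: dict[int, float], lb: float, ub: float) -> None:
        rows.append((entries, lb, ub))

    for r in RH:
        j = idx[r]
        rlb = template.reaction(r).lower_bound
        rub = template.reaction(r).upper_bound
        jp = col_at[("y+", r)]
        # v - (eps - lb) y+ >= lb
        add_row({j: 1.0, jp: -(eps - rlb)}, rlb, np.inf)
        obj[jp] = 1.0
        if ("y-", r) in col_at:
            jm = col_at[("y-", r)]
            # v + (ub + eps) y- <= ub
            add_row({j: 1.0, jm: rub + eps}, -np.inf, rub)
            # y+ + y- <= 1
            add_row({jp: 1.0, jm: 1.0}, -np.inf, 1.0)
            obj[jm] = 1.0
    for r in RL:
        j = idx[r]
        rlb = template.reaction(r).lower_bound
        rub = template.reaction(r).upper_bound
        j0 = col_at[("y0", r)]
        # v + ub y0 <= ub ; v + lb y0 >= lb
        add_row({j: 1.0, j0: rub}, -np.inf, rub)
        add_row({j: 1.0, j0: rlb}, rlb, np.inf)
        obj[j0] = 1.0

    A = sparse.lil_matrix((len(rows), nv + ny))
    lo = np.empty(len(rows))
    hi = np.empty(len(rows))
    for i, (entries, lb_i, ub_i) in enumerate(rows):
        for j, val in entries.items():
            A[i, j] = val
        lo[i], hi[i] = lb_i, ub_i
    Sfull = sparse.hstack([sparse.csr_matrix(S),
                           sparse.csr_matrix((S.shape[0], ny))])
    constraints = [
        LinearConstraint(Sfull, 0.0, 0.0),
        LinearConstraint(A.tocsr(), lo, hi),
    ]
    lbs = np.array([r.lower_bound for r in template.reactions] + [0.0] * ny)
    ubs = np.array([r.upper_bound for r in template.reactions] + [1.0] * ny)
    integrality = np.concatenate([np.zeros(nv), np.ones(ny)])
    res = _milp_solve(-obj, constraints, integrality, Bounds(lbs, ubs), cfg)
    status = "optimal" if res.status == 0 else (
        "timeout" if res.status == 1 and res.x is not None else "error")
    if res.x is None:
        raise TemplateError(f"iMAT MILP failed (status {res.status})")
    v = res.x[:nv]
    objective = float(-res.fun)

    drop = {r for r in RL if abs(v[idx[r]]) <= cfg.flux_zero_tol}
    sub = template.subnetwork(set(ids) - drop)
    keep = consistent_reactions(sub, cfg.consistency_eps)
    return _finish(template, keep, ral.sample, cfg, status, objective)


# ---------------------------------------------------------------------------
# INIT
# ---------------------------------------------------------------------------

def init_weights(ral: ReactionActivity, template: MetabolicModel,
                 cfg: ExtractionConfig) -> dict[str, float]:
    """Activity weights: RAL - cutoff for scored reactions; biomass gets a
    large positive weight (default 2*max|w| + 1)."""
    scores = dict(ral.ral)
    w = {r: s - cfg.activity_cutoff for r, s in scores.items()
         if r != template.biomass_id}
    wmax = max((abs(x) for x in w.values()), default=1.0)
    w[template.biomass_id] = (cfg.init_biomass_weight
                              if cfg.init_biomass_weight is not None
                              else 2.0 * wmax + 1.0)
    return w


def extract_init(template: MetabolicModel, ral: ReactionActivity,
                 cfg: ExtractionConfig) -> ContextModel:
    """MILP maximizing sum of weights over retained scored reactions.

    A scored reaction is retained iff its indicator is on, which forces
    |v| >= eps through it; indicators off force v = 0. Unscored reactions
    are unconstrained and kept as needed for flux consistency.
    """
    w = init_weights(ral, template, cfg)
    ids = template.reaction_ids
    idx = {r: j for j, r in enumerate(ids)}
    n = len(ids)
    eps = cfg.imat_eps
    scored = [r for r in ids if r in w]

    cols: list[tuple[str, str]] = []
    for r in scored:
        cols.append(("y+", r))
        if template.reaction(r).lower_bound < 0:
            cols.append(("y-", r))
    ny = len(cols)
    col_at = {kc: n + k for k, kc in enumerate(cols)}
    obj = np.zeros(n + ny)
    rows: list[tuple[dict[int, float], float, float]] = []
    for r in scored:
        j = idx[r]
        rlb = template.reaction(r).lower_bound
        rub = template.reaction(r).upper_bound
        jp = col_at[("y+", r)]
        obj[jp] = w[r]
        if ("y-", r) in col_at:
            jm = col_at[("y-", r)]
            obj[jm] = w[r]
            # v >= eps y+ + lb y-  ;  v <= ub y+ - eps y-
            rows.append(({j: 1.0, jp: -eps, jm: -rlb}, 0.0, np.inf))
            rows.append(({j: 1.0, jp: -rub, jm: eps}, -np.inf, 0.0))
            rows.append(({jp: 1.0, jm: 1.0}, -np.inf, 1.0))
        else:
            # irreversible: eps y+ <= v <= ub y+
            rows.append(({j: 1.0, jp: -eps}, 0.0, np.inf))
            rows.append(({j: 1.0, jp: -rub}, -np.inf, 0.0))

    S = template.S
    A = sparse.lil_matrix((len(rows), n + ny))
    lo = np.empty(len(rows))
    hi = np.empty(len(rows))
    for i, (entries, lb_i, ub_i) in enumerate(rows):
        for jj, val in entries.items():
            A[i, jj] = val
        lo[i], hi[i] = lb_i, ub_i
    Sfull = sparse.hstack([sparse.csr_matrix(S),
                           sparse.csr_matrix((S.shape[0], ny))])
    lbs = np.array([r.lower_bound for r in template.reactions] + [0.0] * ny)
    ubs = np.array([r.upper_bound for r in template.reactions] + [1.0] * ny)
    integrality = np.concatenate([np.zeros(n), np.ones(ny)])
    res = _milp_solve(-obj, [LinearConstraint(Sfull, 0.0, 0.0),
                             LinearConstraint(A.tocsr(), lo, hi)],
                      integrality, Bounds(lbs, ubs), cfg)
    status = "optimal" if res.status == 0 else (
        "timeout" if res.status == 1 and res.x is not None else "error")
    if res.x is None:
        raise TemplateError(f"INIT MILP failed (status {res.status})")
    y = res.x[n:]
    objective = float(-res.fun)
    on: set[str] = set()
    for k, (kind, r) in enumerate(cols):
        if y[k] > 0.5:
            on.add(r)
    drop = {r for r in scored if r not in on}
    sub = template.subnetwork(set(ids) - drop)
    keep = consistent_reactions(sub, cfg.consistency_eps)
    return _finish(template, keep, ral.sample, cfg, status, objective)


# ---------------------------------------------------------------------------
# FASTCORE
# ---------------------------------------------------------------------------

class _FlipNet:
    """Mutable view of a model with sign flips for reversible reactions."""

    def __init__(self, model: MetabolicModel):
        self.ids = model.reaction_ids
        self.idx = {r: j for j, r in enumerate(self.ids)}
        self.S = model.S
        self.lb = np.array([r.lower_bound for r in model.reactions])
        self.ub = np.array([r.upper_bound for r in model.reactions])
        self.sign = np.ones(len(self.ids))
        self.reversible = {r.id for r in model.reactions if r.lower_bound < 0}

    def flip(self, rxns) -> None:
        for r in rxns:
            j = self.idx[r]
            self.sign[j] *= -1.0
            self.S[:, j] *= -1.0
            self.lb[j], self.ub[j] = -self.ub[j], -self.lb[j]

    def bounds(self):
        return list(zip(self.lb, self.ub))


def _lp7(net: _FlipNet, J: list[str], eps: float) -> np.ndarray | None:
    """Maximize the number of reactions in J carrying forward flux >= eps
    (via auxiliary variables z_j <= min(v_j, eps))."""
    n = len(net.ids)
    m = len(J)
    c = np.concatenate([np.zeros(n), -np.ones(m)])
    A_eq = np.hstack([net.S, np.zeros((net.S.shape[0], m))])
    A_ub = np.zeros((m, n + m))
    for k, r in enumerate(J):
        A_ub[k, net.idx[r]] = -1.0
        A_ub[k, n + k] = 1.0
    bounds = net.bounds() + [(0.0, eps)] * m
    res = linprog(c, A_ub=A_ub, b_ub=np.zeros(m), A_eq=A_eq,
                  b_eq=np.zeros(net.S.shape[0]), bounds=bounds, method="highs")
    return res.x[:n] if res.status == 0 else None


def _lp10(net: _FlipNet, K: list[str], P: list[str],
          eps: float) -> np.ndarray | None:
    """Minimize L1 flux through P subject to v_k >= eps for k in K."""
    n = len(net.ids)
    m = len(P)
    c = np.concatenate([np.zeros(n), np.ones(m)])
    A_eq = np.hstack([net.S, np.zeros((net.S.shape[0], m))])
    # |v_p| <= t_p
    A_ub = np.zeros((2 * m, n + m))
    for k, r in enumerate(P):
        j = net.idx[r]
        A_ub[2 * k, j] = 1.0
        A_ub[2 * k, n + k] = -1.0
        A_ub[2 * k + 1, j] = -1.0
        A_ub[2 * k + 1, n + k] = -1.0
    lb = net.lb.copy()
    for r in K:
        lb[net.idx[r]] = max(lb[net.idx[r]], eps)
    bounds = list(zip(lb, net.ub)) + [(0.0, None)] * m
    res = linprog(c, A_ub=A_ub, b_ub=np.zeros(2 * m), A_eq=A_eq,
                  b_eq=np.zeros(net.S.shape[0]), bounds=bounds, method="highs")
    return res.x[:n] if res.status == 0 else None


def _find_sparse_mode(net: _FlipNet, J: list[str], P: list[str],
                      singleton: bool, eps: float,
                      tol: float) -> set[str]:
    if not J:
        return set()
    target = J[:1] if singleton else J
    v = _lp7(net, target, eps)
    if v is None:
        return set()
    K = [r for r in target if v[net.idx[r]] >= 0.99 * eps]
    if not K:
        return set()
    v = _lp10(net, K, P, eps)
    if v is None:
        return set()
    return {r for r in net.ids if abs(v[net.idx[r]]) > tol}


def fastcore(core: set[str], model: MetabolicModel, eps: float = 1e-4,
             tol: float = FLUX_ZERO_TOL) -> set[str]:
    """Compact flux-consistent superset of ``core`` (LP7/LP10 alternation).

    ``model`` must be flux-consistent; inconsistent core members are dropped
    with a warning.
    """
    net = _FlipNet(model)
    all_ids = set(net.ids)
    core = set(core) & all_ids
    irreversible = all_ids - net.reversible
    A: set[str] = set()
    J = sorted(core & irreversible)
    P = sorted(all_ids - core)
    A |= _find_sparse_mode(net, J, P, False, eps, tol)
    missing = set(J) - A
    if missing:
        warnings.warn(f"irreversible core reactions unsupported, dropped: "
                      f"{sorted(missing)}")
        core -= missing
    J = sorted(core - A)
    flipped = False
    singleton = False
    while J:
        P = sorted(set(P) - A)
        supp = _find_sparse_mode(net, J, P, singleton, eps, tol)
        A |= supp
        if set(J) & A:
            J = sorted(set(J) - A)
            flipped = False
            singleton = False
            continue
        target = J[:1] if singleton else J
        JRev = [r for r in target if r in net.reversible]
        if flipped or not JRev:
            if singleton:
                warnings.warn(f"core reaction {J[0]!r} cannot be supported; dropped")
                J = J[1:]
                flipped = False
                singleton = False
            else:
                flipped = False
                singleton = True
        else:
            net.flip(JRev)
            flipped = True
    return A | core


def extract_fastcore(template: MetabolicModel, ral: ReactionActivity,
                     cfg: ExtractionConfig) -> ContextModel:
    """FASTCORE with core = active reactions plus biomass, restricted to the
    flux-consistent part of the template."""
    scores = _ral_of(ral, template, cfg)
    consistent = consistent_reactions(template, cfg.consistency_eps)
    sub = template.subnetwork(consistent)
    core = {r for r in sub.reaction_ids
            if r in scores and scores[r] >= cfg.activity_cutoff}
    core.add(template.biomass_id)
    dropped = {r for r in scores
               if scores[r] >= cfg.activity_cutoff and r not in consistent}
    if dropped:
        warnings.warn(f"core reactions inconsistent in template, dropped: "
                      f"{sorted(dropped)}")
    keep = fastcore(core, sub, cfg.fastcore_eps, cfg.flux_zero_tol)
    return _finish(template, keep, ral.sample, cfg)


# ---------------------------------------------------------------------------
# MBA
# ---------------------------------------------------------------------------

def extract_mba(template: MetabolicModel, ral: ReactionActivity,
                cfg: ExtractionConfig) -> ContextModel:
    """Greedy randomized pruning preserving high/medium-confidence cores.

    For each seeded ordering of non-core reactions, a reaction (plus the
    reactions its removal renders inconsistent) is removed when no
    high-confidence reaction is lost and the medium-confidence loss stays
    within mba_eps times the other losses. Reactions kept in more than half
    of the orderings survive; consistency is then restored.
    """
    scores = _ral_of(ral, template, cfg)
    cutoff = cfg.activity_cutoff
    med = cfg.medium_cutoff
    ids = template.reaction_ids
    CH = {r for r in ids if r in scores and scores[r] >= cutoff}
    CH.add(template.biomass_id)
    CM = {r for r in ids
          if r in scores and med <= scores[r] < cutoff} - CH
    if np.isinf(cfg.mba_eps):  # limit case: medium core carries no protection
        CM = set()
    noncore = sorted(set(ids) - CH - CM)

    rng = np.random.default_rng(cfg.seed)
    keep_count = {r: 0 for r in ids}
    n_runs = max(1, cfg.mba_orderings)
    for _ in range(n_runs):
        order = list(rng.permutation(noncore))
        present = set(ids)
        for r in order:
            if r not in present:
                continue
            trial = present - {r}
            sub = template.subnetwork(trial)
            cons = consistent_reactions(sub, cfg.consistency_eps)
            lost = (set(sub.reaction_ids) - cons) | {r}
            if lost & CH:
                continue
            n_med = len(lost & CM)
            n_other = len(lost - CM)
            if n_med <= cfg.mba_eps * n_other or not CM:
                present -= lost
        for r in present:
            keep_count[r] += 1
    keep = {r for r, k in keep_count.items() if k > 0.5 * n_runs} | CH
    sub = template.subnetwork(keep)
    final = consistent_reactions(sub, cfg.consistency_eps)
    return _finish(template, final | {template.biomass_id}, ral.sample, cfg)


# ---------------------------------------------------------------------------
# mCADRE
# ---------------------------------------------------------------------------

def mcadre_evidence(template: MetabolicModel, ral: ReactionActivity,
                    cfg: ExtractionConfig
                    ) -> tuple[dict[str, float], dict[str, float]]:
    """Expression evidence min(RAL/cutoff, 1) (unscored -> 0) and
    connectivity evidence (mean expression evidence over stoichiometric
    neighbors)."""
    scores = _ral_of(ral, template, cfg)
    e = {r.id: min(scores[r.id] / cfg.activity_cutoff, 1.0)
         if r.id in scores else 0.0 for r in template.reactions}
    by_met: dict[str, set[str]] = {}
    for rxn in template.reactions:
        for m in rxn.metabolites:
            by_met.setdefault(m, set()).add(rxn.id)
    conn = {}
    for rxn in template.reactions:
        neigh = set()
        for m in rxn.metabolites:
            neigh |= by_met[m]
        neigh.discard(rxn.id)
        conn[rxn.id] = (float(np.mean([e[x] for x in sorted(neigh)]))
                        if neigh else 0.0)
    return e, conn


def extract_mcadre(template: MetabolicModel, ral: ReactionActivity,
                   cfg: ExtractionConfig) -> ContextModel:
    """Evidence-ranked pruning; removals that break growth or the core's
    flux consistency are skipped rather than aborting."""
    e, conn = mcadre_evidence(template, ral, cfg)
    core = {r for r, ev in e.items() if ev >= cfg.mcadre_core_cutoff}
    core.add(template.biomass_id)
    noncore = sorted(set(template.reaction_ids) - core,
                     key=lambda r: (e[r], conn[r], r))
    present = set(template.reaction_ids)
    for r in noncore:
        trial = present - {r}
        sub = template.subnetwork(trial)
        if not can_grow(sub, cfg.biomass_lb):
            continue  # the infeasible-removal fix: skip, do not abort
        cons = consistent_reactions(sub, cfg.consistency_eps)
        if (core & trial) - cons:
            continue  # would render part of the core inconsistent
        present = trial
    return _finish(template, present, ral.sample, cfg)


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

_DISPATCH = {
    "GIMME": extract_gimme,
    "iMAT": extract_imat,
    "INIT": extract_init,
    "FASTCORE": extract_fastcore,
    "MBA": extract_mba,
    "mCADRE": extract_mcadre,
}


def extract(template: MetabolicModel, ral: ReactionActivity,
            cfg: ExtractionConfig) -> ContextModel:
    """Run the configured method; record wall time and the functional flag
    (whether the extracted model attains the biomass lower bound)."""
    method = cfg.method
    if method not in _DISPATCH:
        raise ValueError(f"unknown extraction method {method!r}; "
                         f"choose from {METHODS}")
    t0 = time.perf_counter()
    result = _DISPATCH[method](template, ral, cfg)
    result.seconds = time.perf_counter() - t0
    return result
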