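"""Independent brute-force oracles used to validate the optimization code.

Everything here works by exhaustive enumeration plus plain feasibility LPs,
deliberately avoiding the code paths it checks (MILP formulations, the
block consistency algorithm, and the LP7/LP10 alternation).
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable

from cbmex.fba import consistent_reactions_fva, solve_fba
from cbmex.model import MetabolicModel


def constrained_copy(model: MetabolicModel,
                     overrides: dict[str, tuple[float, float]]) -> MetabolicModel:
    out = model.copy()
    for rid, (lb, ub) in overrides.items():
        rxn = out.reaction(rid)
        rxn.lower_bound = lb
        rxn.upper_bound = ub
    return out


def _feasible(model: MetabolicModel) -> bool:
    return solve_fba(model, model.biomass_id, "min").optimal


def _pattern_options(model: MetabolicModel, rid: str, eps: float,
                     kinds: Iterable[str]):
    """Bound overrides realizing each activation state of one reaction."""
    rxn = model.reaction(rid)
    options = []
    for kind in kinds:
        if kind == "+":
            if rxn.upper_bound >= eps:
                options.append(("+", (max(rxn.lower_bound, eps),
                                      rxn.upper_bound)))
        elif kind == "-":
            if rxn.lower_bound <= -eps:
                options.append(("-", (rxn.lower_bound,
                                      min(rxn.upper_bound, -eps))))
        elif kind == "0":
            options.append(("0", (0.0, 0.0)))
        elif kind == "free":
            options.append(("free", (rxn.lower_bound, rxn.upper_bound)))
    return options


def imat_objective_oracle(template: MetabolicModel, RH: list[str],
                          RL: list[str], eps: float) -> int:
    """Best achievable (#RH active + #RL shut) by signed enumeration."""
    per_rxn = ([_pattern_options(template, r, eps, ("+", "-", "free"))
                for r in RH]
               + [_pattern_options(template, r, eps, ("0", "free"))
                  for r in RL])
    best = -1
    for combo in itertools.product(*per_rxn):
        value = sum(1 for kind, _ in combo[:len(RH)] if kind in "+-")
        value += sum(1 for kind, _ in combo[len(RH):] if kind == "0")
        if value <= best:
            continue
        overrides = {r: bounds for r, (_, bounds)
                     in zip(RH + RL, combo)}
        if _feasible(constrained_copy(template, overrides)):
            best = value
    return best


def init_objective_oracle(template: MetabolicModel,
                          weights: dict[str, float], eps: float) -> float:
    """Best achievable sum of weights over activated scored reactions."""
    scored = sorted(weights)
    per_rxn = [_pattern_options(template, r, eps, ("+", "-", "0"))
               for r in scored]
    best = -float("inf")
    for combo in itertools.product(*per_rxn):
        value = sum(weights[r] for r, (kind, _) in zip(scored, combo)
                    if kind in "+-")
        overrides = {r: bounds for r, (_, bounds) in zip(scored, combo)}
        if _feasible(constrained_copy(template, overrides)):
            best = max(best, value)
    return best


def minimal_consistent_supersets(model: MetabolicModel, core: set[str],
                                 eps: float = 1e-4) -> list[set[str]]:
    """All smallest reaction sets containing the core (and biomass) whose
    induced submodel is feasible and fully flux-consistent."""
    core = set(core) | {model.biomass_id}
    noncore = sorted(set(model.reaction_ids) - core)
    for size in range(len(noncore) + 1):
        found = []
        for extra in itertools.combinations(noncore, size):
            keep = core | set(extra)
            sub = model.subnetwork(keep)
            if not _feasible(sub):
                continue
            if consistent_reactions_fva(sub, eps) == set(sub.reaction_ids):
                found.append(set(sub.reaction_ids))
        if found:
            return found
    return []
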