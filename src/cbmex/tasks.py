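"""Metabolic tasks: representation, feasibility, attribution, and scoring.

A metabolic task probes one capability of a model: with all exchange
reactions closed, can the network convert the task's bounded inputs into its
required outputs at steady state? Tasks are the unit of functional
evaluation: binary task scores are *inferred* from expression (mean RAL of
the reactions a task uses on the template, thresholded at 5 ln 2) and
*predicted* from an extracted model (task feasibility), and the normalized
Hamming distance between the two vectors measures functional accuracy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .fba import FLUX_ZERO_TOL, solve_fba
from .model import MetabolicModel, Metabolite, Reaction
from .scoring import ACTIVITY_CUTOFF, ReactionActivity

SYSTEMS = ("amino acid", "nucleotide", "carbohydrate", "energy", "lipid",
           "vitamin", "glycan")

CYTOPLASM = "c"


class TaskValidationError(ValueError):
    """Raised when a task list violates the schema."""


@dataclass(frozen=True)
class TaskMetabolite:
    """One bounded metabolite requirement: uptake (inputs) or production
    (outputs) between lb and ub. Metabolites are referenced by base name;
    the model metabolite id is ``{met}_{compartment}``."""

    met: str
    compartment: str
    lb: float = 0.0
    ub: float = 1000.0

    def model_id(self) -> str:
        return f"{self.met}_{self.compartment}"


@dataclass
class MetabolicTask:
    id: str
    system: str
    inputs: list[TaskMetabolite]
    outputs: list[TaskMetabolite]
    expected: str = "pass"
    description: str = ""
    unresolvable: bool = False

    def validate(self) -> None:
        if self.system not in SYSTEMS:
            raise TaskValidationError(
                f"task {self.id!r}: system {self.system!r} not in {SYSTEMS}")
        if self.expected not in ("pass", "fail"):
            raise TaskValidationError(
                f"task {self.id!r}: expected must be 'pass' or 'fail'")
        if self.expected == "pass" and not self.outputs:
            raise TaskValidationError(
                f"task {self.id!r}: pass-task requires at least one output")
        for entry in self.inputs + self.outputs:
            if entry.lb > entry.ub:
                raise TaskValidationError(
                    f"task {self.id!r}: {entry.met} lb {entry.lb} > ub {entry.ub}")
        seen_in = [e.model_id() for e in self.inputs]
        seen_out = [e.model_id() for e in self.outputs]
        if len(set(seen_in)) != len(seen_in) or len(set(seen_out)) != len(seen_out):
            raise TaskValidationError(f"task {self.id!r}: duplicate metabolite entry")


def load_tasks(path: str | Path) -> list[MetabolicTask]:
    """Load and validate a JSON task list."""
    doc = json.loads(Path(path).read_text())
    tasks = []
    seen: set[str] = set()
    for entry in doc:
        task = MetabolicTask(
            id=entry["id"],
            system=entry["system"],
            inputs=[TaskMetabolite(e["met"], e["compartment"],
                                   float(e.get("lb", 0.0)),
                                   float(e.get("ub", 1000.0)))
                    for e in entry.get("inputs", [])],
            outputs=[TaskMetabolite(e["met"], e["compartment"],
                                    float(e.get("lb", 0.0)),
                                    float(e.get("ub", 1000.0)))
                     for e in entry.get("outputs", [])],
            expected=entry.get("expected", "pass"),
            description=entry.get("description", ""),
        )
        if task.id in seen:
            raise TaskValidationError(f"duplicate task id {task.id!r}")
        seen.add(task.id)
        task.validate()
        tasks.append(task)
    return tasks


def save_tasks(tasks: list[MetabolicTask], path: str | Path) -> None:
    doc = [
        {
            "id": t.id, "system": t.system,
            "inputs": [{"met": e.met, "compartment": e.compartment,
                        "lb": e.lb, "ub": e.ub} for e in t.inputs],
            "outputs": [{"met": e.met, "compartment": e.compartment,
                         "lb": e.lb, "ub": e.ub} for e in t.outputs],
            "expected": t.expected, "description": t.description,
        }
        for t in tasks
    ]
    Path(path).write_text(json.dumps(doc, indent=1))


def adapt_tasks(tasks: list[MetabolicTask],
                model: MetabolicModel) -> list[MetabolicTask]:
    """Remap task metabolites in compartments the model lacks to the
    cytoplasm; flag tasks whose metabolites are absent entirely."""
    compartments = model.compartments
    out = []
    for task in tasks:
        unresolvable = False

        def fix(entry: TaskMetabolite) -> TaskMetabolite:
            nonlocal unresolvable
            if model.has_metabolite(entry.model_id()):
                return entry
            moved = replace(entry, compartment=CYTOPLASM)
            if entry.compartment not in compartments and \
                    model.has_metabolite(moved.model_id()):
                return moved
            unresolvable = True
            return entry

        adapted = replace(
            task,
            inputs=[fix(e) for e in task.inputs],
            outputs=[fix(e) for e in task.outputs],
        )
        adapted.unresolvable = unresolvable
        out.append(adapted)
    return out


def _task_model(model: MetabolicModel,
                task: MetabolicTask) -> MetabolicModel | None:
    """Copy of the model with all exchanges closed, the biomass requirement
    relaxed, and temporary task uptake/demand reactions appended.

    Returns None when a task metabolite is absent (unresolvable).
    """
    work = model.copy()
    for rxn in work.reactions:
        if rxn.is_exchange:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    bio = work.biomass
    bio.lower_bound = min(0.0, bio.lower_bound)
    extra = []
    for entry in task.inputs:
        if not work.has_metabolite(entry.model_id()):
            return None
        extra.append(Reaction(f"TASK_IN_{entry.model_id()}",
                              {entry.model_id(): 1.0},
                              entry.lb, entry.ub))
    for entry in task.outputs:
        if not work.has_metabolite(entry.model_id()):
            return None
        extra.append(Reaction(f"TASK_OUT_{entry.model_id()}",
                              {entry.model_id(): -1.0},
                              entry.lb, entry.ub))
    return MetabolicModel(work.model_id, work.metabolites,
                          work.reactions + extra, work.genes, work.biomass_id)


def check_task(model: MetabolicModel, task: MetabolicTask) -> bool:
    """Feasibility of one task on the model; bounds are never mutated on
    the caller's model (everything happens on a copy)."""
    if task.unresolvable:
        return False
    work = _task_model(model, task)
    if work is None:
        return False
    sol = solve_fba(work, work.biomass_id, "min")  # any objective: feasibility
    return sol.optimal


def filter_tasks(template: MetabolicModel,
                 tasks: list[MetabolicTask]) -> list[MetabolicTask]:
    """Keep exactly the tasks the template can perform."""
    return [t for t in tasks if check_task(template, t)]


def task_reactions(template: MetabolicModel, task: MetabolicTask,
                   tol: float = FLUX_ZERO_TOL) -> set[str]:
    """Gene-associated reactions a task uses on the template.

    Applies the task bounds, minimizes total absolute flux subject to the
    task demands (pFBA with no growth term), and returns the gene-associated
    reactions carrying flux at the optimum.
    """
    work = _task_model(template, task)
    if work is None:
        raise TaskValidationError(f"task {task.id!r} unresolvable on template")
    from scipy.optimize import linprog

    n = len(work.reactions)
    S = work.S
    A_eq = np.hstack([S, -S])
    bounds = ([(max(0.0, r.lower_bound), max(0.0, r.upper_bound))
               for r in work.reactions]
              + [(max(0.0, -r.upper_bound), max(0.0, -r.lower_bound))
                 for r in work.reactions])
    res = linprog(np.ones(2 * n), A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
                  bounds=bounds, method="highs")
    if res.status != 0:
        raise TaskValidationError(f"task {task.id!r} infeasible on template")
    v = res.x[:n] - res.x[n:]
    out = set()
    for j, rxn in enumerate(work.reactions):
        if abs(v[j]) > tol and template.has_reaction(rxn.id) \
                and template.reaction(rxn.id).gpr is not None:
            out.add(rxn.id)
    return out


def task_reaction_map(template: MetabolicModel,
                      tasks: list[MetabolicTask]) -> dict[str, set[str]]:
    """Task id -> gene-associated reactions, computed once on the template
    and reused for all samples."""
    return {t.id: task_reactions(template, t) for t in tasks}


@dataclass
class TaskScoreVector:
    """Binary task scores for one sample or one extracted model."""

    id: str
    scores: dict[str, int]
    source: str  # inferred | predicted
    values: dict[str, float] = field(default_factory=dict)  # continuous (inferred)


def infer_mt_scores(tasks: list[MetabolicTask], ral: ReactionActivity,
                    reaction_map: dict[str, set[str]],
                    cutoff: float = ACTIVITY_CUTOFF) -> TaskScoreVector:
    """Mean RAL over the reactions a task uses, binarized at 5 ln 2."""
    scores: dict[str, int] = {}
    values: dict[str, float] = {}
    for task in tasks:
        rxns = [r for r in sorted(reaction_map.get(task.id, set()))
                if ral.is_scored(r)]
        if not rxns:
            warnings.warn(f"task {task.id!r}: no scored reactions; score 0")
            scores[task.id] = 0
            values[task.id] = 0.0
            continue
        mt = float(np.mean([ral.get(r) for r in rxns]))
        values[task.id] = mt
        scores[task.id] = int(mt >= cutoff)
    return TaskScoreVector(ral.sample, scores, "inferred", values)


def predict_mt_scores(model: MetabolicModel, tasks: list[MetabolicTask],
                      model_id: str | None = None) -> TaskScoreVector:
    """Binary task feasibility of a (context-specific) model."""
    scores = {t.id: int(check_task(model, t)) for t in tasks}
    return TaskScoreVector(model_id or model.model_id, scores, "predicted")


def task_distance(a: TaskScoreVector, b: TaskScoreVector) -> float:
    """Normalized Hamming distance between two binary score vectors."""
    if set(a.scores) != set(b.scores):
        raise ValueError("task score vectors cover different task lists")
    if not a.scores:
        raise ValueError("empty task score vectors")
    keys = sorted(a.scores)
    return float(np.mean([a.scores[k] != b.scores[k] for k in keys]))
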