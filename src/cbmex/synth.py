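"""Synthetic templates, context-structured expression, and task lists.

The generator emulates the study conditions the pipeline targets: a small
metabolic network with redundant pathways and GPRs, an expression matrix
with per-context active/inactive pathway modules on a CPM-like scale under
an unbalanced two-factor (life stage x feed) design, and a task list probing
the pathway modules — all with recorded ground truth.

Network layout: each of ``n_modules`` precursor slots has ``redundancy``
parallel routes of unequal length (so parsimonious optima are unique) from
an exchanged substrate to a biomass precursor; biomass consumes one unit of
every precursor. Each context (a stage/feed combination) activates exactly
one route per slot: even slots switch with life stage, odd slots with the
feed group (fish-oil-like vs vegetable-oil-like). Genes of active routes are
expressed ``effect_size``-fold above base.

Each slot optionally carries three accessory secretion branches (precursor
-> waste exchange) that discriminate between extraction methods the way
real accessory pathways do: a *medium* branch whose gene sits between half
the activity cutoff and the cutoff (protected by MBA's medium-confidence
core only), a *near-threshold* branch just below the cutoff (also inside
mCADRE's evidence core), and an *unannotated* branch with no GPR (kept by
the methods that retain unscored reactions — GIMME, iMAT, INIT — and
dropped by the core-based methods). GIMME additionally keeps every
accessory exchange reaction.

The 90th-percentile threshold rule makes a gene's above-threshold calls
tie-based whenever it is high in more than 10% of samples: at zero noise a
high sample sits exactly at its threshold and scores exactly 5 ln 2, which
the >= activity rule counts as active. The reference design therefore uses
``noise_sd = 0``; lognormal noise is available for robustness experiments,
where active calls become conservative rather than exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MetabolicModel, Metabolite, Reaction
from .gpr import parse_gpr
from .tasks import MetabolicTask, TaskMetabolite, SYSTEMS

STAGES = ("freshwater", "saltwater")
FEEDS = ("FO", "VO", "FO-VO", "VO-FO")
#: feed levels mapped to the route-switching group
FEED_GROUP = {"FO": 0, "FO-VO": 0, "VO": 1, "VO-FO": 1}


@dataclass
class SyntheticDesign:
    """Parameters of the synthetic study.

    Defaults define the standard validation design: 4 precursor modules with
    2 routes each (lengths 2 and 3), effect size 10, zero noise, and an
    unbalanced stage design (4 freshwater vs 3 saltwater samples per feed
    cell, 28 samples total, echoing a 112/96-style imbalance).
    """

    n_modules: int = 4
    module_len: int = 2          # reactions in the shortest route
    redundancy: int = 2          # parallel routes per precursor
    n_samples_freshwater: int = 4  # per feed cell
    n_samples_saltwater: int = 3
    effect_size: float = 10.0
    noise_sd: float = 0.0        # lognormal sigma
    base_expression: float = 50.0  # CPM-like baseline
    side_branches: bool = True   # accessory secretion branches per slot
    side_expression_factor: float = 0.68  # medium level, fraction of base
    near_expression_factor: float = 0.93  # just below threshold, fraction of base
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 1 or self.redundancy < 1 or self.module_len < 1:
            raise ValueError("counts must be positive")
        if self.effect_size <= 1:
            raise ValueError("effect_size must exceed 1")

    def contexts(self) -> list[tuple[str, str]]:
        return [(stage, feed) for stage in STAGES for feed in FEEDS]


@dataclass
class GroundTruth:
    """What the generator planted, keyed by context (stage, feed group)."""

    active_reactions: dict[tuple[str, int], set[str]]
    performable_tasks: dict[tuple[str, int], set[str]]
    route_reactions: dict[tuple[int, int], set[str]]  # (slot, route) -> rxns
    gene_activity: dict[str, set[tuple[str, int]]]    # gene -> active contexts
    accessory_reactions: set[str] = field(default_factory=set)
    gene_base_factor: dict[str, float] = field(default_factory=dict)

    def inactive_reactions(self, ctx: tuple[str, int]) -> set[str]:
        """Module reactions without expression evidence in this context."""
        module = set().union(*self.route_reactions.values())
        return (module - self.active_reactions[ctx]) | self.accessory_reactions

    @staticmethod
    def context_key(stage: str, feed: str) -> tuple[str, int]:
        return stage, FEED_GROUP[feed]


def _route_for(slot: int, stage: str, feed_group: int,
               redundancy: int) -> int:
    choice = (STAGES.index(stage) if slot % 2 == 0 else feed_group)
    return min(choice, redundancy - 1)


def make_toy_model(design: SyntheticDesign
                   ) -> tuple[MetabolicModel, GroundTruth]:
    """Build the synthetic template and its ground truth.

    Deterministic given the design (the topology has no random element).
    """
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    genes: list[str] = []
    route_reactions: dict[tuple[int, int], set[str]] = {}
    gene_activity: dict[str, set[tuple[str, int]]] = {}
    contexts = [(stage, g) for stage in STAGES for g in (0, 1)]

    always = [(s, g) for s, g in contexts]
    biomass_sto: dict[str, float] = {}
    for s in range(design.n_modules):
        sub_e, sub_c, prec = f"S{s}_e", f"S{s}_c", f"P{s}_c"
        mets += [Metabolite(sub_e, "e"), Metabolite(sub_c, "c"),
                 Metabolite(prec, "c")]
        rxns.append(Reaction(f"EX_S{s}", {sub_e: -1.0}, -1000.0, 1000.0))
        hk = f"hk{s}"
        genes.append(hk)
        gene_activity[hk] = set(always)
        rxns.append(Reaction(f"T_S{s}", {sub_e: -1.0, sub_c: 1.0},
                             0.0, 1000.0, parse_gpr(hk)))
        for r in range(design.redundancy):
            length = design.module_len + r
            chain = [sub_c] + [f"I{s}_{r}_{j}_c" for j in range(1, length)] + [prec]
            mets += [Metabolite(m, "c") for m in chain[1:-1]]
            route_reactions[(s, r)] = set()
            active_in = {(stage, g) for stage, g in contexts
                         if _route_for(s, stage, g, design.redundancy) == r}
            for j in range(length):
                rid = f"M{s}_{r}_{j}"
                if j == 0:
                    # first step gets an isoenzyme pair for GPR variety
                    ga, gb = f"g{s}_{r}_{j}a", f"g{s}_{r}_{j}b"
                    genes += [ga, gb]
                    gene_activity[ga] = set(active_in)
                    gene_activity[gb] = set(active_in)
                    gpr = parse_gpr(f"{ga} or {gb}")
                else:
                    g = f"g{s}_{r}_{j}"
                    genes.append(g)
                    gene_activity[g] = set(active_in)
                    gpr = parse_gpr(g)
                rxns.append(Reaction(rid, {chain[j]: -1.0, chain[j + 1]: 1.0},
                                     0.0, 1000.0, gpr))
                route_reactions[(s, r)].add(rid)
        biomass_sto[prec] = -1.0
    accessory: set[str] = set()
    base_factor: dict[str, float] = {}
    if design.side_branches:
        branch_specs = [("B", "W", "sb", design.side_expression_factor),
                        ("N", "V", "nb", design.near_expression_factor),
                        ("U", "X", None, 1.0)]  # U: no gene association
        for s in range(design.n_modules):
            for rpre, mpre, gpre, factor in branch_specs:
                waste = f"{mpre}{s}_e"
                mets.append(Metabolite(waste, "e"))
                gpr = None
                if gpre is not None:
                    g = f"{gpre}{s}"
                    genes.append(g)
                    gene_activity[g] = set()  # constant sub-threshold level
                    base_factor[g] = factor
                    gpr = parse_gpr(g)
                    accessory.add(f"{rpre}{s}")
                rxns.append(Reaction(f"{rpre}{s}",
                                     {f"P{s}_c": -1.0, waste: 1.0},
                                     0.0, 1000.0, gpr))
                rxns.append(Reaction(f"EX_{mpre}{s}", {waste: -1.0},
                                     0.0, 1000.0))
    rxns.append(Reaction("BIOMASS", biomass_sto, 0.0, 1000.0))

    model = MetabolicModel("synthetic", mets, rxns, genes, "BIOMASS")
    model.validate()

    active: dict[tuple[str, int], set[str]] = {}
    scaffold = {rid for s in range(design.n_modules)
                for rid in (f"EX_S{s}", f"T_S{s}")} | {"BIOMASS"}
    for stage, g in contexts:
        act = set(scaffold)
        for s in range(design.n_modules):
            act |= route_reactions[(s, _route_for(s, stage, g,
                                                  design.redundancy))]
        active[(stage, g)] = act
    truth = GroundTruth(active, {}, route_reactions, gene_activity,
                        accessory, base_factor)
    _fill_performable(design, truth)
    return model, truth


def _task_support(design: SyntheticDesign, truth: GroundTruth,
                  task_id: str) -> set[tuple[int, int]]:
    """(slot, route) pairs whose genes a task's template attribution uses.

    Composite tasks resolve to the shortest (route 0) pathways because
    parsimonious flux attribution picks the shortest route.
    """
    if task_id.startswith("TASK_ROUTE_"):
        s, r = map(int, task_id.split("_")[2:])
        return {(s, r)}
    if task_id.startswith("TASK_SLOT_"):
        s = int(task_id.split("_")[2])
        return {(s, 0)}
    return {(s, 0) for s in range(design.n_modules)}  # biomass composite


def _fill_performable(design: SyntheticDesign, truth: GroundTruth) -> None:
    task_ids = ([f"TASK_ROUTE_{s}_{r}" for s in range(design.n_modules)
                 for r in range(design.redundancy)]
                + [f"TASK_SLOT_{s}" for s in range(design.n_modules)]
                + ["TASK_BIOMASS"])
    for ctx, act in truth.active_reactions.items():
        performable = set()
        for tid in task_ids:
            needed = set().union(*(truth.route_reactions[p]
                                   for p in _task_support(design, truth, tid)))
            if needed <= act:
                performable.add(tid)
        truth.performable_tasks[ctx] = performable


_TASK_SYSTEM = dict(zip(range(len(SYSTEMS)), SYSTEMS))


def make_task_list(model: MetabolicModel, truth: GroundTruth,
                   design: SyntheticDesign) -> list[MetabolicTask]:
    """Task list probing the planted modules.

    One pass-task per route (substrate in, last route-specific intermediate
    out), one per slot (substrate in, precursor out), and a composite
    biomass-precursor task. Ground-truth performable sets per context are
    recorded in ``truth`` by :func:`make_toy_model` using parsimonious
    attribution (composite tasks resolve to the shortest routes).
    """
    tasks: list[MetabolicTask] = []
    k = 0
    for s in range(design.n_modules):
        for r in range(design.redundancy):
            length = design.module_len + r
            out_met = (f"I{s}_{r}_{length - 1}" if length > 1 else f"P{s}")
            tasks.append(MetabolicTask(
                id=f"TASK_ROUTE_{s}_{r}",
                system=_TASK_SYSTEM[k % len(SYSTEMS)],
                inputs=[TaskMetabolite(f"S{s}", "e", 0.0, 1000.0)],
                outputs=[TaskMetabolite(out_met, "c", 1.0, 1000.0)],
                description=f"module {s} via route {r}"))
            k += 1
        tasks.append(MetabolicTask(
            id=f"TASK_SLOT_{s}", system=_TASK_SYSTEM[k % len(SYSTEMS)],
            inputs=[TaskMetabolite(f"S{s}", "e", 0.0, 1000.0)],
            outputs=[TaskMetabolite(f"P{s}", "c", 1.0, 1000.0)],
            description=f"precursor {s} from substrate {s}"))
        k += 1
    tasks.append(MetabolicTask(
        id="TASK_BIOMASS", system="energy",
        inputs=[TaskMetabolite(f"S{s}", "e", 0.0, 1000.0)
                for s in range(design.n_modules)],
        outputs=[TaskMetabolite(f"P{s}", "c", 1.0, 1000.0)
                 for s in range(design.n_modules)],
        description="all biomass precursors from all substrates"))
    for t in tasks:
        t.validate()
    return tasks


def simulate_expression(model: MetabolicModel, truth: GroundTruth,
                        design: SyntheticDesign,
                        seed: int | None = None):
    """Context-structured expression matrix plus sample metadata.

    Gene g in sample with context c: ``base * effect^active(g,c) *
    LogNormal(0, noise_sd)``. Reproducible given the seed; sample order is
    stage-major then feed.
    """
    from .scoring import ExpressionMatrix

    rng = np.random.default_rng(design.seed if seed is None else seed)
    samples, stages, feeds = [], [], []
    for stage in STAGES:
        per_cell = (design.n_samples_freshwater if stage == "freshwater"
                    else design.n_samples_saltwater)
        for feed in FEEDS:
            for i in range(per_cell):
                samples.append(f"{stage[:2].upper()}_{feed}_{i}")
                stages.append(stage)
                feeds.append(feed)
    genes = list(model.genes)
    values = np.empty((len(genes), len(samples)))
    for j, (stage, feed) in enumerate(zip(stages, feeds)):
        ctx = GroundTruth.context_key(stage, feed)
        for i, g in enumerate(genes):
            on = ctx in truth.gene_activity.get(g, set())
            x = (design.base_expression * truth.gene_base_factor.get(g, 1.0)
                 * (design.effect_size if on else 1.0))
            if design.noise_sd > 0:
                x *= float(np.exp(rng.normal(0.0, design.noise_sd)))
            values[i, j] = x
    meta = pd.DataFrame({"life_stage": stages, "feed": feeds},
                        index=pd.Index(samples, name="sample"))
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                        columns=samples)
    return ExpressionMatrix(expr, meta)


# ---------------------------------------------------------------------------
# ToyNet-A: the fixed hand-analysable fixture
# ---------------------------------------------------------------------------

def toynet_a() -> MetabolicModel:
    """Fixed 9-reaction, 6-metabolite, 6-gene network used in examples.

    Substrate A is taken up (limited to 10) and converted to biomass
    precursor D by two redundant routes: route 1 (R1, R2; two steps) and
    route 2 (R3, R4, R5; three steps). BIOMASS drains D; EX_D is an unused
    alternative drain. Hand-derivable LP facts: max growth 10, parsimonious
    total flux 50 (route 1), and 60 when route 1 is knocked out.
    """
    mets = [Metabolite("A_e", "e"), Metabolite("A_c", "c"),
            Metabolite("B_c", "c"), Metabolite("C_c", "c"),
            Metabolite("C2_c", "c"), Metabolite("D_c", "c")]
    rxns = [
        Reaction("EX_A", {"A_e": -1.0}, -10.0, 0.0),
        Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0,
                 parse_gpr("g1")),
        Reaction("R1", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0,
                 parse_gpr("g2")),
        Reaction("R2", {"B_c": -1.0, "D_c": 1.0}, 0.0, 1000.0,
                 parse_gpr("g3")),
        Reaction("R3", {"A_c": -1.0, "C_c": 1.0}, 0.0, 1000.0,
                 parse_gpr("g4")),
        Reaction("R4", {"C_c": -1.0, "C2_c": 1.0}, 0.0, 1000.0,
                 parse_gpr("g5")),
        Reaction("R5", {"C2_c": -1.0, "D_c": 1.0}, 0.0, 1000.0,
                 parse_gpr("g6")),
        Reaction("BIOMASS", {"D_c": -1.0}, 0.0, 1000.0),
        Reaction("EX_D", {"D_c": -1.0}, 0.0, 1000.0),
    ]
    model = MetabolicModel("ToyNet-A", mets, rxns,
                           [f"g{i}" for i in range(1, 7)], "BIOMASS")
    model.validate()
    return model


def toynet_ral(active_route: int = 1, sample: str = "toy",
               high: float | None = None, low: float = 0.5):
    """Reaction activities marking one ToyNet-A route active.

    ``high`` defaults to just above the activity cutoff; transport T_A is
    always active.
    """
    from .scoring import ACTIVITY_CUTOFF, ReactionActivity

    hi = ACTIVITY_CUTOFF if high is None else high
    route1, route2 = ("R1", "R2"), ("R3", "R4", "R5")
    act, inact = (route1, route2) if active_route == 1 else (route2, route1)
    ral = {"T_A": hi}
    ral.update({r: hi for r in act})
    ral.update({r: low for r in inact})
    return ReactionActivity(sample, ral)
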