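"""In-memory representation of a constraint-based metabolic model.

The model is the standard stoichiometric object: a metabolite-by-reaction
matrix S, per-reaction flux bounds, boolean GPR rules, and a designated
biomass (objective) reaction. Steady-state flux vectors v satisfy
S v = 0 with lb <= v <= ub.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gpr import GprRule


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = "c"


@dataclass
class Reaction:
    """A reaction: stoichiometry (metabolite id -> coefficient), bounds, GPR.

    Flux units are mmol·gDW⁻¹·h⁻¹ in genome-scale models and dimensionless
    in toy networks. Negative exchange flux is uptake, positive is secretion.
    """

    id: str
    metabolites: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: GprRule | None = None
    subsystem: str = ""

    @property
    def is_exchange(self) -> bool:
        """True iff exactly one metabolite has a nonzero coefficient."""
        return sum(1 for c in self.metabolites.values() if c != 0.0) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0

    def genes(self) -> frozenset[str]:
        return self.gpr.genes() if self.gpr is not None else frozenset()

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.metabolites), self.lower_bound,
                        self.upper_bound, self.gpr, self.subsystem)


@dataclass
class MetabolicModel:
    model_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str]
    biomass_id: str

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookups ---------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites}

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    @property
    def biomass(self) -> Reaction:
        return self.reaction(self.biomass_id)

    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_exchange]

    # -- stoichiometry ---------------------------------------------------
    @property
    def S(self) -> np.ndarray:
        """Dense metabolite x reaction stoichiometric matrix."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.metabolites.items():
                S[self._met_index[met_id], j] = coef
        return S

    # -- validation ------------------------------------------------------
    def validate(self, tolerant: bool = True) -> list[str]:
        """Check structural invariants; return a plain-text report.

        With ``tolerant=True`` (the default reader behaviour), genes that
        appear in GPRs but not in the gene list are appended with a warning
        instead of failing validation.
        """
        report: list[str] = []
        seen_rxn: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen_rxn:
                raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
            seen_rxn.add(rxn.id)
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                    f"upper bound {rxn.upper_bound}")
            for met_id in rxn.metabolites:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}")
        seen_met: set[str] = set()
        for met in self.metabolites:
            if met.id in seen_met:
                raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
            seen_met.add(met.id)
        if self.biomass_id not in self._rxn_index:
            raise ModelValidationError(f"biomass reaction {self.biomass_id!r} not in model")
        gene_set = set(self.genes)
        missing = sorted(set().union(*(r.genes() for r in self.reactions)) - gene_set
                         if self.reactions else set())
        if missing:
            msg = f"genes referenced by GPRs but absent from gene list: {missing}"
            if not tolerant:
                raise ModelValidationError(msg)
            warnings.warn(msg)
            self.genes = self.genes + missing
            report.append(f"added {len(missing)} GPR-only genes to gene list")
        report.append(f"model {self.model_id}: {len(self.genes)} genes, "
                      f"{len(self.reactions)} reactions, {len(self.metabolites)} metabolites")
        return report

    # -- derived models --------------------------------------------------
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(self.model_id, list(self.metabolites),
                              [r.copy() for r in self.reactions],
                              list(self.genes), self.biomass_id)

    def subnetwork(self, keep: set[str] | frozenset[str],
                   model_id: str | None = None) -> "MetabolicModel":
        """Induced submodel on ``keep``; orphan metabolites/genes are pruned.

        The biomass reaction is always retained.
        """
        keep = set(keep) | {self.biomass_id}
        reactions = [r.copy() for r in self.reactions if r.id in keep]
        used_mets = set()
        used_genes: set[str] = set()
        for rxn in reactions:
            used_mets.update(m for m, c in rxn.metabolites.items() if c != 0.0)
            used_genes.update(rxn.genes())
        metabolites = [m for m in self.metabolites if m.id in used_mets]
        genes = [g for g in self.genes if g in used_genes]
        return MetabolicModel(model_id or self.model_id, metabolites,
                              reactions, genes, self.biomass_id)

    def knock_out(self, rxn_ids: set[str]) -> "MetabolicModel":
        """Copy with the given reactions' bounds closed to zero."""
        out = self.copy()
        for rid in rxn_ids:
            rxn = out.reaction(rid)
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
        return out
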