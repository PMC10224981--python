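"""Reading, writing and preparing constraint-based models.

Two dialects are supported: a COBRA-style JSON schema (hand-writable, used
for toy fixtures and extracted submodels) and SBML Level 3 with flux bounds,
handled through cobrapy/libSBML. The JSON schema mirrors the common COBRA
JSON layout: reactions carry ``id``, ``metabolites``, bounds,
``gene_reaction_rule`` and an ``objective_coefficient`` marking biomass.
"""

from __future__ import annotations

import json
from pathlib import Path

from .gpr import parse_gpr
from .model import MetabolicModel, Metabolite, ModelValidationError, Reaction

OPEN_BOUND = 1000.0


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed."""


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ModelParseError(f"cannot infer model dialect from {path.name!r}; "
                          "pass dialect='json' or 'sbml'")


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_from_dict(doc: dict) -> MetabolicModel:
    try:
        metabolites = [Metabolite(m["id"], m.get("compartment", "c"))
                       for m in doc["metabolites"]]
        reactions = []
        biomass_id = doc.get("biomass")
        for r in doc["reactions"]:
            rxn = Reaction(
                id=r["id"],
                metabolites={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=float(r.get("lower_bound", -OPEN_BOUND)),
                upper_bound=float(r.get("upper_bound", OPEN_BOUND)),
                gpr=parse_gpr(r.get("gene_reaction_rule", "")),
                subsystem=r.get("subsystem", ""),
            )
            reactions.append(rxn)
            if biomass_id is None and float(r.get("objective_coefficient", 0.0)) != 0.0:
                biomass_id = r["id"]
        genes = [g["id"] if isinstance(g, dict) else str(g)
                 for g in doc.get("genes", [])]
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelParseError(f"malformed model document: {exc}") from exc
    if biomass_id is None:
        raise ModelValidationError("no biomass reaction: set 'biomass' or an "
                                   "objective_coefficient on one reaction")
    model = MetabolicModel(doc.get("id", "model"), metabolites, reactions,
                           genes, biomass_id)
    model.validate()
    return model


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.model_id,
        "biomass": model.biomass_id,
        "metabolites": [{"id": m.id, "compartment": m.compartment}
                        for m in model.metabolites],
        "reactions": [
            {
                "id": r.id,
                "metabolites": r.metabolites,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string() if r.gpr else "",
                "subsystem": r.subsystem,
                "objective_coefficient": 1.0 if r.id == model.biomass_id else 0.0,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in model.genes],
    }


# ---------------------------------------------------------------------------
# SBML dialect (via cobrapy)
# ---------------------------------------------------------------------------

def _from_cobra(cmodel) -> MetabolicModel:
    import cobra

    metabolites = [Metabolite(m.id, m.compartment or "c")
                   for m in cmodel.metabolites]
    biomass_id = None
    try:
        expr = cmodel.objective.expression
        for rxn in cmodel.reactions:
            coef = expr.coeff(rxn.forward_variable)
            if coef != 0:
                biomass_id = rxn.id
                break
    except Exception:
        biomass_id = None
    reactions = []
    for rxn in cmodel.reactions:
        reactions.append(Reaction(
            id=rxn.id,
            metabolites={m.id: float(c) for m, c in rxn.metabolites.items()},
            lower_bound=float(rxn.lower_bound),
            upper_bound=float(rxn.upper_bound),
            gpr=parse_gpr(rxn.gene_reaction_rule),
            subsystem=rxn.subsystem or "",
        ))
    genes = [g.id for g in cmodel.genes]
    if biomass_id is None:
        raise ModelValidationError(f"model {cmodel.id!r} has no objective reaction")
    model = MetabolicModel(cmodel.id or "model", metabolites, reactions,
                           genes, biomass_id)
    model.validate()
    return model


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy Model (used for SBML output and cross-checks)."""
    import cobra

    cmodel = cobra.Model(model.model_id)
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment)
            for m in model.metabolites}
    for rxn in model.reactions:
        crxn = cobra.Reaction(rxn.id, lower_bound=rxn.lower_bound,
                              upper_bound=rxn.upper_bound)
        crxn.subsystem = rxn.subsystem
        cmodel.add_reactions([crxn])
        crxn.add_metabolites({mets[m]: c for m, c in rxn.metabolites.items()})
        if rxn.gpr is not None:
            crxn.gene_reaction_rule = rxn.gpr.to_string()
    cmodel.objective = model.biomass_id
    return cmodel


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_model(path: str | Path, dialect: str | None = None) -> MetabolicModel:
    """Load and validate a model from JSON or SBML."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path.name}: invalid JSON: {exc}") from exc
        return _model_from_dict(doc)
    if dialect == "sbml":
        from cobra.io import read_sbml_model
        return _from_cobra(read_sbml_model(str(path)))
    raise ModelParseError(f"unknown model dialect {dialect!r}")


def write_model(model: MetabolicModel, path: str | Path,
                dialect: str | None = None) -> Path:
    """Serialize a model; ``read_model`` round-trips it up to element order."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1))
    elif dialect == "sbml":
        from cobra.io import write_sbml_model
        write_sbml_model(to_cobra(model), str(path))
    else:
        raise ModelParseError(f"unknown model dialect {dialect!r}")
    return path


def open_exchanges(model: MetabolicModel,
                   bound: float = OPEN_BOUND) -> MetabolicModel:
    """Copy with every exchange reaction opened to [-bound, +bound].

    This allows uptake and secretion of all boundary metabolites, the
    standard preparation before extracting context-specific models.
    """
    out = model.copy()
    for rxn in out.reactions:
        if rxn.is_exchange:
            rxn.lower_bound = -bound
            rxn.upper_bound = bound
    return out
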