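import math

import pytest

from cbmex import ExtractionConfig, extract, prepare_template, toynet_ral
from cbmex.extraction import (TemplateError, extract_fastcore, extract_gimme,
                              extract_imat, extract_init, extract_mba,
                              extract_mcadre, fastcore, init_weights)
from cbmex.fba import (consistent_reactions, consistent_reactions_fva,
                       max_growth, solve_fba)
from cbmex.scoring import ACTIVITY_CUTOFF, ReactionActivity

from oracles import (imat_objective_oracle, init_objective_oracle,
                     minimal_consistent_supersets)

HIGH = ACTIVITY_CUTOFF + 0.5
LOW = 0.5
ROUTE1 = {"R1", "R2"}
ROUTE2 = {"R3", "R4", "R5"}


def _ral(active=ROUTE1, inactive=ROUTE2, sample="s"):
    ral = {"T_A": HIGH}
    ral.update({r: HIGH for r in active})
    ral.update({r: LOW for r in inactive})
    return ReactionActivity(sample, ral)


@pytest.fixture(scope="module")
def template(toy_template):
    return toy_template


class TestPrepareTemplate:
    def test_bounds_and_biomass(self, toynet):
        t = prepare_template(toynet)
        assert t.reaction("EX_A").lower_bound == -1000.0
        assert t.reaction("R1").upper_bound == 1000.0
        assert t.reaction("R1").lower_bound == 0.0  # irreversible stays so
        assert t.biomass.lower_bound == 1.0

    def test_idempotent(self, toynet):
        once = prepare_template(toynet)
        twice = prepare_template(once)
        for rxn in once.reactions:
            other = twice.reaction(rxn.id)
            assert (rxn.lower_bound, rxn.upper_bound) == \
                   (other.lower_bound, other.upper_bound)

    def test_non_growing_template_rejected(self, toynet):
        # both routes cut and the alternative drain gone: no D production
        keep = set(toynet.reaction_ids) - {"R2", "R5", "EX_D"}
        with pytest.raises(TemplateError):
            prepare_template(toynet.subnetwork(keep))


class TestGimme:
    def test_inactive_route_removed(self, template):
        ctx = extract_gimme(template, _ral(), ExtractionConfig(method="GIMME"))
        assert ctx.reaction_ids == {"EX_A", "T_A", "R1", "R2", "BIOMASS", "EX_D"}

    def test_all_active_keeps_everything(self, template):
        ral = ReactionActivity("s", {r.id: HIGH for r in template.reactions
                                     if r.gpr is not None})
        ctx = extract_gimme(template, ral, ExtractionConfig(method="GIMME"))
        assert ctx.reaction_ids == set(template.reaction_ids)

    def test_exchanges_always_retained(self, template):
        ctx = extract_gimme(template, _ral(active=ROUTE2, inactive=ROUTE1),
                            ExtractionConfig(method="GIMME"))
        exchanges = {r.id for r in template.reactions if r.is_exchange}
        assert exchanges <= ctx.reaction_ids

    def test_growth_requirement_met(self, template):
        cfg = ExtractionConfig(method="GIMME")
        ctx = extract_gimme(template, _ral(), cfg)
        mu_template = max_growth(template)
        assert max_growth(ctx.model) >= 0.9 * mu_template - 1e-6


class TestImat:
    @pytest.mark.parametrize("active,inactive", [
        (ROUTE1, ROUTE2), (ROUTE2, ROUTE1)])
    def test_objective_matches_enumeration(self, template, active, inactive):
        cfg = ExtractionConfig(method="iMAT")
        ral = _ral(active, inactive)
        ctx = extract_imat(template, ral, cfg)
        RH = sorted(active | {"T_A", "BIOMASS"})
        RL = sorted(inactive)
        oracle = imat_objective_oracle(template, RH, RL, cfg.imat_eps)
        assert ctx.objective_value == pytest.approx(oracle)
        assert not (inactive & ctx.reaction_ids)

    def test_all_high_keeps_consistent_model(self, template):
        ral = ReactionActivity("s", {r.id: HIGH for r in template.reactions
                                     if r.gpr is not None})
        ctx = extract_imat(template, ral, ExtractionConfig(method="iMAT"))
        assert ctx.reaction_ids == consistent_reactions(template)

    def test_blocked_high_reaction_forgone(self, toynet):
        """A dead-end high-activity reaction cannot be activated; the MILP
        forgoes it and still returns a model matching the oracle."""
        from cbmex.model import MetabolicModel, Metabolite, Reaction
        from cbmex.gpr import parse_gpr
        variant = toynet.copy()
        variant.metabolites.append(Metabolite("dead_c", "c"))
        variant.reactions.append(
            Reaction("R_DEAD", {"A_c": -1.0, "dead_c": 1.0}, 0.0, 1000.0,
                     parse_gpr("g7")))
        variant = MetabolicModel(variant.model_id, variant.metabolites,
                                 variant.reactions, variant.genes + ["g7"],
                                 variant.biomass_id)
        t = prepare_template(variant)
        cfg = ExtractionConfig(method="iMAT")
        ral_map = dict(_ral().ral)
        ral_map["R_DEAD"] = HIGH
        ral = ReactionActivity("s", ral_map)
        ctx = extract_imat(t, ral, cfg)
        oracle = imat_objective_oracle(
            t, sorted(ROUTE1 | {"T_A", "BIOMASS", "R_DEAD"}),
            sorted(ROUTE2), cfg.imat_eps)
        assert ctx.objective_value == pytest.approx(oracle)
        assert "R_DEAD" not in ctx.reaction_ids


class TestInit:
    def test_objective_matches_enumeration(self, template):
        cfg = ExtractionConfig(method="INIT")
        ral = _ral()
        ctx = extract_init(template, ral, cfg)
        weights = init_weights(ral, template, cfg)
        oracle = init_objective_oracle(template, weights, cfg.imat_eps)
        assert ctx.objective_value == pytest.approx(oracle)

    def test_negative_weight_route_dropped(self, template):
        ctx = extract_init(template, _ral(), ExtractionConfig(method="INIT"))
        assert not (ROUTE2 & ctx.reaction_ids)
        assert ROUTE1 <= ctx.reaction_ids  # positive weights retained

    def test_all_positive_weights_keep_consistent_model(self, template):
        ral = ReactionActivity("s", {r.id: HIGH for r in template.reactions
                                     if r.gpr is not None})
        ctx = extract_init(template, ral, ExtractionConfig(method="INIT"))
        assert ctx.reaction_ids == consistent_reactions(template)


class TestFastcore:
    def test_minimal_support_matches_exhaustive_search(self, template):
        # EX_D closed so the minimal drain is unique
        fixture = template.knock_out({"EX_D"})
        sub = fixture.subnetwork(consistent_reactions(fixture))
        result = fastcore({"R1", "BIOMASS"}, sub)
        minima = minimal_consistent_supersets(sub, {"R1"})
        assert len(minima) == 1
        assert result == minima[0]
        assert result == {"EX_A", "T_A", "R1", "R2", "BIOMASS"}

    def test_core_all_consistent_is_identity(self, template):
        consistent = consistent_reactions(template)
        sub = template.subnetwork(consistent)
        assert fastcore(set(consistent), sub) == consistent

    def test_output_consistent_and_contains_core(self, template):
        cfg = ExtractionConfig(method="FASTCORE")
        ral = _ral()
        ctx = extract_fastcore(template, ral, cfg)
        kept = ctx.reaction_ids
        core = {r for r, s in ral.ral.items() if s >= cfg.activity_cutoff}
        assert core | {"BIOMASS"} <= kept
        assert consistent_reactions_fva(ctx.model) == kept

    def test_all_active_returns_full_consistent_template(self, template):
        ral = ReactionActivity("s", {r.id: HIGH for r in template.reactions
                                     if r.gpr is not None})
        ctx = extract_fastcore(template, ral, ExtractionConfig(method="FASTCORE"))
        assert ctx.reaction_ids == consistent_reactions(template)


class TestMba:
    def test_high_core_route_never_removed(self, template):
        cfg = ExtractionConfig(method="MBA", seed=11)
        ctx = extract_mba(template, _ral(), cfg)
        assert ROUTE1 | {"T_A", "BIOMASS"} <= ctx.reaction_ids
        assert not (ROUTE2 & ctx.reaction_ids)

    def test_infinite_eps_ignores_medium_core(self, template):
        # medium-confidence reactions lose protection when eps is infinite
        ral = ReactionActivity("s", {**{r: HIGH for r in ROUTE1 | {"T_A"}},
                                     **{r: 0.6 * ACTIVITY_CUTOFF
                                        for r in ROUTE2}})
        keep = extract_mba(template, ral,
                           ExtractionConfig(method="MBA", mba_eps=float("inf"),
                                            seed=3)).reaction_ids
        assert not (ROUTE2 & keep)
        protected = extract_mba(template, ral,
                                ExtractionConfig(method="MBA", seed=3)).reaction_ids
        assert ROUTE2 <= protected  # default eps protects the medium core

    def test_same_seed_same_model(self, template):
        cfg = ExtractionConfig(method="MBA", seed=5, mba_orderings=3)
        a = extract_mba(template, _ral(), cfg)
        b = extract_mba(template, _ral(), cfg)
        assert a.reaction_ids == b.reaction_ids


class TestMcadre:
    def test_zero_evidence_route_pruned(self, template):
        ral = ReactionActivity("s", {**{r: HIGH for r in ROUTE1 | {"T_A"}},
                                     **{r: 0.0 for r in ROUTE2}})
        ctx = extract_mcadre(template, ral, ExtractionConfig(method="mCADRE"))
        assert not (ROUTE2 & ctx.reaction_ids)
        assert max_growth(ctx.model) >= 1.0 - 1e-6

    def test_growth_breaking_removal_skipped(self, template):
        # every gene reaction zero evidence: chain would be removed reaction
        # by reaction, but removals that break growth must be skipped
        ral = ReactionActivity("s", {r.id: 0.0 for r in template.reactions
                                     if r.gpr is not None})
        ctx = extract_mcadre(template, ral, ExtractionConfig(method="mCADRE"))
        assert ctx.functional
        assert max_growth(ctx.model) >= 1.0 - 1e-6

    def test_all_core_is_identity(self, template):
        ral = ReactionActivity("s", {r.id: HIGH for r in template.reactions})
        ctx = extract_mcadre(template, ral,
                             ExtractionConfig(method="mCADRE"))
        assert ctx.reaction_ids == set(template.reaction_ids)


class TestDispatcher:
    @pytest.mark.parametrize("method", ["GIMME", "iMAT", "INIT", "FASTCORE",
                                        "MBA", "mCADRE"])
    def test_submodel_biomass_and_determinism(self, template, method):
        cfg = ExtractionConfig(method=method, seed=2)
        a = extract(template, _ral(), cfg)
        b = extract(template, _ral(), cfg)
        assert a.reaction_ids <= set(template.reaction_ids)
        assert "BIOMASS" in a.reaction_ids
        assert a.reaction_ids == b.reaction_ids  # determinism
        assert a.functional

    def test_metabolites_pruned_to_retained_reactions(self, template):
        ctx = extract(template, _ral(), ExtractionConfig(method="iMAT"))
        touched = set()
        for rxn in ctx.model.reactions:
            touched |= set(rxn.metabolites)
        assert set(ctx.model.metabolite_ids) == touched

    def test_genes_pruned_to_retained_gprs(self, template):
        ctx = extract(template, _ral(), ExtractionConfig(method="INIT"))
        referenced = set()
        for rxn in ctx.model.reactions:
            referenced |= rxn.genes()
        assert set(ctx.model.genes) == referenced

    def test_unknown_method_rejected(self, template):
        cfg = ExtractionConfig(method="GIMME")
        cfg.method = "NOPE"
        with pytest.raises(ValueError, match="NOPE"):
            extract(template, _ral(), cfg)
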