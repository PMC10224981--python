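import itertools
import json

import numpy as np
import pytest

from cbmex import ExtractionConfig, extract, toynet_ral
from cbmex.scoring import ACTIVITY_CUTOFF, ReactionActivity
from cbmex.tasks import (MetabolicTask, TaskMetabolite, TaskScoreVector,
                         TaskValidationError, adapt_tasks, check_task,
                         filter_tasks, infer_mt_scores, load_tasks,
                         predict_mt_scores, save_tasks, task_distance,
                         task_reactions)


def _task(tid="T1", system="energy", inputs=(), outputs=(), **kw):
    return MetabolicTask(tid, system,
                         [TaskMetabolite(*i) for i in inputs],
                         [TaskMetabolite(*o) for o in outputs], **kw)

A_TO_D = dict(inputs=[("A", "e", 0.0, 1000.0)],
              outputs=[("D", "c", 1.0, 1000.0)])


class TestLoadAndValidate:
    def test_round_trip_toy_list(self, tmp_path, synthetic_study):
        _, _, _, tasks = synthetic_study
        path = tmp_path / "tasks.json"
        save_tasks(tasks, path)
        loaded = load_tasks(path)
        assert [t.id for t in loaded] == [t.id for t in tasks]
        assert loaded[0].inputs == tasks[0].inputs

    def test_duplicate_ids_rejected(self, tmp_path):
        doc = [{"id": "T", "system": "energy",
                "inputs": [], "outputs": [{"met": "D", "compartment": "c",
                                           "lb": 1.0, "ub": 10.0}]}] * 2
        path = tmp_path / "dup.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(TaskValidationError, match="duplicate"):
            load_tasks(path)

    def test_system_vocabulary_enforced(self):
        with pytest.raises(TaskValidationError, match="system"):
            _task(system="astrology", **A_TO_D).validate()

    def test_pass_task_needs_output(self):
        with pytest.raises(TaskValidationError, match="output"):
            _task(inputs=[("A", "e", 0.0, 1.0)]).validate()

    def test_duplicate_metabolite_entries_rejected(self):
        task = _task(inputs=[("A", "e", 0.0, 1.0), ("A", "e", 0.0, 2.0)],
                     outputs=[("D", "c", 1.0, 2.0)])
        with pytest.raises(TaskValidationError, match="duplicate"):
            task.validate()


class TestAdapt:
    def test_foreign_compartment_moved_to_cytoplasm(self, toy_template):
        task = _task(inputs=[("A", "e", 0.0, 10.0)],
                     outputs=[("D", "m", 1.0, 10.0)])  # no mitochondria here
        adapted = adapt_tasks([task], toy_template)[0]
        assert adapted.outputs[0].compartment == "c"
        assert not adapted.unresolvable

    def test_compatible_task_unchanged(self, toy_template):
        task = _task(**A_TO_D)
        adapted = adapt_tasks([task], toy_template)[0]
        assert adapted.inputs == task.inputs
        assert adapted.outputs == task.outputs

    def test_absent_metabolite_flagged(self, toy_template):
        task = _task(outputs=[("UNOBTANIUM", "c", 1.0, 2.0)])
        assert adapt_tasks([task], toy_template)[0].unresolvable
        assert check_task(toy_template, adapt_tasks([task], toy_template)[0]) is False


class TestCheckTask:
    def test_a_to_d_feasible(self, toy_template):
        assert check_task(toy_template, _task(**A_TO_D))

    def test_unreachable_product_infeasible(self, toy_template):
        # C2 can only come from route 2; remove it and demand C2
        pruned = toy_template.subnetwork(
            set(toy_template.reaction_ids) - {"R3", "R4", "R5"})
        task = _task(inputs=[("A", "e", 0.0, 1000.0)],
                     outputs=[("C2", "c", 1.0, 1000.0)])
        assert check_task(toy_template, task)
        assert not check_task(pruned, task)

    def test_bounds_restored_after_check(self, toy_template):
        before = {r.id: (r.lower_bound, r.upper_bound)
                  for r in toy_template.reactions}
        check_task(toy_template, _task(**A_TO_D))
        after = {r.id: (r.lower_bound, r.upper_bound)
                 for r in toy_template.reactions}
        assert before == after

    def test_input_forbidden_blocks_task(self, toy_template):
        # output demanded but no input allowed and exchanges closed
        task = _task(outputs=[("D", "c", 1.0, 1000.0)])
        assert not check_task(toy_template, task)


class TestFilterAndAttribution:
    def test_filter_keeps_exactly_feasible(self, toy_template):
        feasible = _task("ok", **A_TO_D)
        infeasible = _task("no", outputs=[("D", "c", 1.0, 2.0)])
        unresolvable = _task("gone", outputs=[("ZZZ", "c", 1.0, 2.0)])
        kept = filter_tasks(toy_template,
                            adapt_tasks([feasible, infeasible, unresolvable],
                                        toy_template))
        assert [t.id for t in kept] == ["ok"]

    def test_filter_membership_agrees_with_check(self, synthetic_template,
                                                 synthetic_study):
        _, _, _, tasks = synthetic_study
        kept = {t.id for t in filter_tasks(synthetic_template, tasks)}
        by_check = {t.id for t in tasks if check_task(synthetic_template, t)}
        assert kept == by_check

    def test_pfba_attribution_uses_short_route(self, toy_template):
        support = task_reactions(toy_template, _task(**A_TO_D))
        assert support == {"T_A", "R1", "R2"}

    def test_exchanges_and_gprless_excluded(self, toy_template):
        support = task_reactions(toy_template, _task(**A_TO_D))
        assert not any(toy_template.reaction(r).gpr is None for r in support)

    def test_infeasible_task_raises(self, toy_template):
        with pytest.raises(TaskValidationError):
            task_reactions(toy_template, _task(outputs=[("D", "c", 1.0, 2.0)]))


class TestMtScores:
    def _vec(self, ral_values, rxn_map={"T": {"R1", "R2"}}):
        tasks = [_task("T", **A_TO_D)]
        ral = ReactionActivity("s", ral_values)
        return infer_mt_scores(tasks, ral, rxn_map)

    def test_mean_above_cutoff_scores_one(self):
        vec = self._vec({"R1": 4.0, "R2": 3.0})
        assert vec.values["T"] == pytest.approx(3.5)
        assert vec.scores["T"] == 1

    def test_mean_below_cutoff_scores_zero(self):
        assert self._vec({"R1": 3.0, "R2": 3.0}).scores["T"] == 0

    def test_all_genes_at_threshold_scores_one(self):
        # expression == threshold propagates to MT score == 5 ln 2 -> active
        vec = self._vec({"R1": ACTIVITY_CUTOFF, "R2": ACTIVITY_CUTOFF})
        assert vec.values["T"] == ACTIVITY_CUTOFF
        assert vec.scores["T"] == 1

    def test_no_scored_reactions_warns_and_scores_zero(self):
        with pytest.warns(UserWarning, match="no scored"):
            vec = self._vec({"other": 9.0})
        assert vec.scores["T"] == 0

    def test_predicted_scores_are_feasibility(self, toy_template):
        tasks = adapt_tasks([_task("T", **A_TO_D)], toy_template)
        assert predict_mt_scores(toy_template, tasks).scores["T"] == 1
        pruned = toy_template.subnetwork({"BIOMASS"})
        assert predict_mt_scores(pruned, tasks).scores["T"] == 0


class TestTaskDistance:
    def _v(self, bits, vid="x"):
        return TaskScoreVector(vid, {f"t{i}": b for i, b in enumerate(bits)},
                               "inferred")

    def test_identical_and_complementary(self):
        assert task_distance(self._v([1, 0, 1]), self._v([1, 0, 1])) == 0.0
        assert task_distance(self._v([1, 0, 1]), self._v([0, 1, 0])) == 1.0

    def test_half_disagreement(self):
        assert task_distance(self._v([1, 0, 1, 1]), self._v([1, 1, 1, 0])) == 0.5

    def test_mismatched_task_lists_rejected(self):
        with pytest.raises(ValueError):
            task_distance(self._v([1, 0]), self._v([1, 0, 1]))

    def test_metric_axioms_by_enumeration(self):
        vectors = [self._v(bits) for bits in
                   itertools.product([0, 1], repeat=4)]
        for a, b in itertools.combinations(vectors, 2):
            assert task_distance(a, b) == task_distance(b, a) > 0
        for a in vectors:
            assert task_distance(a, a) == 0.0
        for a, b, c in itertools.combinations(vectors, 3):
            assert task_distance(a, c) <= \
                task_distance(a, b) + task_distance(b, c) + 1e-12


def test_submodel_feasible_tasks_subset_of_template(toy_template,
                                                    synthetic_template,
                                                    synthetic_study):
    """Removing reactions never creates task capability."""
    _, _, _, tasks = synthetic_study
    tasks = filter_tasks(synthetic_template, tasks)
    rng = np.random.default_rng(4)
    ids = list(synthetic_template.reaction_ids)
    for _ in range(3):
        drop = set(rng.choice(ids, size=8, replace=False))
        sub = synthetic_template.subnetwork(set(ids) - drop)
        for task in tasks:
            if check_task(sub, task):
                assert check_task(synthetic_template, task)
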