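import pytest

from cbmex import (SyntheticDesign, make_task_list, make_toy_model,
                   prepare_template, simulate_expression, toynet_a)
from cbmex.scoring import activity_for_samples, compute_thresholds, gene_scores


@pytest.fixture(scope="session")
def toynet():
    return toynet_a()


@pytest.fixture(scope="session")
def toy_template(toynet):
    return prepare_template(toynet)


@pytest.fixture(scope="session")
def standard_design():
    return SyntheticDesign()


@pytest.fixture(scope="session")
def synthetic_study(standard_design):
    """Standard synthetic template, ground truth, expression, and tasks."""
    model, truth = make_toy_model(standard_design)
    expr = simulate_expression(model, truth, standard_design)
    tasks = make_task_list(model, truth, standard_design)
    return model, truth, expr, tasks


@pytest.fixture(scope="session")
def synthetic_template(synthetic_study):
    model, _, _, _ = synthetic_study
    return prepare_template(model)


@pytest.fixture(scope="session")
def synthetic_activities(synthetic_study, synthetic_template):
    _, _, expr, _ = synthetic_study
    scores = gene_scores(expr, compute_thresholds(expr))
    return activity_for_samples(synthetic_template, scores)


@pytest.fixture(scope="session")
def small_consistent_model():
    """A compact flux-consistent network (no accessory branches)."""
    design = SyntheticDesign(n_modules=2, side_branches=False)
    model, _ = make_toy_model(design)
    return prepare_template(model)
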