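"""End-to-end study orchestration.

``run_study`` drives the whole analysis: load (or simulate) a template model
and expression cohort, score genes and reactions, extract one
context-specific model per (sample, method), evaluate contents and
predictions, score metabolic tasks both ways, compute functional-accuracy
distances against the generic-template baseline, and run the PCA/clustering
analyses. Failures are isolated per (sample, method) pair; the run
continues and the failure is logged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .extraction import (METHODS, ContextModel, ExtractionConfig, extract,
                         prepare_template)
from .fba import max_growth
from .model_io import read_model
from .scoring import (ACTIVITY_CUTOFF, ExpressionMatrix, activity_for_samples,
                      compute_thresholds, gene_scores)
from .stats import hclust, pca, summarize_model
from .synth import SyntheticDesign, make_task_list, make_toy_model, \
    simulate_expression
from .tasks import (TaskScoreVector, adapt_tasks, filter_tasks,
                    infer_mt_scores, load_tasks, predict_mt_scores,
                    task_distance, task_reaction_map)

log = logging.getLogger("cbmex")


@dataclass
class RunConfig:
    """Paths, scoring parameters, and per-method extraction settings.

    When ``model_path`` is unset the synthetic design is used to generate
    the template, expression, and tasks in-memory.
    """

    outdir: str = "results"
    model_path: str | None = None
    expression_path: str | None = None
    metadata_path: str | None = None
    tasks_path: str | None = None
    methods: tuple[str, ...] = METHODS
    p_gene: float = 90.0
    p_floor: float = 25.0
    activity_cutoff: float = ACTIVITY_CUTOFF
    ral_mode: str = "max-score"
    biomass_lb: float = 1.0
    seed: int = 0
    synthetic: SyntheticDesign = field(default_factory=SyntheticDesign)
    method_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        synth_doc = doc.pop("synthetic", {})
        methods = tuple(doc.pop("methods", METHODS))
        return cls(synthetic=SyntheticDesign(**synth_doc), methods=methods,
                   **doc)

    def extraction_config(self, method: str) -> ExtractionConfig:
        overrides = self.method_overrides.get(method, {})
        return ExtractionConfig(method=method,
                                activity_cutoff=self.activity_cutoff,
                                biomass_lb=self.biomass_lb,
                                seed=self.seed, **overrides)


@dataclass
class StudyResults:
    provenance: pd.DataFrame
    evaluation: pd.DataFrame
    distances: pd.DataFrame
    reaction_presence: pd.DataFrame
    tasks_inferred: pd.DataFrame
    tasks_predicted: pd.DataFrame
    pca_variance: pd.DataFrame | None = None
    pca_factor_r2: pd.DataFrame | None = None
    pca_scores: pd.DataFrame | None = None
    pca_within_method: pd.DataFrame | None = None
    hclust_order: list[str] | None = None
    failures: list[str] = field(default_factory=list)
    models: dict[tuple[str, str], ContextModel] = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("provenance", "evaluation", "distances",
                     "reaction_presence", "tasks_inferred", "tasks_predicted",
                     "pca_variance", "pca_factor_r2", "pca_scores",
                     "pca_within_method"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(outdir / f"{name}.csv")
        if self.hclust_order is not None:
            pd.Series(self.hclust_order, name="model").to_csv(
                outdir / "hclust_order.csv", index=False)


def _load_inputs(config: RunConfig):
    if config.model_path:
        model = read_model(config.model_path)
        expr = ExpressionMatrix.from_tsv(config.expression_path,
                                         config.metadata_path)
        tasks = load_tasks(config.tasks_path) if config.tasks_path else []
    else:
        design = dataclasses.replace(config.synthetic, seed=config.seed)
        model, truth = make_toy_model(design)
        expr = simulate_expression(model, truth, design)
        tasks = make_task_list(model, truth, design)
    return model, expr, tasks


def run_study(config: RunConfig, write: bool = True) -> StudyResults:
    """Execute the full pipeline; deterministic given ``config.seed``."""
    model, expr, tasks = _load_inputs(config)
    template = prepare_template(model, config.biomass_lb)
    template_growth = max_growth(template)

    expr = expr.restrict_to_model(template)
    thresholds = compute_thresholds(expr, config.p_gene, config.p_floor)
    scores = gene_scores(expr, thresholds)
    activities = activity_for_samples(template, scores, config.ral_mode)

    tasks = adapt_tasks(tasks, template)
    tasks = filter_tasks(template, tasks)
    rxn_map = task_reaction_map(template, tasks)
    task_ids = [t.id for t in tasks]

    inferred = {s: infer_mt_scores(tasks, ral, rxn_map, config.activity_cutoff)
                for s, ral in activities.items()}
    template_vector = TaskScoreVector("template",
                                      {t: 1 for t in task_ids}, "predicted")

    prov_rows, eval_rows, dist_rows = [], [], []
    presence_rows, pred_rows = {}, {}
    failures: list[str] = []
    models: dict[tuple[str, str], ContextModel] = {}
    meta = expr.metadata
    for sample in expr.samples:
        ral = activities[sample]
        for method in config.methods:
            key = f"{sample}/{method}"
            try:
                cfg = config.extraction_config(method)
                ctx = extract(template, ral, cfg)
                models[(sample, method)] = ctx
                prov_rows.append(dict(
                    sample=sample, method=method, seconds=ctx.seconds,
                    functional=ctx.functional, status=ctx.status,
                    n_genes=len(ctx.model.genes),
                    n_reactions=len(ctx.model.reactions),
                    n_metabolites=len(ctx.model.metabolites)))
                if not ctx.functional:
                    log.warning("%s: non-functional model discarded", key)
                    continue
                predicted = predict_mt_scores(ctx.model, tasks, key)
                result = summarize_model(ctx, template, tasks, predicted,
                                         template_growth)
                dist = task_distance(inferred[sample], predicted)
                base = task_distance(inferred[sample], template_vector)
                result.task_distance = dist
                eval_rows.append(result.as_row())
                dist_rows.append(dict(sample=sample, method=method,
                                      distance=dist,
                                      template_distance=base))
                presence_rows[key] = {r: int(r in ctx.reaction_ids)
                                      for r in template.reaction_ids}
                pred_rows[key] = predicted.scores
            except Exception as exc:  # isolate failures per pair
                log.error("%s failed: %s", key, exc)
                failures.append(f"{key}: {exc}")

    provenance = pd.DataFrame(prov_rows)
    evaluation = pd.DataFrame(eval_rows)
    distances = pd.DataFrame(dist_rows)
    presence = pd.DataFrame.from_dict(presence_rows, orient="index")
    predicted_df = pd.DataFrame.from_dict(pred_rows, orient="index")
    inferred_df = pd.DataFrame(
        {s: v.scores for s, v in inferred.items()}).T.loc[expr.samples]

    results = StudyResults(provenance, evaluation, distances, presence,
                           inferred_df, predicted_df, failures=failures,
                           models=models)

    if len(presence) >= 2 and meta is not None:
        model_meta = pd.DataFrame(
            [dict(method=k.split("/")[1],
                  life_stage=meta.loc[k.split("/")[0], "life_stage"],
                  feed=meta.loc[k.split("/")[0], "feed"])
             for k in presence.index], index=presence.index)
        try:
            global_pca = pca(presence, model_meta)
            results.pca_variance = pd.DataFrame(
                {"variance_explained": global_pca.variance_explained},
                index=global_pca.scores.columns)
            results.pca_factor_r2 = global_pca.factor_r2
            results.pca_scores = global_pca.scores
            results.hclust_order = hclust(presence).leaf_order
        except ValueError as exc:
            log.warning("global PCA skipped: %s", exc)
        within = []
        for method in config.methods:
            rows = [k for k in presence.index if k.endswith(f"/{method}")]
            if len(rows) < 2:
                continue
            try:
                sub = pca(presence.loc[rows], model_meta.loc[rows,
                                                             ["life_stage", "feed"]])
                if sub.factor_r2 is not None:
                    for factor in sub.factor_r2.index:
                        for i, pc in enumerate(sub.factor_r2.columns):
                            within.append(dict(
                                method=method, factor=factor, pc=pc,
                                r2=sub.factor_r2.loc[factor, pc],
                                variance_explained=sub.variance_explained[i]))
            except ValueError as exc:
                log.warning("PCA within %s skipped: %s", method, exc)
        if within:
            results.pca_within_method = pd.DataFrame(within)

    if write:
        results.write(config.outdir)
    return results
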