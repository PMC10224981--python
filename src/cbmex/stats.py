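"""Summaries, PCA with factor-variance attribution, hierarchical clustering.

PCA is run on column-standardized matrices (models x reactions/tasks/fluxes)
after dropping zero-variance columns. The share of each PC's score variance
explained by an experimental factor is max over all orderings of the factor
levels of the squared Pearson correlation between PC scores and the
integer-coded labels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .extraction import ContextModel
from .fba import max_growth, solve_pfba
from .model import MetabolicModel
from .tasks import MetabolicTask, TaskScoreVector, predict_mt_scores


@dataclass
class EvaluationResult:
    sample: str
    method: str
    n_genes: int
    n_reactions: int
    n_metabolites: int
    relative_growth: float
    relative_pfba_flux: float
    feasible_task_count: int
    task_distance: float = float("nan")
    seconds: float = float("nan")

    def as_row(self) -> dict:
        return dict(sample=self.sample, method=self.method,
                    n_genes=self.n_genes, n_reactions=self.n_reactions,
                    n_metabolites=self.n_metabolites,
                    relative_growth=self.relative_growth,
                    relative_pfba_flux=self.relative_pfba_flux,
                    feasible_task_count=self.feasible_task_count,
                    task_distance=self.task_distance, seconds=self.seconds)


def relative_pfba_flux(model: MetabolicModel,
                       template: MetabolicModel) -> float:
    """Ratio of growth-normalized minimal total flux, model vs template.

    Each pFBA runs at its own maximal growth; totals are divided by that
    growth before taking the ratio.
    """
    mu_m, _, total_m = solve_pfba(model)
    mu_t, _, total_t = solve_pfba(template)
    if not (np.isfinite(mu_m) and mu_m > 0 and np.isfinite(mu_t) and mu_t > 0):
        raise ValueError("relative pFBA flux needs both models to grow")
    return (total_m / mu_m) / (total_t / mu_t)


def summarize_model(context: ContextModel, template: MetabolicModel,
                    tasks: list[MetabolicTask],
                    predicted: TaskScoreVector | None = None,
                    template_growth: float | None = None
                    ) -> EvaluationResult:
    """Counts and predictions for one functional extracted model."""
    if not context.functional:
        raise ValueError(f"{context.sample}/{context.method}: model is "
                         "non-functional and excluded from evaluation")
    model = context.model
    mu_t = template_growth if template_growth is not None else max_growth(template)
    mu = max_growth(model)
    predicted = predicted or predict_mt_scores(model, tasks)
    return EvaluationResult(
        sample=context.sample, method=context.method,
        n_genes=len(model.genes), n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
        relative_growth=float(mu / mu_t),
        relative_pfba_flux=relative_pfba_flux(model, template),
        feasible_task_count=int(sum(predicted.scores.values())),
        seconds=context.seconds,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame          # models x PC
    loadings: pd.DataFrame        # feature x PC
    variance_explained: np.ndarray
    dropped_columns: list[str] = field(default_factory=list)
    factor_r2: pd.DataFrame | None = None  # factor x PC


def pca(matrix: pd.DataFrame, meta: pd.DataFrame | None = None,
        n_components: int | None = None) -> PCAResult:
    """Standardized PCA via SVD.

    Zero-variance columns are dropped (and reported); each remaining column
    is standardized to zero mean, unit variance. PC signs are fixed by
    forcing the largest-magnitude loading of each PC positive. When ``meta``
    is given, per-PC factor R2 is computed for every metadata column.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least two rows")
    X = matrix.astype(float)
    std = X.std(axis=0, ddof=0)
    dropped = list(X.columns[std == 0.0])
    X = X.loc[:, std > 0.0]
    if X.shape[1] == 0:
        raise ValueError("all columns are constant; nothing to analyse")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    U, s, Vt = np.linalg.svd(Z.values, full_matrices=False)
    k = n_components or len(s)
    k = min(k, len(s))
    # fix signs: largest-|loading| positive per PC
    for i in range(len(s)):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    var = s ** 2 / np.sum(s ** 2)
    pcs = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * s[:k], index=matrix.index, columns=pcs)
    loadings = pd.DataFrame(Vt[:k].T, index=X.columns, columns=pcs)
    result = PCAResult(scores, loadings, var[:k], dropped)
    if meta is not None:
        rows = {}
        for factor in meta.columns:
            labels = meta.loc[matrix.index, factor]
            if labels.nunique() < 2:
                continue
            rows[factor] = [factor_r2(scores[pc].values, labels.values)
                            for pc in pcs]
        if rows:
            result.factor_r2 = pd.DataFrame(rows, index=pcs).T
    return result


def factor_r2(pc_scores: np.ndarray, labels, max_levels: int = 10) -> float:
    """Variance of PC scores explained by a categorical factor.

    Over all orderings assigning ranks 1..k to the k factor levels, compute
    the Pearson correlation between scores and the coded labels; return the
    maximal |r| squared. Invariant to level relabeling and to affine
    transformation of the scores.
    """
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()))
    if len(levels) < 2:
        raise ValueError("factor needs at least two levels present")
    if len(levels) > max_levels:
        raise ValueError(f"{len(levels)} levels -> {math.factorial(len(levels))} "
                         "orderings; coarsen the factor or raise max_levels")
    scores = np.asarray(pc_scores, dtype=float)
    best = 0.0
    for perm in itertools.permutations(range(1, len(levels) + 1)):
        coding = dict(zip(levels, perm))
        coded = np.array([coding[l] for l in labels], dtype=float)
        if np.std(coded) == 0 or np.std(scores) == 0:
            continue
        r, _ = pearsonr(scores, coded)
        best = max(best, abs(r))
    return best ** 2


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]


def hclust(matrix: pd.DataFrame, method: str = "average",
           metric: str | None = None) -> ClusteringResult:
    """Agglomerative clustering of model rows.

    Metric defaults to Jaccard for binary matrices and Euclidean otherwise.
    """
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least two rows")
    X = matrix.values.astype(float)
    if metric is None:
        metric = "jaccard" if set(np.unique(X)) <= {0.0, 1.0} else "euclidean"
    if metric == "jaccard":
        X = X.astype(bool)
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    order = hierarchy.leaves_list(Z)
    labels = list(matrix.index)
    return ClusteringResult(Z, labels, [labels[i] for i in order])
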