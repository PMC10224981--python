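"""Gene scores and reaction activity levels from expression data.

Expression (CPM-like, non-negative) is turned into per-gene thresholds
(90th percentile of the gene across samples, floored by the 25th percentile
of the pooled distribution), then into gene scores

    score = 5 * ln(1 + expression / threshold),

so a gene exactly at its threshold scores 5 ln 2 — the activity cutoff used
everywhere downstream. Reaction activity levels (RAL) lift gene scores to
reactions through GPR associations (maximum over associated genes by
default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MetabolicModel

#: score of a gene whose expression equals its threshold; the activity cutoff
ACTIVITY_CUTOFF = 5.0 * math.log(2.0)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values plus per-sample factor metadata."""

    values: pd.DataFrame  # genes as rows, samples as columns
    metadata: pd.DataFrame | None = None  # indexed by sample id

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.metadata is not None:
            missing = set(self.values.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def restrict_to_model(self, model: MetabolicModel) -> "ExpressionMatrix":
        """Drop genes absent from the model (done before thresholding)."""
        keep = [g for g in self.values.index if g in set(model.genes)]
        return ExpressionMatrix(self.values.loc[keep], self.metadata)

    @classmethod
    def from_tsv(cls, expr_path, meta_path=None) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path else None
        return cls(values, meta)

    def to_tsv(self, expr_path, meta_path=None) -> None:
        self.values.to_csv(expr_path, sep="\t")
        if meta_path is not None and self.metadata is not None:
            self.metadata.to_csv(meta_path, sep="\t")


def compute_thresholds(expr: ExpressionMatrix, p_gene: float = 90.0,
                       p_floor: float = 25.0) -> pd.Series:
    """Per-gene expression thresholds.

    threshold_g = max(P{p_gene} of gene g across samples,
                      P{p_floor} of the pooled value distribution).

    Percentiles use linear interpolation between order statistics.
    """
    if expr.values.empty:
        raise ValueError("empty expression matrix")
    if expr.values.shape[1] < 2:
        raise ValueError("need at least two samples to set thresholds")
    per_gene = np.percentile(expr.values.values, p_gene, axis=1)
    floor = float(np.percentile(expr.values.values.ravel(), p_floor))
    return pd.Series(np.maximum(per_gene, floor), index=expr.values.index,
                     name="threshold")


@dataclass
class GeneScoreSet:
    """Thresholds and per-sample gene scores; raw expression retained."""

    thresholds: pd.Series
    scores: pd.DataFrame  # gene x sample
    expression: pd.DataFrame = field(repr=False, default=None)

    def sample_scores(self, sample: str) -> pd.Series:
        return self.scores[sample]


def gene_scores(expr: ExpressionMatrix, thresholds: pd.Series) -> GeneScoreSet:
    """Elementwise 5*ln(1 + e/t).

    A gene with threshold 0 (all-zero gene when the pooled floor is also 0)
    scores 0 at zero expression and is scored against the pooled floor if it
    is ever expressed; with a positive floor this case cannot arise.
    """
    values = expr.values
    if (values.values < 0).any():
        raise ValueError("expression values must be non-negative")
    t = thresholds.reindex(values.index)
    if t.isna().any():
        missing = list(t.index[t.isna()])
        raise ValueError(f"genes without thresholds: {missing[:5]}")
    tv = t.values[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(tv > 0, values.values / np.where(tv > 0, tv, 1.0), 0.0)
    scores = 5.0 * np.log1p(ratio)
    # zero-threshold genes: active (above cutoff) only when expressed at all
    zero_t = (t.values == 0)
    if zero_t.any():
        expressed = values.values[zero_t] > 0
        scores[zero_t] = np.where(expressed, 2.0 * ACTIVITY_CUTOFF, 0.0)
    return GeneScoreSet(t, pd.DataFrame(scores, index=values.index,
                                        columns=values.columns), values)


@dataclass
class ReactionActivity:
    """Per-reaction activity for one sample; reactions absent from ``ral``
    are unscored (no GPR, or no measured genes)."""

    sample: str
    ral: dict[str, float]

    def get(self, rxn_id: str) -> float | None:
        return self.ral.get(rxn_id)

    def is_scored(self, rxn_id: str) -> bool:
        return rxn_id in self.ral


def reaction_activity(model: MetabolicModel, scores: GeneScoreSet,
                      sample: str, mode: str = "max-score") -> ReactionActivity:
    """Reaction activity levels for one sample.

    Modes:
      ``max-score`` (default): RAL = max gene score over the reaction's
        flat gene set.
      ``gpr``: evaluate the GPR tree with min for AND and max for OR.
      ``max-expression``: RAL = score of the gene with maximal raw
        expression among associated genes.
    """
    s = scores.sample_scores(sample)
    measured = set(s.index)
    ral: dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        genes = [g for g in rxn.genes() if g in measured]
        if not genes:
            continue
        if mode == "max-score":
            ral[rxn.id] = float(max(s[g] for g in genes))
        elif mode == "max-expression":
            e = scores.expression[sample]
            top = max(genes, key=lambda g: (e[g], g))
            ral[rxn.id] = float(s[top])
        elif mode == "gpr":
            ral[rxn.id] = _eval_gpr(rxn.gpr, s, measured)
        else:
            raise ValueError(f"unknown RAL mode {mode!r}")
    return ReactionActivity(sample, ral)


def _eval_gpr(node, s: pd.Series, measured: set[str]) -> float:
    if node.op == "gene":
        return float(s[node.gene]) if node.gene in measured else 0.0
    vals = [_eval_gpr(c, s, measured) for c in node.children]
    return min(vals) if node.op == "and" else max(vals)


def activity_for_samples(model: MetabolicModel, scores: GeneScoreSet,
                         mode: str = "max-score") -> dict[str, ReactionActivity]:
    return {smp: reaction_activity(model, scores, smp, mode)
            for smp in scores.scores.columns}
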