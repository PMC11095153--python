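"""Metabolic pathway activity scores from expression.

A gene's relative expression in a condition is the ratio of its mean
(normalized) expression in that condition to the average of its per-condition
means; a pathway's activity in a condition is the weighted average of the
relative expression of its measured genes.  The default weight of a gene is
the reciprocal of the number of pathways containing it, with a uniform-weight
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import gene_membership_counts


@dataclass
class RelativeExpressionTable:
    """Per-gene per-condition relative expression ratios."""

    ratios: pd.DataFrame                 # genes x conditions
    excluded_genes: list[str] = field(default_factory=list)  # all-zero genes


@dataclass
class ActivityTable:
    """Per-pathway per-condition activity scores."""

    scores: pd.DataFrame                 # pathways x conditions
    n_genes_used: pd.Series
    dropped_pathways: list[str] = field(default_factory=list)

    def difference(self, cond1: str, cond2: str) -> pd.Series:
        return self.scores[cond2] - self.scores[cond1]


def relative_expression(expr: pd.DataFrame, design: dict[str, str],
                        ) -> RelativeExpressionTable:
    """Ratio of each gene's per-condition mean to its average across conditions.

    By construction the per-gene mean of the ratios over conditions is 1.
    Genes with zero expression everywhere are excluded and listed.
    """
    conditions = sorted(set(design.values()))
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    means = {}
    for cond in conditions:
        samples = [s for s, c in design.items() if c == cond]
        if not samples:
            raise ValueError(f"condition {cond} has no samples")
        means[cond] = expr[samples].mean(axis=1)
    mean_df = pd.DataFrame(means)
    grand = mean_df.mean(axis=1)
    zero = grand == 0
    ratios = mean_df.loc[~zero].div(grand.loc[~zero], axis=0)
    return RelativeExpressionTable(ratios=ratios,
                                   excluded_genes=list(mean_df.index[zero]))


def pathway_activity(rel: RelativeExpressionTable, db: dict[str, set[str]],
                     weighting: str = "reciprocal_membership") -> ActivityTable:
    """Weighted average of relative gene expression over each pathway's genes.

    ``score(p, c) = sum_g w_g * r_gc / sum_g w_g`` over the pathway's measured
    genes.  Pathways with no measured genes are dropped and listed.
    """
    if weighting not in ("reciprocal_membership", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    membership = gene_membership_counts(db)
    measured = set(rel.ratios.index)
    rows = {}
    n_used = {}
    dropped = []
    for name, genes in db.items():
        present = sorted(genes & measured)
        if not present:
            dropped.append(name)
            continue
        if weighting == "uniform":
            w = np.ones(len(present))
        else:
            w = np.array([1.0 / membership[g] for g in present])
        sub = rel.ratios.loc[present]
        rows[name] = (sub.mul(w, axis=0)).sum(axis=0) / w.sum()
        n_used[name] = len(present)
    scores = pd.DataFrame(rows).T
    scores.index.name = "pathway"
    return ActivityTable(scores=scores,
                         n_genes_used=pd.Series(n_used, dtype=int),
                         dropped_pathways=dropped)


def filter_divergent_pathways(tbl: ActivityTable, cond1: str, cond2: str,
                              threshold: float = 0.1) -> ActivityTable:
    """Retain pathways whose |activity difference| strictly exceeds threshold."""
    diff = tbl.difference(cond1, cond2)
    keep = diff.abs() > threshold
    return ActivityTable(scores=tbl.scores.loc[keep],
                         n_genes_used=tbl.n_genes_used.loc[keep],
                         dropped_pathways=list(tbl.dropped_pathways))
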