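"""Mutation-group assignment, Wilcoxon differential expression, and the
signed -log(p) ranking statistic (S-score) for pre-ranked GSEA.

Samples are partitioned by where their mutations fall relative to a
hotspot region: within the region, elsewhere in the gene, or nowhere in
the gene (wild type). Expression differences between groups are scored by
the two-sided Wilcoxon rank-sum test; genes are ranked by
S(i) = -log(p_i) * sign(mean_in - mean_out), natural log.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hotspot_test import bh_adjust
from .region_model import Region

__all__ = [
    "assign_mutation_groups",
    "filter_expressed",
    "diff_expression",
    "s_score",
    "has_min_roi_mutations",
]

#: smallest positive normal double; p-values are floored here before log
_P_FLOOR = np.finfo(float).tiny

MIN_ROI_MUTATIONS = 3


def assign_mutation_groups(
    mutations: pd.DataFrame,
    hotspot_region: Region,
    gene: str,
    samples: Sequence[str],
) -> dict[str, set[str]]:
    """Partition cohort samples by mutation status relative to a region.

    A sample with at least one event inside [start, end] is ``within_ROI``
    (this takes precedence over events elsewhere in the gene); otherwise a
    sample with any event in the gene is ``outside_ROI``; all remaining
    samples are ``wild_type``. The three sets are disjoint and exhaustive.
    """
    gene_mut = mutations[mutations["gene"] == gene]
    pos = gene_mut["protein_position"].to_numpy(dtype=np.int64)
    inside = (pos >= hotspot_region.start) & (pos <= hotspot_region.end)
    within = set(gene_mut.loc[inside.tolist(), "sample_id"]) & set(samples)
    mutated = set(gene_mut["sample_id"]) & set(samples)
    outside = mutated - within
    wild_type = set(samples) - mutated
    return {"within_ROI": within, "outside_ROI": outside, "wild_type": wild_type}


def has_min_roi_mutations(
    groups: Mapping[str, set[str]], min_within: int = MIN_ROI_MUTATIONS
) -> bool:
    """Eligibility rule for group comparisons: >= 3 samples mutated in the ROI."""
    return len(groups["within_ROI"]) >= min_within


def filter_expressed(expr: pd.DataFrame, max_zero_fraction: float = 0.30) -> pd.DataFrame:
    """Drop genes not expressed (value exactly 0) in more than 30% of samples."""
    zero_frac = (expr == 0).sum(axis=1) / expr.shape[1]
    return expr.loc[zero_frac <= max_zero_fraction]


def _ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum P; 1.0 when every value is tied."""
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def diff_expression(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
    max_zero_fraction: float = 0.30,
) -> pd.DataFrame:
    """Per-gene Wilcoxon differential expression between two sample groups.

    Genes failing the expression filter (zero in > ``max_zero_fraction`` of
    the pooled samples) are excluded before testing. Fold change is
    mean(group_a) / mean(group_b); direction is "up" for fold change >
    ``fc_threshold`` with adjusted P <= ``padj_threshold``, "down" for fold
    change < the threshold with adjusted P <= the cutoff, "ns" otherwise.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    pooled = expr[group_a + group_b]
    pooled = filter_expressed(pooled, max_zero_fraction)
    a = pooled[group_a].to_numpy(dtype=float)
    b = pooled[group_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_b > 0, mean_a / np.where(mean_b > 0, mean_b, 1.0), np.inf)
        fc = np.where((mean_a == 0) & (mean_b == 0), 1.0, fc)
    pvals = np.array([_ranksum_pvalue(a[i], b[i]) for i in range(len(pooled))])
    padj = bh_adjust(pvals) if len(pvals) else np.array([])
    direction = np.full(len(pooled), "ns", dtype=object)
    direction[(fc > fc_threshold) & (padj <= padj_threshold)] = "up"
    direction[(fc < fc_threshold) & (padj <= padj_threshold)] = "down"
    return pd.DataFrame(
        {
            "gene": pooled.index,
            "fold_change": fc,
            "p_value": pvals,
            "p_adjusted": padj,
            "direction": direction,
        }
    ).set_index("gene")


def s_score(
    expr: pd.DataFrame,
    group_in: Sequence[str],
    group_out: Sequence[str],
    max_zero_fraction: float = 0.30,
) -> pd.DataFrame:
    """Signed ranking statistic S(i) = -log(p_i) * sign(mean_in - mean_out).

    ``p_i`` is the two-sided rank-sum P comparing the two groups; the sign
    of the mean difference equals the sign of log(fold change) wherever the
    fold change is defined and avoids dividing by zero means. P-values are
    floored at the smallest positive normal double before the (natural)
    logarithm. The result has one row per retained gene, sorted by S
    descending with ties broken by gene symbol.
    """
    group_in, group_out = list(group_in), list(group_out)
    if not group_in or not group_out:
        raise ValueError("both groups must be non-empty")
    pooled = expr[group_in + group_out]
    pooled = filter_expressed(pooled, max_zero_fraction)
    a = pooled[group_in].to_numpy(dtype=float)
    b = pooled[group_out].to_numpy(dtype=float)
    signs = np.sign(a.mean(axis=1) - b.mean(axis=1))
    pvals = np.maximum(
        [_ranksum_pvalue(a[i], b[i]) for i in range(len(pooled))], _P_FLOOR
    )
    scores = -np.log(pvals) * signs
    out = pd.DataFrame({"gene": pooled.index, "S": scores})
    out = out.sort_values(["S", "gene"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)
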