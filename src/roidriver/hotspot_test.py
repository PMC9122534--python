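"""The hotspot statistic: binomial tail test for region mutation enrichment.

For a region of interest (ROI) of length L_ROI on a protein of length L_g
carrying N missense events in total, the event count k in the region is
modelled as Binomial(N, p_ri) with p_ri = L_ROI / L_g under the null that
mutations fall uniformly along the protein. The tail probability
P(X >= k), the enrichment ratio E = k / (N * p_ri), Benjamini-Hochberg
adjustment within a testing family, and the significance call
(P_adj < 0.05, raw P < 0.01, E > 2, k above the minimum count) together
define a hotspot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .region_model import GeneRegionModel, Region

__all__ = [
    "HotspotResult",
    "HotspotThresholds",
    "binomial_tail_pvalue",
    "enrichment_ratio",
    "bh_adjust",
    "call_hotspots",
]


@dataclass
class HotspotThresholds:
    """Significance thresholds for hotspot calling.

    Defaults are the method's standard operating point: adjusted P < 0.05,
    raw P < 0.01, enrichment ratio > 2, and at least 4 region mutations
    (strictly more than 3). ``stratify_by_class`` corrects IDRs and domains
    as separate families; set False for joint correction.
    """

    padj: float = 0.05
    praw: float = 0.01
    min_enrichment: float = 2.0
    min_mutations: int = 4
    stratify_by_class: bool = True


@dataclass
class HotspotResult:
    """Per-region test output."""

    cohort: str
    gene: str
    protein_id: str
    region: Region
    L_gene: int
    k: int
    N: int
    p_ri: float
    enrichment: float
    p_value: float
    p_adjusted: float = float("nan")
    significant: bool = False


def binomial_tail_pvalue(k: int, N: int, p_ri: float) -> float:
    """P(X >= k) for X ~ Binomial(N, p_ri), via the survival function.

    Computed as ``binom.sf(k - 1, N, p_ri)`` so small tail probabilities
    (down to ~1e-300) keep full relative precision; naive 1 - CDF would
    cancel catastrophically below ~1e-16. Exactly 1.0 when k == 0.
    """
    if not 0 <= k <= N:
        raise ValueError(f"require 0 <= k <= N, got k={k}, N={N}")
    if not 0.0 < p_ri <= 1.0:
        raise ValueError(f"require 0 < p_ri <= 1, got {p_ri}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, N, p_ri))


def enrichment_ratio(k: int, N: int, L_roi: int, L_g: int) -> float:
    """Observed in-region events over their length-proportional expectation:
    E = k / (N * L_ROI / L_g)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 1 <= L_roi <= L_g:
        raise ValueError(f"require 1 <= L_roi <= L_g, got L_roi={L_roi}, L_g={L_g}")
    return k * L_g / (N * L_roi)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order.

    adj(i) = min_{j: p(j) >= p(i)} p(j) * m / rank(j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def call_hotspots(
    models: Sequence[GeneRegionModel],
    cohort: str,
    thresholds: HotspotThresholds | None = None,
) -> list[HotspotResult]:
    """Test every sufficiently mutated region and flag significant hotspots.

    Regions with k < ``min_mutations`` are excluded *before* adjustment: the
    count filter defines the testing family, and BH is computed on that
    family only, separately per region class by default. A result is
    emitted for every tested region, significant or not.
    """
    if thresholds is None:
        thresholds = HotspotThresholds()
    results: list[HotspotResult] = []
    for model in models:
        L_g = model.protein.length
        if model.N == 0:
            continue
        for region, k in zip(model.regions, model.region_counts):
            if k < thresholds.min_mutations:
                continue
            p_ri = region.length / L_g
            results.append(
                HotspotResult(
                    cohort=cohort,
                    gene=model.gene,
                    protein_id=model.protein.protein_id,
                    region=region,
                    L_gene=L_g,
                    k=k,
                    N=model.N,
                    p_ri=p_ri,
                    enrichment=enrichment_ratio(k, model.N, region.length, L_g),
                    p_value=binomial_tail_pvalue(k, model.N, p_ri),
                )
            )

    if thresholds.stratify_by_class:
        strata = {}
        for r in results:
            strata.setdefault(r.region.region_class, []).append(r)
    else:
        strata = {"all": list(results)}

    for members in strata.values():
        adjusted = bh_adjust([r.p_value for r in members])
        for r, padj in zip(members, adjusted):
            r.p_adjusted = float(padj)
            r.significant = bool(
                r.p_adjusted < thresholds.padj
                and r.p_value < thresholds.praw
                and r.enrichment > thresholds.min_enrichment
                and r.k >= thresholds.min_mutations
            )
    return results
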