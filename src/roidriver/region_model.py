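"""Per-gene protein model: isoform selection, IDR/domain overlap resolution,
and assignment of mutation events to regions.

Coordinates are 1-based inclusive residue intervals, the convention of
HGVS protein notation; a region [start, end] has length end - start + 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "Region",
    "GeneRegionModel",
    "select_longest_isoform",
    "resolve_overlaps",
    "map_mutations",
    "build_gene_models",
    "mutation_frequency",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A gene's selected protein isoform; ``length`` is L_g in residues."""

    gene: str
    protein_id: str
    length: int

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"protein {self.protein_id}: length must be >= 1")


@dataclass(frozen=True)
class Region:
    """A contiguous region of interest (IDR or domain) on a protein."""

    protein_id: str
    gene: str
    start: int
    end: int
    region_class: str
    source: str = ""

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"region {self.gene}:{self.start}-{self.end}: require 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> set[int]:
        return set(range(self.start, self.end + 1))

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class GeneRegionModel:
    """One gene's protein, its resolved regions, and mapped mutation counts.

    ``N`` counts every retained missense event in the gene (recurrences at
    the same position in different samples each count); ``region_counts[i]``
    is the event count k for ``regions[i]``.
    """

    protein: ProteinRecord
    regions: list[Region]
    region_counts: list[int] = field(default_factory=list)
    N: int = 0
    n_dropped_out_of_range: int = 0

    @property
    def gene(self) -> str:
        return self.protein.gene


def select_longest_isoform(candidates: Sequence[tuple[str, int]]) -> tuple[str, int]:
    """Pick the longest isoform; ties go to the lexicographically smallest id."""
    if not candidates:
        raise ValueError("no isoform candidates supplied")
    return min(candidates, key=lambda c: (-c[1], c[0]))


def resolve_overlaps(
    regions: Iterable[Region],
    protein_length: int,
    policy: str = "remove",
    min_region_length: int = 5,
) -> list[Region]:
    """Resolve IDR/domain conflicts so no residue belongs to both classes.

    ``policy="remove"`` (default): any IDR sharing at least one residue with
    any domain is dropped entirely. ``policy="trim"``: domain residues are
    subtracted from each IDR and the remaining fragments of length >=
    ``min_region_length`` are kept. Domains are never modified. Output is
    sorted by (region_class, start).
    """
    regions = list(regions)
    for r in regions:
        if r.end > protein_length:
            raise ValueError(
                f"region {r.gene}:{r.start}-{r.end} ({r.region_class}) extends "
                f"beyond protein length {protein_length}"
            )
    domains = [r for r in regions if r.region_class == "domain"]
    idrs = [r for r in regions if r.region_class == "IDR"]

    domain_residues: set[int] = set()
    for d in domains:
        domain_residues.update(range(d.start, d.end + 1))

    resolved: list[Region] = list(domains)
    if policy == "remove":
        for idr in idrs:
            if not (domain_residues & idr.residues()):
                resolved.append(idr)
    elif policy == "trim":
        for idr in idrs:
            keep = sorted(idr.residues() - domain_residues)
            for fragment in _runs(keep):
                if fragment[1] - fragment[0] + 1 >= min_region_length:
                    resolved.append(
                        Region(
                            protein_id=idr.protein_id,
                            gene=idr.gene,
                            start=fragment[0],
                            end=fragment[1],
                            region_class="IDR",
                            source=idr.source,
                        )
                    )
    else:
        raise ValueError(f"unknown overlap policy {policy!r}")
    return sorted(resolved, key=lambda r: (r.region_class, r.start, r.end))


def _runs(sorted_positions: Sequence[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers, as (first, last) pairs."""
    runs = []
    for p in sorted_positions:
        if runs and p == runs[-1][1] + 1:
            runs[-1][1] = p
        else:
            runs.append([p, p])
    return [tuple(r) for r in runs]


def map_mutations(
    protein: ProteinRecord,
    regions: Sequence[Region],
    mutations: pd.DataFrame,
) -> GeneRegionModel:
    """Count mutation events per region for one gene in one cohort.

    ``mutations`` must already be restricted to the gene (and cohort).
    Events beyond the protein length are dropped and counted, never errors.
    Counting is order-independent and inclusive of region endpoints.
    """
    positions = mutations["protein_position"].to_numpy(dtype=np.int64)
    in_range = (positions >= 1) & (positions <= protein.length)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d events beyond protein length %d",
            protein.gene, n_dropped, protein.length,
        )
    positions = positions[in_range]
    counts = [int(((positions >= r.start) & (positions <= r.end)).sum()) for r in regions]
    return GeneRegionModel(
        protein=protein,
        regions=list(regions),
        region_counts=counts,
        N=int(positions.size),
        n_dropped_out_of_range=n_dropped,
    )


def build_gene_models(
    mutations: pd.DataFrame,
    proteins: Mapping[str, ProteinRecord],
    regions: pd.DataFrame,
    overlap_policy: str = "remove",
    min_region_length: int = 5,
) -> list[GeneRegionModel]:
    """Assemble per-gene models for every gene with a protein and >= 1 region.

    Region rows whose gene has no selected protein, or whose protein_id does
    not match the selected isoform, are skipped with a logged count.
    """
    models = []
    n_skipped = 0
    by_gene = dict(tuple(mutations.groupby("gene", sort=False)))
    for gene, gene_regions in regions.groupby("gene", sort=True):
        protein = proteins.get(gene)
        if protein is None:
            n_skipped += len(gene_regions)
            continue
        matching = gene_regions[gene_regions["protein_id"] == protein.protein_id]
        n_skipped += len(gene_regions) - len(matching)
        if matching.empty:
            continue
        region_objs = [
            Region(
                protein_id=row["protein_id"],
                gene=gene,
                start=int(row["start"]),
                end=int(row["end"]),
                region_class=row["region_class"],
                source=row.get("source", ""),
            )
            for _, row in matching.iterrows()
        ]
        resolved = resolve_overlaps(
            region_objs, protein.length, policy=overlap_policy,
            min_region_length=min_region_length,
        )
        if not resolved:
            continue
        gene_mut = by_gene.get(gene, mutations.iloc[0:0])
        models.append(map_mutations(protein, resolved, gene_mut))
    if n_skipped:
        logger.info("skipped %d region rows without a matching selected protein", n_skipped)
    return models


def mutation_frequency(mutations: pd.DataFrame, cohort_size: int) -> dict[str, float]:
    """Per-gene fraction of cohort samples carrying >= 1 retained mutation."""
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    counts = mutations.groupby("gene")["sample_id"].nunique()
    if len(counts) and counts.max() > cohort_size:
        raise ValueError(
            f"cohort_size {cohort_size} is smaller than the number of distinct "
            f"mutated samples ({counts.max()}) in gene {counts.idxmax()}"
        )
    return {gene: n / cohort_size for gene, n in counts.items()}
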