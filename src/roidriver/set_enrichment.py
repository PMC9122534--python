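"""Gene-set statistics for prioritized hotspot genes.

Two questions are answered here: whether the prioritized genes overlap a
reference catalogue (known cancer genes) more than random gene sets of the
same size drawn from the universe — quantified by the observed/expected
(O/E) ratio and an empirical permutation P — and whether they are enriched
for a labelled subset (phase-separation-prone proteins, PScore Z >= 4) by
a one-sided Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapEnrichmentResult",
    "oe_ratio",
    "overlap_permutation_test",
    "fisher_enrichment",
    "fisher_from_table",
    "label_phase_separation",
]


@dataclass(frozen=True)
class OverlapEnrichmentResult:
    """Outcome of the random-sampling overlap test.

    ``N_universe`` is the size of the gene universe the random sets are
    drawn from (distinct from the per-gene mutation count N of the hotspot
    model). ``p_empirical`` uses the add-one estimator and is therefore
    bounded below by 1/(n_perm + 1).
    """

    n_overlap: int
    M: int
    K: int
    N_universe: int
    oe_ratio: float
    p_empirical: float
    n_perm: int
    seed: int
    rng: str = "numpy.random.PCG64"


def oe_ratio(n: int, M: int, K: int, N_universe: int) -> float:
    """Observed/expected overlap: O/E = n / ((M*K)/N)."""
    if min(M, K, N_universe) < 1:
        raise ValueError("M, K and N_universe must be >= 1")
    if n > min(M, K):
        raise ValueError(f"overlap n={n} exceeds min(M, K)={min(M, K)}")
    if max(M, K) > N_universe:
        raise ValueError("M and K cannot exceed the universe size")
    return n * N_universe / (M * K)


def overlap_permutation_test(
    prioritized: Iterable[str],
    reference: Iterable[str],
    universe: Iterable[str],
    n_perm: int = 100_000,
    seed: int = 0,
    strict_greater: bool = False,
) -> OverlapEnrichmentResult:
    """Empirical significance of a gene-set overlap by random resampling.

    Draws ``n_perm`` uniform samples of size |prioritized| without
    replacement from the universe and compares their overlap with the
    reference set to the observed one. The default estimator is
    ``(#draws with overlap >= observed + 1) / (n_perm + 1)``, which can
    never return 0; ``strict_greater=True`` instead counts draws with
    strictly larger overlap divided by n_perm (the literal random-test
    definition), which can.

    Genes outside the universe are dropped from both sets with a logged
    count. Identical seed and inputs give bit-identical results.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    prioritized_set = set(prioritized)
    reference_set = set(reference)
    n_outside = len(prioritized_set - universe_set) + len(reference_set - universe_set)
    if n_outside:
        logger.info("dropped %d genes outside the universe", n_outside)
    prioritized_set &= universe_set
    reference_set &= universe_set
    if len(prioritized_set) > len(universe_set):  # pragma: no cover - set algebra
        raise ValueError("prioritized set larger than universe")

    genes = sorted(universe_set)
    N = len(genes)
    M = len(prioritized_set)
    K = len(reference_set)
    observed = len(prioritized_set & reference_set)

    is_reference = np.zeros(N, dtype=bool)
    index = {g: i for i, g in enumerate(genes)}
    for g in reference_set:
        is_reference[index[g]] = True

    rng = np.random.default_rng(seed)
    exceed = 0  # draws with overlap >= observed (or > observed under strict_greater)
    if M > 0 and K > 0:
        # uniform sample of size M without replacement == M smallest of N
        # iid uniform keys; chunked to bound memory
        chunk = max(1, min(n_perm, 2_000_000 // max(N, 1)))
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            keys = rng.random((b, N))
            picks = np.argpartition(keys, M - 1, axis=1)[:, :M]
            overlaps = is_reference[picks].sum(axis=1)
            if strict_greater:
                exceed += int((overlaps > observed).sum())
            else:
                exceed += int((overlaps >= observed).sum())
            done += b
    elif not strict_greater:
        exceed = n_perm  # overlap is identically 0 and ties the observed 0

    if strict_greater:
        p = exceed / n_perm
    else:
        p = (exceed + 1) / (n_perm + 1)

    ratio = 0.0 if (M == 0 or K == 0) else oe_ratio(observed, M, K, N)
    return OverlapEnrichmentResult(
        n_overlap=observed,
        M=M,
        K=K,
        N_universe=N,
        oe_ratio=ratio,
        p_empirical=p,
        n_perm=n_perm,
        seed=seed,
    )


def fisher_from_table(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (enrichment) Fisher's exact test on [[a, b], [c, d]].

    Returns the sample odds ratio a*d/(b*c) (inf when b*c == 0 and a*d > 0)
    and P(X >= a) for X hypergeometric with the table's margins.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n_total = a + b + c + d
    if n_total == 0:
        raise ValueError("empty 2x2 table")
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = float("inf")
    else:
        odds = float("nan")  # 0/0: both diagonals degenerate
    p = float(stats.hypergeom.sf(a - 1, n_total, a + c, a + b))
    return odds, min(p, 1.0)


def fisher_enrichment(
    prioritized: Iterable[str],
    labeled: Iterable[str],
    universe: Iterable[str],
) -> tuple[float, float]:
    """Fisher's exact enrichment of a labelled subset among prioritized genes.

    Builds the 2x2 table over the universe — (prioritized & labelled,
    prioritized & not, not prioritized & labelled, neither) — and returns
    the sample odds ratio with the one-sided enrichment P.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    pri = set(prioritized) & universe_set
    lab = set(labeled) & universe_set
    a = len(pri & lab)
    b = len(pri - lab)
    c = len(lab - pri)
    d = len(universe_set) - a - b - c
    return fisher_from_table(a, b, c, d)


def label_phase_separation(
    scores: Mapping[str, float], threshold: float = 4.0
) -> set[str]:
    """Genes whose PScore Z-score meets the phase-separation cutoff (>= 4)."""
    for gene, score in scores.items():
        if not np.isfinite(score):
            raise ValueError(f"non-finite score for gene {gene!r}")
    return {gene for gene, score in scores.items() if score >= threshold}
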