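# Methods

## Model

Mutational hotspot detection treats each annotated protein region (ROI)
as a binomial enrichment problem. Conditional on a gene carrying `N`
missense events in a cohort, and under the null hypothesis that events
fall uniformly along the selected protein of length `L_g`, the count `k`
inside an ROI of `L_ROI` residues is `Binomial(N, p_ri)` with
`p_ri = L_ROI / L_g`. The reported P-value is the upper tail
`P(X >= k)`; the enrichment ratio `E = k / (N · p_ri)` measures effect
size on a scale where 1 is the uniform expectation. Conditioning on `N`
removes per-gene mutation-rate differences from the null, which is what
lets a single test run across genes with wildly different burdens; the
price is that the test is blind to whole-gene enrichment and only ranks
regions *within* their gene's own burden.

Assumptions worth keeping in mind: uniform placement ignores sequence
context (trinucleotide signatures, CpG content) and local covariates
(replication timing, expression); regions are taken as given from
upstream predictors and are not re-estimated; all isoform positions are
interpreted on the single selected (longest) isoform.

## Pipeline conventions

* **Mutation filter.** Only single-nucleotide missense rows
  (`Variant_Type == SNP`, `Variant_Classification == Missense_Mutation`)
  are analysed. Positions come from `Protein_position` (the `pos/len`
  dialect takes the part before the slash) with `HGVSp_Short` as
  fallback; rows with missing or non-positive positions are dropped and
  counted in the load report, never silently.
* **Isoform selection.** One protein per gene: maximal length, ties to
  the lexicographically smallest protein id, so selection is
  deterministic across file orderings. FASTA lengths exclude `*`.
* **IDR/domain conflicts.** Residues predicted as both disordered and
  domain are ambiguous. The default policy removes any IDR sharing at
  least one residue with a domain (region-level exclusion); a `trim`
  policy instead subtracts domain residues and keeps IDR fragments of at
  least `min_region_length` (default 5) residues, for sensitivity
  analysis. Domains are never modified. After either policy the IDR and
  domain residue sets are disjoint by construction.
* **Counting.** `N` counts events, not samples: recurrent mutation of
  the same residue in different patients is exactly the signal a hotspot
  test wants. Region membership is inclusive on both endpoints.
  Positions beyond the protein length are dropped with a logged count
  (annotation/isoform mismatches occur in real MAFs).
* **Testing family.** Regions with fewer than `min_mutations = 4` events
  (strictly more than 3) are never tested; Benjamini–Hochberg runs on
  the tested family only, separately per region class by default. The
  filter-then-adjust order matters: it keeps thousands of untestable
  low-count regions from diluting the correction. Joint correction
  across classes is available (`--joint-adjust`).
* **Significance** is the conjunction `P_adj < 0.05 ∧ P < 0.01 ∧ E > 2 ∧
  k ≥ min_mutations`. All four thresholds are CLI flags.

## Gene-set statistics

The overlap permutation test draws `n_perm` (default 100 000) uniform
same-size gene sets from the universe and compares their overlap with a
reference catalogue to the observed one. The default estimator is
`(#{overlap ≥ observed} + 1) / (n_perm + 1)`: it is a valid permutation
P-value bounded below by `1/(n_perm+1)` and never returns 0. The
strict-greater variant (`#{overlap > observed} / n_perm`) is available
behind a flag for comparison with the literal random-test definition.
Sampling uses numpy's seeded PCG64 generator; the seed and generator
name are recorded in the result. The universe is explicit: by default
the genes with at least one tested ROI, overridable with any gene list
— the O/E ratio `n·N/(M·K)` is computed on whatever universe sampling
used, so the two stay consistent.

Fisher enrichment of a labelled subset (e.g. phase-separation-prone
proteins, PScore Z ≥ 4, scores consumed as input) uses the one-sided
hypergeometric tail and reports the sample odds ratio `ad/bc`.

## Expression statistics

Samples split into `within_ROI` (≥ 1 event inside the hotspot region —
this takes precedence), `outside_ROI` (≥ 1 event elsewhere in the gene)
and `wild_type`; the partition is exhaustive and disjoint. Group
comparisons require at least 3 within-ROI samples (configurable).

Differential expression excludes genes with value exactly 0 in more than
30% of the pooled samples, then applies the two-sided Wilcoxon rank-sum
test with BH correction; fold change is the ratio of group means, and
direction is `up`/`down`/`ns` against fold-change 1 and adjusted-P 0.05
cutoffs. The ranking statistic is `S = -ln(p) · sign(mean_in − mean_out)`.
Natural log is a free choice — any base gives the same ranking, only
|S| rescales — and the sign of the mean difference equals the sign of
log fold change wherever the latter is defined while tolerating zero
denominators. P-values are floored at the smallest positive normal
double before the logarithm; all-constant genes get S = 0. Ties in the
ranked list break by gene symbol so output is deterministic.

## Synthetic cohorts

The generator emulates the statistical structure the hotspot test
assumes: a proteome of genes with non-overlapping IDR/domain intervals,
missense events placed uniformly along each protein, samples assigned
uniformly, and optional injected hotspots adding a controlled excess of
in-region events. Expression matrices are log-normal (between-gene
log-sd 1, within-gene log-sd 0.5) with a multiplicative effect in one
group. Everything is deterministic under its seed, and fixtures are
written in the external formats (MAF, length table, FASTA, region TSV)
so tests exercise the full I/O path.

Default cohort scale: gene lengths uniform on 500–1500 residues, two
regions per gene of 100–400 residues (capped at half the gene), and an
aggregate burden of 0.2 missense events per residue — a heavily mutated
gene in a large pan-cancer cohort, i.e. the regime the test actually
operates in, since only regions with > 3 events are ever tested. The
scale also matters for validation: discrete binomial tails are
conservative, and with tens of expected in-region events the achieved
level at the 0.01 cutoff is ≈ 0.008 (computed from the binomial law
directly), close enough to nominal for a calibration check to be
meaningful. What passing these tests does *not* show: robustness to
non-uniform mutational processes, annotation error, or isoform
mismatch — real-data behaviour on those axes is outside what synthetic
uniform cohorts can certify.

The power fixture is one candidate gene (L_g = 1000, one 50-residue
region, 10 background events) with 10 injected in-region events:
`p_ri = 0.05`, so the injected region reaches `E ≈ 10` and tail
probabilities around 1e-9, recovered in ≈ 100% of seeded replicates,
while matched null replicates essentially never produce a call
(a false call needs ≥ 4 of 10 uniform events in a 5% region,
probability ≈ 1e-3 per replicate).

The permutation-uniformity check uses universe 2000, reference 1000,
prioritized 1000: the overlap distribution then has standard deviation
≈ 11, so empirical P-values are fine-grained enough to compare against
a continuous uniform with a Kolmogorov–Smirnov test. With much smaller
sets the overlap lives on a handful of atoms and KS rejects by
discreteness alone, which would test the fixture, not the code.

## Numerical choices

* Binomial tails via the survival function, never `1 − CDF`: observed
  hotspot P-values reach 1e-10 and below, far under double-precision
  cancellation (~1e-16).
* BH step-up implemented directly (sort, `p·m/rank`, reverse cumulative
  minimum, cap at 1); an independent reference implementation is used
  as the oracle in tests.
* Fisher's one-sided P via the hypergeometric survival function; exact
  integer-arithmetic enumeration is the test oracle.
* Permutation sampling without replacement is vectorised as the M
  smallest of N iid uniform keys per draw, chunked to bound memory;
  identical seeds give bit-identical results.
* Hotspot TSVs serialize floats with the shortest round-tripping
  representation, so `read(write(x)) == x` exactly and reruns are
  byte-identical.
* Degenerate inputs: all-tied expression rows get rank-sum P = 1
  (avoiding a 0/0 in the tie-corrected normal approximation); empty
  tested sets and empty result lists are valid, producing header-only
  output.

## Validation problem sizes

The acceptance script (`scripts/acceptance.py --seed N --out f.json`)
uses: the full binomial grid `0 ≤ k ≤ N ≤ 25` at six `p_ri` values
(2100 cases); a 2000-gene null cohort (~4000 tested regions); 100
injected-hotspot and 100 matched-null replicates; every 2×2 table with
all four margins ≤ 50 (~1.17 million tables); 500 permutation runs at
`n_perm = 2000`; 1000 random BH vectors; and 200 expression replicates
at n = 30 vs 30. These sizes keep the whole script around half a minute
on one CPU while leaving each stochastic check enough resolution to
fail if the statistics were wrong.

## Known limitations

No background-rate covariates (expression, replication timing); no
position-level (single-residue) tests; no transcript-aware remapping
across isoforms; gene identity is the symbol string, with no aliasing.
The O/E permutation P is bounded by the number of draws — reporting
"P < 1/(n_perm+1)"-scale significance requires raising `--n-perm`.
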