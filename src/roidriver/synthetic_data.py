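"""Synthetic cohorts with known ground truth.

Generates proteomes (gene lengths plus non-overlapping IDR/domain
annotations), cohorts of samples with missense events placed uniformly
along each protein (the null of the hotspot test), optional injected
hotspots with a controlled excess of in-region events, and log-normal
expression matrices with designated differentially expressed genes.
Fixtures can be written out in the exact external formats (MAF, length
table, FASTA, region TSV) so tests exercise the full I/O path.

Default cohort parameters emulate a heavily mutated pan-cancer aggregate:
gene lengths 500-1500 residues, two regions per gene of 100-400 residues,
and an aggregate missense burden of 0.2 events per residue, so a typical
tested region carries tens of events. This is the regime the hotspot test
targets (only regions with more than 3 mutations are ever tested).

All generators are deterministic under their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_proteome",
    "simulate_null_mutations",
    "inject_hotspot",
    "simulate_expression",
    "write_fixture_dir",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    ``mutations_per_residue`` is the cohort-aggregate missense burden: a
    gene of length L receives Poisson(L * mutations_per_residue) events.
    ``hotspots`` lists (gene, region_index, k_extra) triples of events to
    inject uniformly into that region on top of the null background.
    """

    n_genes: int = 100
    gene_length: tuple[int, int] = (500, 1500)
    regions_per_gene: int = 2
    region_length: tuple[int, int] = (100, 400)
    cohort_size: int = 100
    mutations_per_residue: float = 0.2
    hotspots: list[tuple[str, int, int]] = field(default_factory=list)
    seed: int = 0
    cohort: str = "SYNTH"

    def __post_init__(self):
        if self.n_genes < 1 or self.cohort_size < 1:
            raise ValueError("n_genes and cohort_size must be >= 1")
        if self.mutations_per_residue < 0:
            raise ValueError("mutations_per_residue must be >= 0")


def _sample_names(n: int) -> list[str]:
    return [f"SAMPLE-{i:04d}" for i in range(n)]


def simulate_proteome(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate gene lengths and non-overlapping regions.

    Returns (length table with columns gene/protein_id/length, region table
    in the external TSV schema). Region classes alternate IDR/domain so
    both testing families are populated; placement distributes the free
    residues between regions uniformly at random. Raises when the requested
    regions cannot fit inside the shortest admissible gene.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length
    rlo, rhi = config.region_length
    if config.regions_per_gene * rlo > lo:
        raise ValueError(
            f"{config.regions_per_gene} regions of length >= {rlo} cannot fit a "
            f"gene of length {lo}; shorten regions or lengthen genes"
        )
    genes, proteins, lengths = [], [], []
    region_rows = []
    for i in range(config.n_genes):
        gene = f"GENE{i:04d}"
        protein = f"PROT{i:04d}"
        L = int(rng.integers(lo, hi + 1))
        n_regions = config.regions_per_gene
        starts_lens: list[tuple[int, int]] = []
        if n_regions:
            # cap each region at half the gene so p_ri stays a proper fraction
            cap = max(rlo, min(rhi, L // 2))
            lens = rng.integers(rlo, cap + 1, size=n_regions)
            while lens.sum() > L:
                lens = np.maximum(rlo, lens - 1)
                if lens.sum() > L:  # pragma: no cover - guarded by the check above
                    raise ValueError(f"cannot pack regions into gene of length {L}")
            free = L - int(lens.sum())
            # distribute free residues into n_regions + 1 gaps
            cuts = np.sort(rng.integers(0, free + 1, size=n_regions))
            gaps = np.diff(np.concatenate([[0], cuts]))
            pos = 1
            for j in range(n_regions):
                pos += int(gaps[j])
                starts_lens.append((pos, int(lens[j])))
                pos += int(lens[j])
        genes.append(gene)
        proteins.append(protein)
        lengths.append(L)
        for j, (start, rlen) in enumerate(starts_lens):
            region_rows.append(
                {
                    "protein_id": protein,
                    "gene": gene,
                    "start": start,
                    "end": start + rlen - 1,
                    "region_class": "IDR" if j % 2 == 0 else "domain",
                    "source": "synthetic",
                }
            )
    length_table = pd.DataFrame({"gene": genes, "protein_id": proteins, "length": lengths})
    regions = pd.DataFrame(region_rows, columns=io_formats.REGION_COLUMNS)
    return length_table, regions


def simulate_null_mutations(
    length_table: pd.DataFrame,
    cohort_size: int,
    mutations_per_residue: float = 0.2,
    seed: int = 0,
    cohort: str = "SYNTH",
    events_per_gene: int | None = None,
) -> pd.DataFrame:
    """Place missense events uniformly along each gene (the null model).

    Each gene receives Poisson(L * mutations_per_residue) events — or
    exactly ``events_per_gene`` when given — at positions uniform on
    [1, L], assigned to samples uniform over the cohort.
    """
    rng = np.random.default_rng(seed)
    samples = np.array(_sample_names(cohort_size))
    rows = []
    for _, rec in length_table.iterrows():
        L = int(rec["length"])
        n = events_per_gene if events_per_gene is not None else rng.poisson(
            mutations_per_residue * L
        )
        if n == 0:
            continue
        positions = rng.integers(1, L + 1, size=n)
        carriers = samples[rng.integers(0, cohort_size, size=n)]
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": carriers,
                    "gene": rec["gene"],
                    "protein_position": positions,
                    "variant_classification": "Missense_Mutation",
                    "variant_type": "SNP",
                    "cohort": cohort,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=io_formats.MUTATION_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def inject_hotspot(
    mutations: pd.DataFrame,
    length_table: pd.DataFrame,
    gene: str,
    region: tuple[int, int],
    k_extra: int,
    cohort_size: int,
    seed: int = 0,
    cohort: str = "SYNTH",
) -> pd.DataFrame:
    """Append ``k_extra`` events uniform within a region of one gene.

    The injected rows carry ``injected=True`` in an extra column recording
    the ground truth; ``k_extra=0`` returns the input unchanged.
    """
    if gene not in set(length_table["gene"]):
        raise ValueError(f"unknown gene {gene!r}")
    start, end = region
    L = int(length_table.set_index("gene").loc[gene, "length"])
    if not 1 <= start <= end <= L:
        raise ValueError(f"region [{start}, {end}] does not fit gene {gene} (L={L})")
    if k_extra == 0:
        return mutations
    rng = np.random.default_rng(seed)
    samples = np.array(_sample_names(cohort_size))
    extra = pd.DataFrame(
        {
            "sample_id": samples[rng.integers(0, cohort_size, size=k_extra)],
            "gene": gene,
            "protein_position": rng.integers(start, end + 1, size=k_extra),
            "variant_classification": "Missense_Mutation",
            "variant_type": "SNP",
            "cohort": cohort,
        }
    )
    base = mutations.copy()
    base["injected"] = False
    extra["injected"] = True
    return pd.concat([base, extra], ignore_index=True)


def simulate_expression(
    genes: list[str],
    n_in: int,
    n_out: int,
    de_genes: list[str] | None = None,
    effect: float = 2.0,
    sigma: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Log-normal expression with a multiplicative effect in one group.

    Baseline per-gene medians are log-normal across genes; within-gene
    noise is log-normal with log-sd ``sigma``. Genes in ``de_genes`` are
    scaled by ``effect`` in the first group ("in"); ``effect=1`` is the
    null. Returns (matrix, {"in": samples, "out": samples}).
    """
    if effect <= 0:
        raise ValueError("effect must be > 0")
    rng = np.random.default_rng(seed)
    de = set(de_genes or [])
    in_samples = [f"IN-{i:03d}" for i in range(n_in)]
    out_samples = [f"OUT-{i:03d}" for i in range(n_out)]
    base = rng.lognormal(mean=3.0, sigma=1.0, size=len(genes))
    noise = rng.lognormal(mean=0.0, sigma=sigma, size=(len(genes), n_in + n_out))
    values = base[:, None] * noise
    fold = np.array([effect if g in de else 1.0 for g in genes])
    values[:, :n_in] *= fold[:, None]
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                        columns=in_samples + out_samples)
    return expr, {"in": in_samples, "out": out_samples}


def _random_protein_sequences(length_table: pd.DataFrame, rng: np.random.Generator):
    for _, rec in length_table.iterrows():
        seq = "".join(rng.choice(AMINO_ACIDS, size=int(rec["length"])))
        yield rec["gene"], rec["protein_id"], seq


def write_fixture_dir(
    config: SimulationConfig,
    out_dir: str | Path,
    write_fasta: bool = False,
) -> dict[str, Path]:
    """Simulate a full cohort and write it in the external formats.

    Produces ``mutations.maf``, ``protein_lengths.tsv``, ``regions.tsv``
    and optionally ``proteins.fasta`` (random sequences of the simulated
    lengths, headers ``>PROT gene=GENE``) under ``out_dir``. Hotspots in
    the config are injected with seeds derived from the config seed.
    Returns the paths keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    length_table, regions = simulate_proteome(config)
    mutations = simulate_null_mutations(
        length_table,
        config.cohort_size,
        config.mutations_per_residue,
        seed=config.seed + 1,
        cohort=config.cohort,
    )
    for i, (gene, region_index, k_extra) in enumerate(config.hotspots):
        sub = regions[regions["gene"] == gene].reset_index(drop=True)
        if region_index >= len(sub):
            raise ValueError(f"gene {gene!r} has no region index {region_index}")
        row = sub.iloc[region_index]
        mutations = inject_hotspot(
            mutations, length_table, gene,
            (int(row["start"]), int(row["end"])),
            k_extra, config.cohort_size,
            seed=config.seed + 1000 + i, cohort=config.cohort,
        )
    paths = {
        "maf": out_dir / "mutations.maf",
        "lengths": out_dir / "protein_lengths.tsv",
        "regions": out_dir / "regions.tsv",
    }
    io_formats.write_mutations(mutations, paths["maf"])
    length_table.to_csv(paths["lengths"], sep="\t", index=False)
    io_formats.write_regions(regions, paths["regions"])
    if write_fasta:
        rng = np.random.default_rng(config.seed + 2)
        fasta = out_dir / "proteins.fasta"
        with open(fasta, "w") as fh:
            for gene, protein, seq in _random_protein_sequences(length_table, rng):
                fh.write(f">{protein} gene={gene}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        paths["fasta"] = fasta
    return paths
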