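"""Readers and writers for the tabular formats the pipeline consumes and emits.

Mutations arrive as MAF-like tab-delimited tables (MC3-style columns),
protein lengths as FASTA or a three-column length table, region annotations
(IDRs and domains) as a TSV of 1-based inclusive residue intervals, gene
sets as plain symbol lists, and expression as a gene-by-sample TSV.
All tables round-trip byte-stably on their data rows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ConfigurationError",
    "LoadReport",
    "MUTATION_COLUMNS",
    "REGION_COLUMNS",
    "HOTSPOT_COLUMNS",
    "read_maf",
    "read_protein_lengths",
    "read_regions",
    "write_regions",
    "read_gene_list",
    "read_expression",
    "write_hotspots",
    "write_ranked_list",
]


class ConfigurationError(ValueError):
    """An input file does not match the expected dialect (e.g. missing columns)."""


MUTATION_COLUMNS = [
    "sample_id",
    "gene",
    "protein_position",
    "variant_classification",
    "variant_type",
    "cohort",
]

REGION_COLUMNS = ["protein_id", "gene", "start", "end", "region_class", "source"]

HOTSPOT_COLUMNS = [
    "cohort",
    "gene",
    "protein_id",
    "region_class",
    "start",
    "end",
    "L_roi",
    "L_gene",
    "k",
    "N",
    "p_ri",
    "E",
    "p_value",
    "p_adjusted",
    "significant",
]

REGION_CLASSES = frozenset({"IDR", "domain"})

_MAF_REQUIRED = [
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Variant_Type",
]

# HGVS protein notation: "p.S33C", "p.Ser33Cys", optionally parenthesised.
_HGVSP_RE = re.compile(r"^p\.\(?(?:[A-Z][a-z]{2}|[A-Z*])(\d+)")


@dataclass
class LoadReport:
    """Row bookkeeping for a filtered load: (kept + dropped) == input rows."""

    input_rows: int = 0
    kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str, n: int = 1) -> None:
        if n:
            self.dropped[reason] = self.dropped.get(reason, 0) + n

    @property
    def total_dropped(self) -> int:
        return sum(self.dropped.values())


def _parse_protein_position(value: object) -> int | None:
    """Parse a protein residue position from a Protein_position-style field.

    Accepts plain integers and the "pos/length" dialect (takes the part
    before the slash). Returns None for missing/unparseable markers such as
    "." or "-" and for non-positive positions.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if not text or text in {".", "-", "NA", "nan"}:
        return None
    text = text.split("/")[0]
    # ranges like "33-35" (in-frame dialects) are not single-residue positions
    if not text.isdigit():
        return None
    pos = int(text)
    return pos if pos >= 1 else None


def _parse_hgvsp(value: object) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    m = _HGVSP_RE.match(str(value).strip())
    return int(m.group(1)) if m else None


def read_maf(path: str | Path, cohort: str) -> pd.DataFrame:
    """Load a MAF-like mutation table, keeping only missense SNP rows.

    Only rows with ``Variant_Type == "SNP"`` and
    ``Variant_Classification == "Missense_Mutation"`` survive; every other
    mutation class is excluded. Protein positions come from the
    ``Protein_position`` column when present, otherwise from
    ``HGVSp_Short``. Rows whose position is missing, unparseable or < 1 are
    dropped and counted.

    Returns a DataFrame with columns ``MUTATION_COLUMNS``; the
    :class:`LoadReport` is attached as ``df.attrs["load_report"]``.

    Raises :class:`ConfigurationError` when a mandatory column is absent or
    the file has no data rows.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.shape[1] == 0 or len(df) == 0:
        raise ConfigurationError(f"MAF file {path} contains no data rows")
    for col in _MAF_REQUIRED:
        if col not in df.columns:
            raise ConfigurationError(f"MAF file {path} is missing required column {col!r}")
    has_pos = "Protein_position" in df.columns
    has_hgvsp = "HGVSp_Short" in df.columns
    if not has_pos and not has_hgvsp:
        raise ConfigurationError(
            f"MAF file {path} carries neither 'Protein_position' nor 'HGVSp_Short'"
        )

    report = LoadReport(input_rows=len(df))

    missense = df["Variant_Classification"] == "Missense_Mutation"
    report.drop("not_missense", int((~missense).sum()))
    df = df[missense]
    snp = df["Variant_Type"] == "SNP"
    report.drop("not_snp", int((~snp).sum()))
    df = df[snp]

    positions = []
    keep_idx = []
    for idx, row in df.iterrows():
        pos = _parse_protein_position(row["Protein_position"]) if has_pos else None
        if pos is None and has_hgvsp:
            pos = _parse_hgvsp(row["HGVSp_Short"])
        if pos is None:
            report.drop("unparseable_position")
            continue
        positions.append(pos)
        keep_idx.append(idx)

    out = pd.DataFrame(
        {
            "sample_id": df.loc[keep_idx, "Tumor_Sample_Barcode"].to_numpy(),
            "gene": df.loc[keep_idx, "Hugo_Symbol"].to_numpy(),
            "protein_position": pd.array(positions, dtype="int64"),
            "variant_classification": df.loc[keep_idx, "Variant_Classification"].to_numpy(),
            "variant_type": df.loc[keep_idx, "Variant_Type"].to_numpy(),
            "cohort": cohort,
        }
    )
    report.kept = len(out)
    assert report.kept + report.total_dropped == report.input_rows
    out.attrs["load_report"] = report
    return out


def _fasta_gene_and_id(record) -> tuple[str, str]:
    """Extract (gene, protein_id) from a FASTA record.

    Two header dialects are accepted: ``>PROT1 gene=TP53 ...`` (key=value in
    the description) and ``>PROT1|TP53`` (pipe-delimited id).
    """
    for token in record.description.split()[1:]:
        if token.lower().startswith("gene="):
            return token.split("=", 1)[1], record.id
    if "|" in record.id:
        protein_id, gene = record.id.split("|", 2)[:2]
        return gene, protein_id
    raise ConfigurationError(
        f"FASTA header {record.description!r} carries no gene symbol "
        "(expected 'gene=SYMBOL' in the description or 'PROTEIN|GENE' ids)"
    )


def read_protein_lengths(path: str | Path, format: str = "table"):
    """Read protein lengths and select one isoform per gene (the longest).

    ``format="fasta"``: residue counts exclude stop ('*') characters.
    ``format="table"``: 3-column TSV ``gene  protein_id  length`` with header.

    Returns a mapping ``gene -> ProteinRecord``. Duplicate
    (gene, protein_id) pairs with conflicting lengths raise
    :class:`ConfigurationError`.
    """
    from .region_model import ProteinRecord, select_longest_isoform

    candidates: dict[str, dict[str, int]] = {}

    def add(gene: str, protein_id: str, length: int) -> None:
        per_gene = candidates.setdefault(gene, {})
        if protein_id in per_gene and per_gene[protein_id] != length:
            raise ConfigurationError(
                f"conflicting lengths for ({gene}, {protein_id}): "
                f"{per_gene[protein_id]} vs {length}"
            )
        per_gene[protein_id] = length

    if format == "fasta":
        for record in SeqIO.parse(str(path), "fasta"):
            gene, protein_id = _fasta_gene_and_id(record)
            add(gene, protein_id, len(str(record.seq).replace("*", "")))
    elif format == "table":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        for col in ("gene", "protein_id", "length"):
            if col not in df.columns:
                raise ConfigurationError(f"length table {path} is missing column {col!r}")
        for _, row in df.iterrows():
            add(row["gene"], row["protein_id"], int(row["length"]))
    else:
        raise ConfigurationError(f"unknown protein length format {format!r}")

    result: dict[str, ProteinRecord] = {}
    for gene, per_gene in candidates.items():
        protein_id, length = select_longest_isoform(list(per_gene.items()))
        result[gene] = ProteinRecord(gene=gene, protein_id=protein_id, length=length)
    return result


def read_regions(path: str | Path) -> pd.DataFrame:
    """Load the region annotation table (1-based inclusive residue intervals)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in REGION_COLUMNS[:5]:
        if col not in df.columns:
            raise ConfigurationError(f"region table {path} is missing column {col!r}")
    if "source" not in df.columns:
        df["source"] = ""
    df = df[REGION_COLUMNS].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad_class = ~df["region_class"].isin(REGION_CLASSES)
    if bad_class.any():
        value = df.loc[bad_class, "region_class"].iloc[0]
        raise ConfigurationError(f"unknown region_class value {value!r} in {path}")
    for offset, (_, row) in enumerate(df.iterrows()):
        if row["start"] < 1 or row["start"] > row["end"]:
            raise ConfigurationError(
                f"region table {path} row {offset + 1}: invalid interval "
                f"[{row['start']}, {row['end']}]"
            )
    return df.reset_index(drop=True)


def write_regions(regions: pd.DataFrame, path: str | Path) -> None:
    regions[REGION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; '#' comments and blank lines are skipped."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if line:
            genes.append(line)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene-by-sample expression TSV: first column gene, one column per sample.

    Values must be non-negative and sample ids unique.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    for sample in header:
        if sample in seen:
            raise ConfigurationError(f"duplicate sample id {sample!r} in {path}")
        seen.add(sample)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ConfigurationError(f"negative expression values in {path}")
    df.index.name = "gene"
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t")


def _float_repr(x: float) -> str:
    """Shortest decimal string that re-parses to the identical float."""
    return repr(float(x))


def write_hotspots(results, path: str | Path) -> None:
    """Write hotspot results as TSV with deterministic row and column order.

    Rows are sorted by (cohort, gene, region_class, start); P-values use the
    shortest round-trip float representation so re-parsing is lossless.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "cohort": r.cohort,
                "gene": r.gene,
                "protein_id": r.protein_id,
                "region_class": r.region.region_class,
                "start": r.region.start,
                "end": r.region.end,
                "L_roi": r.region.length,
                "L_gene": r.L_gene,
                "k": r.k,
                "N": r.N,
                "p_ri": _float_repr(r.p_ri),
                "E": _float_repr(r.enrichment),
                "p_value": _float_repr(r.p_value),
                "p_adjusted": _float_repr(r.p_adjusted),
                "significant": r.significant,
            }
        )
    df = pd.DataFrame(rows, columns=HOTSPOT_COLUMNS)
    if len(df):
        df = df.sort_values(["cohort", "gene", "region_class", "start"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_hotspots(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ranked_list(ranked: pd.DataFrame, path: str | Path) -> None:
    """Write a two-column pre-ranked .rnk file (gene, score), no header."""
    ranked[["gene", "S"]].to_csv(path, sep="\t", index=False, header=False)


def write_mutations(mutations: pd.DataFrame, path: str | Path) -> None:
    """Write an internal mutation table back out in MAF dialect."""
    out = pd.DataFrame(
        {
            "Hugo_Symbol": mutations["gene"],
            "Tumor_Sample_Barcode": mutations["sample_id"],
            "Variant_Classification": mutations["variant_classification"],
            "Variant_Type": mutations["variant_type"],
            "Protein_position": mutations["protein_position"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
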