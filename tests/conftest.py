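import math

import pandas as pd
import pytest

from roidriver.region_model import ProteinRecord, Region

MAF_HEADER = [
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Variant_Type",
    "Protein_position",
    "HGVSp_Short",
]


def write_maf(path, rows, columns=None):
    """Write a minimal MAF-like file; each row is a dict of column values."""
    columns = columns or MAF_HEADER
    with open(path, "w") as fh:
        fh.write("#version synthetic\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
    return path


def maf_row(sample="S1", gene="GENE1", classification="Missense_Mutation",
            vtype="SNP", position="", hgvsp=""):
    return {
        "Hugo_Symbol": gene,
        "Tumor_Sample_Barcode": sample,
        "Variant_Classification": classification,
        "Variant_Type": vtype,
        "Protein_position": position,
        "HGVSp_Short": hgvsp,
    }


def mutation_table(events, cohort="TEST"):
    """Build an in-memory mutation table from (sample, gene, position) triples."""
    return pd.DataFrame(
        {
            "sample_id": [e[0] for e in events],
            "gene": [e[1] for e in events],
            "protein_position": pd.array([e[2] for e in events], dtype="int64"),
            "variant_classification": "Missense_Mutation",
            "variant_type": "SNP",
            "cohort": cohort,
        }
    )


def binom_tail_bruteforce(k, N, p):
    """Exhaustive P(X >= k) by direct summation of the binomial pmf."""
    return sum(math.comb(N, x) * p**x * (1 - p) ** (N - x) for x in range(k, N + 1))


@pytest.fixture
def toy_protein():
    return ProteinRecord(gene="GENE1", protein_id="P1", length=1000)


@pytest.fixture
def toy_region():
    return Region(protein_id="P1", gene="GENE1", start=1, end=50, region_class="IDR")
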