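"""The published reference family table and its aggregate statistics.

The packaged TSV transcribes the printed characteristics table of the 41
African bermudagrass HSP20 genes (name, gene id, chromosome, genomic
location, CDS length, residue count, molecular weight, isoelectric point).
It anchors the pipeline's report format and provides an end-to-end fixture:
the CDS-to-residue rule and the family-wide ranges can be recomputed from
it and compared against the printed values.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .properties import protein_length_from_cds

REFERENCE_COLUMNS = [
    "gene_name", "gene_id", "chr", "start", "end", "cds_bp", "aa", "mw_kda", "pi",
]


def load_reference_table(path=None) -> pd.DataFrame:
    if path is None:
        path = importlib.resources.files("hsp20pipe.data") / "reference_family_table.tsv"
    df = pd.read_csv(path, sep="\t")
    missing = set(REFERENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reference table is missing columns {sorted(missing)}")
    return df


def aggregate_reference(df: pd.DataFrame) -> dict:
    """Family-wide summary statistics of the reference table."""
    per_chrom = df["chr"].value_counts().to_dict()
    return {
        "n_genes": int(len(df)),
        "genes_per_chromosome": per_chrom,
        "aa_min": int(df["aa"].min()),
        "aa_max": int(df["aa"].max()),
        "mw_min_kda": float(df["mw_kda"].min()),
        "mw_max_kda": float(df["mw_kda"].max()),
        "pi_min": float(df["pi"].min()),
        "pi_max": float(df["pi"].max()),
    }


def check_cds_aa_consistency(df: pd.DataFrame) -> pd.Series:
    """Residue counts implied by the CDS lengths (one codon per residue plus
    a stop), for comparison with the table's printed counts."""
    return df["cds_bp"].map(protein_length_from_cds)
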