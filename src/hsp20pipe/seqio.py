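"""Sequence and annotation I/O.

FASTA reading/writing goes through Biopython. Gene models are exchanged as
GFF3 (1-based, closed intervals) with ``gene``/``mRNA``/``CDS`` feature rows;
only the minimal single-transcript, single-CDS layout emitted by the
simulator (and typical of compact gene-family pipelines) is interpreted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: 1-based closed genomic interval plus strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.start}-{self.end} for {self.gene_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta-2line" if width == 0 else "fasta")


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key putting Chr2 before Chr10 (numeric-aware)."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "hsp20pipe") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs_gene = f"ID={g.gene_id}"
            attrs_mrna = f"ID={g.gene_id}.t1;Parent={g.gene_id}"
            attrs_cds = f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1"
            for ftype, attrs in (
                ("gene", attrs_gene),
                ("mRNA", attrs_mrna),
                ("CDS", attrs_cds),
            ):
                fh.write(
                    f"{g.chrom}\t{source}\t{ftype}\t{g.start}\t{g.end}\t.\t{g.strand}\t"
                    f"{'0' if ftype == 'CDS' else '.'}\t{attrs}\n"
                )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read ``gene`` features from a GFF3 file into GeneModel records."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID")
            if gene_id is None:
                raise ValueError(f"gene feature without ID attribute: {line!r}")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                )
            )
    return genes


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(cds: str, strip_stop: bool = True) -> str:
    """Translate a CDS (standard code). A single trailing stop is removed."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    prot = str(Seq(cds).translate())
    if strip_stop and prot.endswith("*"):
        prot = prot[:-1]
    return prot
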