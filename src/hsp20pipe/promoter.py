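"""Promoter extraction, cis-element and HSE scanning, enrichment testing.

Promoters are the 1.5-kb windows immediately upstream of the annotated gene
start (strand-aware, truncated at contig ends). Cis-elements are exact
matches of a named IUPAC catalog, scanned on both strands with every
overlapping occurrence reported. Heat-shock elements are the two degenerate
15-bp modules of alternating GAA/TTC triplets, nGAAnnTTCnnGAAn and
nTTCnnGAAnnTTCn. The two modules are reverse complements of each other, so
each matching window is reported once: ``module`` names the motif spelled by
the promoter's forward strand and ``strand`` is '+' for the GAA-first
reading and '-' for the TTC-first reading.

The HSE/up-regulation association is a two-tailed Fisher exact test computed
by summing hypergeometric probabilities of tables as or more extreme
(smaller point probability) than the observed one.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .seqio import GeneModel, reverse_complement

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

HSE_GAA_FIRST = "NGAANNTTCNNGAAN"
HSE_TTC_FIRST = "NTTCNNGAANNTTCN"

CATEGORIES = ("stress_responsive", "hormone_related", "development_related")


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    sequence: str
    requested: int
    truncated: bool


@dataclass(frozen=True)
class CisElementHit:
    gene_id: str
    motif_name: str
    category: str
    subtype: str
    offset: int   # 1-based position within the promoter (forward coordinates)
    strand: str


@dataclass(frozen=True)
class HSEHit:
    gene_id: str
    module: str   # GAA_first / TTC_first (motif spelled by the + strand)
    offset: int
    strand: str
    matched_sequence: str


@dataclass(frozen=True)
class EnrichmentResult:
    contingency: tuple  # ((hse&up, hse&not), (nohse&up, nohse&not))
    odds_ratio: float
    p_value: float


def iupac_regex(pattern: str) -> re.Pattern:
    try:
        body = "".join(
            IUPAC[c] if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]"
            for c in pattern.upper()
        )
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter {exc.args[0]!r} in {pattern!r}") from exc
    return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


def load_motif_catalog(path=None) -> pd.DataFrame:
    """Load the named-IUPAC motif catalog (TSV). The packaged default seeds
    the motif names of the usual plant promoter catalogs and is meant to be
    replaced or extended by the user."""
    if path is None:
        path = importlib.resources.files("hsp20pipe.data") / "motif_catalog.tsv"
    cat = pd.read_csv(path, sep="\t")
    required = {"motif_name", "pattern", "category", "subtype"}
    if not required.issubset(cat.columns):
        raise ValueError(f"motif catalog needs columns {sorted(required)}")
    bad = set(cat["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories in catalog: {sorted(bad)}")
    for pat in cat["pattern"]:
        iupac_regex(pat)  # validates letters
    return cat


def extract_promoters(
    genome: dict[str, str], genes: list[GeneModel], window: int = 1500
) -> dict[str, Promoter]:
    """Strand-aware upstream windows, 5'->3', truncated at contig ends."""
    out: dict[str, Promoter] = {}
    for g in genes:
        if g.chrom not in genome:
            raise KeyError(f"gene {g.gene_id}: chromosome {g.chrom} not in genome")
        contig = genome[g.chrom]
        if g.strand == "+":
            lo = max(0, g.start - 1 - window)
            seq = contig[lo : g.start - 1]
        else:
            hi = min(len(contig), g.end + window)
            seq = reverse_complement(contig[g.end : hi])
        out[g.gene_id] = Promoter(
            gene_id=g.gene_id,
            sequence=seq,
            requested=window,
            truncated=len(seq) < window,
        )
    return out


def scan_motifs(
    promoter: Promoter | str, motif_table: pd.DataFrame, gene_id: str | None = None
) -> list[CisElementHit]:
    """All overlapping occurrences of each catalog motif, both strands."""
    if isinstance(promoter, Promoter):
        seq, gid = promoter.sequence.upper(), promoter.gene_id
    else:
        seq, gid = promoter.upper(), gene_id or ""
    L = len(seq)
    rc = reverse_complement(seq)
    hits: list[CisElementHit] = []
    for row in motif_table.itertuples(index=False):
        rx = iupac_regex(row.pattern)
        mlen = len(row.pattern)
        for m in rx.finditer(seq):
            hits.append(
                CisElementHit(gid, row.motif_name, row.category, row.subtype,
                              m.start() + 1, "+")
            )
        for m in rx.finditer(rc):
            # map the reverse-strand window back to forward coordinates
            offset = L - m.start() - mlen + 1
            hits.append(
                CisElementHit(gid, row.motif_name, row.category, row.subtype,
                              offset, "-")
            )
    hits.sort(key=lambda h: (h.offset, h.strand, h.motif_name))
    return hits


def scan_hse(promoter: Promoter | str, gene_id: str | None = None) -> list[HSEHit]:
    """Match the two 15-bp HSE modules.

    Because the modules are mutual reverse complements, every HSE window
    matches exactly one module on the forward strand; it is reported once,
    with strand '+' when the forward strand reads GAA-first and '-' when it
    reads TTC-first.
    """
    if isinstance(promoter, Promoter):
        seq, gid = promoter.sequence.upper(), promoter.gene_id
    else:
        seq, gid = promoter.upper(), gene_id or ""
    hits: list[HSEHit] = []
    for module, pattern, strand in (
        ("GAA_first", HSE_GAA_FIRST, "+"),
        ("TTC_first", HSE_TTC_FIRST, "-"),
    ):
        for m in iupac_regex(pattern).finditer(seq):
            hits.append(
                HSEHit(
                    gene_id=gid,
                    module=module,
                    offset=m.start() + 1,
                    strand=strand,
                    matched_sequence=m.group(1),
                )
            )
    hits.sort(key=lambda h: h.offset)
    return hits


def summarize_categories(hits: list[CisElementHit]) -> pd.DataFrame:
    """Counts and percentages per element category (percent of all
    classified elements; sums to 100 within rounding)."""
    if not hits:
        return pd.DataFrame(columns=["category", "count", "percent"])
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.category] = counts.get(h.category, 0) + 1
    total = sum(counts.values())
    rows = [
        {"category": c, "count": n, "percent": 100.0 * n / total}
        for c, n in sorted(counts.items(), key=lambda kv: -kv[1])
    ]
    return pd.DataFrame(rows)


def fisher_exact_two_tailed(table) -> tuple[float, float]:
    """Two-tailed Fisher exact test on a 2x2 table.

    Returns (odds_ratio, p). p sums hypergeometric probabilities of all
    tables with the observed margins whose point probability does not exceed
    the observed one (with a small relative tolerance for float ties). The
    odds ratio is the sample ratio with the Haldane-Anscombe +0.5 correction
    when any cell is zero.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if 0 in (a, b, c, d):
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = a * d / (b * c)
    n = a + b + c + d
    r1 = a + b          # margin: HSE-positive genes
    c1 = a + c          # margin: up-regulated genes
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        logger.warning("degenerate margins in Fisher table %s; p = 1", table)
        return orr, 1.0
    rv = hypergeom(n, r1, c1)
    k_lo = max(0, c1 - (n - r1))
    k_hi = min(r1, c1)
    ks = np.arange(k_lo, k_hi + 1)
    pmf = rv.pmf(ks)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return orr, min(p, 1.0)


def hse_enrichment(
    hse_presence: dict[str, bool], upregulated: dict[str, bool]
) -> EnrichmentResult:
    """Association between HSE presence and up-regulation over one gene set."""
    if set(hse_presence) != set(upregulated):
        raise ValueError("HSE and up-regulation labels must cover the same genes")
    a = sum(1 for g in hse_presence if hse_presence[g] and upregulated[g])
    b = sum(1 for g in hse_presence if hse_presence[g] and not upregulated[g])
    c = sum(1 for g in hse_presence if not hse_presence[g] and upregulated[g])
    d = sum(1 for g in hse_presence if not hse_presence[g] and not upregulated[g])
    orr, p = fisher_exact_two_tailed(((a, b), (c, d)))
    return EnrichmentResult(contingency=((a, b), (c, d)), odds_ratio=orr, p_value=p)
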