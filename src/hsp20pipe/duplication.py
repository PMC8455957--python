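"""Paralog detection, tandem/WGD-segmental classification, synteny.

All-vs-all protein similarity is Smith-Waterman local alignment with
BLOSUM62 and affine gaps (open 11, extend 1) through Biopython's pairwise
aligner, with Karlin-Altschul E-values. Genes are ranked by chromosomal
position; a similar pair with rank difference 1 on one chromosome is a
tandem duplicate, a pair anchored inside a collinear block is a
WGD/segmental duplicate, and block membership takes priority when both
conditions hold. Remaining similar pairs are reported as dispersed.

Collinear blocks are found by dynamic-programming chaining of anchor pairs
in rank space (>= ``min_anchors`` anchors, per-step rank gap <=
``max_gap``, both orientations). For cross-genome synteny, anchors are
first filtered by cscore — the pair's alignment score normalized by the
best score of either gene — at the configured cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import GeneModel, natural_chrom_key

# Karlin-Altschul parameters for gapped BLOSUM62 with open 11 / extend 1
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    alignment_score: float
    e_value: float
    identity_fraction: float
    coverage: float = 1.0  # aligned columns / length of the shorter protein

    def pair(self) -> frozenset:
        return frozenset((self.query_id, self.subject_id))


@dataclass(frozen=True)
class GeneRank:
    gene_id: str
    chromosome: str
    rank: int  # 1-based among genes on the chromosome, sorted by start


@dataclass(frozen=True)
class CollinearBlock:
    block_id: int
    anchor_pairs: tuple  # ordered ((geneA, geneB), ...)
    chain_score: float

    def pairs(self) -> set:
        return {frozenset(p) for p in self.anchor_pairs}


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    duplicate_class: str  # 'tandem' | 'wgd_segmental' | 'dispersed'
    block_id: int | None = None


def _aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


def _identity_and_cols(alignment) -> tuple[float, int]:
    a, b = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    cols = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
    return (matches / cols if cols else 0.0), cols


def all_vs_all(
    proteins: dict[str, str],
    e_value_max: float = 1e-10,
    cross: dict[str, str] | None = None,
) -> list[SimilarityHit]:
    """Local-alignment similarity search.

    Within one protein set (``cross`` is None) each unordered pair is
    reported once and self-hits are excluded; with ``cross``, all pairs
    between the two sets are scanned.
    """
    if cross is None and len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    al = _aligner()
    db_residues = sum(map(len, (cross or proteins).values()))
    if cross is None:
        pairs = combinations(sorted(proteins), 2)
    else:
        pairs = ((q, s) for q in sorted(proteins) for s in sorted(cross))
    get_b = (cross or proteins).__getitem__
    hits: list[SimilarityHit] = []
    for qid, sid in pairs:
        qseq, sseq = proteins[qid], get_b(sid)
        score = al.score(qseq, sseq)
        ev = KA_K * len(qseq) * db_residues * math.exp(-KA_LAMBDA * score)
        if ev >= e_value_max:
            continue
        aln = al.align(qseq, sseq)[0]
        ident, cols = _identity_and_cols(aln)
        hits.append(
            SimilarityHit(
                query_id=qid,
                subject_id=sid,
                alignment_score=float(score),
                e_value=ev,
                identity_fraction=ident,
                coverage=cols / min(len(qseq), len(sseq)),
            )
        )
    hits.sort(key=lambda h: (h.e_value, h.query_id, h.subject_id))
    return hits


def gene_ranks(genes: list[GeneModel]) -> dict[str, GeneRank]:
    """1-based position of each gene among its chromosome's genes by start."""
    ranks: dict[str, GeneRank] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom, key=natural_chrom_key):
        for i, g in enumerate(sorted(by_chrom[chrom], key=lambda x: x.start), 1):
            ranks[g.gene_id] = GeneRank(g.gene_id, chrom, i)
    return ranks


def _chain_anchors(anchors, max_gap: int):
    """Best monotone chain (LIS-style DP) over anchors sorted by rank A.

    ``anchors`` is a list of (rank_a, rank_b, pair_index); both coordinates
    must strictly increase along a chain with per-step gaps <= max_gap.
    """
    anchors = sorted(anchors)
    n = len(anchors)
    best = [1] * n
    back = [-1] * n
    for i in range(n):
        ra, rb, _ = anchors[i]
        for j in range(i):
            qa, qb, _ = anchors[j]
            if 0 < ra - qa <= max_gap and 0 < rb - qb <= max_gap:
                if best[j] + 1 > best[i]:
                    best[i] = best[j] + 1
                    back[i] = j
    if not anchors:
        return [], []
    end = max(range(n), key=lambda i: best[i])
    chain = []
    i = end
    while i != -1:
        chain.append(anchors[i])
        i = back[i]
    chain.reverse()
    rest = [a for a in anchors if a not in chain]
    return chain, rest


def detect_collinear_blocks(
    anchors: list[SimilarityHit],
    ranks: dict[str, GeneRank],
    min_anchors: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Chain anchors in rank space into collinear blocks.

    Chains are extracted greedily (best chain first) per chromosome pair and
    orientation; a chain is kept if it has at least ``min_anchors`` anchors.
    """
    grouped: dict[tuple, list] = {}
    for idx, h in enumerate(anchors):
        if h.query_id not in ranks or h.subject_id not in ranks:
            raise KeyError(
                f"gene missing from rank table in hit {h.query_id}/{h.subject_id}"
            )
        ra, rb = ranks[h.query_id], ranks[h.subject_id]
        # orient the pair deterministically by chromosome then rank
        if (natural_chrom_key(ra.chromosome), ra.rank) <= (
            natural_chrom_key(rb.chromosome),
            rb.rank,
        ):
            key = (ra.chromosome, rb.chromosome)
            grouped.setdefault(key, []).append((ra.rank, rb.rank, idx))
        else:
            key = (rb.chromosome, ra.chromosome)
            grouped.setdefault(key, []).append((rb.rank, ra.rank, idx))

    blocks: list[CollinearBlock] = []
    bid = 0
    for key in sorted(grouped, key=lambda k: (natural_chrom_key(k[0]), natural_chrom_key(k[1]))):
        for orientation in (1, -1):
            pool = [(a, orientation * b, i) for a, b, i in grouped[key]]
            while True:
                chain, pool = _chain_anchors(pool, max_gap)
                if len(chain) < min_anchors:
                    break
                bid += 1
                pairs = []
                for _, _, idx in chain:
                    h = anchors[idx]
                    pairs.append((h.query_id, h.subject_id))
                blocks.append(
                    CollinearBlock(
                        block_id=bid,
                        anchor_pairs=tuple(pairs),
                        chain_score=float(len(chain)),
                    )
                )
    return blocks


def classify_duplicates(
    hits: list[SimilarityHit],
    ranks: dict[str, GeneRank],
    blocks: list[CollinearBlock],
) -> list[DuplicatePair]:
    """Apply the tandem / WGD-segmental rules with block priority.

    Block-anchored pairs are WGD/segmental regardless of adjacency; else a
    same-chromosome pair with rank difference 1 is tandem; everything else
    similar is dispersed.
    """
    in_block: dict[frozenset, int] = {}
    for blk in blocks:
        for p in blk.pairs():
            in_block.setdefault(p, blk.block_id)
    out: list[DuplicatePair] = []
    seen: set[frozenset] = set()
    for h in sorted(hits, key=lambda h: tuple(sorted((h.query_id, h.subject_id)))):
        pair = h.pair()
        if pair in seen or len(pair) < 2:
            continue
        seen.add(pair)
        a, b = sorted(pair)
        if a not in ranks or b not in ranks:
            raise KeyError(f"gene missing from rank table: {a}/{b}")
        ra, rb = ranks[a], ranks[b]
        if pair in in_block:
            out.append(DuplicatePair(a, b, "wgd_segmental", in_block[pair]))
        elif ra.chromosome == rb.chromosome and abs(ra.rank - rb.rank) == 1:
            out.append(DuplicatePair(a, b, "tandem"))
        else:
            out.append(DuplicatePair(a, b, "dispersed"))
    return out


def cscore(hits: list[SimilarityHit]) -> dict[frozenset, float]:
    """Score of each pair normalized by the best score of either gene."""
    best: dict[str, float] = {}
    for h in hits:
        best[h.query_id] = max(best.get(h.query_id, 0.0), h.alignment_score)
        best[h.subject_id] = max(best.get(h.subject_id, 0.0), h.alignment_score)
    return {
        h.pair(): h.alignment_score / max(best[h.query_id], best[h.subject_id])
        for h in hits
    }


def cross_species_synteny(
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    hits: list[SimilarityHit],
    cscore_min: float = 0.70,
    min_anchors: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Synteny between two genomes: cscore-filter anchors, then chain.

    Gene ids of the two genomes must be disjoint; ranks are computed per
    genome so rank coordinates never mix chromosomes across genomes.
    """
    ids_a = {g.gene_id for g in genes_a}
    ids_b = {g.gene_id for g in genes_b}
    if ids_a & ids_b:
        raise ValueError("gene ids of the two genomes must be disjoint")
    # prefix chromosome names so Chr1 of genome A never aliases Chr1 of B
    ranks = {
        gid: GeneRank(gid, f"A|{r.chromosome}", r.rank)
        for gid, r in gene_ranks(genes_a).items()
    }
    ranks.update(
        {
            gid: GeneRank(gid, f"B|{r.chromosome}", r.rank)
            for gid, r in gene_ranks(genes_b).items()
        }
    )
    scores = cscore(hits)
    kept = [h for h in hits if scores[h.pair()] >= cscore_min]
    return detect_collinear_blocks(kept, ranks, min_anchors=min_anchors, max_gap=max_gap)


def find_duplicates(
    genes: list[GeneModel],
    proteins: dict[str, str],
    e_value_max: float = 1e-10,
    min_anchors: int = 5,
    max_gap: int = 25,
    cscore_min: float = 0.70,
    anchor_coverage_min: float = 0.90,
    anchor_identity_min: float = 0.90,
) -> tuple[list[DuplicatePair], list[CollinearBlock], list[SimilarityHit]]:
    """One-call intra-genome duplicate analysis.

    Candidate synteny anchors are the similarity hits that pass the cscore
    cutoff AND align near full length (``anchor_coverage_min`` of the
    shorter protein) at high identity (``anchor_identity_min``). In a
    genome-wide gene family every member resembles every other through the
    shared signature domain: a domain-only hit has high identity but low
    coverage, and a hit stretched across the unrelated flanks has coverage
    but diluted identity, so the joint requirement keeps only the
    near-identical full-length paralog pairs that duplicated blocks are
    made of. Classification itself still sees every hit.
    """
    hits = all_vs_all(proteins, e_value_max=e_value_max)
    ranks = gene_ranks(genes)
    scores = cscore(hits)
    anchors = [
        h
        for h in hits
        if scores[h.pair()] >= cscore_min
        and h.coverage >= anchor_coverage_min
        and h.identity_fraction >= anchor_identity_min
    ]
    blocks = detect_collinear_blocks(
        anchors, ranks, min_anchors=min_anchors, max_gap=max_gap
    )
    return classify_duplicates(hits, ranks, blocks), blocks, hits
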