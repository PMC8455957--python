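"""Synthetic genomes with a planted gene family and a truth manifest.

The generator emulates the statistical structure the downstream stages are
designed to detect: family genes carrying a mutated copy of a seed domain,
decoy genes with background composition, tandem duplicate pairs adjacent in
gene order, segmentally duplicated blocks of consecutive genes copied to
another chromosome, promoters with planted heat-shock elements whose
presence is associated (at a configurable odds ratio) with an up-regulation
label, and a five-condition expression matrix with three archetypes
(heat-up, cold-up, control-up). Everything derives from one RNG seed, so a
given parameter set reproduces byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationParams
from .seqio import GeneModel, natural_chrom_key, reverse_complement

AA = "ACDEFGHIKLMNPQRSTVWY"
CONDITIONS = ("RTS", "DSS", "SSS", "HTS", "LTS")
N_REPLICATES = 3
GROUP_ARCHETYPE = {"I": "HTS", "II": "LTS", "III": "RTS"}
HSE_MODULES = {"GAA_first": "nGAAnnTTCnnGAAn", "TTC_first": "nTTCnnGAAnnTTCn"}

# Synthetic seed domain consensus: a hand-written, alpha-crystallin-domain-like
# sequence (not copied from any database entry) used as the family signature.
_BASE_DOMAIN = (
    "PSLFDPFSLDLWDPFEGFFTPSSALANARIDWKETPEAHVFKADLPGLKKEEVKVEVEDDRVLQISGERS"
    "KEHEEKNDKWHRVERSSGKFLRRFRLPENAKMDQVKASMENGVLTVTVPK"
)

_SYN_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "E": ["GAA", "GAG"], "Q": ["CAA", "CAG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA", "GTG"],
}
_STOPS = ["TAA", "TAG", "TGA"]


@dataclass
class TruthManifest:
    """Machine-readable ground truth for recovery tests."""

    family_gene_ids: list = field(default_factory=list)
    tandem_pairs: list = field(default_factory=list)       # [gene_a, gene_b]
    segmental_pairs: list = field(default_factory=list)    # [gene_a, gene_b]
    hse_positions: dict = field(default_factory=dict)      # gene -> [{offset,strand,module}]
    upregulated_ids: list = field(default_factory=list)
    group_labels: dict = field(default_factory=dict)       # gene -> I/II/III

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticGenome:
    genome: dict            # chrom -> sequence
    genes: list             # GeneModel, in genomic order
    proteins: dict          # gene_id -> protein sequence
    cds: dict               # gene_id -> CDS (with stop codon)
    manifest: TruthManifest


def default_seed_alignment(
    length: int = 90, n_seqs: int = 12, seed: int = 12345
) -> dict[str, str]:
    """A synthetic aligned domain family standing in for a curated seed
    alignment: diverged copies of the built-in consensus, with a small
    gapped region in a minority of rows."""
    base = (_BASE_DOMAIN * (length // len(_BASE_DOMAIN) + 1))[:length]
    rng = np.random.default_rng(seed)
    rows = {}
    for k in range(n_seqs):
        chars = list(base)
        for i in range(length):
            if rng.random() < 0.12:
                chars[i] = AA[rng.integers(0, 20)]
        if k < n_seqs // 4:  # minority gap run; columns stay match states
            g0 = length // 2
            chars[g0] = chars[g0 + 1] = "-"
        rows[f"seed{k + 1:02d}"] = "".join(chars)
    return rows


def alignment_consensus(alignment: dict[str, str] | list[str]) -> str:
    """Column-majority consensus, ignoring gaps."""
    rows = list(alignment.values()) if isinstance(alignment, dict) else list(alignment)
    ncol = len(rows[0])
    out = []
    for j in range(ncol):
        counts: dict[str, int] = {}
        for r in rows:
            a = r[j]
            if a in AA:
                counts[a] = counts.get(a, 0) + 1
        out.append(max(sorted(counts), key=counts.get) if counts else "A")
    return "".join(out)


def alignment_background(alignment: dict[str, str] | list[str]) -> np.ndarray:
    rows = list(alignment.values()) if isinstance(alignment, dict) else list(alignment)
    counts = np.ones(20)
    for r in rows:
        for a in r:
            if a in AA:
                counts[AA.index(a)] += 1
    return counts / counts.sum()


def _rand_protein(rng: np.random.Generator, length: int, background: np.ndarray) -> str:
    return "".join(AA[i] for i in rng.choice(20, size=length, p=background))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            choices = AA.replace(chars[i], "") if chars[i] in AA else AA
            chars[i] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def _encode_cds(protein: str, rng: np.random.Generator) -> str:
    codons = [_SYN_CODONS[a][rng.integers(0, len(_SYN_CODONS[a]))] for a in protein]
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def _derive_cds(
    base_cds: str, new_protein: str, rng: np.random.Generator, syn_rate: float = 0.05
) -> str:
    """CDS of a duplicate derived from its ancestor's CDS.

    Codons whose residue changed are re-encoded; unchanged codons receive a
    synonymous re-draw with probability ``syn_rate``, so duplicate pairs
    carry a realistic, unsaturated synonymous divergence (Ks of a recent
    duplication) rather than independent codon usage.
    """
    base_codons = [base_cds[i : i + 3] for i in range(0, len(base_cds) - 3, 3)]
    out = []
    for i, aa in enumerate(new_protein):
        choices = _SYN_CODONS[aa]
        if i < len(base_codons) and base_codons[i] in choices:
            codon = base_codons[i]
            if rng.random() < syn_rate:
                codon = choices[rng.integers(0, len(choices))]
        else:
            codon = choices[rng.integers(0, len(choices))]
        out.append(codon)
    stop = base_cds[-3:]
    if rng.random() < syn_rate:
        stop = _STOPS[rng.integers(0, 3)]
    out.append(stop)
    return "".join(out)


@dataclass
class _Member:
    kind: str       # 'family' or 'decoy'
    protein: str
    cds: str


@dataclass
class _Unit:
    """A run of genes placed consecutively on one chromosome."""

    members: list
    role: str                      # 'plain', 'tandem', 'source', 'copy'
    placed_ids: list = field(default_factory=list)
    partner: "object" = None       # for 'copy': its source unit


def _plan_segmental_blocks(n_pairs: int):
    """Split segmental pairs into blocks of <= 3 family genes, padded with
    enough decoy anchors that each copied block has >= 5 genes."""
    blocks = []
    remaining = n_pairs
    while remaining > 0:
        f = min(3, remaining)
        remaining -= f
        d = max(f + 1, 5 - f)
        blocks.append((f, d))
    return blocks


def generate_family_genome(
    params: SimulationParams, seed_alignment: dict[str, str] | None = None
) -> SyntheticGenome:
    """Generate the synthetic genome, annotations, sequences, and truth."""
    rng = np.random.default_rng(params.seed)
    if seed_alignment is None:
        seed_alignment = default_seed_alignment(length=params.domain_length_aa)
    domain = alignment_consensus(seed_alignment)[: params.domain_length_aa]
    background = alignment_background(seed_alignment)

    def _fresh_decoy() -> _Member:
        length = int(rng.integers(110, 300))
        prot = "M" + _rand_protein(rng, length, background)
        return _Member("decoy", prot, _encode_cds(prot, rng))

    # -- family base proteins; each tandem/segmental pair contributes one
    #    derived partner/copy, so bases + pairs = n_family_genes total
    n_bases = (
        params.n_family_genes - params.n_tandem_pairs - params.n_segmental_pairs
    )
    fam: list[tuple[str, int, int]] = []  # (protein, dom_start, dom_end) 0-based
    for _ in range(n_bases):
        nterm = _rand_protein(rng, int(rng.integers(25, 45)), background)
        cterm = _rand_protein(rng, int(rng.integers(8, 18)), background)
        dom = _mutate(domain, params.domain_mutation_rate, rng)
        prot = "M" + nterm + dom + cterm
        fam.append((prot, 1 + len(nterm), 1 + len(nterm) + len(dom)))

    def _fam_member(entry) -> _Member:
        return _Member("family", entry[0], _encode_cds(entry[0], rng))

    def _diverged_partner(entry, base: _Member, rate=0.04) -> _Member:
        prot, a, b = entry
        left = _mutate(prot[1:a], rate, rng)
        right = _mutate(prot[b:], rate, rng)
        partner = "M" + left + prot[a:b] + right
        return _Member("family", partner, _derive_cds(base.cds, partner, rng))

    fam_iter = iter(fam)

    # -- units (all sequences resolved up front so copies can be laid out
    #    before their sources without ordering hazards) --------------------
    units_by_chrom: list[list[_Unit]] = [[] for _ in range(params.n_chromosomes)]
    nchrom = params.n_chromosomes
    if nchrom < 1:
        raise ValueError("need at least one chromosome")
    counter = 0
    copy_units: list[_Unit] = []
    block_decoys = 0
    for f, d in _plan_segmental_blocks(params.n_segmental_pairs):
        members: list[_Member] = []
        fam_in_block = [_fam_member(next(fam_iter)) for _ in range(f)]
        block_decoys += d
        fi, di = 0, d
        while fi < len(fam_in_block) or di > 0:
            if di > 0:
                members.append(_fresh_decoy())
                di -= 1
            if fi < len(fam_in_block):
                members.append(fam_in_block[fi])
                fi += 1
        src = _Unit(members, "source")
        # the copied block carries synonymous-only divergence: proteins
        # stay identical (anchor detection unaffected) but Ks > 0
        copy_members = [
            _Member(m.kind, m.protein, _derive_cds(m.cds, m.protein, rng))
            for m in members
        ]
        cp = _Unit(copy_members, "copy", partner=src)
        copy_units.append(cp)
        c_src = counter % nchrom
        counter += 1
        c_cp = (c_src + 1) % nchrom if nchrom > 1 else c_src
        units_by_chrom[c_src].append(src)
        units_by_chrom[c_cp].append(cp)
    for _ in range(params.n_tandem_pairs):
        base = next(fam_iter)
        base_member = _fam_member(base)
        u = _Unit([base_member, _diverged_partner(base, base_member)], "tandem")
        units_by_chrom[counter % nchrom].append(u)
        counter += 1
    for entry in fam_iter:
        units_by_chrom[counter % nchrom].append(_Unit([_fam_member(entry)], "plain"))
        counter += 1

    # -- decoy budget ----------------------------------------------------
    separators = sum(max(0, len(cu) - 1) for cu in units_by_chrom)
    fillers = params.n_decoy_genes - (2 * block_decoys + separators)
    if fillers < 0:
        raise ValueError(
            "n_decoy_genes too small: the layout needs "
            f"{2 * block_decoys + separators} decoys (block anchors "
            f"{2 * block_decoys}, separators {separators}) but "
            f"n_decoy_genes={params.n_decoy_genes}"
        )

    # -- place genes ------------------------------------------------------
    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    manifest = TruthManifest()
    chrom_arrays: dict[str, np.ndarray] = {}
    gene_counter = 0

    def _place(chrom: str, member: _Member, start: int) -> GeneModel:
        nonlocal gene_counter
        gene_counter += 1
        gid = f"g{gene_counter:04d}"
        end = start + len(member.cds) - 1
        if end + 1700 > params.chromosome_length_bp:
            raise ValueError(
                f"infeasible packing: gene {gid} would end at {end} bp on "
                f"{chrom} but chromosome_length_bp={params.chromosome_length_bp}; "
                "increase chromosome_length_bp or reduce gene counts"
            )
        strand = "+-"[int(rng.integers(0, 2))]
        nt = member.cds if strand == "+" else reverse_complement(member.cds)
        chrom_arrays[chrom][start - 1 : end] = list(nt)
        g = GeneModel(gene_id=gid, chrom=chrom, start=start, end=end, strand=strand)
        genes.append(g)
        proteins[gid] = member.protein
        cds[gid] = member.cds
        if member.kind == "family":
            manifest.family_gene_ids.append(gid)
        return g

    alphabet = np.array(list("ACGT"))
    for c in range(nchrom):
        chrom = f"Chr{c + 1}"
        chrom_arrays[chrom] = alphabet[
            rng.integers(0, 4, size=params.chromosome_length_bp)
        ]
        cursor = 1701 + int(rng.integers(0, 200))
        for u_idx, unit in enumerate(units_by_chrom[c]):
            if u_idx > 0:
                # decoy separator keeps unrelated family genes from
                # becoming rank-adjacent
                g = _place(chrom, _fresh_decoy(), cursor)
                cursor = g.end + 3100 + int(rng.integers(0, 200))
            for member in unit.members:
                g = _place(chrom, member, cursor)
                cursor = g.end + 3100 + int(rng.integers(0, 200))
                unit.placed_ids.append(g.gene_id)
        n_fill = fillers // nchrom + (1 if c < fillers % nchrom else 0)
        for _ in range(n_fill):
            g = _place(chrom, _fresh_decoy(), cursor)
            cursor = g.end + 3100 + int(rng.integers(0, 200))

    # -- record duplicate-pair truth --------------------------------------
    for chrom_units in units_by_chrom:
        for unit in chrom_units:
            if unit.role == "tandem":
                manifest.tandem_pairs.append(list(unit.placed_ids))
    for cp in copy_units:
        src = cp.partner
        for m_idx, member in enumerate(cp.members):
            if member.kind == "family":
                manifest.segmental_pairs.append(
                    [src.placed_ids[m_idx], cp.placed_ids[m_idx]]
                )

    # -- promoters: plant HSEs -------------------------------------------
    for g in genes:
        if rng.random() >= params.hse_planting_rate:
            continue
        k = 1 if rng.random() < 0.7 else 2
        offsets: list[int] = []
        entries = []
        for _ in range(k):
            for _try in range(50):
                off = int(rng.integers(1, 1500 - 15 + 2))
                if all(abs(off - o) >= 15 for o in offsets):
                    break
            else:
                continue
            offsets.append(off)
            module = ("GAA_first", "TTC_first")[int(rng.integers(0, 2))]
            pat = HSE_MODULES[module]
            inst = "".join(
                "ACGT"[rng.integers(0, 4)] if ch == "n" else ch for ch in pat
            )
            _write_promoter_segment(chrom_arrays[g.chrom], g, off, inst)
            entries.append(
                {
                    "offset": off,
                    "strand": "+" if module == "GAA_first" else "-",
                    "module": module,
                }
            )
        if entries:
            manifest.hse_positions[g.gene_id] = sorted(
                entries, key=lambda e: e["offset"]
            )

    # -- up-regulation label (logistic association with HSE presence) -----
    p0 = params.upregulation_base_rate
    odds1 = params.hse_upregulation_odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    for gid in manifest.family_gene_ids:
        p = p1 if manifest.hse_positions.get(gid) else p0
        if rng.random() < p:
            manifest.upregulated_ids.append(gid)

    # -- expression group labels, coupled to the up-regulation label ------
    # Up-labeled genes preferentially receive the heat-up archetype (Group
    # I) while the marginal group proportions stay at group_proportions:
    # P(I|up)=a and P(I|not up)=b solve a*q + b*(1-q) = P(I) for the
    # marginal up-probability q implied by the planting rate and odds ratio.
    p_i, p_ii, p_iii = params.group_proportions
    q = params.hse_planting_rate * p1 + (1 - params.hse_planting_rate) * p0
    a_cond = min(0.9, p_i + 0.3)
    b_cond = (p_i - a_cond * q) / (1 - q) if q < 1 else p_i
    b_cond = min(max(b_cond, 0.02), 0.98)
    up_set = set(manifest.upregulated_ids)
    w_ii = p_ii / (p_ii + p_iii) if (p_ii + p_iii) > 0 else 0.5
    for gid in manifest.family_gene_ids:
        pi_gene = a_cond if gid in up_set else b_cond
        rest = 1.0 - pi_gene
        label = rng.choice(
            ["I", "II", "III"], p=[pi_gene, rest * w_ii, rest * (1 - w_ii)]
        )
        manifest.group_labels[gid] = str(label)

    genome = {c: "".join(a) for c, a in chrom_arrays.items()}
    genes.sort(key=lambda g: (natural_chrom_key(g.chrom), g.start))
    return SyntheticGenome(
        genome=genome, genes=genes, proteins=proteins, cds=cds, manifest=manifest
    )


def _write_promoter_segment(arr, gene: GeneModel, offset: int, segment: str) -> None:
    """Write ``segment`` at 1-based promoter ``offset`` of a 1500-bp window.

    For + strand genes the promoter is [start-1500, start-1] read forward;
    for - strand genes it is the reverse complement of [end+1, end+1500], so
    the segment goes in reverse-complemented.
    """
    if gene.strand == "+":
        g0 = gene.start - 1501 + offset  # 1-based genomic start of the segment
        arr[g0 - 1 : g0 - 1 + len(segment)] = list(segment)
    else:
        g0 = gene.end + 1501 - offset - len(segment) + 1
        arr[g0 - 1 : g0 - 1 + len(segment)] = list(reverse_complement(segment))


def generate_expression_matrix(
    manifest: TruthManifest, params: SimulationParams
) -> pd.DataFrame:
    """TPM matrix (family genes x condition_replicate columns).

    Log-scale abundances get an archetype boost at the group's signature
    condition (I: HTS, II: LTS, III: RTS) plus N(0, expression_noise_sd)
    replicate noise; each replicate column is then normalized to one million.
    """
    rng = np.random.default_rng([params.seed, 7])
    ids = list(manifest.family_gene_ids)
    if not ids:
        raise ValueError("manifest lists no family genes")
    base = rng.normal(3.0, 1.0, size=len(ids))
    boost = 2.0
    cols = [f"{c}_{r + 1}" for c in CONDITIONS for r in range(N_REPLICATES)]
    mat = np.zeros((len(ids), len(cols)))
    for ci, cond in enumerate(CONDITIONS):
        arch = np.array(
            [GROUP_ARCHETYPE[manifest.group_labels[g]] == cond for g in ids]
        )
        for r in range(N_REPLICATES):
            noise = rng.normal(0.0, params.expression_noise_sd, size=len(ids))
            logv = base + boost * arch + noise
            mat[:, ci * N_REPLICATES + r] = np.exp(logv)
    mat = mat / mat.sum(axis=0, keepdims=True) * 1e6
    return pd.DataFrame(mat, index=ids, columns=cols)


def draw_group_labels(
    ids: list[str], params: SimulationParams, rng: np.random.Generator
) -> dict[str, str]:
    """Multinomial group labels at the configured proportions (helper for
    label-recovery experiments that do not need a full genome)."""
    labels = rng.choice(["I", "II", "III"], size=len(ids),
                        p=list(params.group_proportions))
    return dict(zip(ids, labels.tolist()))
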