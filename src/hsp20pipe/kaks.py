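"""Codon-aware alignment and NG86 Ka/Ks estimation.

The estimator is the classical Nei-Gojobori (1986) counting method:
synonymous and non-synonymous site fractions per codon (averaged over the
two sequences), pathway-averaged difference counting for codons differing
at more than one position (substitution paths through stop codons are
excluded), and Jukes-Cantor multiple-hit correction of the proportions.
Ka/Ks > 1, = 1 and < 1 are read as positive, neutral and purifying
selection. Proportions at or beyond 0.74 are flagged saturated (the
correction's logarithm degenerates as p approaches 3/4) and yield an
undefined distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .seqio import translate_cds

SATURATION_P = 0.74


def _codon_table(table_id: int = 1) -> dict[str, str]:
    table = unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@dataclass(frozen=True)
class CodonAlignment:
    """A pair of gap-aligned CDS strings; gaps come in whole codons."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError("alignment length must be divisible by 3")
        for s in (self.seq_a, self.seq_b):
            for i in range(0, len(s), 3):
                codon = s[i : i + 3]
                if "-" in codon and codon != "---":
                    raise ValueError(f"gap not in whole-codon units at column {i}")

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Ungapped aligned codon pairs."""
        out = []
        for i in range(0, len(self.seq_a), 3):
            ca, cb = self.seq_a[i : i + 3], self.seq_b[i : i + 3]
            if "-" not in ca and "-" not in cb:
                out.append((ca, cb))
        return out


@dataclass(frozen=True)
class KaKsResult:
    ka: float | None
    ks: float | None
    ratio: float | None
    selection_class: str  # positive | neutral | purifying | undefined
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_differences: float = 0.0
    nonsyn_differences: float = 0.0


def _strip_stop(cds: str, code: dict[str, str]) -> str:
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if len(cds) >= 3 and code.get(cds[-3:].upper()) == "*":
        return cds[:-3]
    return cds


def align_proteins(prot_a: str, prot_b: str) -> tuple[str, str]:
    """Global protein alignment (BLOSUM62, affine gaps) as the codon guide."""
    al = PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    aln = al.align(prot_a, prot_b)[0]
    return str(aln[0]), str(aln[1])


def back_translate_alignment(
    protein_alignment: tuple[str, str], cds_a: str, cds_b: str, table_id: int = 1
) -> CodonAlignment:
    """Thread the two CDS onto a guiding protein alignment.

    Trailing stop codons are stripped first; each protein gap becomes a
    3-base gap. Translation of each CDS must match its ungapped protein row.
    """
    code = _codon_table(table_id)
    cds_a = _strip_stop(cds_a.upper(), code)
    cds_b = _strip_stop(cds_b.upper(), code)
    row_a, row_b = protein_alignment

    def _thread(row: str, cds: str, which: str) -> str:
        prot = row.replace("-", "")
        if len(cds) != 3 * len(prot):
            raise ValueError(
                f"CDS {which} has {len(cds) // 3} codons but the protein row "
                f"has {len(prot)} residues"
            )
        translated = translate_cds(cds + "TAA")  # re-add a stop for the helper
        for i, (res, obs) in enumerate(zip(prot, translated), 1):
            if res != obs:
                raise ValueError(
                    f"translation mismatch in {which} at residue {i}: "
                    f"alignment has {res!r}, CDS encodes {obs!r}"
                )
        out, k = [], 0
        for res in row:
            if res == "-":
                out.append("---")
            else:
                out.append(cds[3 * k : 3 * k + 3])
                k += 1
        return "".join(out)

    return CodonAlignment(_thread(row_a, cds_a, "sequence A"),
                          _thread(row_b, cds_b, "sequence B"))


def codon_site_counts(codon: str, code: dict[str, str]) -> tuple[float, float]:
    """(synonymous, non-synonymous) site fractions of one codon.

    At each position the synonymous fraction is taken over the single-base
    changes that do not create a stop codon; the two fractions sum to 3.
    """
    codon = codon.upper()
    syn = 0.0
    for pos in range(3):
        s, valid = 0, 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if code[alt] == "*":
                continue
            valid += 1
            if code[alt] == code[codon]:
                s += 1
        if valid:
            syn += s / valid
    return syn, 3.0 - syn


def codon_differences(ca: str, cb: str, code: dict[str, str]) -> tuple[float, float]:
    """Pathway-averaged (synonymous, non-synonymous) differences.

    All orderings of the differing positions are enumerated; paths passing
    through a stop codon are discarded (all paths are kept if every path
    hits a stop). Counts are averaged over the surviving paths.
    """
    ca, cb = ca.upper(), cb.upper()
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = ca
        s = n = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if code[nxt] == "*":
                ok = False
                break
            if code[nxt] == code[cur]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            paths.append((s, n))
    if not paths:  # every route passes a stop; fall back to all routes
        for order in permutations(diff_pos):
            cur = ca
            s = n = 0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if code.get(nxt, "*") == code.get(cur, "*"):
                    s += 1
                else:
                    n += 1
                cur = nxt
            paths.append((s, n))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 correction d = -3/4 ln(1 - 4p/3); None when saturated."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= SATURATION_P:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0  # +0.0 normalizes -0.0


def kaks_ng86(alignment: CodonAlignment, table_id: int = 1) -> KaKsResult:
    """NG86 Ka, Ks and their ratio on a codon alignment."""
    code = _codon_table(table_id)
    pairs = alignment.codon_pairs()
    if not pairs:
        return KaKsResult(None, None, None, "undefined")
    S = N = Sd = Nd = 0.0
    for ca, cb in pairs:
        sa, na = codon_site_counts(ca, code)
        sb, nb = codon_site_counts(cb, code)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = codon_differences(ca, cb, code)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    if ka is None or ks is None:
        return KaKsResult(ka, ks, None, "undefined", S, N, Sd, Nd)
    if ks == 0.0:
        return KaKsResult(ka, ks, None, "undefined", S, N, Sd, Nd)
    ratio = ka / ks
    if ratio > 1.0:
        cls = "positive"
    elif ratio < 1.0:
        cls = "purifying"
    else:
        cls = "neutral"
    return KaKsResult(ka, ks, ratio, cls, S, N, Sd, Nd)


def kaks_for_cds_pair(cds_a: str, cds_b: str, table_id: int = 1) -> KaKsResult:
    """Convenience: align the translations, back-translate, run NG86."""
    code = _codon_table(table_id)
    pa = translate_cds(_strip_stop(cds_a.upper(), code) + "TAA")
    pb = translate_cds(_strip_stop(cds_b.upper(), code) + "TAA")
    guide = align_proteins(pa, pb)
    return kaks_ng86(back_translate_alignment(guide, cds_a, cds_b, table_id))


def evolve_codon_pair(
    n_codons: int,
    omega: float,
    n_events: int,
    rng,
    table_id: int = 1,
) -> tuple[str, str]:
    """Simulate a diverged CDS pair under a crude omega model.

    From a random stop-free ancestor, each lineage receives ``n_events``
    proposed single-base changes at random positions; synonymous proposals
    are accepted with probability min(1, 1/omega), non-synonymous with
    min(1, omega), so the realized dN/dS tracks omega. Stops are rejected.
    """
    code = _codon_table(table_id)
    sense = sorted(c for c, aa in code.items() if aa != "*")
    ancestor = "".join(sense[rng.integers(0, len(sense))] for _ in range(n_codons))
    p_syn = min(1.0, 1.0 / omega)
    p_non = min(1.0, omega)

    def _branch(seq: str) -> str:
        chars = list(seq)
        for _ in range(n_events):
            i = int(rng.integers(0, len(chars)))
            old = chars[i]
            nt = "ACGT"[rng.integers(0, 4)]
            if nt == old:
                continue
            c0 = i - i % 3
            cur = "".join(chars[c0 : c0 + 3])
            new = cur[: i % 3] + nt + cur[i % 3 + 1 :]
            if code[new] == "*":
                continue
            accept = p_syn if code[new] == code[cur] else p_non
            if rng.random() < accept:
                chars[i] = nt
        return "".join(chars)

    return _branch(ancestor), _branch(ancestor)
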