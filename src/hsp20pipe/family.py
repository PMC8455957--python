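"""Family membership confirmation, filtering, and positional naming.

Candidates from the two-pass profile search are confirmed by a re-scan with
the profile (a single-tool stand-in for multi-database domain agreement),
gated on molecular weight — small heat-shock proteins fall in the 12-42 kDa
window, closed on both ends — and named with consecutive ordinals by
chromosomal position (chromosome in natural order, then start coordinate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .profile_hmm import ProfileModel, p_value, score_sequence
from .properties import isoelectric_point, molecular_weight
from .seqio import GeneModel, natural_chrom_key

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FamilyMember:
    gene_id: str
    assigned_name: str
    chromosome: str
    start_bp: int
    mw_kda: float
    pi: float
    aa_length: int


def confirm_and_filter(
    candidates: list[str],
    proteome: dict[str, str],
    profile: ProfileModel,
    gene_models: dict[str, GeneModel],
    mw_min_kda: float = 12.0,
    mw_max_kda: float = 42.0,
    confirm_e_value: float = 0.01,
    name_prefix: str = "HSP20",
) -> list[FamilyMember]:
    """Confirm candidates, apply the molecular-weight gate, assign names.

    Returns members named ``<prefix>-1 .. <prefix>-n`` in chromosomal order.
    The exclusion count is logged per filter.
    """
    missing = [c for c in candidates if c not in proteome]
    if missing:
        raise KeyError(f"candidates absent from proteome: {missing}")
    missing_models = [c for c in candidates if c not in gene_models]
    if missing_models:
        raise KeyError(f"candidates absent from gene models: {missing_models}")

    confirmed = []
    for cid in dict.fromkeys(candidates):  # de-duplicate, keep order
        seq = proteome[cid]
        score = score_sequence(profile, seq)
        ev = p_value(profile, score, len(seq)) * len(proteome)
        if ev < confirm_e_value:
            confirmed.append(cid)
    logger.info(
        "confirmation re-scan: %d of %d candidates retain the domain",
        len(confirmed), len(set(candidates)),
    )

    survivors = []
    for cid in confirmed:
        mw = round(molecular_weight(proteome[cid]), 2)
        if mw_min_kda <= mw <= mw_max_kda:
            survivors.append((cid, mw))
    logger.info(
        "molecular-weight gate [%g, %g] kDa excluded %d candidates",
        mw_min_kda, mw_max_kda, len(confirmed) - len(survivors),
    )

    survivors.sort(
        key=lambda t: (
            natural_chrom_key(gene_models[t[0]].chrom),
            gene_models[t[0]].start,
        )
    )
    members = []
    for ordinal, (cid, mw) in enumerate(survivors, start=1):
        g = gene_models[cid]
        members.append(
            FamilyMember(
                gene_id=cid,
                assigned_name=f"{name_prefix}-{ordinal}",
                chromosome=g.chrom,
                start_bp=g.start,
                mw_kda=mw,
                pi=round(isoelectric_point(proteome[cid]), 2),
                aa_length=len(proteome[cid]),
            )
        )
    return members
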