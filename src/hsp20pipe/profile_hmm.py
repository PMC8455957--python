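"""Profile search for the family signature domain.

A compact profile model in the Plan7 mould: match states with log-odds
emissions over the 20 residues, insert states emitting at background, delete
states, and local (glocal-free) alignment so the domain may sit anywhere
inside a protein. Scoring is exact Viterbi dynamic programming in bits.

Statistical significance follows the classical recipe for local-alignment
scores: optimal scores on unrelated sequences are Gumbel distributed, so the
null is fitted empirically (maximum likelihood) to scores of sequences drawn
from the background composition, and the E-value is the database-size-scaled
tail probability with a first-order length correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import gumbel_r

logger = logging.getLogger(__name__)

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
_NEG = -1e30

# Transition probabilities of the three-state architecture (log2 below).
_DEFAULT_TRANS = {
    "mm": 0.90, "mi": 0.05, "md": 0.05,
    "im": 0.40, "ii": 0.60,
    "dm": 0.40, "dd": 0.60,
}


@dataclass
class ProfileModel:
    """A calibrated profile over match/insert/delete states."""

    length: int
    match_probs: np.ndarray        # (L, 20) emission probabilities
    match_scores: np.ndarray       # (L, 20) log2-odds vs background
    background: np.ndarray         # (20,)
    transitions: dict = field(default_factory=lambda: dict(_DEFAULT_TRANS))
    calibration: tuple | None = None   # (loc, scale) of the Gumbel null fit
    calibration_length: int = 200
    calibration_n: int = 0

    def __post_init__(self) -> None:
        if self.length < 5:
            raise ValueError(f"profile length {self.length} < 5")
        sums = self.match_probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("match emission probabilities must sum to 1 per state")

    @property
    def consensus(self) -> str:
        return "".join(AA[i] for i in self.match_scores.argmax(axis=1))

    def log2_transitions(self) -> dict:
        return {k: float(np.log2(v)) for k, v in self.transitions.items()}


@dataclass(frozen=True)
class DomainHit:
    """One profile match on one protein (1-based closed envelope)."""

    protein_id: str
    bit_score: float
    e_value: float
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.bit_score):
            raise ValueError("bit_score must be finite")
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")
        if self.env_start < 1 or self.env_end < self.env_start:
            raise ValueError("invalid envelope")


def encode(seq: str) -> np.ndarray:
    """Map residues to indices; unknowns (X etc.) get a sentinel of -1."""
    return np.array([AA_INDEX.get(a, -1) for a in seq], dtype=np.int64)


def build_profile(
    alignment: Sequence[str] | dict[str, str],
    match_gap_fraction: float = 0.5,
    pseudocount: float = 2.0,
    transitions: dict | None = None,
) -> ProfileModel:
    """Estimate a profile from an aligned set of domain sequences.

    Columns with fewer than ``match_gap_fraction`` gaps become match states;
    the rest are treated as insertions (their residues contribute only to the
    background). Emissions are smoothed with background-proportional
    pseudocounts totalling ``pseudocount`` observations per state.
    """
    rows = list(alignment.values()) if isinstance(alignment, dict) else list(alignment)
    if not rows:
        raise ValueError("empty alignment")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("alignment rows have inconsistent lengths")
    rows = [r.upper() for r in rows]

    # Background: overall residue usage, lightly smoothed towards uniform.
    counts_total = np.ones(20)  # +1 uniform smoothing
    for r in rows:
        for a in r:
            if a in AA_INDEX:
                counts_total[AA_INDEX[a]] += 1
    background = counts_total / counts_total.sum()

    match_cols = []
    for j in range(ncol):
        col = [r[j] for r in rows]
        gaps = sum(1 for a in col if a not in AA_INDEX)
        if gaps / len(col) < match_gap_fraction:
            match_cols.append(j)
    if len(match_cols) < 5:
        raise ValueError(
            f"only {len(match_cols)} match columns; need >= 5 for a usable profile"
        )

    L = len(match_cols)
    probs = np.empty((L, 20))
    for k, j in enumerate(match_cols):
        c = np.zeros(20)
        for r in rows:
            a = r[j]
            if a in AA_INDEX:
                c[AA_INDEX[a]] += 1
        p = (c + pseudocount * background) / (c.sum() + pseudocount)
        probs[k] = p / p.sum()
    scores = np.log2(probs / background)
    return ProfileModel(
        length=L,
        match_probs=probs,
        match_scores=scores,
        background=background,
        transitions=dict(transitions or _DEFAULT_TRANS),
    )


def score_sequence(profile: ProfileModel, seq: str) -> float:
    """Optimal local alignment score of ``seq`` against the profile, in bits.

    Row-vectorized Viterbi: match/insert come from the previous row; delete
    is a within-row prefix-max over match scores (a geometric gap chain),
    computed with a running maximum.
    """
    x = encode(seq)
    n = x.size
    L = profile.length
    t = profile.log2_transitions()
    entry = -float(np.log2(L))  # uniform local entry over match states
    zero_emis = np.zeros(L)  # unknown residues score at background
    j_idx = np.arange(L)
    M = np.full(L, _NEG)
    I = np.full(L, _NEG)
    D = np.full(L, _NEG)
    best = _NEG
    tmm, tmi, tmd = t["mm"], t["mi"], t["md"]
    tim, tii = t["im"], t["ii"]
    tdm, tdd = t["dm"], t["dd"]
    for i in range(n):
        xi = x[i]
        e = profile.match_scores[:, xi] if xi >= 0 else zero_emis
        prev_diag_M = np.concatenate(([_NEG], M[:-1]))
        prev_diag_I = np.concatenate(([_NEG], I[:-1]))
        prev_diag_D = np.concatenate(([_NEG], D[:-1]))
        from_prev = np.maximum.reduce(
            [prev_diag_M + tmm, prev_diag_I + tim, prev_diag_D + tdm]
        )
        M_new = e + np.maximum(entry, from_prev)
        I_new = np.maximum(M + tmi, I + tii)
        # D_new[j] = max_{k<j} M_new[k] + tmd + (j-1-k) * tdd
        a = M_new + tmd - j_idx * tdd
        run = np.maximum.accumulate(a)
        D_new = np.concatenate(([_NEG], run[:-1] + (j_idx[1:] - 1) * tdd))
        M, I, D = M_new, I_new, D_new
        m = M.max()
        if m > best:
            best = m
    return float(best)


def score_with_traceback(profile: ProfileModel, seq: str):
    """Viterbi with full traceback.

    Returns ``(score_bits, env_start, env_end, match_row)`` where
    ``match_row`` is the hit rendered on the profile's match states (one
    character per state; '-' for deletions, inserts dropped) — i.e. one row
    of a profile-anchored alignment.
    """
    x = encode(seq)
    n = x.size
    L = profile.length
    t = profile.log2_transitions()
    entry = -float(np.log2(L))
    M = np.full((n + 1, L + 1), _NEG)
    I = np.full((n + 1, L + 1), _NEG)
    D = np.full((n + 1, L + 1), _NEG)
    ptr_M = np.zeros((n + 1, L + 1), dtype=np.int8)  # 0=entry 1=M 2=I 3=D
    ptr_I = np.zeros((n + 1, L + 1), dtype=np.int8)  # 1=M 2=I
    ptr_D = np.zeros((n + 1, L + 1), dtype=np.int8)  # 1=M 3=D
    best, best_ij = _NEG, (0, 0)
    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(1, L + 1):
            e = profile.match_scores[j - 1, xi] if xi >= 0 else 0.0
            cands = (
                entry,
                M[i - 1, j - 1] + t["mm"],
                I[i - 1, j - 1] + t["im"],
                D[i - 1, j - 1] + t["dm"],
            )
            k = int(np.argmax(cands))
            M[i, j] = e + cands[k]
            ptr_M[i, j] = k
            if M[i - 1, j] + t["mi"] >= I[i - 1, j] + t["ii"]:
                I[i, j] = M[i - 1, j] + t["mi"]
                ptr_I[i, j] = 1
            else:
                I[i, j] = I[i - 1, j] + t["ii"]
                ptr_I[i, j] = 2
            if M[i, j - 1] + t["md"] >= D[i, j - 1] + t["dd"]:
                D[i, j] = M[i, j - 1] + t["md"]
                ptr_D[i, j] = 1
            else:
                D[i, j] = D[i, j - 1] + t["dd"]
                ptr_D[i, j] = 3
            if M[i, j] > best:
                best, best_ij = M[i, j], (i, j)
    # traceback from the best match cell
    i, j = best_ij
    state = 1  # in M
    row = ["-"] * L
    env_end = i
    env_start = i
    while True:
        if state == 1:
            row[j - 1] = seq[i - 1]
            env_start = i
            k = ptr_M[i, j]
            i, j = i - 1, j - 1
            if k == 0:
                break
            state = k
        elif state == 2:
            state = ptr_I[i, j]
            i -= 1
        else:  # delete
            state = ptr_D[i, j]
            j -= 1
            if state == 1:
                state = 1
    return float(best), env_start, env_end, "".join(row)


def sample_background_sequence(rng: np.random.Generator, background: np.ndarray, length: int) -> str:
    idx = rng.choice(20, size=length, p=background)
    return "".join(AA[i] for i in idx)


def calibrate(
    profile: ProfileModel,
    rng: np.random.Generator,
    n_null: int = 500,
    null_length: int = 200,
) -> ProfileModel:
    """Fit the Gumbel null from scores of background-composition sequences."""
    if n_null < 200:
        raise ValueError("calibration requires >= 200 null scores")
    scores = np.array(
        [
            score_sequence(
                profile, sample_background_sequence(rng, profile.background, null_length)
            )
            for _ in range(n_null)
        ]
    )
    loc, scale = gumbel_r.fit(scores)
    return replace(
        profile,
        calibration=(float(loc), float(scale)),
        calibration_length=null_length,
        calibration_n=n_null,
    )


def p_value(profile: ProfileModel, bit_score: float, seq_length: int) -> float:
    """Per-sequence tail probability under the fitted null, length-corrected."""
    if profile.calibration is None:
        raise ValueError("profile is not calibrated; run calibrate() first")
    loc, scale = profile.calibration
    p = float(gumbel_r.sf(bit_score, loc, scale))
    p *= max(seq_length, 1) / profile.calibration_length
    return min(max(p, 1e-300), 1.0)


def search(
    profile: ProfileModel,
    proteome: dict[str, str],
    e_value_max: float | None = None,
    database_size: int | None = None,
) -> list[DomainHit]:
    """Scan a proteome; return hits sorted by E-value ascending.

    The E-value is the per-sequence tail probability scaled by the number of
    sequences searched (``database_size``, defaulting to the proteome size).
    Sequences shorter than 5 residues are skipped with a warning.
    """
    if database_size is None:
        database_size = len(proteome)
    hits: list[DomainHit] = []
    for pid, seq in proteome.items():
        if len(seq) < 5:
            logger.warning("skipping %s: length %d < 5", pid, len(seq))
            continue
        s = score_sequence(profile, seq)
        ev = p_value(profile, s, len(seq)) * database_size
        if e_value_max is not None and ev >= e_value_max:
            continue
        _, start, end, _ = score_with_traceback(profile, seq)
        hits.append(
            DomainHit(
                protein_id=pid,
                bit_score=s,
                e_value=max(ev, 1e-300),
                env_start=start,
                env_end=end,
            )
        )
    hits.sort(key=lambda h: (h.e_value, h.protein_id))
    return hits


def two_pass_search(
    seed_profile: ProfileModel,
    proteome: dict[str, str],
    rng: np.random.Generator,
    e_first: float = 0.01,
    e_strict: float = 1e-20,
    calibration_n: int = 500,
) -> list[str]:
    """Two-pass family search.

    Pass 1 scans with the seed profile at ``E < e_first``. Hit envelopes
    passing the stricter ``E < e_strict`` cut are re-rendered on the match
    states (a ready-made alignment) and used to train a species-specific
    profile; pass 2 re-scans with it at ``E < e_first``. The result is the
    de-duplicated union of both passes. If no hit survives the strict cut,
    pass 2 falls back to the seed profile with a warning.
    """
    if seed_profile.calibration is None:
        seed_profile = calibrate(seed_profile, rng, n_null=calibration_n)
    pass1 = search(seed_profile, proteome, e_value_max=e_first)
    strict = [h for h in pass1 if h.e_value < e_strict]
    if strict:
        rows = [
            score_with_traceback(seed_profile, proteome[h.protein_id])[3]
            for h in strict
        ]
        species_profile = build_profile(rows, transitions=seed_profile.transitions)
        species_profile = calibrate(species_profile, rng, n_null=calibration_n)
    else:
        logger.warning(
            "no pass-1 hit below E=%g; falling back to the seed profile", e_strict
        )
        species_profile = seed_profile
    pass2 = search(species_profile, proteome, e_value_max=e_first)
    seen: dict[str, None] = {}
    for h in pass1 + pass2:
        seen.setdefault(h.protein_id, None)
    return list(seen)
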