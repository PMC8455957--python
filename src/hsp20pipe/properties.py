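"""Physicochemical protein properties: length, molecular weight, pI.

Molecular weight uses average (isotope-abundance weighted) residue masses
plus one water, matching the kDa scale reported by the usual web calculators.
The isoelectric point is the pH at which the Henderson-Hasselbalch net charge
over the termini and ionizable side chains (D, E, C, Y, H, K, R) vanishes,
located by bisection on [0, 14]. The default pKa set is the Bjellqvist table
(the ExPASy convention), including residue-specific N-terminal pKa values;
an alternative table can be passed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

# Average residue (i.e. water-free) masses in Da.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153


@dataclass(frozen=True)
class PKaTable:
    """Ionization constants for the charge model.

    ``n_terminus`` maps the N-terminal residue to its amino-group pKa
    (``default_n`` when the residue has no specific value); acidic groups are
    negative above their pKa, basic groups positive below.
    """

    c_terminus: float = 3.55
    default_n: float = 7.5
    n_terminus: dict = None  # type: ignore[assignment]
    acidic: dict = None  # type: ignore[assignment]
    basic: dict = None  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(
            self,
            "n_terminus",
            self.n_terminus
            or {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7},
        )
        object.__setattr__(
            self, "acidic", self.acidic or {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
        )
        object.__setattr__(
            self, "basic", self.basic or {"H": 5.98, "K": 10.0, "R": 12.0}
        )


BJELLQVIST = PKaTable()


class AlphabetError(ValueError):
    """A sequence letter outside the 20-residue alphabet."""


class FrameError(ValueError):
    """A CDS length incompatible with a single open reading frame."""


def _check_alphabet(sequence: str) -> None:
    for pos, aa in enumerate(sequence, start=1):
        if aa not in AVERAGE_RESIDUE_MASS:
            raise AlphabetError(
                f"non-standard residue {aa!r} at position {pos}"
            )


def protein_length_from_cds(cds_length_bp: int) -> int:
    """Residue count implied by a CDS length: one codon per residue plus stop."""
    if cds_length_bp < 6 or cds_length_bp % 3 != 0:
        raise FrameError(
            f"CDS length {cds_length_bp} bp is not a stop-terminated reading frame "
            "(need >= 6 and divisible by 3)"
        )
    return cds_length_bp // 3 - 1


def molecular_weight(sequence: str, kda: bool = True) -> float:
    """Average-mass molecular weight of a peptide (one water for the chain)."""
    if not sequence:
        raise ValueError("empty sequence")
    _check_alphabet(sequence)
    mass = sum(AVERAGE_RESIDUE_MASS[aa] for aa in sequence) + WATER_MASS
    return mass / 1000.0 if kda else mass


def net_charge(sequence: str, ph: float, pka: PKaTable = BJELLQVIST) -> float:
    """Henderson-Hasselbalch net charge at the given pH."""
    if not sequence:
        raise ValueError("empty sequence")
    _check_alphabet(sequence)
    pos = 1.0 / (1.0 + 10 ** (ph - pka.n_terminus.get(sequence[0], pka.default_n)))
    neg = 1.0 / (1.0 + 10 ** (pka.c_terminus - ph))
    for aa in sequence:
        if aa in pka.basic:
            pos += 1.0 / (1.0 + 10 ** (ph - pka.basic[aa]))
        elif aa in pka.acidic:
            neg += 1.0 / (1.0 + 10 ** (pka.acidic[aa] - ph))
    return pos - neg


def isoelectric_point(
    sequence: str,
    pka: PKaTable = BJELLQVIST,
    tol: float = 1e-4,
    max_iter: int = 60,
) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, positive at pH 0 and
    negative at pH 14, so the root exists and bisection cannot fail.
    """
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
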