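"""Elemental carbon/nitrogen accounting for predicted proteomes.

Nitrogen-limited selection can shift proteome composition away from
nitrogen-rich side chains (Arg, His, Lys, ...), raising the bulk
carbon-to-nitrogen atom ratio.  We count C and N atoms per residue using
the free amino acid formulas: peptide-bond condensation removes only H2O,
so per-residue C and N counts in a chain are identical to the free form and
no terminal correction is needed.

Selenocysteine (U) and pyrrolysine (O) are counted; the ambiguity codes
X, B, Z and J are skipped and tallied rather than guessed.  Stop symbols
(``*``) are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import InputError

# residue -> (carbon, nitrogen) atoms of the free amino acid
ATOM_COUNTS: dict[str, tuple[int, int]] = {
    "A": (3, 1),   # alanine C3H7NO2
    "R": (6, 4),   # arginine C6H14N4O2
    "N": (4, 2),   # asparagine C4H8N2O3
    "D": (4, 1),   # aspartate C4H7NO4
    "C": (3, 1),   # cysteine C3H7NO2S
    "E": (5, 1),   # glutamate C5H9NO4
    "Q": (5, 2),   # glutamine C5H10N2O3
    "G": (2, 1),   # glycine C2H5NO2
    "H": (6, 3),   # histidine C6H9N3O2
    "I": (6, 1),   # isoleucine C6H13NO2
    "L": (6, 1),   # leucine C6H13NO2
    "K": (6, 2),   # lysine C6H14N2O2
    "M": (5, 1),   # methionine C5H11NO2S
    "F": (9, 1),   # phenylalanine C9H11NO2
    "P": (5, 1),   # proline C5H9NO2
    "S": (3, 1),   # serine C3H7NO3
    "T": (4, 1),   # threonine C4H9NO3
    "W": (11, 2),  # tryptophan C11H12N2O2
    "Y": (9, 1),   # tyrosine C9H11NO3
    "V": (5, 1),   # valine C5H11NO2
    "U": (3, 1),   # selenocysteine C3H7NO2Se
    "O": (12, 3),  # pyrrolysine C12H21N3O3
}

AMBIGUOUS = frozenset("XBZJ")


@dataclass(frozen=True)
class ProteomeCn:
    genome_id: str
    total_carbon: int
    total_nitrogen: int
    cn_ratio: float
    skipped_residues: int


def residue_atoms(residue: str) -> tuple[int, int]:
    """(carbon, nitrogen) for a one-letter residue code.

    Raises :class:`InputError` for non-alphabetic input; returns ``None``-free
    counts for the 20 standard residues plus U and O.  Ambiguity codes are
    reported as non-countable via a :class:`KeyError`-like error.
    """
    if len(residue) != 1 or not residue.isalpha():
        raise InputError(f"not a one-letter residue code: {residue!r}")
    code = residue.upper()
    if code in AMBIGUOUS:
        raise InputError(f"residue {code!r} is ambiguous (non-countable)")
    try:
        return ATOM_COUNTS[code]
    except KeyError:
        raise InputError(f"unknown residue code {code!r}") from None


def proteome_cn_ratio(
    proteins: Iterable[str], genome_id: str = ""
) -> ProteomeCn:
    """Total C and N atoms over a proteome and their ratio.

    Ambiguous residues are skipped and counted in ``skipped_residues``;
    stop symbols are ignored.  Raises if no residue is countable.
    """
    carbon = nitrogen = skipped = 0
    for seq in proteins:
        for ch in seq.upper():
            if ch == "*":
                continue
            counts = ATOM_COUNTS.get(ch)
            if counts is None:
                skipped += 1
                continue
            carbon += counts[0]
            nitrogen += counts[1]
    if nitrogen == 0:
        raise InputError(
            f"proteome {genome_id!r}: zero countable residues"
        )
    return ProteomeCn(
        genome_id=genome_id,
        total_carbon=carbon,
        total_nitrogen=nitrogen,
        cn_ratio=carbon / nitrogen,
        skipped_residues=skipped,
    )
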