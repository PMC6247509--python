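"""IUPAC nucleotide alphabet: base sets, complements, expansion, consensus codes.

Every degenerate code denotes a set of concrete bases; matching, GC weighting
and degeneracy all derive from these sets.  Inosine (I) is carried as an extra
letter: it pairs with every base when matching, contributes nothing to the G+C
count, and encodes a single concrete nucleotide (degeneracy 1).
"""

from __future__ import annotations

# code -> set of concrete bases it can stand for (matching semantics)
BASE_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "I": frozenset("ACGT"),  # universal-pairing base
}

COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N", "I": "I",
}

# expected G+C contribution of each code (fraction of its base set that is G/C)
GC_WEIGHT: dict[str, float] = {
    "A": 0.0, "T": 0.0, "W": 0.0,
    "G": 1.0, "C": 1.0, "S": 1.0,
    "R": 0.5, "Y": 0.5, "K": 0.5, "M": 0.5, "N": 0.5,
    "B": 2 / 3, "V": 2 / 3,
    "D": 1 / 3, "H": 1 / 3,
    "I": 0.0,  # inosine: weak pairing, no G+C contribution
}

# number of concrete sequences the code encodes; I is one physical base
DEGENERACY: dict[str, int] = {c: len(s) for c, s in BASE_SETS.items()}
DEGENERACY["I"] = 1

# frozen base set -> minimal IUPAC code (I excluded: it is not a set code)
_SET_TO_CODE: dict[frozenset[str], str] = {
    s: c for c, s in BASE_SETS.items() if c != "I"
}

# 4-bit masks for fast set-intersection matching (A=1, C=2, G=4, T=8)
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
BITMASK: dict[str, int] = {
    c: sum(_BIT[b] for b in s) for c, s in BASE_SETS.items()
}


class InvalidNucleotideError(ValueError):
    """A character outside the IUPAC alphabet, reported with its position."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position  # 1-based
        super().__init__(
            f"invalid nucleotide {char!r} at position {position}"
        )


def normalize(sequence: str) -> str:
    """Uppercase, fold U to T, and validate against the IUPAC alphabet."""
    seq = sequence.upper().replace("U", "T")
    for i, c in enumerate(seq):
        if c not in BASE_SETS:
            raise InvalidNucleotideError(c, i + 1)
    return seq


def complement_code(code: str) -> str:
    return COMPLEMENT[code]


def code_for_set(bases: frozenset[str]) -> str:
    """Minimal IUPAC code for a non-empty set of concrete bases."""
    try:
        return _SET_TO_CODE[frozenset(bases)]
    except KeyError:
        raise ValueError(f"not a concrete base set: {sorted(bases)}") from None


def expand(sequence: str) -> list[str]:
    """All concrete sequences a degenerate oligo encodes.

    Inosine is kept as-is (a single physical base), so the expansion size
    equals :func:`mycoprimer.oligo.degeneracy`.
    """
    seq = normalize(sequence)
    variants = [""]
    for c in seq:
        options = [c] if c == "I" else sorted(BASE_SETS[c])
        variants = [v + b for v in variants for b in options]
    return variants
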