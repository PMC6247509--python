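"""Oligonucleotide properties: GC content, melting temperature, degeneracy,
reverse complement, and standardized naming on the reference coordinate system.

Melting temperatures follow the OligoCalc composition formulas: the Wallace
rule for short oligos (< 14 nt), and for longer ones

    basic:          Tm = 64.9 + 41 * (nGC - 16.4) / N
    salt-adjusted:  Tm = 100.5 + 41 * nGC / N - 820 / N + 16.6 * log10([Na+])

with nGC the (ambiguity-weighted) G+C count and N the length.  Reported Tm is
rounded to 0.1 degC; comparisons elsewhere use the unrounded value.

Primer names follow the Gargas & DePriest nomenclature: position on the
Saccharomyces cerevisiae 18S rRNA gene (acc. Z75578), zero-padded to four
digits, with a 5'/3' orientation suffix and an optional length suffix used to
disambiguate primers sharing a position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from .iupac import (
    COMPLEMENT,
    DEGENERACY,
    GC_WEIGHT,
    normalize,
)

Orientation = Literal["forward", "reverse"]

PRIME_5 = "5′"
PRIME_3 = "3′"


@dataclass(frozen=True)
class TmParams:
    """Melting-temperature settings.

    sodium_molar: monovalent cation concentration in mol/L (OligoCalc
    default 0.05 M); only the salt-adjusted formula uses it.
    """

    sodium_molar: float = 0.05
    method: Literal["basic", "salt_adjusted"] = "basic"

    def __post_init__(self) -> None:
        if self.sodium_molar <= 0:
            raise ValueError("sodium_molar must be > 0")


def gc_content(sequence: str) -> float:
    """Weighted G+C fraction; ambiguity codes contribute their expected
    G+C share (S=1, W=0, R/Y/K/M/N=0.5, B/V=2/3, D/H=1/3, I=0)."""
    seq = normalize(sequence)
    if not seq:
        raise ValueError("empty sequence")
    return sum(GC_WEIGHT[c] for c in seq) / len(seq)


def gc_count(sequence: str) -> float:
    """Weighted G+C count (not fraction)."""
    seq = normalize(sequence)
    if not seq:
        raise ValueError("empty sequence")
    return sum(GC_WEIGHT[c] for c in seq)


def melting_temperature(
    sequence: str, params: TmParams | None = None
) -> float:
    """Unrounded Tm in degC under the OligoCalc composition formulas."""
    params = params or TmParams()
    seq = normalize(sequence)
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    ngc = sum(GC_WEIGHT[c] for c in seq)
    nat = n - ngc
    if n < 14:
        # Wallace rule; the salt-adjusted short form rescales from the
        # 50 mM reference condition
        tm = 2.0 * nat + 4.0 * ngc
        if params.method == "salt_adjusted":
            tm += 16.6 * math.log10(params.sodium_molar) - 16.6 * math.log10(0.05)
        return tm
    if params.method == "basic":
        return 64.9 + 41.0 * (ngc - 16.4) / n
    return 100.5 + 41.0 * ngc / n - 820.0 / n + 16.6 * math.log10(params.sodium_molar)


def round_tm(tm: float) -> float:
    """Reporting convention: 0.1 degC."""
    return round(tm, 1)


def reverse_complement(sequence: str) -> str:
    seq = normalize(sequence)
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def degeneracy(sequence: str) -> int:
    """Number of concrete sequences the oligo encodes (product of
    per-position base-set sizes; inosine counts 1)."""
    seq = normalize(sequence)
    d = 1
    for c in seq:
        d *= DEGENERACY[c]
    return d


def standard_name(
    ref_position: int,
    orientation: Orientation,
    length: int | None = None,
    needs_length_suffix: bool = False,
) -> str:
    """Gargas & DePriest-style name, e.g. 'nu-SSU-1333-5′' or
    'nu-SSU-0817-5′-24'."""
    if ref_position < 1:
        raise ValueError("ref_position must be >= 1")
    suffix = PRIME_5 if orientation == "forward" else PRIME_3
    name = f"nu-SSU-{ref_position:04d}-{suffix}"
    if needs_length_suffix:
        if length is None:
            raise ValueError("length required for length suffix")
        name += f"-{length}"
    return name


@dataclass
class Oligo:
    """A primer or probe with derived physical properties.

    ref_position is the reference coordinate of the oligo's 5' terminus in
    its own sense: for forward primers the leftmost plus-strand coordinate
    of the annealing site, for reverse primers the rightmost.
    """

    name: str
    sequence: str
    orientation: Orientation = "forward"
    ref_position: int | None = None
    _tm_params: TmParams = field(default_factory=TmParams, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence)
        if not self.sequence:
            raise ValueError(f"oligo {self.name!r}: empty sequence")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(
                f"oligo {self.name!r}: orientation must be forward|reverse"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)

    @property
    def tm_basic(self) -> float:
        return melting_temperature(self.sequence, TmParams(method="basic"))

    @property
    def tm_salt(self) -> float:
        return melting_temperature(
            self.sequence,
            TmParams(sodium_molar=self._tm_params.sodium_molar, method="salt_adjusted"),
        )

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.sequence)

    def standard_name(self, needs_length_suffix: bool = False) -> str:
        if self.ref_position is None:
            raise ValueError(f"oligo {self.name!r}: no reference position")
        return standard_name(
            self.ref_position, self.orientation, self.length, needs_length_suffix
        )
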