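"""Conserved-word primer discovery with quorum parameters, candidate-pair
filters, barcode coverage/specificity metrics, and degenerate-consensus
construction.

The word search is quorum-driven, in the style of conserved-word primer
design tools: a word of permitted length is a candidate when it occurs
exactly in at least ``strict_quorum`` of the target records, matches (within
the design mismatch allowance) at least ``sensitivity_quorum`` of them, and
matches at most ``false_positive_quorum`` of the outgroup records.
Enumeration is exhaustive over the target records; desk-scale databases do
not need suffix-structure optimization.

Barcode metrics: Bc is the proportion of target species amplified in silico;
Bs the proportion of amplified species whose (dereplicated) insert set is
disjoint from every other species' inserts, i.e. unambiguously identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .iupac import BASE_SETS, code_for_set, normalize
from .oligo import Oligo
from .pairs import PrimerPair
from .pcr import DEFAULT_LENGTH_BOUNDS, amplify, find_binding_sites
from .reference import ReferenceRecord


class DesignError(ValueError):
    pass


@dataclass
class DesignParams:
    """Design-time knobs.

    The quorum defaults sit inside the published exploration ranges
    (0.5-0.8 sensitivity and strict, 0.1-0.3 false positive); they are
    configuration, not claims.
    """

    sensitivity_quorum: float = 0.7
    strict_quorum: float = 0.7
    false_positive_quorum: float = 0.2
    min_length: int = 18
    max_length: int = 21
    max_amplicon: int = 600
    max_pair_tm_diff: float = 10.0
    max_coamplification: float = 0.20
    design_mismatch_allowance: int = 2

    def __post_init__(self) -> None:
        for name in ("sensitivity_quorum", "strict_quorum", "false_positive_quorum"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DesignError(f"{name} must be in [0,1], got {v}")
        if not (10 <= self.min_length <= self.max_length <= 40):
            raise DesignError("primer length interval must lie within [10, 40]")


@dataclass(frozen=True)
class BarcodeMetrics:
    Bc: float
    Bs: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.Bc <= 1.0 and 0.0 <= self.Bs <= 1.0):
            raise DesignError("Bc and Bs must be fractions in [0,1]")


@dataclass
class DesignCandidate:
    """A candidate pair with the annotations the design filters consume."""

    pair: PrimerPair
    all_groups_targeted: bool
    co_amplification: float
    amplicon_nt: int
    # per-primer specificity: the member's own outgroup match rate;
    # lower is more specific
    fwd_coamp: float = 0.0
    rev_coamp: float = 0.0
    metrics: BarcodeMetrics | None = None


def _word_occurs_exact(word: str, sequence: str) -> bool:
    return word in sequence


def _word_occurs_fuzzy(word: str, record: ReferenceRecord, allowance: int) -> bool:
    return bool(find_binding_sites(word, record, allowance, orientation="forward"))


def find_conserved_words(
    targets: Sequence[ReferenceRecord],
    params: DesignParams | None = None,
    outgroup: Sequence[ReferenceRecord] = (),
) -> list[Oligo]:
    """Candidate primer words satisfying the three quorums.

    Exhaustive: every word of permitted length occurring in any target
    record is tested.  Quorum comparisons are inclusive (>= for the target
    quorums, a word is discarded when its outgroup rate exceeds the false
    positive quorum).  Deterministic output order: by length then sequence.
    """
    params = params or DesignParams()
    if not targets:
        raise DesignError("empty target set")
    n = len(targets)
    out: list[Oligo] = []
    for length in range(params.min_length, params.max_length + 1):
        # exact occurrence counts via per-record word sets
        counts: dict[str, int] = {}
        for rec in targets:
            seen = {
                rec.sequence[i:i + length]
                for i in range(len(rec.sequence) - length + 1)
            }
            for w in seen:
                counts[w] = counts.get(w, 0) + 1
        for word in sorted(w for w, c in counts.items() if c / n >= params.strict_quorum):
            fuzzy = sum(
                _word_occurs_fuzzy(word, rec, params.design_mismatch_allowance)
                for rec in targets
            )
            if fuzzy / n < params.sensitivity_quorum:
                continue
            if outgroup:
                fp = sum(
                    _word_occurs_fuzzy(word, rec, params.design_mismatch_allowance)
                    for rec in outgroup
                )
                if fp / len(outgroup) > params.false_positive_quorum:
                    continue
            out.append(Oligo(name=f"w{length}_{word}", sequence=word))
    return out


def apply_design_filters(
    candidates: Sequence[DesignCandidate],
    params: DesignParams | None = None,
) -> list[DesignCandidate]:
    """Conjunctive filters: (i) all fungal groups targeted, (ii)
    co-amplification within bound, (iii) amplicon <= 600 nt, (iv) primer
    lengths in [18, 21], (v) the more specific member of the pair has the
    lower Tm, (vi) Tm difference <= 10 degC."""
    params = params or DesignParams()
    out = []
    for cand in candidates:
        fwd, rev = cand.pair.forward, cand.pair.reverse
        if not cand.all_groups_targeted:
            continue
        if cand.co_amplification > params.max_coamplification:
            continue
        if cand.amplicon_nt > params.max_amplicon:
            continue
        if not (
            params.min_length <= fwd.length <= params.max_length
            and params.min_length <= rev.length <= params.max_length
        ):
            continue
        # (v): specificity = the member's own outgroup match rate; the more
        # specific member (strictly lower rate) must have the lower Tm
        if cand.fwd_coamp < cand.rev_coamp and fwd.tm_basic > rev.tm_basic:
            continue
        if cand.rev_coamp < cand.fwd_coamp and rev.tm_basic > fwd.tm_basic:
            continue
        if abs(fwd.tm_basic - rev.tm_basic) > params.max_pair_tm_diff:
            continue
        out.append(cand)
    return out


def barcode_metrics(
    pair: PrimerPair,
    targets: Sequence[ReferenceRecord],
    max_mismatch: int = 1,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> BarcodeMetrics:
    """Bc and Bs for a pair over a species-labelled target set.

    A species is amplified when any of its records yields an amplicon; its
    barcode is the dereplicated set of inserts (primer footprints excluded).
    Bs counts species whose insert set is disjoint from every other
    amplified species' set, over amplified species; Bs = 0 when nothing
    amplifies (documented convention).
    """
    if not targets:
        raise DesignError("empty target set")
    species_inserts: dict[str, set[str]] = {}
    all_species: set[str] = set()
    for rec in targets:
        if not rec.taxonomy:
            raise DesignError(f"record {rec.id!r} lacks a species label")
        all_species.add(rec.species)
        for amp in amplify(pair, rec, max_mismatch, length_bounds):
            species_inserts.setdefault(rec.species, set()).add(amp.insert)
    amplified = sorted(species_inserts)
    bc = len(amplified) / len(all_species)
    if not amplified:
        return BarcodeMetrics(Bc=0.0, Bs=0.0)
    unambiguous = 0
    for sp in amplified:
        others = set().union(
            *(species_inserts[o] for o in amplified if o != sp)
        ) if len(amplified) > 1 else set()
        if not (species_inserts[sp] & others):
            unambiguous += 1
    return BarcodeMetrics(Bc=bc, Bs=unambiguous / len(amplified))


def consensus_primer(variants: Sequence[str]) -> str:
    """Position-wise union of observed bases as minimal IUPAC codes.

    The result matches every input variant with zero mismatches; building it
    from the matched variants of a primer is how coverage of target groups
    is widened with degenerate positions.
    """
    if not variants:
        raise DesignError("no variants")
    seqs = [normalize(v) for v in variants]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise DesignError("variants must all have the same length")
    out = []
    for i in range(length):
        union = frozenset().union(*(BASE_SETS[s[i]] for s in seqs))
        out.append(code_for_set(union))
    return "".join(out)
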