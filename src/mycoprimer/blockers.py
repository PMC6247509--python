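"""Annealing blocking-oligonucleotide design.

A blocking oligo is a 3'-modified oligo (non-extendable, e.g. a C3 spacer)
that overlaps the primer annealing site of co-amplified non-target taxa and
competes for annealing.  The design algorithm: amplify the database with the
primer pair keeping the template bases under both primer footprints, split
the amplicons by taxonomic group and dereplicate, enumerate every 18-25-mer
from the target group's amplicons that overlaps a primer footprint by at
least 3 nt, then select the candidate with the best exact-match coverage of
the target group subject to a cap on cumulative fungal coverage and a Tm
within tolerance of the competing primer.

The blocker is built in the same sense as the competing primer, since it
competes for that primer's annealing site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .iupac import BITMASK
from .oligo import Oligo, reverse_complement
from .pairs import PrimerPair
from .pcr import DEFAULT_LENGTH_BOUNDS, amplify
from .reference import ReferenceDB, ReferenceRecord


class BlockerDesignError(ValueError):
    pass


@dataclass
class BlockerParams:
    k_min: int = 18
    k_max: int = 25
    min_primer_overlap: int = 3
    tm_tolerance: float = 2.0  # degC around the competing primer's Tm
    fungal_coverage_cap: float = 0.01
    selection_mismatch: int = 0  # coverage here is strict exact matching
    three_prime_mod: str = "C3 spacer"

    def __post_init__(self) -> None:
        if not (10 <= self.k_min <= self.k_max <= 40):
            raise BlockerDesignError("k range must lie within [10, 40]")
        if self.min_primer_overlap < 1:
            raise BlockerDesignError("min_primer_overlap must be >= 1")


@dataclass(frozen=True)
class BlockerCandidate:
    sequence: str
    footprint_overlap: int  # positions shared with the primer footprint
    overlap_nt: int  # identical aligned positions with the primer


@dataclass
class BlockingOligo:
    sequence: str
    target_group: str
    competing_primer: str
    overlap_nt: int
    tm: float
    target_coverage: float
    fungal_cumulative_coverage: float
    per_group_offtarget: dict[str, float] = field(default_factory=dict)
    three_prime_mod: str = "C3 spacer"

    @property
    def length(self) -> int:
        return len(self.sequence)


def _group_key(rec: ReferenceRecord) -> str:
    if rec.is_fungal:
        return rec.phylum or "Fungi"
    return rec.outgroup or "unclassified_eukaryote"


def amplify_with_flanks(
    pair: PrimerPair,
    db: ReferenceDB,
    max_mismatch_per_primer: int = 1,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> dict[str, list[str]]:
    """Amplicon sequences (template bases under both primer footprints
    included) keyed by taxonomic group, dereplicated within each group.

    Group keys are exactly the groups with at least one amplicon; no
    amplification anywhere yields an empty mapping.
    """
    grouped: dict[str, list[str]] = {}
    seen: dict[str, set[str]] = {}
    for rec in db:
        for amp in amplify(pair, rec, max_mismatch_per_primer, length_bounds):
            key = _group_key(rec)
            if amp.sequence in seen.setdefault(key, set()):
                continue
            seen[key].add(amp.sequence)
            grouped.setdefault(key, []).append(amp.sequence)
    return grouped


def _shared_identical(
    blocker: str, start: int, primer: Oligo, footprint: tuple[int, int]
) -> int:
    """Identical aligned positions between blocker and primer over the
    footprint interval; degenerate/inosine primer positions count when the
    base sets intersect (they pair)."""
    f1, f2 = footprint
    shared = 0
    for pos in range(max(start, f1), min(start + len(blocker) - 1, f2) + 1):
        b = blocker[pos - start]
        p = primer.sequence[pos - f1]
        if BITMASK[b] & BITMASK[p]:
            shared += 1
    return shared


def enumerate_blocker_candidates(
    amplicons: Sequence[str],
    primer_footprint: tuple[int, int],
    params: BlockerParams | None = None,
    primer: Oligo | None = None,
) -> list[BlockerCandidate]:
    """All k-mers (k in [k_min, k_max]) from the group's amplicons, in the
    competing primer's sense, overlapping the primer footprint by at least
    ``min_primer_overlap`` positions; duplicate sequences collapsed (the
    placement with the largest footprint overlap is kept).

    The amplicons must already be oriented in the competing primer's sense
    and ``primer_footprint`` given 1-based in those coordinates.
    """
    params = params or BlockerParams()
    f1, f2 = primer_footprint
    if f1 < 1 or f2 < f1:
        raise BlockerDesignError(f"invalid footprint interval {primer_footprint}")
    best: dict[str, BlockerCandidate] = {}
    for ampseq in amplicons:
        if f2 > len(ampseq):
            raise BlockerDesignError(
                f"footprint {primer_footprint} exceeds amplicon length {len(ampseq)}"
            )
        n = len(ampseq)
        for k in range(params.k_min, params.k_max + 1):
            for start in range(1, n - k + 2):
                end = start + k - 1
                overlap = min(end, f2) - max(start, f1) + 1
                if overlap < params.min_primer_overlap:
                    continue
                word = ampseq[start - 1:end]
                ident = (
                    _shared_identical(word, start, primer, primer_footprint)
                    if primer is not None else overlap
                )
                prev = best.get(word)
                if prev is None or overlap > prev.footprint_overlap:
                    best[word] = BlockerCandidate(word, overlap, ident)
    return sorted(best.values(), key=lambda c: c.sequence)


def _exact_occurrence(blocker: str, record: ReferenceRecord) -> bool:
    # strict criterion: full-length 0-mismatch occurrence on either strand
    return blocker in record.sequence or reverse_complement(blocker) in record.sequence


def score_candidate(
    candidate: BlockerCandidate,
    db: ReferenceDB,
    target_group: str,
) -> tuple[float, float, dict[str, float]]:
    """(target coverage, cumulative fungal coverage, per-outgroup coverage)
    by exact full-length occurrence."""
    target = [r for r in db if _group_key(r) == target_group]
    if not target:
        raise BlockerDesignError(f"no records in target group {target_group!r}")
    fungal = db.fungal_records
    target_cov = sum(_exact_occurrence(candidate.sequence, r) for r in target) / len(target)
    fungal_cov = (
        sum(_exact_occurrence(candidate.sequence, r) for r in fungal) / len(fungal)
        if fungal else 0.0
    )
    per_group: dict[str, float] = {}
    for g, n in sorted(db.outgroup_counts().items()):
        members = [r for r in db.nonfungal_records if r.outgroup == g]
        per_group[g] = sum(
            _exact_occurrence(candidate.sequence, r) for r in members
        ) / n
    return target_cov, fungal_cov, per_group


def score_and_select(
    candidates: Sequence[BlockerCandidate],
    db: ReferenceDB,
    competing_primer: Oligo,
    params: BlockerParams | None = None,
    target_group: str = "",
) -> BlockingOligo:
    """Pick the best blocking oligo: maximize exact-match target coverage
    subject to cumulative fungal coverage <= cap and Tm within tolerance of
    the competing primer.  Ties break toward lower fungal coverage, smaller
    Tm distance, then the lexicographically smallest sequence."""
    params = params or BlockerParams()
    if not candidates:
        raise BlockerDesignError("no candidates to score")
    primer_tm = competing_primer.tm_basic
    scored = []
    for cand in candidates:
        tm = Oligo(name="cand", sequence=cand.sequence).tm_basic
        dtm = abs(tm - primer_tm)
        if dtm > params.tm_tolerance:
            continue
        target_cov, fungal_cov, per_group = score_candidate(cand, db, target_group)
        if fungal_cov > params.fungal_coverage_cap:
            continue
        scored.append((cand, tm, dtm, target_cov, fungal_cov, per_group))
    if not scored:
        raise BlockerDesignError(
            f"no candidate for {target_group!r} satisfies the fungal-coverage "
            f"cap ({params.fungal_coverage_cap}) and Tm tolerance "
            f"(+/-{params.tm_tolerance} degC); consider relaxing tm_tolerance "
            "or the cap"
        )
    scored.sort(key=lambda s: (-s[3], s[4], s[2], s[0].sequence))
    cand, tm, _, target_cov, fungal_cov, per_group = scored[0]
    return BlockingOligo(
        sequence=cand.sequence,
        target_group=target_group,
        competing_primer=competing_primer.name,
        overlap_nt=cand.overlap_nt,
        tm=tm,
        target_coverage=target_cov,
        fungal_cumulative_coverage=fungal_cov,
        per_group_offtarget=per_group,
        three_prime_mod=params.three_prime_mod,
    )


def design_blocker(
    pair: PrimerPair,
    db: ReferenceDB,
    target_group: str,
    competing: Literal["forward", "reverse"],
    params: BlockerParams | None = None,
    max_mismatch_per_primer: int = 1,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> BlockingOligo:
    """End-to-end design of one group-specific blocker.

    Orients the target group's amplicons into the competing primer's sense
    (reverse primers anneal to the plus strand's complement, so amplicons
    are reverse-complemented for them), enumerates candidates over the
    primer footprint, and selects.
    """
    params = params or BlockerParams()
    grouped = amplify_with_flanks(pair, db, max_mismatch_per_primer, length_bounds)
    if target_group not in grouped:
        raise BlockerDesignError(
            f"group {target_group!r} is not co-amplified by {pair.name}"
        )
    amplicons = grouped[target_group]
    if competing == "forward":
        primer = pair.forward
        oriented = amplicons
    else:
        primer = pair.reverse
        oriented = [reverse_complement(a) for a in amplicons]
    footprint = (1, primer.length)
    candidates = enumerate_blocker_candidates(oriented, footprint, params, primer)
    return score_and_select(candidates, db, primer, params, target_group)
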