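"""Mismatch-tolerant in silico PCR: degenerate matching, binding-site
discovery, virtual amplification, and coverage / co-amplification statistics.

Match semantics are base-set intersection: a primer position mismatches a
reference position iff their IUPAC base sets are disjoint.  Primer N (and
inosine) therefore never mismatch, and reference ambiguity codes are handled
gracefully.  Coordinates in all reports are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .iupac import BITMASK, normalize
from .oligo import Oligo, reverse_complement
from .reference import ReferenceDB, ReferenceRecord

#: default amplicon geometry bounds: wide enough for the long-read size
#: class (>1000 nt) while excluding degenerate geometries
DEFAULT_LENGTH_BOUNDS = (50, 3000)

#: detailed-match mode ceiling (per primer)
MAX_DETAILED_MISMATCHES = 3


class PCRError(ValueError):
    pass


@dataclass(frozen=True)
class MatchHit:
    record_id: str
    strand: Literal["plus", "minus"]
    start: int  # 1-based position of the site's leftmost base on the record
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    record_id: str
    start: int  # 1-based inclusive
    end: int
    sequence: str  # primers included
    insert: str  # primer footprints removed
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _mask_array(sequence: str) -> np.ndarray:
    return np.frombuffer(
        bytes(BITMASK[c] for c in sequence), dtype=np.uint8
    ).copy()


def count_mismatches(primer: str, window: str) -> int:
    """Positions where the primer's and the window's base sets are disjoint."""
    p = normalize(primer)
    w = normalize(window)
    if len(p) != len(w):
        raise PCRError(
            f"length disagreement: primer {len(p)} nt vs window {len(w)} nt"
        )
    return sum(
        1 for a, b in zip(p, w) if not (BITMASK[a] & BITMASK[b])
    )


def _scan(
    query_masks: np.ndarray, record_masks: np.ndarray, max_mismatch: int
) -> list[tuple[int, int]]:
    """(1-based start, mismatches) of every window within the allowance."""
    L = len(query_masks)
    n = len(record_masks)
    if L > n:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(record_masks, L)
    mm = np.count_nonzero((windows & query_masks) == 0, axis=1)
    starts = np.nonzero(mm <= max_mismatch)[0]
    return [(int(s) + 1, int(mm[s])) for s in starts]


def find_binding_sites(
    primer: Oligo | str,
    record: ReferenceRecord,
    max_mismatch: int = 0,
    orientation: str | None = None,
) -> list[MatchHit]:
    """All annealing sites of a primer on a record, sorted by start.

    Forward primers are scanned against plus-strand windows; for reverse
    primers the window's reverse complement must match, i.e. the plus strand
    is scanned with the primer's reverse complement.
    """
    if max_mismatch < 0:
        raise PCRError("max_mismatch must be >= 0")
    if isinstance(primer, Oligo):
        seq, orient = primer.sequence, primer.orientation
    else:
        seq = normalize(primer)
        orient = orientation or "forward"
    rec_masks = _mask_array(record.sequence)
    if orient == "forward":
        query, strand = seq, "plus"
    else:
        query, strand = reverse_complement(seq), "minus"
    hits = _scan(_mask_array(query), rec_masks, max_mismatch)
    return [
        MatchHit(record.id, strand, start, mm) for start, mm in hits
    ]


def amplify(
    pair,
    record: ReferenceRecord,
    max_mismatch_per_primer: int = 1,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> list[Amplicon]:
    """Virtual PCR products of a primer pair on one record.

    For a forward site at [i, i+Lf-1] and a reverse-complement site at
    [j, j+Lr-1] with j >= i+Lf, the amplicon spans [i, j+Lr-1]; the mismatch
    allowance applies per primer independently.  No valid geometry yields an
    empty list, never an error.
    """
    fwd, rev = pair.forward, pair.reverse
    lo, hi = length_bounds
    fwd_hits = find_binding_sites(fwd, record, max_mismatch_per_primer)
    if not fwd_hits:
        return []
    rev_hits = find_binding_sites(rev, record, max_mismatch_per_primer)
    if not rev_hits:
        return []
    lf, lr = fwd.length, rev.length
    out: list[Amplicon] = []
    for fh in fwd_hits:
        for rh in rev_hits:
            if rh.start < fh.start + lf:
                continue
            start, end = fh.start, rh.start + lr - 1
            length = end - start + 1
            if not (lo <= length <= hi):
                continue
            seq = record.sequence[start - 1:end]
            out.append(
                Amplicon(
                    record_id=record.id, start=start, end=end,
                    sequence=seq, insert=seq[lf:len(seq) - lr],
                    fwd_mismatches=fh.mismatches, rev_mismatches=rh.mismatches,
                )
            )
    out.sort(key=lambda a: (a.start, a.end))
    return out


@dataclass
class CoverageReport:
    """Per-mismatch-level coverage for one query (primer or pair).

    All cells are stored as (matched, denominator); fractions are derived.
    ``group_coverage`` covers fungal phylum/subphylum labels, ``per_outgroup``
    the non-fungal eukaryotic groups, and ``co_amplification`` pools all
    non-fungal eukaryotes.
    """

    query_label: str
    mismatch_levels: list[int]
    fungal: dict[int, tuple[int, int]] = field(default_factory=dict)
    groups: dict[tuple[str, int], tuple[int, int]] = field(default_factory=dict)
    coamp: dict[int, tuple[int, int]] = field(default_factory=dict)
    outgroups: dict[tuple[str, int], tuple[int, int]] = field(default_factory=dict)

    @staticmethod
    def _frac(cell: tuple[int, int]) -> float:
        matched, denom = cell
        return matched / denom if denom else 0.0

    def fungal_coverage(self, level: int) -> float:
        self._require_level(level)
        return self._frac(self.fungal[level])

    def group_coverage(self, group: str, level: int) -> float:
        self._require_level(level)
        key = (group, level)
        if key not in self.groups:
            raise PCRError(f"group {group!r} missing from report {self.query_label!r}")
        return self._frac(self.groups[key])

    def co_amplification(self, level: int) -> float:
        self._require_level(level)
        return self._frac(self.coamp[level])

    def outgroup_coverage(self, outgroup: str, level: int) -> float:
        self._require_level(level)
        return self._frac(self.outgroups.get((outgroup, level), (0, 0)))

    def fungal_group_labels(self) -> list[str]:
        return sorted({g for g, _ in self.groups})

    def group_denominator(self, group: str) -> int:
        for (g, _), (_, denom) in self.groups.items():
            if g == group:
                return denom
        raise PCRError(f"group {group!r} missing from report {self.query_label!r}")

    def _require_level(self, level: int) -> None:
        if level not in self.mismatch_levels:
            raise PCRError(
                f"report {self.query_label!r} has no mismatch level {level}"
            )


def _coverage_from_best(
    query_label: str,
    best: dict[str, int | None],  # record id -> best (minimum) mismatch count
    db: ReferenceDB,
    levels: Sequence[int],
) -> CoverageReport:
    fungal = db.fungal_records
    nonfungal = db.nonfungal_records
    if not fungal:
        raise PCRError("reference database has no fungal records")
    report = CoverageReport(query_label=query_label, mismatch_levels=list(levels))
    group_members: dict[str, list[ReferenceRecord]] = {}
    for rec in fungal:
        for g in rec.group_labels:
            group_members.setdefault(g, []).append(rec)
    outgroup_members: dict[str, list[ReferenceRecord]] = {}
    for rec in nonfungal:
        if rec.outgroup:
            outgroup_members.setdefault(rec.outgroup, []).append(rec)

    def hit(rec: ReferenceRecord, level: int) -> bool:
        b = best.get(rec.id)
        return b is not None and b <= level

    for level in levels:
        report.fungal[level] = (
            sum(hit(r, level) for r in fungal), len(fungal)
        )
        report.coamp[level] = (
            sum(hit(r, level) for r in nonfungal), len(nonfungal)
        )
        for g, members in group_members.items():
            report.groups[(g, level)] = (
                sum(hit(r, level) for r in members), len(members)
            )
        for g, members in outgroup_members.items():
            report.outgroups[(g, level)] = (
                sum(hit(r, level) for r in members), len(members)
            )
    return report


def primer_coverage(
    primer: Oligo,
    db: ReferenceDB,
    levels: Sequence[int] = (0, 1),
) -> CoverageReport:
    """Fraction of each taxon group's records carrying >= 1 binding site at
    each allowed-mismatch level."""
    if not len(db):
        raise PCRError("empty reference database")
    max_level = max(levels)
    best: dict[str, int | None] = {}
    for rec in db:
        hits = find_binding_sites(primer, rec, max_level)
        best[rec.id] = min((h.mismatches for h in hits), default=None)
    return _coverage_from_best(primer.name, best, db, levels)


def pair_coverage(
    pair,
    db: ReferenceDB,
    levels: Sequence[int] = (0, 1),
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> CoverageReport:
    """A record is covered at a level iff the pair yields >= 1 amplicon with
    that per-primer allowance; co-amplification pools non-fungal eukaryotes."""
    if not len(db):
        raise PCRError("empty reference database")
    max_level = max(levels)
    best: dict[str, int | None] = {}
    for rec in db:
        amps = amplify(pair, rec, max_level, length_bounds)
        # the binding stringency of an amplicon is its worse primer
        best[rec.id] = min(
            (max(a.fwd_mismatches, a.rev_mismatches) for a in amps),
            default=None,
        )
    label = f"{pair.forward.name}/{pair.reverse.name}"
    return _coverage_from_best(label, best, db, levels)


def scan_all(
    primers: Iterable[Oligo],
    db: ReferenceDB,
    max_mismatch: int = 1,
) -> list[tuple[str, MatchHit]]:
    """(primer name, hit) for every binding site of every primer; CLI helper."""
    out = []
    for primer in primers:
        for rec in db:
            for hit in find_binding_sites(primer, rec, max_mismatch):
                out.append((primer.name, hit))
    return out
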