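"""Seeded generator of taxonomically structured reference databases with
planted primer binding sites and exact per-record mismatch counts.

The generator emulates the shape of a SILVA-style 18S reference set: taxon
groups (fungal phyla/subphyla and non-fungal eukaryotic outgroups) of chosen
sizes, i.i.d. background sequence, and primer annealing sites planted at
fixed positions with an exact number of mutated positions per record.  Every
mutation is guaranteed to be a true mismatch (the substituted base falls
outside the primer's IUPAC set at that position), and each finished record is
re-scanned to reject accidental secondary binding sites, so the returned
ground truth is exact at every tested mismatch level — the toolkit-wide
oracle for coverage statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .iupac import BASE_SETS
from .oligo import Oligo, reverse_complement
from .reference import ReferenceDB, make_record
from .pcr import find_binding_sites

BASES = "ACGT"


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSpec:
    label: str
    is_fungal: bool
    n: int
    subphylum: str | None = None  # fungal groups only

    def taxonomy(self, species: str) -> list[str]:
        if self.is_fungal:
            path = ["Eukaryota", "Opisthokonta", "Fungi", self.label]
            if self.subphylum:
                path.append(self.subphylum)
        else:
            path = ["Eukaryota", "SAR", self.label]
        return path + [species]


@dataclass(frozen=True)
class PlantedSite:
    """One oligo planted at a fixed template position.

    ``mismatch_counts`` maps group label -> {mismatch count -> number of
    records}; within each group, records are assigned in index order
    (ascending mismatch count first), so multiple sites planted with the
    same distribution land in the same records — the construction used for
    pair fixtures.
    """

    oligo: Oligo
    position: int  # 1-based start of the annealing site on the template
    mismatch_counts: dict[str, dict[int, int]] = field(default_factory=dict)


@dataclass
class FixtureSpec:
    groups: Sequence[GroupSpec]
    template_length: int = 1200
    planted_sites: Sequence[PlantedSite] = ()
    seed: int = 0
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    levels: tuple[int, ...] = (0, 1)
    protected_three_prime: int = 0  # mutations never land this close to the 3' end
    max_resample: int = 100

    def validate(self) -> None:
        if not self.groups:
            raise FixtureError("at least one group required")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise FixtureError("duplicate group labels")
        sizes = {g.label: g.n for g in self.groups}
        intervals = []
        for site in self.planted_sites:
            L = site.oligo.length
            if site.position < 1 or site.position + L - 1 > self.template_length:
                raise FixtureError(
                    f"site for {site.oligo.name!r} at {site.position} exceeds "
                    f"template length {self.template_length}"
                )
            intervals.append((site.position, site.position + L - 1, site.oligo.name))
            for label, dist in site.mismatch_counts.items():
                if label not in sizes:
                    raise FixtureError(f"unknown group {label!r} in planted site")
                if any(m < 0 or n < 0 for m, n in dist.items()):
                    raise FixtureError("negative mismatch count or record count")
                if sum(dist.values()) > sizes[label]:
                    raise FixtureError(
                        f"site {site.oligo.name!r}: {sum(dist.values())} planted "
                        f"records exceed group {label!r} size {sizes[label]}"
                    )
        intervals.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(intervals, intervals[1:]):
            if s2 <= e1:
                raise FixtureError(f"planted sites {n1!r} and {n2!r} overlap")


@dataclass
class GroundTruth:
    """Exact per-record planted mismatch counts and derived coverages."""

    group_sizes: dict[str, int]
    fungal_groups: tuple[str, ...]
    levels: tuple[int, ...]
    # (group, record index) -> {oligo name -> planted mismatch count}
    planted: dict[tuple[str, int], dict[str, int]]

    def coverage(self, oligo_name: str, group: str, level: int) -> float:
        n = self.group_sizes[group]
        hit = sum(
            1 for i in range(n)
            if self.planted.get((group, i), {}).get(oligo_name, 10**9) <= level
        )
        return hit / n

    def pair_coverage(
        self, oligo_names: Sequence[str], group: str, level: int
    ) -> float:
        """Records carrying every named site within the allowance."""
        n = self.group_sizes[group]
        hit = 0
        for i in range(n):
            rec = self.planted.get((group, i), {})
            if all(rec.get(name, 10**9) <= level for name in oligo_names):
                hit += 1
        return hit / n

    def fungal_coverage(self, oligo_name: str, level: int) -> float:
        total = sum(self.group_sizes[g] for g in self.fungal_groups)
        hit = sum(
            round(self.coverage(oligo_name, g, level) * self.group_sizes[g])
            for g in self.fungal_groups
        )
        return hit / total


def _site_query(oligo: Oligo) -> str:
    """The plus-strand query the scanner uses for this oligo."""
    return oligo.sequence if oligo.orientation == "forward" else reverse_complement(
        oligo.sequence
    )


def _concrete_site(query: str, rng: np.random.Generator) -> str:
    """A concrete annealing site drawn from the query's base sets."""
    return "".join(
        rng.choice(sorted(BASE_SETS[c])) for c in query
    )


def _mutate(
    site: str,
    query: str,
    m: int,
    rng: np.random.Generator,
    protected: set[int],
) -> str:
    """Substitute exactly m positions with bases outside the query's set.

    Positions where the query is N or inosine cannot mismatch and are never
    chosen.
    """
    allowed = [
        i for i in range(len(site))
        if i not in protected and len(BASE_SETS[query[i]]) < 4
    ]
    if m > len(allowed):
        raise FixtureError(
            f"cannot place {m} mismatches in query {query!r}: only "
            f"{len(allowed)} mutable positions"
        )
    positions = rng.choice(len(allowed), size=m, replace=False)
    out = list(site)
    for idx in positions:
        i = allowed[int(idx)]
        choices = [b for b in BASES if b not in BASE_SETS[query[i]]]
        out[i] = str(rng.choice(choices))
    return "".join(out)


def generate_reference_db(spec: FixtureSpec) -> tuple[ReferenceDB, GroundTruth]:
    """Build the database and its exact ground truth.

    Identical seeds give byte-identical output.  Background sequence is drawn
    i.i.d. from ``background_composition``; a record is resampled (bounded
    retries) whenever any unplanted window matches a planted oligo within the
    highest tested mismatch level.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    probs = np.asarray(spec.background_composition, dtype=float)
    probs = probs / probs.sum()
    max_level = max(spec.levels)

    # per group: record index -> {oligo name: (window sequence, mismatches)}
    assignments: dict[str, dict[int, dict[str, tuple[int, int]]]] = {
        g.label: {} for g in spec.groups
    }
    for site in spec.planted_sites:
        for label, dist in site.mismatch_counts.items():
            idx = 0
            for m in sorted(dist):
                for _ in range(dist[m]):
                    assignments[label].setdefault(idx, {})[site.oligo.name] = (
                        site.position, m
                    )
                    idx += 1

    site_by_name = {s.oligo.name: s for s in spec.planted_sites}
    records = []
    planted: dict[tuple[str, int], dict[str, int]] = {}
    for group in spec.groups:
        for i in range(group.n):
            rec_sites = assignments[group.label].get(i, {})
            planted[(group.label, i)] = {
                name: m for name, (_, m) in rec_sites.items()
            }
            rec_id = f"{group.label}_{i:04d}"
            species = f"{group.label}_sp{i:04d}"
            record = None
            for _attempt in range(spec.max_resample):
                seq = rng.choice(list(BASES), size=spec.template_length, p=probs)
                seq = "".join(seq)
                for name, (pos, m) in rec_sites.items():
                    site = site_by_name[name]
                    query = _site_query(site.oligo)
                    window = _concrete_site(query, rng)
                    if m:
                        if site.oligo.orientation == "forward":
                            protected = {
                                len(query) - 1 - k
                                for k in range(spec.protected_three_prime)
                            }
                        else:  # primer 3' end is the left end of the + window
                            protected = set(range(spec.protected_three_prime))
                        window = _mutate(window, query, m, rng, protected)
                    seq = seq[:pos - 1] + window + seq[pos - 1 + len(window):]
                candidate = make_record(
                    rec_id, seq, group.taxonomy(species)
                )
                if _no_accidental_sites(candidate, spec, rec_sites, max_level):
                    record = candidate
                    break
            if record is None:
                raise FixtureError(
                    f"could not generate {rec_id} without accidental binding "
                    f"sites after {spec.max_resample} attempts"
                )
            records.append(record)

    truth = GroundTruth(
        group_sizes={g.label: g.n for g in spec.groups},
        fungal_groups=tuple(g.label for g in spec.groups if g.is_fungal),
        levels=spec.levels,
        planted=planted,
    )
    return ReferenceDB(records), truth


def _no_accidental_sites(record, spec: FixtureSpec, rec_sites, max_level: int) -> bool:
    for site in spec.planted_sites:
        hits = find_binding_sites(site.oligo, record, max_level)
        expected = rec_sites.get(site.oligo.name)
        if expected is not None and expected[1] <= max_level:
            pos, m = expected
            if len(hits) != 1 or hits[0].start != pos or hits[0].mismatches != m:
                return False
        else:
            if hits:
                return False
    return True


def generate_primer_panel(
    n: int,
    length_range: tuple[int, int] = (18, 22),
    tm_spread: float = 8.0,
    seed: int = 0,
) -> list[Oligo]:
    """A panel of concrete primers with a controlled basic-Tm spread and
    alternating orientations; reference positions are spaced so that every
    forward/reverse combination has positive expected amplicon length."""
    if n < 1:
        raise FixtureError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    panel = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        # pick a GC count that lands the basic Tm inside the requested spread
        center_gc = 0.5 * length
        jitter = tm_spread * length / 41.0 / 2.0  # dTm=41*dGC/N inverted
        gc = int(np.clip(round(center_gc + rng.uniform(-jitter, jitter)), 0, length))
        positions = rng.permutation(length)[:gc]
        seq = "".join(
            str(rng.choice(["G", "C"])) if j in set(int(p) for p in positions)
            else str(rng.choice(["A", "T"]))
            for j in range(length)
        )
        orientation = "forward" if i % 2 == 0 else "reverse"
        ref_position = 100 + 5 * i if orientation == "forward" else 900 + 5 * i
        panel.append(
            Oligo(
                name=f"p{i:03d}_{orientation[0]}",
                sequence=seq,
                orientation=orientation,
                ref_position=ref_position,
            )
        )
    return panel
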