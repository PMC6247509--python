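"""Primer-pair construction: the Tm-difference pairing rule, amplicon
geometry on the naming reference, amplicon size classes, and variable-region
annotation.

Size classes follow the sequencing-platform split: S (<=600 nt, short-read),
M (600-1000 nt, Sanger) and L (>1000 nt, long-read).  The variable-region map
for the 18S rRNA gene lists V1-V9 without V6, which does not exist in this
numbering; shipped coordinates are approximate S. cerevisiae (Z75578)
intervals and editable as configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .oligo import Oligo

SizeGroup = Literal["S", "M", "L"]
RegionCoverage = Literal["full", "partial"]

#: approximate variable-region intervals on the S. cerevisiae 18S reference
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "V1": (69, 109),
    "V2": (134, 297),
    "V3": (437, 545),
    "V4": (620, 880),
    "V5": (1049, 1107),
    "V7": (1400, 1465),
    "V8": (1480, 1560),
    "V9": (1727, 1786),
}


class PairError(ValueError):
    pass


@dataclass
class VariableRegionMap:
    regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )

    def __post_init__(self) -> None:
        if "V6" in self.regions:
            raise PairError("V6 does not exist in the 18S numbering")
        items = sorted(self.regions.items(), key=lambda kv: kv[1][0])
        prev_end = 0
        for label, (start, end) in items:
            if start < 1 or end < start:
                raise PairError(f"invalid interval for {label}: ({start}, {end})")
            if start <= prev_end:
                raise PairError(f"region {label} overlaps its predecessor")
            prev_end = end
        self.regions = dict(items)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariableRegionMap":
        """3-column config: region <TAB> start <TAB> end."""
        regions = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            label, start, end = line.split("\t")
            regions[label.strip()] = (int(start), int(end))
        return cls(regions)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["#region\tstart\tend"]
        lines += [f"{r}\t{s}\t{e}" for r, (s, e) in self.regions.items()]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PrimerPair:
    forward: Oligo
    reverse: Oligo
    expected_amplicon_nt: int | None = None
    size_group: SizeGroup | None = None
    regions: list[tuple[str, RegionCoverage]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.forward.orientation != "forward":
            raise PairError(f"{self.forward.name!r} is not a forward primer")
        if self.reverse.orientation != "reverse":
            raise PairError(f"{self.reverse.name!r} is not a reverse primer")

    @property
    def name(self) -> str:
        return f"{self.forward.name}/{self.reverse.name}"

    @property
    def tm_difference(self) -> float:
        return abs(self.forward.tm_basic - self.reverse.tm_basic)

    @property
    def geometry_known(self) -> bool:
        return self.expected_amplicon_nt is not None


def size_group(amplicon_nt: int) -> SizeGroup:
    """S iff <=600; M iff in (600, 1000]; L iff >1000."""
    if amplicon_nt <= 0:
        raise PairError(f"non-positive amplicon length: {amplicon_nt}")
    if amplicon_nt <= 600:
        return "S"
    if amplicon_nt <= 1000:
        return "M"
    return "L"


def expected_amplicon_length(forward: Oligo, reverse: Oligo) -> int | None:
    """Amplicon length on the naming reference, from stored 5'-terminus
    positions (reverse position is the rightmost plus-strand coordinate)."""
    if forward.ref_position is None or reverse.ref_position is None:
        return None
    return reverse.ref_position - forward.ref_position + 1


def covered_regions(
    amplicon_interval: tuple[int, int],
    region_map: VariableRegionMap | None = None,
) -> list[tuple[str, RegionCoverage]]:
    """Regions the amplicon covers: 'full' when the region interval is
    contained in the amplicon, 'partial' on any overlap >= 1 nt."""
    region_map = region_map or VariableRegionMap()
    a_start, a_end = amplicon_interval
    if a_start < 1 or a_end < a_start:
        raise PairError(f"invalid amplicon interval {amplicon_interval}")
    out: list[tuple[str, RegionCoverage]] = []
    for label, (r_start, r_end) in region_map.regions.items():
        if r_end < a_start or r_start > a_end:
            continue
        full = a_start <= r_start and r_end <= a_end
        out.append((label, "full" if full else "partial"))
    return out


def build_pair(
    forward: Oligo,
    reverse: Oligo,
    region_map: VariableRegionMap | None = None,
) -> PrimerPair:
    """Assemble one pair with geometry, size class and region annotation."""
    nt = expected_amplicon_length(forward, reverse)
    pair = PrimerPair(forward, reverse, expected_amplicon_nt=nt)
    if nt is not None:
        pair.size_group = size_group(nt)
        interval = (forward.ref_position, reverse.ref_position)
        pair.regions = covered_regions(interval, region_map)
    return pair


def enumerate_pairs(
    primers: Sequence[Oligo],
    max_tm_diff: float = 5.0,
    region_map: VariableRegionMap | None = None,
) -> list[PrimerPair]:
    """All forward x reverse combinations whose basic Tm difference is
    strictly below ``max_tm_diff`` (the < 5 degC pairing rule) and whose
    expected amplicon length, when geometry is known, is positive.

    Pairs lacking reference positions are kept with unknown geometry; they
    are excluded from size grouping but not from coverage evaluation.
    Output order is deterministic and independent of input ordering.
    """
    for p in primers:
        if p.orientation not in ("forward", "reverse"):
            raise PairError(f"primer {p.name!r} has no orientation")
    forwards = sorted(
        (p for p in primers if p.orientation == "forward"), key=lambda p: p.name
    )
    reverses = sorted(
        (p for p in primers if p.orientation == "reverse"), key=lambda p: p.name
    )
    out: list[PrimerPair] = []
    for f in forwards:
        for r in reverses:
            if abs(f.tm_basic - r.tm_basic) >= max_tm_diff:
                continue
            nt = expected_amplicon_length(f, r)
            if nt is not None and nt <= 0:
                continue
            out.append(build_pair(f, r, region_map))
    return out
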