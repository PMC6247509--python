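"""Primer screening and ranking.

The evaluation ladder: (1) single primers must cover at least 50% of fungal
sequences with one mismatch; (2) biodiversity pairs need >=65% / >=75% fungal
coverage at zero / one mismatch, must target every major fungal phylum and
subphylum, and must co-amplify <20% of non-fungal eukaryotes at one mismatch;
(3) group-specific shortlists (Sanger-size pairs only) need <20% / <30%
co-amplification at zero / one mismatch and group coverage exceeding 70%,
keeping at most five pairs per group.  Ranking is lexicographic: highest
fungal coverage at 0M, then lowest co-amplification, then lowest
co-amplification of the problematic marine groups (Stramenopiles, Alveolata,
Rhizaria, Telonema).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .pairs import PrimerPair
from .pcr import CoverageReport, PCRError


class ScreeningError(ValueError):
    pass


DEFAULT_FOCUS_GROUPS = ("Stramenopiles", "Alveolata", "Rhizaria", "Telonema")


@dataclass
class Thresholds:
    """All screening thresholds, defaulting to the published criteria.

    Fractions are stored in [0, 1]; rendered tables show percentages.
    """

    single_screen_cov1: float = 0.50  # inclusive: "at least 50%"
    biodiversity_cov0: float = 0.65  # inclusive
    biodiversity_cov1: float = 0.75  # inclusive
    biodiversity_coamp1: float = 0.20  # exclusive: "< 20%"
    group_specific_coamp0: float = 0.20  # exclusive
    group_specific_coamp1: float = 0.30  # exclusive
    group_specific_cov: float = 0.70  # exclusive: "exceeded 70%"
    max_per_group: int = 5
    major_group_min_records: int = 10
    targeting_level: int = 1  # mismatch level at which "targeting" is judged
    group_specific_level: int = 0  # level for the shortlist coverage rule
    focus_groups: tuple[str, ...] = DEFAULT_FOCUS_GROUPS

    def __post_init__(self) -> None:
        for name in (
            "single_screen_cov1", "biodiversity_cov0", "biodiversity_cov1",
            "biodiversity_coamp1", "group_specific_coamp0",
            "group_specific_coamp1", "group_specific_cov",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScreeningError(f"{name} must be a fraction in [0,1], got {v}")


@dataclass
class CriteriaFlags:
    cov0_ok: bool
    cov1_ok: bool
    all_groups_hit: bool
    coamp_ok: bool

    @property
    def passed(self) -> bool:
        return self.cov0_ok and self.cov1_ok and self.all_groups_hit and self.coamp_ok


@dataclass
class PairEvaluation:
    pair: PrimerPair
    report: CoverageReport
    flags: CriteriaFlags | None = None
    missing_groups: list[str] = field(default_factory=list)

    @property
    def name(self) -> str:
        return self.pair.name

    def focus_coamp(self, focus_groups: Sequence[str], level: int = 0) -> float:
        """Mean coverage over the problematic marine outgroups (groups absent
        from the database contribute 0)."""
        if not focus_groups:
            return 0.0
        return sum(
            self.report.outgroup_coverage(g, level) for g in focus_groups
        ) / len(focus_groups)

    def rank_key(self, thresholds: Thresholds) -> tuple:
        return (
            -self.report.fungal_coverage(0),
            self.report.co_amplification(0),
            self.focus_coamp(thresholds.focus_groups, 0),
            self.name,
        )


def screen_single_primers(
    reports: Sequence[CoverageReport],
    thresholds: Thresholds | None = None,
) -> list[CoverageReport]:
    """Retain primers with fungal coverage at one mismatch >= 50% (inclusive)."""
    thresholds = thresholds or Thresholds()
    retained = []
    for rep in reports:
        if 1 not in rep.mismatch_levels:
            raise ScreeningError(
                f"report {rep.query_label!r} lacks the one-mismatch level"
            )
        if rep.fungal_coverage(1) >= thresholds.single_screen_cov1:
            retained.append(rep)
    return retained


def major_fungal_groups(
    report: CoverageReport, thresholds: Thresholds
) -> list[str]:
    """Phylum/subphylum labels with at least the configured minimum record
    count in the underlying database (the report stores group sizes as
    denominators)."""
    return [
        g for g in report.fungal_group_labels()
        if report.group_denominator(g) >= thresholds.major_group_min_records
    ]


def biodiversity_criteria(
    evaluation: PairEvaluation,
    thresholds: Thresholds | None = None,
) -> CriteriaFlags:
    """Apply the biodiversity-pair criteria and store flags on the evaluation."""
    thresholds = thresholds or Thresholds()
    rep = evaluation.report
    for level in (0, 1):
        if level not in rep.mismatch_levels:
            raise ScreeningError(
                f"report {rep.query_label!r} lacks mismatch level {level}"
            )
    majors = major_fungal_groups(rep, thresholds)
    missing = [
        g for g in majors
        if rep.group_coverage(g, thresholds.targeting_level) <= 0.0
    ]
    flags = CriteriaFlags(
        cov0_ok=rep.fungal_coverage(0) >= thresholds.biodiversity_cov0,
        cov1_ok=rep.fungal_coverage(1) >= thresholds.biodiversity_cov1,
        all_groups_hit=not missing,
        coamp_ok=rep.co_amplification(1) < thresholds.biodiversity_coamp1,
    )
    evaluation.flags = flags
    evaluation.missing_groups = missing
    return flags


def group_specific_shortlist(
    evaluations: Sequence[PairEvaluation],
    group: str,
    thresholds: Thresholds | None = None,
) -> list[PairEvaluation]:
    """Up to five best pairs for one fungal group, among Sanger-size (M)
    pairs: co-amplification <20% at 0M and <30% at 1M, group coverage
    strictly above 70%, sorted by group coverage descending."""
    thresholds = thresholds or Thresholds()
    level = thresholds.group_specific_level
    known = {g for ev in evaluations for g in ev.report.fungal_group_labels()}
    if evaluations and group not in known:
        raise ScreeningError(f"unknown group label {group!r}")
    qualifying = []
    for ev in evaluations:
        if ev.pair.size_group != "M":
            continue
        try:
            cov = ev.report.group_coverage(group, level)
        except PCRError:
            continue
        if (
            ev.report.co_amplification(0) < thresholds.group_specific_coamp0
            and ev.report.co_amplification(1) < thresholds.group_specific_coamp1
            and cov > thresholds.group_specific_cov
        ):
            qualifying.append(ev)
    qualifying.sort(
        key=lambda ev: (-ev.report.group_coverage(group, level), ev.name)
    )
    return qualifying[: thresholds.max_per_group]


def rank_pairs(
    evaluations: Sequence[PairEvaluation],
    thresholds: Thresholds | None = None,
) -> list[PairEvaluation]:
    """Total order: passing pairs first, then by highest fungal coverage at
    0M, lowest co-amplification at 0M, lowest focus-group co-amplification,
    name.  Stable, deterministic, a permutation of the input."""
    thresholds = thresholds or Thresholds()
    return sorted(
        evaluations,
        key=lambda ev: (
            not (ev.flags.passed if ev.flags else False),
            *ev.rank_key(thresholds),
        ),
    )
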