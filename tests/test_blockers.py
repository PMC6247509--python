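"""Blocking-oligonucleotide design: flanked amplification, candidate
enumeration, exhaustive-scoring equivalence, and selection constraints."""

import numpy as np
import pytest

from mycoprimer import Oligo, build_pair, reverse_complement
from mycoprimer.blockers import (
    BlockerDesignError,
    BlockerParams,
    _shared_identical,
    amplify_with_flanks,
    design_blocker,
    enumerate_blocker_candidates,
    score_and_select,
)
from mycoprimer.reference import ReferenceDB, make_record

FWD = "CGATAACGAACGAGACCT"  # published forward primer (FF390)
REV = "AICCATTCAATCGGTAIT"  # published reverse primer (FR-1)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def pair():
    f = Oligo("fwd", FWD, "forward", ref_position=1333)
    r = Oligo("rev", REV, "reverse", ref_position=1647)
    return build_pair(f, r)


@pytest.fixture(scope="module")
def three_group_db(pair):
    """Fungi with varying inserts; two outgroups each sharing a
    group-characteristic amplicon region (one substitution in the forward
    site) so a blocker can cover the whole group."""
    rng = np.random.default_rng(17)
    records = []
    rc_rev = reverse_complement("ATCCATTCAATCGGTAAT")  # concrete rev site
    # Alveolata: forward site with substitution at position 5, shared insert
    alv_site = FWD[:4] + "C" + FWD[5:]
    alv_insert = random_seq(rng, 60)
    for i in range(4):
        seq = random_seq(rng, 30) + alv_site + alv_insert + rc_rev + random_seq(rng, 30)
        records.append(
            make_record(f"alv{i}", seq, ["Eukaryota", "SAR", "Alveolata", f"asp{i}"])
        )
    # Rhizaria: different substitution, different shared insert
    rhiz_site = FWD[:9] + "T" + FWD[10:]
    rhiz_insert = random_seq(rng, 60)
    for i in range(4):
        seq = random_seq(rng, 30) + rhiz_site + rhiz_insert + rc_rev + random_seq(rng, 30)
        records.append(
            make_record(f"rhiz{i}", seq, ["Eukaryota", "SAR", "Rhizaria", f"rsp{i}"])
        )
    # Fungi: exact sites, record-specific inserts
    for i in range(6):
        seq = (
            random_seq(rng, 30) + FWD + random_seq(rng, 60) + rc_rev
            + random_seq(rng, 30)
        )
        records.append(
            make_record(
                f"fun{i}", seq, ["Eukaryota", "Fungi", "Ascomycota", f"fsp{i}"]
            )
        )
    return ReferenceDB(records)


class TestAmplifyWithFlanks:
    def test_amplicon_keeps_primer_footprints(self, pair, three_group_db):
        grouped = amplify_with_flanks(pair, three_group_db, 1)
        for amp in grouped["Ascomycota"]:
            assert amp[:18] == FWD  # template under the forward primer

    def test_group_keys_are_amplified_groups(self, pair, three_group_db):
        grouped = amplify_with_flanks(pair, three_group_db, 1)
        assert set(grouped) == {"Ascomycota", "Alveolata", "Rhizaria"}

    def test_dereplication_within_group(self, pair):
        seq = "T" * 20 + FWD + "A" * 60 + reverse_complement("ATCCATTCAATCGGTAAT") + "T" * 20
        recs = [
            make_record(f"x{i}", seq, ["Eukaryota", "SAR", "Alveolata", "sp"])
            for i in range(3)
        ]
        grouped = amplify_with_flanks(pair, ReferenceDB(recs), 1)
        assert len(grouped["Alveolata"]) == 1

    def test_no_amplification_is_empty_mapping(self, pair):
        recs = [make_record("x", "T" * 200, ["Eukaryota", "Fungi", "X", "sp"])]
        assert amplify_with_flanks(pair, ReferenceDB(recs), 1) == {}


class TestEnumerateCandidates:
    def test_counts_match_hand_enumeration(self):
        rng = np.random.default_rng(3)
        amplicon = random_seq(rng, 60)
        params = BlockerParams()
        got = enumerate_blocker_candidates([amplicon], (1, 18), params)
        # independent enumeration over (k, offset)
        expected = set()
        for k in range(18, 26):
            for start in range(1, 60 - k + 2):
                overlap = min(start + k - 1, 18) - max(start, 1) + 1
                if overlap >= 3:
                    expected.add(amplicon[start - 1:start + k - 1])
        assert {c.sequence for c in got} == expected
        # closed form: 16 admissible starts for each of the 8 k values
        assert len(expected) == 16 * 8

    def test_lengths_within_k_range(self):
        rng = np.random.default_rng(4)
        cands = enumerate_blocker_candidates([random_seq(rng, 80)], (1, 18))
        assert all(18 <= len(c.sequence) <= 25 for c in cands)

    def test_two_nt_overlap_excluded(self):
        rng = np.random.default_rng(5)
        cands = enumerate_blocker_candidates([random_seq(rng, 60)], (1, 18))
        assert all(c.footprint_overlap >= 3 for c in cands)
        # an 18-mer starting at 17 would overlap the footprint by only 2
        starts_seen = {c.footprint_overlap for c in cands}
        assert min(starts_seen) == 3

    def test_footprint_longer_than_amplicon_is_error(self):
        with pytest.raises(BlockerDesignError):
            enumerate_blocker_candidates(["ACGT" * 5], (1, 30))

    def test_published_rhizaria_overlap_convention(self):
        # the published Rhizaria blocker shares 15 identical nt with the
        # forward primer when aligned at its annealing offset
        blocker = "TTAACGAACGAGACCTCGA"
        primer = Oligo("fwd", FWD, "forward")
        assert _shared_identical(blocker, 3, primer, (1, 18)) == 15


class TestScoreAndSelect:
    def params(self, **kw):
        base = dict(tm_tolerance=8.0, fungal_coverage_cap=0.01)
        base.update(kw)
        return BlockerParams(**base)

    def exhaustive_best(self, candidates, db, primer, params, group):
        """Brute-force oracle: score every candidate independently."""
        def occurs(word, rec):
            return word in rec.sequence or reverse_complement(word) in rec.sequence

        target = [r for r in db if (not r.is_fungal and r.outgroup == group)]
        fungal = db.fungal_records
        rows = []
        for c in candidates:
            tm = Oligo("c", c.sequence).tm_basic
            if abs(tm - primer.tm_basic) > params.tm_tolerance:
                continue
            tcov = sum(occurs(c.sequence, r) for r in target) / len(target)
            fcov = sum(occurs(c.sequence, r) for r in fungal) / len(fungal)
            if fcov > params.fungal_coverage_cap:
                continue
            rows.append((-tcov, fcov, abs(tm - primer.tm_basic), c.sequence))
        rows.sort()
        return rows[0][3] if rows else None

    def test_equals_exhaustive_scoring(self, pair, three_group_db):
        params = self.params()
        grouped = amplify_with_flanks(pair, three_group_db, 1)
        for group in ("Alveolata", "Rhizaria"):
            cands = enumerate_blocker_candidates(
                grouped[group], (1, 18), params, pair.forward
            )
            selected = score_and_select(
                cands, three_group_db, pair.forward, params, group
            )
            expected = self.exhaustive_best(
                cands, three_group_db, pair.forward, params, group
            )
            assert selected.sequence == expected
            assert 18 <= selected.length <= 25
            assert selected.fungal_cumulative_coverage <= params.fungal_coverage_cap

    def test_full_target_coverage(self, pair, three_group_db):
        blocker = design_blocker(
            pair, three_group_db, "Alveolata", "forward", self.params()
        )
        assert blocker.target_coverage == 1.0
        assert blocker.fungal_cumulative_coverage == 0.0
        assert blocker.competing_primer == pair.forward.name
        assert blocker.three_prime_mod == "C3 spacer"

    def test_offtarget_rates_reported(self, pair, three_group_db):
        blocker = design_blocker(
            pair, three_group_db, "Alveolata", "forward", self.params()
        )
        assert set(blocker.per_group_offtarget) == {"Alveolata", "Rhizaria"}
        assert blocker.per_group_offtarget["Rhizaria"] == 0.0

    def test_tm_outside_tolerance_never_selected(self, pair, three_group_db):
        params = self.params(tm_tolerance=0.01)
        grouped = amplify_with_flanks(pair, three_group_db, 1)
        cands = enumerate_blocker_candidates(
            grouped["Alveolata"], (1, 18), params, pair.forward
        )
        tms = [Oligo("c", c.sequence).tm_basic for c in cands]
        if all(abs(t - pair.forward.tm_basic) > 0.01 for t in tms):
            with pytest.raises(BlockerDesignError, match="tolerance"):
                score_and_select(cands, three_group_db, pair.forward, params, "Alveolata")

    def test_dominant_candidate_selected(self, pair, three_group_db):
        # a candidate covering 100% of the target and 0% of fungi exists and
        # must win against any partial-coverage candidate
        blocker = design_blocker(
            pair, three_group_db, "Rhizaria", "forward", self.params()
        )
        assert blocker.target_coverage == 1.0

    def test_deterministic_selection(self, pair, three_group_db):
        a = design_blocker(pair, three_group_db, "Alveolata", "forward", self.params())
        b = design_blocker(pair, three_group_db, "Alveolata", "forward", self.params())
        assert a.sequence == b.sequence and a.overlap_nt == b.overlap_nt

    def test_not_coamplified_group_is_error(self, pair, three_group_db):
        with pytest.raises(BlockerDesignError):
            design_blocker(pair, three_group_db, "Telonema", "forward", self.params())

    def test_candidates_occur_in_group_amplicons(self, pair, three_group_db):
        grouped = amplify_with_flanks(pair, three_group_db, 1)
        cands = enumerate_blocker_candidates(grouped["Alveolata"], (1, 18))
        for c in cands:
            assert any(c.sequence in amp for amp in grouped["Alveolata"])


class TestBlockerParams:
    def test_k_range_validation(self):
        with pytest.raises(BlockerDesignError):
            BlockerParams(k_min=5)

    def test_overlap_validation(self):
        with pytest.raises(BlockerDesignError):
            BlockerParams(min_primer_overlap=0)
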