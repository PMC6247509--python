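"""The in silico PCR engine against brute-force expansion oracles."""

import numpy as np
import pytest

from mycoprimer import (
    Oligo,
    amplify,
    build_pair,
    count_mismatches,
    find_binding_sites,
    pair_coverage,
    primer_coverage,
)
from mycoprimer.pcr import PCRError
from mycoprimer.reference import ReferenceDB, make_record

from tests.oracles import min_hamming, scan_brute

IUPAC_CODES = "ACGTRYSWKMBDHVN"
AMBIGUOUS = "RYSWKMBDHVN"


def random_primer(rng, length, max_ambiguous=2):
    """Random primer with a bounded number of degenerate positions, keeping
    the expansion oracle tractable."""
    chars = list(rng.choice(list("ACGT"), size=length))
    n_amb = int(rng.integers(0, max_ambiguous + 1))
    for i in rng.choice(length, size=n_amb, replace=False):
        chars[int(i)] = str(rng.choice(list(AMBIGUOUS)))
    return "".join(chars)


def random_record(rng, length=300, rec_id="r0", fungal=True):
    seq = "".join(rng.choice(list("ACGT"), size=length))
    tax = ["Eukaryota", "Fungi", "Ascomycota"] if fungal else ["Eukaryota", "SAR", "Rhizaria"]
    return make_record(rec_id, seq, tax)


class TestCountMismatches:
    @pytest.mark.parametrize(
        "primer, window, expected",
        [
            ("R", "A", 0),
            ("R", "C", 1),
            ("N", "G", 0),
            ("I", "T", 0),
            ("ACGT", "ACGT", 0),
            ("ACGT", "TGCA", 4),
            ("ARN", "AAA", 0),
        ],
    )
    def test_base_set_intersection(self, primer, window, expected):
        assert count_mismatches(primer, window) == expected

    def test_reference_ambiguity_handled(self):
        # reference N intersects every primer set
        assert count_mismatches("ACGT", "NNNN") == 0
        assert count_mismatches("R", "Y") == 1  # {A,G} vs {C,T} disjoint

    def test_length_disagreement(self):
        with pytest.raises(PCRError):
            count_mismatches("ACG", "AC")

    def test_equals_min_hamming_over_expansions(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            L = int(rng.integers(4, 10))
            primer = random_primer(rng, L, max_ambiguous=3)
            window = "".join(rng.choice(list("ACGT"), size=L))
            assert count_mismatches(primer, window) == min_hamming(primer, window)


class TestFindBindingSites:
    def test_exact_planted_site(self):
        rng = np.random.default_rng(1)
        primer = Oligo("p", "ACGTACGTACGTACGTAC", "forward")
        rec = make_record(
            "r", "T" * 100 + primer.sequence + "T" * 100, ["Eukaryota", "Fungi", "X"]
        )
        hits = find_binding_sites(primer, rec, 0)
        assert len(hits) == 1 and hits[0].start == 101 and hits[0].mismatches == 0

    def test_single_substitution_threshold(self):
        primer = Oligo("p", "ACGTACGTACGTACGTAC", "forward")
        mutated = "G" + primer.sequence[1:]
        rec = make_record("r", "T" * 50 + mutated + "T" * 50, ["Eukaryota", "Fungi", "X"])
        assert not find_binding_sites(primer, rec, 0)
        hits = find_binding_sites(primer, rec, 1)
        assert len(hits) == 1 and hits[0].mismatches == 1

    def test_primer_longer_than_record_is_empty(self):
        primer = Oligo("p", "ACGTACGTACGTACGTACGT", "forward")
        rec = make_record("r", "ACGT", ["Eukaryota", "Fungi", "X"])
        assert find_binding_sites(primer, rec, 3) == []

    def test_reverse_primer_matches_reverse_complement(self):
        from mycoprimer import reverse_complement

        primer = Oligo("p", "ACCTTGGAACCTTGGACT", "reverse")
        site = reverse_complement(primer.sequence)
        rec = make_record("r", "T" * 30 + site + "T" * 30, ["Eukaryota", "Fungi", "X"])
        hits = find_binding_sites(primer, rec, 0)
        assert len(hits) == 1
        assert hits[0].strand == "minus" and hits[0].start == 31

    @pytest.mark.parametrize("orientation", ["forward", "reverse"])
    def test_scan_equals_brute_force_on_random_records(self, orientation):
        rng = np.random.default_rng(2024)
        for i in range(200):
            rec = random_record(rng, length=120, rec_id=f"r{i}")
            L = int(rng.integers(8, 14))
            primer_seq = random_primer(rng, L)
            max_mm = int(rng.integers(0, 3))
            primer = Oligo("p", primer_seq, orientation)
            got = [(h.start, h.mismatches) for h in find_binding_sites(primer, rec, max_mm)]
            expected = scan_brute(primer_seq, rec.sequence, max_mm, orientation)
            assert got == expected

    def test_mirrored_coordinates_on_reverse_complemented_record(self):
        from mycoprimer import reverse_complement

        rng = np.random.default_rng(5)
        rec = random_record(rng, length=150)
        primer = Oligo("p", "ACGTACGTACGT", "forward")
        mirror = make_record("m", reverse_complement(rec.sequence), rec.taxonomy)
        rc_primer = Oligo("q", primer.sequence, "reverse")
        fwd_hits = find_binding_sites(primer, rec, 2)
        mirror_hits = find_binding_sites(rc_primer, mirror, 2)
        n = len(rec.sequence)
        L = primer.length
        mirrored = sorted(n - (h.start + L - 1) + 1 for h in fwd_hits)
        assert sorted(h.start for h in mirror_hits) == mirrored
        assert sorted(h.mismatches for h in mirror_hits) == sorted(
            h.mismatches for h in fwd_hits
        )


class TestAmplify:
    def make_template(self, fwd, rev, gap=264):
        from mycoprimer import reverse_complement

        site = reverse_complement(rev.sequence)
        return (
            "T" * 9 + fwd.sequence + "A" * gap + site + "T" * 20
        )

    def test_planted_geometry(self, ff390, fr1):
        # forward at 10 (len 18), reverse-complement site at 300 (len 18)
        seq = self.make_template(ff390, fr1, gap=300 - 10 - 18)
        rec = make_record("r", seq, ["Eukaryota", "Fungi", "X"])
        pair = build_pair(ff390, fr1)
        amps = amplify(pair, rec, 0)
        assert len(amps) == 1
        amp = amps[0]
        assert (amp.start, amp.end) == (10, 317)
        assert amp.length == 308 == len(amp.sequence)
        assert amp.insert == amp.sequence[18:-18]

    def test_reverse_site_upstream_is_empty(self, ff390, fr1):
        from mycoprimer import reverse_complement

        seq = (
            "T" * 10 + reverse_complement(fr1.sequence) + "A" * 100
            + ff390.sequence + "T" * 10
        )
        rec = make_record("r", seq, ["Eukaryota", "Fungi", "X"])
        assert amplify(build_pair(ff390, fr1), rec, 1) == []

    def test_no_reverse_site_is_empty(self, ff390, fr1):
        seq = "T" * 10 + ff390.sequence + "A" * 200
        rec = make_record("r", seq, ["Eukaryota", "Fungi", "X"])
        assert amplify(build_pair(ff390, fr1), rec, 1) == []

    def test_length_bounds_exclude(self, ff390, fr1):
        seq = self.make_template(ff390, fr1)
        rec = make_record("r", seq, ["Eukaryota", "Fungi", "X"])
        pair = build_pair(ff390, fr1)
        assert amplify(pair, rec, 0, length_bounds=(50, 100)) == []

    def test_invariant_to_record_relabeling(self, ff390, fr1):
        seq = self.make_template(ff390, fr1)
        a = make_record("a", seq, ["Eukaryota", "Fungi", "X"])
        b = make_record("b", seq, ["Eukaryota", "Fungi", "X"])
        pair = build_pair(ff390, fr1)
        amps_a = amplify(pair, a, 1)
        amps_b = amplify(pair, b, 1)
        assert [(x.start, x.end, x.sequence) for x in amps_a] == [
            (x.start, x.end, x.sequence) for x in amps_b
        ]


class TestCoverage:
    def test_planted_ground_truth_recovered(self, planted_db, ff390):
        db, truth = planted_db
        report = primer_coverage(ff390, db, (0, 1))
        assert report.fungal_coverage(0) == truth.fungal_coverage(ff390.name, 0) == 0.60
        assert report.fungal_coverage(1) == truth.fungal_coverage(ff390.name, 1) == 0.90

    def test_all_exact_sites_is_full_coverage(self, ff390):
        rng = np.random.default_rng(9)
        records = []
        for i in range(10):
            pad = "".join(rng.choice(list("ACGT"), size=60))
            records.append(
                make_record(
                    f"f{i}", pad + ff390.sequence + pad, ["Eukaryota", "Fungi", "X"]
                )
            )
        db = ReferenceDB(records)
        assert primer_coverage(ff390, db, (0,)).fungal_coverage(0) == 1.0

    def test_monotone_in_mismatch_level(self, planted_db, ff390, fr1):
        db, _ = planted_db
        for primer in (ff390, fr1):
            rep = primer_coverage(primer, db, (0, 1, 2))
            assert (
                rep.fungal_coverage(0)
                <= rep.fungal_coverage(1)
                <= rep.fungal_coverage(2)
            )
            for g in rep.fungal_group_labels():
                assert rep.group_coverage(g, 0) <= rep.group_coverage(g, 1)

    def test_empty_fungal_partition_is_error(self, ff390):
        db = ReferenceDB(
            [make_record("o", "ACGT" * 30, ["Eukaryota", "SAR", "Rhizaria"])]
        )
        with pytest.raises(PCRError):
            primer_coverage(ff390, db)


class TestPairCoverage:
    def test_planted_dual_sites(self, planted_db, planted_pair, ff390, fr1):
        db, truth = planted_db
        rep = pair_coverage(planted_pair, db, (0, 1))
        names = [ff390.name, fr1.name]
        assert rep.fungal_coverage(0) == truth.pair_coverage(names, "Ascomycota", 0) == 0.60
        assert rep.fungal_coverage(1) == 0.90
        # 2 of 20 outgroup records carry both sites
        assert rep.co_amplification(0) == 0.10

    def test_pair_bounded_by_single_coverages(self, planted_db, planted_pair, ff390, fr1):
        db, _ = planted_db
        pair_rep = pair_coverage(planted_pair, db, (0, 1))
        fwd_rep = primer_coverage(ff390, db, (0, 1))
        rev_rep = primer_coverage(fr1, db, (0, 1))
        for level in (0, 1):
            assert pair_rep.fungal_coverage(level) <= min(
                fwd_rep.fungal_coverage(level), rev_rep.fungal_coverage(level)
            )

    def test_no_dual_outgroup_sites_means_zero_coamp(self, ff390, fr1):
        rng = np.random.default_rng(11)
        from mycoprimer import reverse_complement

        records = []
        for i in range(5):  # fungal with dual sites
            seq = (
                "T" * 20 + ff390.sequence + "A" * 100
                + reverse_complement(fr1.sequence) + "T" * 20
            )
            records.append(make_record(f"f{i}", seq, ["Eukaryota", "Fungi", "X"]))
        for i in range(5):  # outgroup with forward site only
            seq = "T" * 20 + ff390.sequence + "A" * 140 + "T" * 16
            records.append(
                make_record(f"o{i}", seq, ["Eukaryota", "SAR", "Rhizaria"])
            )
        rep = pair_coverage(build_pair(ff390, fr1), ReferenceDB(records), (0, 1))
        assert rep.co_amplification(0) == rep.co_amplification(1) == 0.0
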