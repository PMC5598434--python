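"""ORF finding, F-box scoring and S-locus candidacy tests."""

import numpy as np
import pytest
from Bio.Seq import Seq

from conftest import walk_orfs
from srscout.slocus_scan import (
    find_disrupted_fbox,
    find_orfs,
    load_fbox_refs,
    scan_haplotype,
    score_fbox,
)
from srscout.synth_fixtures import FixtureSpec, backtranslate, make_haplotype


def random_contig(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def plant(contig, pos, fragment):
    return contig[:pos] + fragment + contig[pos + len(fragment) :]


@pytest.fixture(scope="module")
def refs():
    return load_fbox_refs()


def sense_cds(rng, n_codons):
    """ATG + stop-free codons + TAA."""
    aas = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n_codons - 2))
    return "ATG" + backtranslate(aas) + "TAA"


class TestFindOrfs:
    def test_planted_1200nt_orf_is_reported_exactly(self):
        rng = np.random.default_rng(1)
        orf = sense_cds(rng, 400)
        assert len(orf) == 1200
        contig = plant(random_contig(rng, 5000), 2000, orf)
        hits = [h for h in find_orfs(contig) if h.strand == "+"]
        assert any((h.start, h.end) == (2000, 3200) for h in hits)

    def test_short_orf_is_excluded_by_the_lower_bound(self):
        rng = np.random.default_rng(2)
        orf = sense_cds(rng, 200)  # 600 nt
        contig = plant(random_contig(rng, 4000), 1500, orf)
        assert not any(
            h.start <= 1500 < h.end and h.strand == "+" and h.frame == 1500 % 3
            for h in find_orfs(contig)
        )

    def test_length_bounds_are_inclusive(self):
        rng = np.random.default_rng(3)
        for n_codons in (300, 600):  # exactly 900 and 1800 nt
            orf = sense_cds(rng, n_codons)
            contig = plant(random_contig(rng, 6000), 2001, orf)
            assert any(
                (h.start, h.end) == (2001, 2001 + 3 * n_codons)
                for h in find_orfs(contig)
            )

    def test_equals_exhaustive_atg_walk_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            contig = random_contig(rng, 10_000)
            got = {
                (h.start, h.end)
                for h in find_orfs(contig, min_nt=90, max_nt=1800)
                if h.strand == "+"
            }
            assert got == walk_orfs(contig, 90, 1800)

    def test_strand_symmetry_under_reverse_complement(self):
        rng = np.random.default_rng(5)
        contig = random_contig(rng, 8000)
        fwd = find_orfs(contig, min_nt=90, max_nt=1800)
        rev = find_orfs(str(Seq(contig).reverse_complement()), min_nt=90, max_nt=1800)
        n = len(contig)
        mirrored = {(n - h.end, n - h.start, "-" if h.strand == "+" else "+") for h in fwd}
        assert {(h.start, h.end, h.strand) for h in rev} == mirrored

    def test_gap_runs_break_orfs_but_single_n_does_not(self):
        rng = np.random.default_rng(6)
        orf = sense_cds(rng, 400)
        # single N inside a codon: still one ORF, translated as X
        broken = orf[:600] + "N" + orf[601:]
        contig = plant(random_contig(rng, 5000), 1000, broken)
        assert any((h.start, h.end) == (1000, 2200) for h in find_orfs(contig))
        # a 12-N assembly gap kills it
        gapped = orf[:600] + "N" * 12 + orf[612:]
        contig = plant(random_contig(rng, 5000), 1000, gapped)
        assert not any((h.start, h.end) == (1000, 2200) for h in find_orfs(contig))

    def test_longest_per_stop_deduplicates_nested_starts(self):
        rng = np.random.default_rng(7)
        inner = sense_cds(rng, 320)
        orf = "ATG" + backtranslate("".join(rng.choice(list("ACDEFGHIKLNQRSTVWY"), size=19))) + inner
        contig = plant(random_contig(rng, 5000), 999, orf)
        all_hits = [h for h in find_orfs(contig) if h.end == 999 + len(orf)]
        dedup = [
            h
            for h in find_orfs(contig, longest_per_stop=True)
            if h.end == 999 + len(orf)
        ]
        assert len(all_hits) >= 2
        assert len(dedup) == 1
        assert dedup[0].nt_length == max(h.nt_length for h in all_hits)


class TestScoreFbox:
    def test_reference_scores_one(self, refs):
        score, is_fbox = score_fbox(refs[0][1], refs)
        assert score == pytest.approx(1.0)
        assert is_fbox

    def test_random_proteins_are_rejected(self, refs):
        rng = np.random.default_rng(9)
        rejections = 0
        for _ in range(100):
            protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=350))
            _score, is_fbox = score_fbox(protein, refs)
            rejections += not is_fbox
        assert rejections >= 99

    def test_mutation_degrades_the_score_monotonically(self, refs):
        rng = np.random.default_rng(10)
        ref = refs[1][1]
        mutated = list(ref)
        for i in rng.choice(len(ref), size=len(ref) // 10, replace=False):
            mutated[int(i)] = str(rng.choice(list("ACDEFGHIKLMNPQRSTVWY")))
        score, _ = score_fbox("".join(mutated), refs)
        random_score, _ = score_fbox(
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=len(ref))), refs
        )
        assert random_score < score < 1.0


class TestFindDisruptedFbox:
    def test_single_stop_mutation_is_detected_at_the_planted_site(self, refs):
        rng = np.random.default_rng(11)
        ref = refs[0][1]  # 320 aa
        cds = backtranslate(ref) + "TAA"
        disrupted = cds[:450] + "TGA" + cds[453:]
        pos = 6000
        contig = plant(random_contig(rng, 20_000), pos, disrupted)
        hits = find_disrupted_fbox(contig, refs)
        assert len(hits) == 1
        assert hits[0].disrupted
        assert hits[0].start <= pos + 450 < pos + 453 <= hits[0].end

    def test_intact_gene_is_not_reported_as_disrupted(self, refs):
        rng = np.random.default_rng(12)
        cds = backtranslate(refs[0][1]) + "TAA"
        contig = plant(random_contig(rng, 20_000), 6000, cds)
        assert find_disrupted_fbox(contig, refs) == []
        # but find_orfs sees it
        assert any(
            (h.start, h.end) == (6000, 6000 + len(cds)) for h in find_orfs(contig)
        )

    def test_random_contigs_give_no_hits(self, refs):
        rng = np.random.default_rng(13)
        hits = sum(
            bool(find_disrupted_fbox(random_contig(rng, 10_000), refs))
            for _ in range(100)
        )
        assert hits <= 1

    def test_minus_strand_disruption_is_found(self, refs):
        rng = np.random.default_rng(14)
        cds = backtranslate(refs[0][1]) + "TAA"
        disrupted = cds[:450] + "TGA" + cds[453:]
        fragment = str(Seq(disrupted).reverse_complement())
        pos = 6000
        contig = plant(random_contig(rng, 20_000), pos, fragment)
        hits = find_disrupted_fbox(contig, refs)
        assert len(hits) == 1
        assert hits[0].strand == "-"


@pytest.fixture(scope="module")
def small_haplotype():
    spec = FixtureSpec(
        seed=21, contig_length=120_000, n_fbox_intact=6, n_fbox_disrupted=2
    )
    return make_haplotype(spec)


class TestScanHaplotype:
    def test_planted_truth_is_recovered(self, small_haplotype):
        contig, truth = small_haplotype
        report = scan_haplotype(contig, truth.rnase_loci)
        intact = [h for h in report.fbox_loci if not h.disrupted]
        disrupted = [h for h in report.fbox_loci if h.disrupted]

        def overlaps(h, feats):
            return any(s < h.end and h.start < e for s, e, _st in feats)

        assert all(overlaps(h, truth.intact_fbox) for h in intact)
        assert all(
            any(h.start < e and s < h.end for h in intact)
            for s, e, _st in truth.intact_fbox
        )
        assert all(
            any(h.start < e and s < h.end for h in disrupted)
            for s, e, _st in truth.disrupted_fbox
        )
        assert report.candidate == truth.candidate is True

    def test_fboxes_outside_the_flank_are_dropped(self):
        spec = FixtureSpec(
            seed=22,
            contig_length=3_500_000,
            n_fbox_intact=5,
            n_fbox_disrupted=0,
            fbox_distance_range=(2_400_000, 2_900_000),
        )
        contig, truth = make_haplotype(spec)
        assert truth.candidate is False
        report = scan_haplotype(contig, truth.rnase_loci)
        assert report.fbox_loci == []
        assert report.candidate is False

    def test_class_one_locus_with_many_fboxes_is_never_candidate(self, small_haplotype):
        contig, truth = small_haplotype
        loci = [(locus, "I") for locus, _cls in truth.rnase_loci]
        report = scan_haplotype(contig, loci)
        assert report.candidate is False
        assert any("class I" in note for note in report.notes)
        assert len(report.fbox_loci) >= 7  # reported, just not candidate

    def test_candidate_flag_is_monotone_in_min_fbox(self, small_haplotype):
        contig, truth = small_haplotype
        flags = [
            scan_haplotype(contig, truth.rnase_loci, min_fbox=m).candidate
            for m in (1, 4, 8, 20)
        ]
        assert flags == sorted(flags, reverse=True)

    def test_report_distances_are_consistent_with_coordinates(self, small_haplotype):
        contig, truth = small_haplotype
        report = scan_haplotype(contig, truth.rnase_loci)
        rows = report.to_rows()
        for prev, row in zip(rows, rows[1:]):
            assert row["distance_to_previous_kb"] >= 0
            assert row["distance_to_previous_kb"] == pytest.approx(
                max(0, row["start"] - prev["end"]) / 1000.0
            )

    def test_overlapping_rnase_loci_rejected(self, small_haplotype):
        contig, _truth = small_haplotype
        with pytest.raises(ValueError):
            scan_haplotype(contig, [((10, 500), "III"), ((400, 900), "III")])
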