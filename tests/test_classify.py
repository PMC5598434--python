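"""Alignment scoring, nearest-reference labeling and the decision ladder."""

import numpy as np
import pytest

from conftest import enumerate_global_score, random_protein
from srscout.classify import (
    ClassCall,
    FeatureVector,
    Thresholds,
    classify_fasta,
    classify_sequence,
    global_align_score,
    nearest_reference,
)
from srscout.motifs import BLOSUM62
from srscout.synth_fixtures import FixtureSpec, make_classified_panel, make_protein


class TestGlobalAlignScore:
    def test_self_alignment_is_the_diagonal_sum(self):
        seq = "HGLWP"
        expected = sum(float(BLOSUM62[c, c]) for c in seq)
        assert global_align_score(seq, seq) == pytest.approx(expected)

    def test_linear_gap_examples(self):
        assert global_align_score(
            "ACGT", "ACG", matrix=(1, -1), gap_open=-2, gap_extend=-2
        ) == pytest.approx(1.0)
        assert global_align_score(
            "A", "AAA", matrix=(1, -1), gap_open=-2, gap_extend=-2
        ) == pytest.approx(-3.0)

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            global_align_score("", "ACGT")

    def test_equals_exhaustive_enumeration_for_short_pairs(self):
        rng = np.random.default_rng(12)
        for trial in range(60):
            a = random_protein(rng, int(rng.integers(1, 7)))
            b = random_protein(rng, int(rng.integers(1, 7)))
            if trial % 2:
                kwargs = dict(matrix=(1, -1), gap_open=-2.0, gap_extend=-2.0)
            else:
                kwargs = dict(gap_open=-5.0, gap_extend=-1.0)
            assert global_align_score(a, b, **kwargs) == pytest.approx(
                enumerate_global_score(a, b, **kwargs)
            )


class TestNearestReference:
    def _refs(self):
        return [
            (f"ref_{cls}_{i}", make_protein(cls, pi, seed=50 + i).seq, cls)
            for i, (cls, pi) in enumerate(
                [("I", 5.0), ("I", 5.5), ("II", 6.0), ("II", 5.6), ("III", 9.0)]
            )
        ]

    def test_exact_exemplar_is_its_own_class_at_distance_zero(self):
        refs = self._refs()
        label, dist = nearest_reference(refs[2][1], refs, k=1)
        assert label == "II"
        assert dist == pytest.approx(0.0, abs=1e-9)

    def test_k1_tie_between_classes_is_unclassified(self):
        refs = [("a", "HGLWPKA", "I"), ("b", "HGLWPKA", "III")]
        label, _ = nearest_reference("HGLWPKA", refs, k=2)
        assert label == "unclassified"

    def test_shuffled_query_is_farther_than_the_original(self):
        rng = np.random.default_rng(31)
        refs = self._refs()
        ref_seq = refs[0][1]
        base = nearest_reference(ref_seq, refs, k=1)[1]
        worse = 0
        for _ in range(100):
            shuffled = "".join(rng.permutation(list(ref_seq)))
            if nearest_reference(shuffled, refs, k=1)[1] > base:
                worse += 1
        assert worse >= 95

    def test_everything_distant_is_unclassified(self):
        refs = [("a", "W" * 50, "I")]
        label, _ = nearest_reference("P" * 50, refs)
        assert label == "unclassified"


class TestDecisionLadder:
    def test_eight_intron_pattern_is_class_two_exact(self):
        fv = FeatureVector(
            id="q",
            pI=5.5,
            regions_hit=5,
            cas2_his=True,
            intron_pattern=frozenset({3, 4, 5, 6, 7, 8, 10, 11}),
            pattern_names=["II"],
        )
        call = classify_sequence(fv)
        assert (call.class_label, call.confidence) == ("II", "pattern-exact")
        assert not call.s_rnase_candidate

    def test_position_five_basic_protein_is_an_s_rnase_candidate(self):
        fv = FeatureVector(
            id="q",
            pI=9.2,
            regions_hit=5,
            cas2_his=True,
            intron_pattern=frozenset({5}),
            pattern_names=["I-B", "III-C"],
            nn_class=("III", 0.1),
        )
        call = classify_sequence(fv)
        assert call.class_label == "III"
        assert call.s_rnase_candidate

    def test_i_d_pattern_acidic_is_class_one_not_candidate(self):
        fv = FeatureVector(
            id="q",
            pI=5.0,
            regions_hit=5,
            cas2_his=True,
            intron_pattern=frozenset({2, 5, 9}),
            pattern_names=["I-D"],
        )
        call = classify_sequence(fv)
        assert call.class_label == "I"
        assert not call.s_rnase_candidate

    def test_ambiguous_pattern_resolved_by_pi_alone(self):
        fv = FeatureVector(
            id="q",
            pI=5.2,
            regions_hit=4,
            cas2_his=True,
            intron_pattern=frozenset({5}),
            pattern_names=["I-B", "III-C"],
        )
        call = classify_sequence(fv)
        assert call.class_label == "I"
        assert call.confidence == "multi-line"

    @pytest.mark.parametrize(
        "pi, cas2, pattern, names, expect_candidate",
        [
            (9.0, True, frozenset({5}), ["I-B", "III-C"], True),
            (7.5, True, frozenset({5}), ["I-B", "III-C"], False),  # pI < 8
            (9.0, False, frozenset({5}), ["I-B", "III-C"], False),  # CAS II lost
            (9.0, True, frozenset({5, 9}), ["III-A"], False),  # position 9
            (9.0, True, None, [], True),  # cDNA: pattern undetermined
            (9.0, None, frozenset({1, 5}), ["III-D"], True),  # CAS undetermined ok
        ],
    )
    def test_candidate_rule(self, pi, cas2, pattern, names, expect_candidate):
        fv = FeatureVector(
            id="q",
            pI=pi,
            regions_hit=5,
            cas2_his=cas2,
            intron_pattern=pattern,
            pattern_names=names,
            nn_class=("III", 0.05),
        )
        call = classify_sequence(fv)
        assert call.s_rnase_candidate is expect_candidate

    def test_candidate_implies_class_three_on_random_vectors(self):
        rng = np.random.default_rng(77)
        patterns = [
            None,
            frozenset({5}),
            frozenset({2, 5, 9}),
            frozenset({1, 5}),
            frozenset({5, 9}),
            frozenset({3, 4, 5, 6, 7, 8, 10, 11}),
        ]
        from srscout.intron_arch import assign_pattern

        for _ in range(300):
            pattern = patterns[int(rng.integers(len(patterns)))]
            names = [] if pattern is None else assign_pattern(pattern)
            nn = (
                None
                if rng.random() < 0.3
                else (["I", "II", "III"][int(rng.integers(3))], float(rng.random()))
            )
            fv = FeatureVector(
                id="q",
                pI=float(rng.uniform(3.5, 10.5)),
                regions_hit=int(rng.integers(0, 6)),
                cas2_his=[True, False, None][int(rng.integers(3))],
                intron_pattern=pattern,
                pattern_names=names,
                nn_class=nn,
            )
            call = classify_sequence(fv)
            if call.s_rnase_candidate:
                assert call.class_label == "III"

    def test_pattern_evidence_never_breaks_a_correct_multiline_call(self):
        # monotone in evidence: adding the uniquely matching pattern to a
        # call that is already correct keeps the class
        fv_no_pattern = FeatureVector(
            id="q", pI=9.0, regions_hit=5, cas2_his=True, nn_class=("III", 0.1)
        )
        base = classify_sequence(fv_no_pattern)
        assert base.class_label == "III"
        fv_pattern = FeatureVector(
            id="q",
            pI=9.0,
            regions_hit=5,
            cas2_his=True,
            intron_pattern=frozenset({1, 5}),
            pattern_names=["III-D"],
            nn_class=("III", 0.1),
        )
        assert classify_sequence(fv_pattern).class_label == "III"

    def test_class_call_invariant(self):
        with pytest.raises(ValueError):
            ClassCall(
                class_label="I", s_rnase_candidate=True, evidence=[], confidence="x"
            )


@pytest.fixture(scope="module")
def panel30():
    spec = FixtureSpec(seed=13, n_per_class={"I": 10, "II": 10, "III": 10})
    return make_classified_panel(spec)


class TestClassifyFasta:
    def test_thirty_synthetic_genes_all_correct(self, panel30):
        genes = {r["id"]: r["gene"] for r in panel30}
        aln = {r["id"]: r["aligned_row"] for r in panel30}
        seqs = [(r["id"], r["protein"].seq) for r in panel30]
        table = classify_fasta(seqs, genes=genes, alignment=aln).set_index("id")
        for r in panel30:
            assert table.loc[r["id"], "class"] == r["true_class"]

    def test_protein_only_input_still_produces_a_call(self, panel30):
        rec = panel30[0]
        table = classify_fasta([(rec["id"], rec["protein"].seq)])
        assert len(table) == 1
        assert table.iloc[0]["pattern"] == "undetermined"
        assert table.iloc[0]["class"] != "error"

    def test_nucleotide_input_is_translated(self, panel30):
        from srscout.synth_fixtures import backtranslate

        rec = panel30[0]
        cds = "ATG" + backtranslate(rec["protein"].seq) + "TAA"
        table = classify_fasta([("nt", cds)])
        assert table.iloc[0]["regions_hit"] == 5

    def test_untranslatable_nucleotide_gives_error_row_and_continues(self, panel30):
        rec = panel30[0]
        table = classify_fasta(
            [("bad", "ACGT" * 10), (rec["id"], rec["protein"].seq)]
        )
        assert table.iloc[0]["class"] == "error"
        assert table.iloc[1]["class"] != "error"

    def test_empty_input_gives_empty_table(self):
        assert classify_fasta([]).empty
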