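"""Similarity statistic, relative divergence, filtering and categorization."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthosim.pairwise_align import LocalAlignment, align_local
from orthosim.similarity_metrics import (
    GeneComparison,
    IncompleteGeneError,
    SimilarityScore,
    UndefinedSimilarityError,
    categorize,
    compare_gene,
    filter_min_length,
    genetic_distance,
    similarity_score,
    summary_from_counts,
)

RABBIT = "Oryctolagus cuniculus"
MOUSE = "Mus musculus"


def make_alignment(n_match, n_mismatch, n_gap):
    """Synthesize a structurally valid alignment with the given column mix."""
    q = "A" * n_match + "C" * n_mismatch + "G" * n_gap
    r = "A" * n_match + "G" * n_mismatch + "-" * n_gap
    return LocalAlignment(q, r, 0, (0, len(q)), (0, n_match + n_mismatch),
                          n_match, n_mismatch, n_gap)


def make_comparison(gene, s_rabbit, s_mouse, min_len=900):
    scores = {
        RABBIT: SimilarityScore(gene, RABBIT, s_rabbit, min_len, 0, int(s_rabbit * min_len)),
        MOUSE: SimilarityScore(gene, MOUSE, s_mouse, min_len, 0, int(s_mouse * min_len)),
    }
    return GeneComparison(gene, scores, s_rabbit - s_mouse, min_len)


class TestSimilarityScore:
    def test_all_match_is_one(self):
        assert similarity_score(make_alignment(4, 0, 0)) == 1.0

    def test_worked_case_seven_ninths(self):
        # length 10, 7 matches, 2 mismatches, 1 gap column: S = 7/(10-1)
        aln = make_alignment(7, 2, 1)
        assert similarity_score(aln) == pytest.approx(7 / 9, abs=1e-15)

    def test_equals_identity_over_residue_columns(self, rng):
        # independent column-scan oracle on random aligned pairs
        for _ in range(100):
            n = int(rng.integers(10, 60))
            q = rng.choice(list("ACGT-"), size=n, p=[0.23, 0.23, 0.23, 0.23, 0.08])
            r = rng.choice(list("ACGT"), size=n)
            cols = [(a, b) for a, b in zip(q, r)]
            n_match = sum(a == b for a, b in cols if a != "-")
            n_gap = sum(a == "-" for a, b in cols)
            n_mm = n - n_match - n_gap
            aln = LocalAlignment("".join(q), "".join(r), 0, (0, n - n_gap), (0, n),
                                 n_match, n_mm, n_gap)
            residue_cols = [(a, b) for a, b in cols if a != "-"]
            mismatch_frac = sum(a != b for a, b in residue_cols) / len(residue_cols)
            assert similarity_score(aln) == pytest.approx(1 - mismatch_frac, abs=1e-12)

    def test_all_gap_alignment_is_undefined(self):
        aln = LocalAlignment("AA", "--", 0, (0, 2), (0, 0), 0, 0, 2)
        with pytest.raises(UndefinedSimilarityError):
            similarity_score(aln)


class TestGeneticDistance:
    @pytest.mark.parametrize("s,d", [(1.0, 0.0), (0.7778, 0.2222), (0.0, 1.0)])
    def test_complement(self, s, d):
        assert genetic_distance(s) == pytest.approx(d, abs=1e-12)

    def test_delta_equals_distance_difference(self, rng):
        for _ in range(100):
            s_rabbit, s_mouse = rng.random(2)
            c = make_comparison("G", s_rabbit, s_mouse)
            assert c.delta == pytest.approx(
                genetic_distance(s_mouse) - genetic_distance(s_rabbit), abs=1e-12
            )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            genetic_distance(1.5)


class TestCompareGene:
    def test_rabbit_closer_positive_delta(self):
        c = compare_gene(
            [
                SimilarityScore("G1", RABBIT, 0.90, 300, 0, 270),
                SimilarityScore("G1", MOUSE, 0.80, 300, 0, 240),
            ]
        )
        assert c.delta == pytest.approx(0.10)
        assert c.min_aligned_length == 300

    def test_equal_similarity_is_tie(self):
        c = compare_gene(
            [
                SimilarityScore("G1", RABBIT, 0.85, 300, 0, 255),
                SimilarityScore("G1", MOUSE, 0.85, 280, 0, 238),
            ]
        )
        assert c.delta == 0.0
        assert c.min_aligned_length == 280

    def test_missing_species_raises(self):
        with pytest.raises(IncompleteGeneError):
            compare_gene([SimilarityScore("G1", RABBIT, 0.9, 300, 0, 270)])


class TestLengthFilter:
    def test_strict_boundary(self):
        at, above = make_comparison("A", 0.9, 0.8, 150), make_comparison("B", 0.9, 0.8, 151)
        assert filter_min_length([at, above]) == [above]

    def test_matches_brute_force_filter(self, rng):
        lengths = rng.integers(50, 400, size=10)
        comps = [make_comparison(f"G{i}", 0.9, 0.8, int(n)) for i, n in enumerate(lengths)]
        kept = filter_min_length(comps, 150)
        assert {c.gene_symbol for c in kept} == {
            c.gene_symbol for c in comps if c.min_aligned_length > 150
        }


class TestCategorize:
    def test_three_way_split_unthresholded(self):
        comps = [
            make_comparison("A", 0.9, 0.8),   # +0.1
            make_comparison("B", 0.6, 0.8),   # -0.2
            make_comparison("C", 0.7, 0.7),   # 0.0
        ]
        s = categorize(comps)
        assert (s.n_rabbit_closer, s.n_mouse_closer, s.n_tie, s.n_total) == (1, 1, 1, 3)

    def test_threshold_excludes_small_deltas(self):
        comps = [
            make_comparison("A", 0.84, 0.80),  # +0.04 excluded
            make_comparison("B", 0.86, 0.80),  # +0.06
            make_comparison("C", 0.73, 0.80),  # -0.07
        ]
        s = categorize(comps, threshold=0.05)
        assert (s.n_total, s.n_rabbit_closer, s.n_mouse_closer) == (2, 1, 1)

    def test_reported_counts_give_reported_percentages(self):
        # the published innate-immunity comparison: 2468 rabbit-closer,
        # 320 mouse-closer, 5 exact ties out of 2793 genes
        s = summary_from_counts(2468, 320, 5)
        assert s.n_total == 2793
        assert s.pct_rabbit_closer == 88
        s5 = summary_from_counts(429, 30, 0, threshold=0.05)
        assert s5.n_total == 459
        assert (s5.pct_rabbit_closer, s5.pct_mouse_closer) == (93, 7)

    def test_empty_input_gives_zero_summary(self):
        s = categorize([])
        assert (s.n_total, s.pct_rabbit_closer) == (0, 0)
        assert math.isnan(s.frac_rabbit_closer)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1, 1, allow_nan=False), max_size=30), st.data())
    def test_conservation_permutation_and_monotonicity(self, deltas, data):
        comps = [make_comparison(f"G{i}", 0.5 + d / 2, 0.5 - d / 2) for i, d in enumerate(deltas)]
        s = categorize(comps)
        assert s.n_total == s.n_rabbit_closer + s.n_mouse_closer + s.n_tie == len(comps)
        perm = data.draw(st.permutations(comps))
        assert categorize(perm) == s
        t_low, t_high = sorted(data.draw(st.tuples(st.floats(0, 1), st.floats(0, 1))))
        assert categorize(comps, t_high).n_total <= categorize(comps, t_low).n_total

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            categorize([], threshold=-0.1)


def test_pipeline_statistic_on_real_alignment():
    """End-to-end sanity: S from an actual local alignment with a gap."""
    ref = "ATGAAACCCGGGTTTAAACCCGGG"
    query = ref[:9] + ref[12:]  # one codon deleted
    aln = align_local(query, ref)
    s = similarity_score(aln)
    assert aln.n_gap_columns == 3
    assert s == pytest.approx(aln.n_match / (aln.length - 3), abs=1e-15)
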