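"""Alignment engine: distances, signal enhancement, DP, normalised scores."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import array_shapes, arrays

from conftest import brute_force_align_score
from eba.core import (
    AlignmentResult,
    SubstitutionMatrix,
    align_pair,
    eba_scores,
    euclidean_distance_matrix,
    global_align,
    path_identity,
    signal_enhance,
)
from eba.embeddings import EmbeddingMatrix


def emb(pid, arr):
    return EmbeddingMatrix(pid, np.asarray(arr, dtype=float))


class TestDistanceMatrix:
    def test_identical_single_residue_gives_zero(self):
        e = emb("a", [[1.0, 2.0]])
        np.testing.assert_allclose(euclidean_distance_matrix(e, e).scores, [[0.0]], atol=1e-12)

    def test_pythagorean_pair(self):
        d = euclidean_distance_matrix(emb("a", [[0.0, 0.0]]), emb("b", [[3.0, 4.0]]))
        np.testing.assert_allclose(d.scores, [[5.0]], atol=1e-12)
        assert d.kind == "raw_distance"

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal((3, 2)), rng.standard_normal((4, 2))
        d = euclidean_distance_matrix(emb("a", a), emb("b", b)).scores
        expected = np.array(
            [[np.sqrt(((a[i] - b[j]) ** 2).sum()) for j in range(4)] for i in range(3)]
        )
        np.testing.assert_allclose(d, expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            euclidean_distance_matrix(emb("a", [[1.0, 2.0]]), emb("b", [[1.0, 2.0, 3.0]]))


class TestSignalEnhance:
    def test_constant_matrix_maps_to_zero(self):
        d = SubstitutionMatrix(np.full((3, 5), 7.3), "raw_distance")
        np.testing.assert_allclose(signal_enhance(d).scores, 0.0, atol=1e-12)

    def test_hand_computed_two_by_two(self):
        d = SubstitutionMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), "raw_distance")
        np.testing.assert_allclose(
            signal_enhance(d).scores, [[-0.5, 0.5], [0.5, -0.5]], atol=1e-12
        )

    def test_transpose_equivariance(self):
        rng = np.random.default_rng(11)
        d = np.abs(rng.standard_normal((4, 6)))
        a = signal_enhance(SubstitutionMatrix(d, "raw_distance")).scores
        b = signal_enhance(SubstitutionMatrix(d.T, "raw_distance")).scores
        np.testing.assert_allclose(a.T, b, atol=1e-12)

    @given(
        arrays(
            np.float64,
            array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=6),
            elements=st.floats(0, 100),
        )
    )
    def test_global_mean_of_enhanced_matrix_is_zero(self, d):
        enhanced = signal_enhance(SubstitutionMatrix(d, "raw_distance")).scores
        assert abs(enhanced.mean()) < 1e-9

    def test_requires_raw_distance_kind(self):
        s = SubstitutionMatrix(np.zeros((2, 2)), "enhanced")
        with pytest.raises(ValueError, match="raw distance"):
            signal_enhance(s)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            SubstitutionMatrix(np.zeros((0, 3)), "raw_distance")


class TestGlobalAlign:
    def test_single_cell(self):
        res = global_align(np.array([[2.0]]), gap_open=-5.0, gap_extend=-1.0)
        assert res.s_align == pytest.approx(2.0)
        assert res.path == ((0, 0),)

    def test_two_by_two_diagonal(self):
        # enumeration over all global alignments of a 2x2 gives 2 on the diagonal
        res = global_align(np.array([[1.0, -1.0], [-1.0, 1.0]]), gap_open=-1.0, gap_extend=-1.0)
        assert res.s_align == pytest.approx(2.0)
        assert res.path == ((0, 0), (1, 1))

    def test_seeded_case_matches_enumeration(self):
        rng = np.random.default_rng(3)
        S = rng.standard_normal((4, 3))
        res = global_align(S, gap_open=-1.0, gap_extend=-0.5)
        assert res.s_align == pytest.approx(brute_force_align_score(S, -1.0, -0.5))

    @pytest.mark.parametrize("gaps", [(-1.0, -1.0), (-1.0, -0.1), (-2.5, -0.5), (0.0, 0.0)])
    def test_matches_enumeration_on_seeded_grid(self, gaps):
        """Exhaustive-oracle equivalence over all shapes up to 5x5."""
        go, ge = gaps
        rng = np.random.default_rng(17)
        for l1 in range(1, 6):
            for l2 in range(1, 6):
                for _ in range(2):
                    S = rng.standard_normal((l1, l2)) * 2.0
                    got = global_align(S, gap_open=go, gap_extend=ge)
                    want = brute_force_align_score(S, go, ge)
                    assert got.s_align == pytest.approx(want), (l1, l2, gaps)

    def test_path_is_monotone_and_complete(self):
        rng = np.random.default_rng(23)
        S = rng.standard_normal((6, 9))
        res = global_align(S)
        is_, js = [], []
        for i, j in res.path:
            if i is not None:
                is_.append(i)
            if j is not None:
                js.append(j)
        assert is_ == list(range(6)) and js == list(range(9))

    def test_swap_symmetry_of_score(self):
        rng = np.random.default_rng(29)
        S = rng.standard_normal((5, 8))
        a = global_align(S)
        b = global_align(S.T)
        assert a.s_align == pytest.approx(b.s_align)
        assert tuple((j, i) for i, j in b.path) == a.path

    def test_positive_gap_penalties_rejected(self):
        with pytest.raises(ValueError, match="<= 0"):
            global_align(np.ones((2, 2)), gap_open=1.0)


class TestEbaScores:
    def test_direct_formula(self):
        assert eba_scores(100.0, 200, 250) == pytest.approx((0.4, 0.5))

    def test_zero_score(self):
        assert eba_scores(0.0, 3, 9) == (0.0, 0.0)

    @given(
        st.floats(0.001, 1e6),
        st.integers(1, 10_000),
        st.integers(1, 10_000),
    )
    def test_min_le_max_with_equality_iff_equal_lengths(self, s, l1, l2):
        lo, hi = eba_scores(s, l1, l2)
        assert lo <= hi
        assert (lo == hi) == (l1 == l2)

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            eba_scores(1.0, 0, 5)


class TestPathIdentity:
    def test_identical_sequences_diagonal(self):
        path = [(i, i) for i in range(4)]
        assert path_identity(path, "ACDE", "ACDE") == 100.0

    def test_no_matches(self):
        path = [(0, 0), (1, 1)]
        assert path_identity(path, "AC", "DE") == 0.0

    def test_two_of_three_match(self):
        path = [(0, 0), (1, 1), (2, 2)]
        assert path_identity(path, "ACD", "AED") == pytest.approx(66.7, abs=0.05)

    def test_gap_only_path_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert path_identity([(0, None), (None, 0)], "A", "C") == 0.0


class TestAlignPair:
    def test_self_pair_scores_higher_than_unrelated(self):
        rng = np.random.default_rng(31)
        a = emb("a", rng.standard_normal((12, 8)))
        b = emb("b", rng.standard_normal((12, 8)) + 4.0)
        self_res = align_pair(a, a)
        cross = align_pair(a, b)
        assert self_res.eba_min > cross.eba_min

    def test_identity_filled_when_sequences_given(self):
        rng = np.random.default_rng(37)
        a = emb("a", rng.standard_normal((4, 8)))
        res = align_pair(a, a, "ACDE", "ACDE")
        assert res.identity_pct == 100.0

    def test_ablation_mode_negates_distances(self):
        rng = np.random.default_rng(41)
        a = emb("a", rng.standard_normal((3, 4)))
        b = emb("b", rng.standard_normal((3, 4)))
        res = align_pair(a, b, enhance=False)
        assert isinstance(res, AlignmentResult)
        assert res.s_align <= 0.0  # negated distances never reward a match
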