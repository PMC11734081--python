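"""Alignment, difference scores, classical MDS and cluster separation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from nlrkit.diversity import (
    Alignment,
    Embedding,
    center_star_align,
    classical_mds,
    cluster_recovery,
    difference_matrix,
    pairwise_global,
)
from nlrkit.errors import ValidationError


def nw_score_oracle(a, b, match=1, mismatch=-1, gap=-2):
    """Exhaustive dynamic-programming global-alignment score (independent)."""
    m, n = len(a), len(b)
    S = [[0.0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        S[i][0] = i * gap
    for j in range(1, n + 1):
        S[0][j] = j * gap
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            diag = S[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            S[i][j] = max(diag, S[i - 1][j] + gap, S[i][j - 1] + gap)
    return S[m][n]


def column_score(ra, rb, match=1, mismatch=-1, gap=-2):
    s = 0.0
    for x, y in zip(ra, rb):
        if x == "-" and y == "-":
            continue
        if x == "-" or y == "-":
            s += gap
        else:
            s += match if x == y else mismatch
    return s


sequences = st.lists(
    st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=25),
    min_size=1, max_size=6,
).map(lambda seqs: [(f"s{i}", s) for i, s in enumerate(seqs)])


class TestPairwiseAlignment:
    @given(st.text(alphabet="ACDKV", min_size=1, max_size=18),
           st.text(alphabet="ACDKV", min_size=1, max_size=18))
    def test_score_matches_dp_oracle(self, a, b):
        ga, gb, score = pairwise_global(a, b)
        assert score == nw_score_oracle(a, b)
        assert column_score(ga, gb) == score
        assert ga.replace("-", "") == a and gb.replace("-", "") == b

    def test_mkv_mv_worked_example(self):
        aln = center_star_align([("p1", "MKV"), ("p2", "MV")],
                                match=1, mismatch=-1, gap=-1)
        assert aln.rows[aln.ids.index("p1")] == "MKV"
        assert aln.rows[aln.ids.index("p2")].count("-") == 1
        ga, gb, score = pairwise_global("MKV", "MV", 1, -1, -1)
        assert score == nw_score_oracle("MKV", "MV", 1, -1, -1) == 1


class TestCenterStar:
    def test_identical_sequences_gapless(self):
        aln = center_star_align([("a", "MKVA"), ("b", "MKVA"), ("c", "MKVA")])
        assert set(aln.rows) == {"MKVA"}

    def test_single_sequence(self):
        aln = center_star_align([("a", "MKV")])
        assert aln.rows == ("MKV",)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            center_star_align([])

    def test_nonnegative_gap_rejected(self):
        with pytest.raises(ValidationError):
            center_star_align([("a", "MK")], gap=0)

    @given(sequences)
    @settings(max_examples=40)
    def test_rows_ungap_to_inputs(self, seqs):
        aln = center_star_align(seqs)
        by_id = dict(seqs)
        assert len({len(r) for r in aln.rows}) == 1
        for pid, row in zip(aln.ids, aln.rows):
            assert row.replace("-", "") == by_id[pid]


class TestDifferenceMatrix:
    def test_identical_rows_zero(self):
        D, _ = difference_matrix(Alignment(("a", "b"), ("ACDE", "ACDE")))
        assert D[0, 1] == 0

    def test_one_of_four_sites(self):
        D, _ = difference_matrix(Alignment(("a", "b"), ("ACDE", "ACDA")))
        assert D[0, 1] == 0.25

    def test_gap_versus_residue_counts(self):
        D, _ = difference_matrix(Alignment(("a", "b"), ("AC-E", "ACDE")))
        assert D[0, 1] == 0.25  # 4 eligible columns, 1 differs

    def test_both_gap_columns_excluded(self):
        D, _ = difference_matrix(Alignment(("a", "b"), ("AC--", "AD--")))
        assert D[0, 1] == 0.5  # only 2 eligible columns

    def test_all_gap_pair_warns_and_scores_zero(self):
        # rows a and b share no column where either has a residue
        aln = Alignment(("a", "b", "c"), ("--", "--", "AC"))
        with pytest.warns(UserWarning):
            D, _ = difference_matrix(aln)
        assert D[0, 1] == 0

    def test_symmetric_zero_diagonal_row_order_invariant(self):
        rows = ("ACDE", "AKDE", "ACWE")
        D1, ids1 = difference_matrix(Alignment(("a", "b", "c"), rows))
        D2, ids2 = difference_matrix(Alignment(("c", "b", "a"), rows[::-1]))
        assert np.allclose(D1, D1.T) and np.all(np.diag(D1) == 0)
        perm = [ids2.index(i) for i in ids1]
        assert np.allclose(D1, D2[np.ix_(perm, perm)])


class TestClassicalMDS:
    def test_two_points(self):
        emb = classical_mds(np.array([[0.0, 2.0], [2.0, 0.0]]), k=1)
        assert np.allclose(sorted(emb.coords.ravel()), [-1.0, 1.0])

    def test_3_4_5_triangle_embeds_exactly(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        emb = classical_mds(D, k=2)
        recon = squareform(pdist(emb.coords))
        assert np.abs(recon - D).max() <= 1e-9

    def test_all_zero_matrix_puts_points_at_origin(self):
        emb = classical_mds(np.zeros((4, 4)), k=2)
        assert np.allclose(emb.coords, 0)

    @pytest.mark.parametrize("seed, dim", [(0, 2), (1, 3), (2, 5)])
    def test_full_rank_reconstruction_of_euclidean_distances(self, seed, dim):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(12, dim))
        D = squareform(pdist(pts))
        emb = classical_mds(D, k=dim)
        recon = squareform(pdist(emb.coords))
        assert np.abs(recon - D).max() <= 1e-9

    def test_k_truncated_to_positive_eigenvalues(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        emb = classical_mds(D, k=5)
        assert emb.coords.shape[1] == 1

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(8, 2))
        D = squareform(pdist(pts))
        a = classical_mds(D, k=2)
        b = classical_mds(D.copy(), k=2)
        assert np.allclose(a.coords, b.coords)
        for col in range(2):
            v = a.coords[:, col]
            assert v[np.argmax(np.abs(v))] >= 0

    def test_goodness_of_fit_in_unit_interval(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 4))
        emb = classical_mds(squareform(pdist(pts)), k=2)
        assert 0 < emb.goodness_of_fit <= 1

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]), k=1)

    def test_embedding_invariant_under_permutation(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(9, 2))
        D = squareform(pdist(pts))
        perm = rng.permutation(9)
        emb1 = classical_mds(D, k=2)
        emb2 = classical_mds(D[np.ix_(perm, perm)], k=2)
        labels = ["a"] * 5 + ["b"] * 4
        s1 = cluster_recovery(emb1, labels)
        s2 = cluster_recovery(emb2, [labels[i] for i in perm])
        assert s1 == pytest.approx(s2, abs=1e-9)


class TestClusterRecovery:
    def test_far_separated_clusters_score_high(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.5, (20, 2)), rng.normal(20, 0.5, (20, 2))])
        emb = Embedding(coords=pts, eigenvalues=np.ones(2), ids=tuple(map(str, range(40))))
        labels = ["a"] * 20 + ["b"] * 20
        assert cluster_recovery(emb, labels) > 0.8

    def test_random_labels_on_one_blob_near_zero(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(200, 2))
        labels = list(rng.choice(["a", "b"], size=200))
        emb = Embedding(coords=pts, eigenvalues=np.ones(2), ids=tuple(map(str, range(200))))
        assert abs(cluster_recovery(emb, labels)) < 0.15

    def test_coincident_clusters_nonpositive(self):
        pts = np.zeros((10, 2))
        emb = Embedding(coords=pts, eigenvalues=np.ones(2), ids=tuple(map(str, range(10))))
        assert cluster_recovery(emb, ["a"] * 5 + ["b"] * 5) <= 0

    def test_single_label_rejected(self):
        emb = Embedding(coords=np.zeros((4, 2)), eigenvalues=np.ones(2),
                        ids=("1", "2", "3", "4"))
        with pytest.raises(ValidationError):
            cluster_recovery(emb, ["a"] * 4)
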