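import numpy as np
import pytest

from hapscan.io import GenomicWindow
from hapscan.structure import (
    CandidateRegion,
    MDSEmbedding,
    cluster_outlier_windows,
    corner_outliers,
    distance_matrix,
    mds_embed,
    merge_overlapping_regions,
    window_covariance,
    window_distance,
)

W = GenomicWindow("chr1", 0, 100, 0)


def _wc(dosage, min_sites=2, k=2, window=W):
    idx = np.arange(dosage.shape[1])
    return window_covariance(dosage, window, idx, min_sites=min_sites, k=k)


class TestWindowCovariance:
    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 2, size=(6, 15))
        wc = _wc(X, min_sites=2, k=3)
        # textbook covariance: centered per site, X_c X_c^T / (m - 1)
        Xc = X - X.mean(axis=0)
        naive = np.zeros((6, 6))
        for a in range(6):
            for b in range(6):
                naive[a, b] = np.sum(Xc[a] * Xc[b]) / (X.shape[1] - 1)
        naive /= np.trace(naive)
        np.testing.assert_allclose(wc.cov, naive, atol=1e-12)
        assert np.trace(wc.cov) == pytest.approx(1.0, abs=1e-9)

    def test_two_block_structure_is_rank_one(self):
        X = np.vstack([np.zeros((4, 12)), np.full((4, 12), 2.0)])
        wc = _wc(X)
        assert wc.eigenvalues[0] == pytest.approx(1.0, abs=1e-9)

    def test_identical_samples_skipped(self):
        X = np.tile(np.linspace(0, 2, 10), (5, 1))
        assert _wc(X) is None

    def test_too_few_polymorphic_sites_skipped(self):
        X = np.zeros((5, 30))
        X[0, 0] = 1.0
        assert _wc(X, min_sites=10) is None

    def test_missing_dosages_mean_imputed(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 2, size=(5, 10))
        Xm = X.copy()
        Xm[2, 3] = np.nan
        wc = _wc(Xm)
        assert wc is not None and np.isfinite(wc.cov).all()


class TestWindowDistance:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(2)
        a = _wc(rng.uniform(0, 2, (6, 20)))
        b = _wc(rng.uniform(0, 2, (6, 20)))
        assert window_distance(a, a) == pytest.approx(0.0, abs=1e-12)
        assert window_distance(a, b) == pytest.approx(window_distance(b, a))

    def test_matches_dense_reconstruction_oracle(self):
        rng = np.random.default_rng(3)
        wcs = [_wc(rng.uniform(0, 2, (6, 20))) for _ in range(3)]
        for i in range(3):
            for j in range(3):
                # brute force: rebuild rank-2 matrices and subtract
                def rank2(w):
                    m = np.zeros_like(w.cov)
                    for a in range(2):
                        u = w.eigenvectors[:, a]
                        m += w.eigenvalues[a] * np.outer(u, u)
                    return m

                expected = np.linalg.norm(rank2(wcs[i]) - rank2(wcs[j]), "fro")
                assert window_distance(wcs[i], wcs[j]) == pytest.approx(expected, abs=1e-12)

    def test_distance_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(4)
        wcs = [_wc(rng.uniform(0, 2, (5, 15))) for _ in range(4)]
        D = distance_matrix(wcs)
        for i in range(4):
            for j in range(4):
                assert D[i, j] == pytest.approx(window_distance(wcs[i], wcs[j]), abs=1e-9)

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(5)
        a = _wc(rng.uniform(0, 2, (5, 15)))
        b = _wc(rng.uniform(0, 2, (6, 15)))
        with pytest.raises(ValueError, match="sample"):
            window_distance(a, b)


def _windows(n, chrom="chr1"):
    return [GenomicWindow(chrom, i * 100, (i + 1) * 100, i) for i in range(n)]


class TestMds:
    def test_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        emb = mds_embed(D, _windows(3), n_axes=2)
        d01 = np.linalg.norm(emb.coords[0] - emb.coords[1])
        d02 = np.linalg.norm(emb.coords[0] - emb.coords[2])
        d12 = np.linalg.norm(emb.coords[1] - emb.coords[2])
        assert d01 == pytest.approx(d02, abs=1e-9)
        assert d01 == pytest.approx(d12, abs=1e-9)

    def test_recovers_line_ordering(self):
        x = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
        D = np.abs(x[:, None] - x[None, :])
        emb = mds_embed(D, _windows(5), n_axes=3)
        order = np.argsort(emb.coords[:, 0])
        assert list(order) == [0, 1, 2, 3, 4] or list(order) == [4, 3, 2, 1, 0]
        assert emb.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)
        assert emb.degenerate[1]

    def test_duplicate_windows_coincide(self):
        x = np.array([0.0, 0.0, 3.0, 5.0])
        D = np.abs(x[:, None] - x[None, :])
        emb = mds_embed(D, _windows(4), n_axes=2)
        np.testing.assert_allclose(emb.coords[0], emb.coords[1], atol=1e-9)

    def test_zero_column_means(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = mds_embed(D, _windows(10), n_axes=5)
        np.testing.assert_allclose(emb.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_sign_convention(self):
        x = np.array([0.0, 1.0, 2.0, 10.0])
        D = np.abs(x[:, None] - x[None, :])
        emb = mds_embed(D, _windows(4), n_axes=1)
        i = np.argmax(np.abs(emb.coords[:, 0]))
        assert emb.coords[i, 0] > 0

    def test_asymmetry_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            mds_embed(D, _windows(2), n_axes=1)


def _emb(coords, chrom="chr1"):
    coords = np.asarray(coords, dtype=float)
    n, k = coords.shape
    return MDSEmbedding(
        _windows(n, chrom), coords, np.ones(k), np.zeros(k, dtype=bool)
    )


class TestCornerOutliers:
    def test_exact_count_per_corner(self):
        rng = np.random.default_rng(7)
        emb = _emb(rng.normal(size=(100, 2)))
        labels = corner_outliers(emb, pct=0.05)
        assert len(labels) == 4  # one axis pair, four corners
        for members in labels.values():
            assert len(members) == 5

    def test_extreme_window_tops_its_corner(self):
        coords = np.zeros((30, 2))
        coords[:, 0] = np.random.default_rng(8).normal(0, 0.01, 30)
        coords[:, 1] = np.random.default_rng(9).normal(0, 0.01, 30)
        coords[7] = [10.0, 10.0]
        emb = _emb(coords)
        labels = corner_outliers(emb, pct=0.05)
        assert 7 in labels[(0, 1, (1, 1))]

    def test_rotation_by_180_swaps_corner_signs(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(size=(40, 2))
        l1 = corner_outliers(_emb(coords), pct=0.05)
        l2 = corner_outliers(_emb(-coords), pct=0.05)
        for (a, b, (sa, sb)), members in l1.items():
            np.testing.assert_array_equal(members, l2[(a, b, (-sa, -sb))])

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="20"):
            corner_outliers(_emb(np.zeros((10, 2))), pct=0.05)


class TestClustering:
    @staticmethod
    def _labels_for(indices, n=50, side=1):
        """One corner label holding the given window positions, with strong
        coordinates for those windows on axis 0."""
        coords = np.zeros((n, 2))
        coords[:, 0] = -0.1 * side
        coords[list(indices), 0] = 1.0 * side
        coords[:, 1] = np.linspace(-0.2, 0.2, n)
        emb = _emb(coords)
        return {(0, 1, (side, 1)): np.array(sorted(indices))}, emb

    def test_contiguous_run_forms_region(self):
        labels, emb = self._labels_for([10, 11, 12])
        regions = cluster_outlier_windows(labels, emb, min_run=3, max_gap=2)
        assert len(regions) == 1
        assert regions[0].member_windows == [10, 11, 12]
        assert (regions[0].start, regions[0].end) == (1000, 1300)

    def test_wide_gap_blocks_merge(self):
        labels, emb = self._labels_for([10, 14])
        assert cluster_outlier_windows(labels, emb, min_run=3, max_gap=2) == []

    def test_gap_tolerant_merge_traced_by_hand(self):
        labels, emb = self._labels_for([10, 11, 13, 14, 15])
        regions = cluster_outlier_windows(labels, emb, min_run=3, max_gap=2)
        assert len(regions) == 1
        assert regions[0].member_windows == [10, 11, 13, 14, 15]
        assert regions[0].n_outliers == 5
        assert (regions[0].start, regions[0].end) == (1000, 1600)

    def test_axis_pooling_unites_corner_fragments(self):
        # two corners of the same axis side each hold half of one run
        coords = np.zeros((50, 2))
        coords[20:26, 0] = 1.0
        coords[:, 1] = np.linspace(-0.2, 0.2, 50)
        emb = _emb(coords)
        labels = {
            (0, 1, (1, 1)): np.array([23, 24, 25]),
            (0, 1, (1, -1)): np.array([20, 21, 22]),
        }
        regions = cluster_outlier_windows(labels, emb, min_run=3, max_gap=2, mode="axis")
        assert len(regions) == 1
        assert regions[0].member_windows == list(range(20, 26))

    def test_corner_mode_keeps_labels_separate(self):
        coords = np.zeros((50, 2))
        coords[20:26, 0] = 1.0
        emb = _emb(coords)
        labels = {
            (0, 1, (1, 1)): np.array([23, 24, 25]),
            (0, 1, (1, -1)): np.array([20, 21, 22]),
        }
        regions = cluster_outlier_windows(labels, emb, min_run=3, max_gap=2, mode="corner")
        # overlapping per-label regions would merge; adjacent ones stay apart
        assert len(regions) == 2

    def test_half_max_guard_drops_weak_members(self):
        # window 5 is corner-labeled but sits near the origin on axis 0
        coords = np.zeros((50, 2))
        coords[[10, 11, 12], 0] = 1.0
        coords[5, 0] = 0.1
        emb = _emb(coords)
        labels = {(0, 1, (1, 1)): np.array([5, 10, 11, 12])}
        regions = cluster_outlier_windows(labels, emb, min_run=3, max_gap=2)
        assert len(regions) == 1 and regions[0].member_windows == [10, 11, 12]

    def test_merge_overlapping_regions_unions_members(self):
        r1 = CandidateRegion("chr1", 0, 300, [0, 1, 2], (0, 1), 3)
        r2 = CandidateRegion("chr1", 200, 500, [2, 3, 4], (1, 1), 3)
        r3 = CandidateRegion("chr2", 0, 300, [0, 1, 2], (0, 1), 3)
        merged = merge_overlapping_regions([r1, r2, r3])
        assert len(merged) == 2
        assert merged[0].member_windows == [0, 1, 2, 3, 4]
        assert merged[0].end == 500


class TestSamplePermutationEquivariance:
    def test_distances_and_regions_unchanged(self):
        rng = np.random.default_rng(11)
        n_samples, n_windows = 12, 25
        dosage = rng.uniform(0, 2, size=(n_samples, n_windows * 10))
        windows = _windows(n_windows)
        idx = [np.arange(i * 10, (i + 1) * 10) for i in range(n_windows)]
        perm = rng.permutation(n_samples)
        wcs_a = [window_covariance(dosage, w, i, min_sites=2) for w, i in zip(windows, idx)]
        wcs_b = [window_covariance(dosage[perm], w, i, min_sites=2) for w, i in zip(windows, idx)]
        Da = distance_matrix([w for w in wcs_a if w])
        Db = distance_matrix([w for w in wcs_b if w])
        np.testing.assert_allclose(Da, Db, atol=1e-9)
        ea = mds_embed(Da, windows)
        eb = mds_embed(Db, windows)
        np.testing.assert_allclose(np.abs(ea.coords), np.abs(eb.coords), atol=1e-7)
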