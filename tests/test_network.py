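"""Filter-bank network: patch algebra, eigen oracles, encoding contracts."""

import numpy as np
import pytest

import eecgnet as e
from eecgnet.network import _transform_one

# ---------------------------------------------------------------- oracles


def patches_bruteforce(image, k1, k2):
    """Independent patch extraction: explicit loops over a zero-padded image."""
    m, n = image.shape
    p1, p2 = (k1 - 1) // 2, (k2 - 1) // 2
    padded = np.zeros((m + 2 * p1, n + 2 * p2))
    padded[p1: p1 + m, p2: p2 + n] = image
    cols = []
    for i in range(m):
        for j in range(n):
            patch = padded[i: i + k1, j: j + k2]
            cols.append(patch.flatten(order="F"))
    return np.array(cols).T


def convolve_bruteforce(image, kernel):
    """Direct double-loop 'same' 2-D convolution (kernel flipped)."""
    m, n = image.shape
    k1, k2 = kernel.shape
    c1, c2 = (k1 - 1) // 2, (k2 - 1) // 2
    out = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            acc = 0.0
            for a in range(k1):
                for b in range(k2):
                    ii, jj = i - (a - c1), j - (b - c2)
                    if 0 <= ii < m and 0 <= jj < n:
                        acc += kernel[a, b] * image[ii, jj]
            out[i, j] = acc
    return out


def count_blocks_bruteforce(rows, cols, h1, h2, s1, s2):
    """Enumerate every fully contained block start position."""
    count = 0
    for i in range(0, rows - h1 + 1, s1):
        for j in range(0, cols - h2 + 1, s2):
            count += 1
    return count


# ---------------------------------------------------------------- patches


class TestPatchMatrix:
    def test_center_column_is_the_whole_image(self):
        img = np.arange(9.0).reshape(3, 3)
        X = e.extract_patch_matrix(img, 3, 3)
        assert X.shape == (9, 9)
        np.testing.assert_array_equal(X[:, 4], img.flatten(order="F"))

    def test_corner_patch_zero_padded(self):
        img = np.ones((3, 3))
        X = e.extract_patch_matrix(img, 3, 3)
        corner = X[:, 0].reshape(3, 3, order="F")
        assert corner[0, 0] == 0 and corner[0, 1] == 0 and corner[1, 0] == 0
        assert corner[1, 1] == 1

    @pytest.mark.parametrize("m,n,k1,k2", [(5, 7, 3, 3), (8, 8, 5, 3), (6, 6, 1, 1)])
    def test_matches_bruteforce_extraction(self, m, n, k1, k2):
        img = np.random.default_rng(0).normal(size=(m, n))
        np.testing.assert_allclose(e.extract_patch_matrix(img, k1, k2),
                                   patches_bruteforce(img, k1, k2), atol=1e-14)

    def test_even_patch_dims_rejected(self):
        with pytest.raises(ValueError):
            e.extract_patch_matrix(np.ones((4, 4)), 2, 3)

    def test_mean_removal_zeroes_column_sums(self):
        X = np.random.default_rng(1).normal(size=(9, 40))
        Xb = e.remove_patch_mean(X)
        assert np.abs(Xb.sum(axis=0)).max() < 1e-9
        np.testing.assert_allclose(e.remove_patch_mean(np.full((5, 3), 7.0)), 0.0)
        np.testing.assert_allclose(
            e.remove_patch_mean(np.array([[1.0], [2.0], [3.0]])).ravel(),
            [-1.0, 0.0, 1.0])


# ---------------------------------------------------------------- filters


class TestLearnFilters:
    def test_diagonal_scatter_gives_canonical_filters(self):
        # Xbar with rows scaled so Xbar Xbar^T = diag(8, 2, 0, ...)
        Xbar = np.zeros((9, 9))
        Xbar[0, 0] = np.sqrt(8.0)
        Xbar[1, 1] = np.sqrt(2.0)
        bank = e.learn_pca_filters(Xbar, 2, 3, 3)
        np.testing.assert_allclose(bank.eigenvalues, [8.0, 2.0], atol=1e-12)
        e1 = np.zeros(9); e1[0] = 1
        e2 = np.zeros(9); e2[1] = 1
        np.testing.assert_allclose(bank.filters[0].flatten(order="F"), e1, atol=1e-12)
        np.testing.assert_allclose(bank.filters[1].flatten(order="F"), e2, atol=1e-12)

    def test_matches_dense_eigendecomposition(self):
        """Oracle: direct eigh of the 9x9 scatter, compared by |cosine|."""
        rng = np.random.default_rng(2)
        Xbar = e.remove_patch_mean(rng.normal(size=(9, 200)))
        bank = e.learn_pca_filters(Xbar, 4, 3, 3)
        evals, evecs = np.linalg.eigh(Xbar @ Xbar.T)
        order = np.argsort(evals)[::-1]
        for l in range(4):
            v = bank.filters[l].flatten(order="F")
            u = evecs[:, order[l]]
            assert abs(np.dot(v, u)) >= 1 - 1e-8
            assert np.isclose(bank.eigenvalues[l], evals[order[l]])

    def test_complete_basis_reconstructs_exactly(self):
        rng = np.random.default_rng(3)
        Xbar = e.remove_patch_mean(rng.normal(size=(9, 50)))
        bank = e.learn_pca_filters(Xbar, 9, 3, 3)
        V = np.stack([f.flatten(order="F") for f in bank.filters])
        np.testing.assert_allclose(V.T @ (V @ Xbar), Xbar, atol=1e-8)

    def test_orthonormal_and_descending(self):
        rng = np.random.default_rng(4)
        Xbar = e.remove_patch_mean(rng.normal(size=(25, 300)))
        bank = e.learn_pca_filters(Xbar, 10, 5, 5)
        V = np.stack([f.flatten(order="F") for f in bank.filters])
        np.testing.assert_allclose(V @ V.T, np.eye(10), atol=1e-8)
        assert np.all(np.diff(bank.eigenvalues) <= 1e-8)

    def test_captured_variance_equals_eigenvalue(self):
        rng = np.random.default_rng(5)
        Xbar = e.remove_patch_mean(rng.normal(size=(9, 400)))
        bank = e.learn_pca_filters(Xbar, 4, 3, 3)
        for l in range(4):
            v = bank.filters[l].flatten(order="F")
            assert np.isclose(np.sum((v @ Xbar) ** 2), bank.eigenvalues[l],
                              rtol=1e-8)


# ---------------------------------------------------------------- convolution


class TestConvolveBank:
    def test_delta_kernel_is_identity(self):
        img = np.random.default_rng(6).normal(size=(10, 10))
        delta = np.zeros((3, 3)); delta[1, 1] = 1.0
        bank = e.FilterBank(filters=delta[None], eigenvalues=np.array([1.0]), stage=1)
        np.testing.assert_allclose(e.convolve_bank(img, bank)[0], img, atol=1e-12)

    def test_box_kernel_sums_interior_ones(self):
        img = np.ones((6, 6))
        box = np.ones((3, 3))
        bank = e.FilterBank(filters=box[None], eigenvalues=np.array([1.0]), stage=1)
        out = e.convolve_bank(img, bank)[0]
        np.testing.assert_allclose(out[1:-1, 1:-1], 9.0)
        assert out[0, 0] == 4.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        img = rng.normal(size=(8, 8))
        kern = rng.normal(size=(3, 3))
        bank = e.FilterBank(filters=kern[None], eigenvalues=np.array([1.0]), stage=1)
        np.testing.assert_allclose(e.convolve_bank(img, bank)[0],
                                   convolve_bruteforce(img, kern), atol=1e-10)


# ---------------------------------------------------------------- fit


class TestFit:
    def test_deterministic(self, random_images):
        p = e.PCANetParams(k1=3, k2=3, L1=4, L2=4, h1=4, h2=4, R=0.5)
        a = e.fit(random_images, p)
        b = e.fit(random_images, p)
        np.testing.assert_array_equal(a.stage1.filters, b.stage1.filters)
        np.testing.assert_array_equal(a.stage2.filters, b.stage2.filters)

    def test_stage2_pools_all_channels(self, random_images):
        """Stage-2 scatter equals the pooled N*L1-map patch scatter."""
        p = e.PCANetParams(k1=3, k2=3, L1=2, L2=2, h1=4, h2=4, R=0.5)
        model = e.fit(random_images[:4], p)
        pooled = []
        for im in random_images[:4]:
            for mp in e.convolve_bank(im, model.stage1):
                pooled.append(e.remove_patch_mean(e.extract_patch_matrix(mp, 3, 3)))
        Y = np.hstack(pooled)
        assert Y.shape[1] == 4 * 2 * 64
        evals = np.sort(np.linalg.eigvalsh(Y @ Y.T))[::-1]
        np.testing.assert_allclose(model.stage2.eigenvalues, evals[:2], rtol=1e-8)

    def test_zero_image_degenerate(self):
        """An all-zero training image has zero patch scatter after mean
        removal (a nonzero constant would not: its zero-padded border patches
        still carry variance)."""
        p = e.PCANetParams(k1=3, k2=3, L1=2, L2=2, h1=4, h2=4, R=0.5)
        with pytest.raises(ValueError, match="degenerate"):
            e.fit([np.zeros((8, 8))], p)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            e.fit([], e.PCANetParams(k1=3, k2=3, L1=2, L2=2, h1=4, h2=4))

    def test_model_round_trips_through_disk(self, tmp_path, random_images):
        p = e.PCANetParams(k1=3, k2=3, L1=3, L2=3, h1=4, h2=4, R=0.5)
        model = e.fit(random_images, p)
        model.save(tmp_path / "model")
        back = e.EECGNetModel.load(tmp_path / "model")
        np.testing.assert_array_equal(back.stage1.filters, model.stage1.filters)
        np.testing.assert_array_equal(back.stage2.filters, model.stage2.filters)
        assert back.params == model.params
        assert back.image_dims == model.image_dims


# ---------------------------------------------------------------- encoding


class TestBinarizeEncode:
    def test_all_positive_maps_give_full_code(self):
        maps = np.ones((3, 5, 5))
        np.testing.assert_array_equal(e.binarize_and_encode(maps, 3),
                                      np.full((5, 5), 7))

    def test_nonpositive_maps_give_zero(self):
        maps = np.concatenate([np.zeros((2, 4, 4)), -np.ones((1, 4, 4))])
        np.testing.assert_array_equal(e.binarize_and_encode(maps, 3), 0)

    def test_mixed_signs_weighted_by_power_of_two(self):
        maps = np.stack([np.full((2, 2), 1.0), np.full((2, 2), -1.0),
                         np.full((2, 2), 0.5)])
        np.testing.assert_array_equal(e.binarize_and_encode(maps, 3), 5)

    def test_map_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            e.binarize_and_encode(np.ones((2, 4, 4)), 3)


class TestBlockGeometry:
    @pytest.mark.parametrize("h,R,expect", [(7, 0.5, 4), (7, 0.0, 7), (7, 0.9, 1)])
    def test_stride_round_half_up_with_floor(self, h, R, expect):
        assert e.compute_strides(h, h, R) == (expect, expect)

    def test_single_block_when_block_fills_image(self):
        assert e.count_blocks(5, 5, 5, 5, 1, 1) == 1

    def test_34x34_grid_counts(self):
        assert e.count_blocks(34, 34, 7, 7, 4, 4) == 49
        assert e.count_blocks(34, 34, 7, 7, 3, 3) == 100

    @pytest.mark.parametrize("rows,cols", [(28, 28), (34, 34), (40, 46), (13, 9)])
    def test_matches_enumeration_oracle(self, rows, cols):
        for h in (3, 5, 7, 9):
            if h > min(rows, cols):
                continue
            for s in (1, 2, 3, 4, h):
                assert e.count_blocks(rows, cols, h, h, s, s) == \
                    count_blocks_bruteforce(rows, cols, h, h, s, s)

    def test_block_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            e.count_blocks(5, 5, 7, 7, 1, 1)


class TestSlideBlocks:
    def test_block_equal_to_image_is_single_vectorized_block(self):
        T = np.arange(16).reshape(4, 4)
        p = e.PCANetParams(k1=3, k2=3, L1=1, L2=1, h1=4, h2=4, R=0.0)
        blocks = e.slide_blocks(T, p)
        assert blocks.shape == (16, 1)
        np.testing.assert_array_equal(blocks[:, 0], T.flatten(order="F"))

    def test_34x34_default_blocking(self):
        T = np.random.default_rng(8).integers(0, 256, (34, 34))
        p = e.PCANetParams()  # h=7, R=0.5 -> stride 4
        blocks = e.slide_blocks(T, p)
        assert blocks.shape == (49, 49)
        assert set(np.unique(blocks)) <= set(np.unique(T))


class TestBlockHistograms:
    def test_constant_block_concentrates_in_one_bin(self):
        blocks = np.full((9, 1), 5)
        hist = e.block_histograms(blocks, 3)
        assert hist.shape == (8,)
        assert hist[5] == 9 and hist.sum() == 9

    def test_histograms_sum_to_block_size(self):
        rng = np.random.default_rng(9)
        blocks = rng.integers(0, 16, (25, 7))
        hist = e.block_histograms(blocks, 4)
        assert hist.shape == (16 * 7,)
        np.testing.assert_array_equal(hist.reshape(7, 16).sum(axis=1), 25)

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError):
            e.block_histograms(np.array([[8]]), 3)


# ---------------------------------------------------------------- transform


class TestTransform:
    def test_feature_length_formula(self):
        p = e.PCANetParams()  # k=7, L=8, h=7, R=0.5
        assert e.feature_length(p, 28, 28) == 2**8 * 8 * 49 == 100352

    def test_transform_contracts(self, random_images):
        p = e.PCANetParams(k1=3, k2=3, L1=4, L2=4, h1=4, h2=4, R=0.5)
        model = e.fit(random_images, p)
        F = e.transform(model, random_images[:5]).toarray()
        assert F.shape == (5, e.feature_length(p, 8, 8))
        assert np.all(F >= 0)
        np.testing.assert_array_equal(F, F.astype(int))
        s1, s2 = e.compute_strides(4, 4, 0.5)
        B = e.count_blocks(10, 10, 4, 4, s1, s2)
        np.testing.assert_array_equal(F.sum(axis=1), 4 * B * 16)

    def test_transform_deterministic(self, random_images):
        p = e.PCANetParams(k1=3, k2=3, L1=2, L2=3, h1=4, h2=4, R=0.5)
        model = e.fit(random_images, p)
        a = e.transform(model, random_images[:3]).toarray()
        b = e.transform(model, random_images[:3]).toarray()
        np.testing.assert_array_equal(a, b)

    def test_dim_mismatch_rejected(self, random_images):
        p = e.PCANetParams(k1=3, k2=3, L1=2, L2=2, h1=4, h2=4)
        model = e.fit(random_images, p)
        with pytest.raises(ValueError):
            e.transform(model, [np.zeros((9, 9))])

    def test_decimal_range_inside_transform(self, random_images):
        p = e.PCANetParams(k1=3, k2=3, L1=2, L2=5, h1=4, h2=4, R=0.5)
        model = e.fit(random_images, p)
        maps1 = e.convolve_bank(random_images[0], model.stage1)
        T = e.binarize_and_encode(e.convolve_bank(maps1[0], model.stage2), 5)
        assert T.min() >= 0 and T.max() <= 2**5 - 1
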