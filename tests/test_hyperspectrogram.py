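"""PCA diagnostics, hyperspectrogram assembly, score-image reconstruction.

The PCA, Q-residual and Hotelling-T² paths are each checked against an
independent brute-force oracle (covariance eigendecomposition, explicit
per-row reconstruction, explicit score/eigenvalue summation).
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import brulat as bl
from brulat.dataset import disc_mask
from brulat.hypercube import PixelMatrix
from brulat.simulate import demo_config


def _random_matrix(n, p, seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n, p)) @ rng.normal(size=(p, p))
    return PixelMatrix(values, (n, 1), pixel_indices=np.arange(n))


class TestFitPCA:
    def test_loadings_orthonormal(self):
        X = _random_matrix(20, 6, 0)
        model = bl.fit_pca(X, 4)
        assert np.allclose(model.loadings @ model.loadings.T, np.eye(4),
                           atol=1e-10)

    def test_eigenvalues_match_covariance_eigendecomposition(self):
        X = _random_matrix(20, 6, 1)
        model = bl.fit_pca(X, 6)
        cov = np.cov(X.values, rowvar=False, ddof=1)
        expected = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(model.eigenvalues, expected, atol=1e-8)

    def test_rank_one_matrix_concentrates_variance(self):
        u = np.outer(np.arange(8, dtype=float), np.ones(5))
        X = PixelMatrix(u, (8, 1), pixel_indices=np.arange(8))
        model = bl.fit_pca(X, 1)
        total = np.var(u, axis=0, ddof=1).sum()
        assert model.eigenvalues[0] == pytest.approx(total)

    def test_sign_convention_deterministic(self):
        X = _random_matrix(30, 8, 2)
        m1, m2 = bl.fit_pca(X, 3), bl.fit_pca(X, 3)
        assert np.array_equal(m1.loadings, m2.loadings)
        for row in m1.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_scores_reproduce_centred_projection(self):
        X = _random_matrix(15, 5, 3)
        model = bl.fit_pca(X, 2)
        expected = (X.values - X.values.mean(0)) @ model.loadings.T
        assert np.allclose(model.scores(X), expected)

    def test_component_count_out_of_range_raises(self):
        X = _random_matrix(10, 4, 4)
        with pytest.raises(ValueError):
            bl.fit_pca(X, 5)


class TestQResidual:
    def test_matches_bruteforce_reconstruction(self):
        X = _random_matrix(10, 4, 5)
        model = bl.fit_pca(X, 2)
        scores = model.scores(X)
        recon = model.mean + scores @ model.loadings
        expected = np.sum((X.values - recon) ** 2, axis=1)
        assert np.allclose(bl.q_residual(model, X), expected, atol=1e-10)

    def test_full_rank_gives_zero(self):
        X = _random_matrix(10, 4, 6)
        model = bl.fit_pca(X, 4)
        assert np.allclose(bl.q_residual(model, X), 0.0, atol=1e-18)

    def test_in_plane_pixel_has_zero_residual(self):
        X = _random_matrix(12, 5, 7)
        model = bl.fit_pca(X, 3)
        in_plane = PixelMatrix(
            model.mean + np.array([[0.3, -1.2, 0.7]]) @ model.loadings,
            (1, 1))
        assert bl.q_residual(model, in_plane)[0] == pytest.approx(0.0, abs=1e-20)

    def test_q_decreases_as_components_grow(self):
        X = _random_matrix(30, 8, 8)
        means = [bl.q_residual(bl.fit_pca(X, a), X).mean() for a in (1, 2, 4, 8)]
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_band_mismatch_raises(self):
        model = bl.fit_pca(_random_matrix(10, 4, 9), 2)
        with pytest.raises(ValueError, match="band count"):
            bl.q_residual(model, _random_matrix(10, 5, 9))


class TestHotellingT2:
    def test_matches_bruteforce_summation(self):
        X = _random_matrix(10, 4, 10)
        model = bl.fit_pca(X, 2)
        scores = model.scores(X)
        expected = (scores ** 2 / model.eigenvalues).sum(axis=1)
        assert np.allclose(bl.hotelling_t2(model, X), expected, atol=1e-10)

    def test_mean_spectrum_has_zero_t2(self):
        X = _random_matrix(10, 4, 11)
        model = bl.fit_pca(X, 2)
        at_mean = PixelMatrix(model.mean[None, :], (1, 1))
        assert bl.hotelling_t2(model, at_mean)[0] == pytest.approx(0.0, abs=1e-16)

    def test_non_negative(self):
        X = _random_matrix(40, 6, 12)
        model = bl.fit_pca(X, 3)
        assert np.all(bl.hotelling_t2(model, X) >= 0)

    def test_zero_eigenvalue_raises(self):
        X = _random_matrix(10, 4, 13)
        model = bl.fit_pca(X, 2)
        model.eigenvalues = np.array([model.eigenvalues[0], 0.0])
        with pytest.raises(ValueError, match="eigenvalue"):
            bl.hotelling_t2(model, X)


class TestHyperspectrogram:
    def test_length_formula_and_sorted_segments(self):
        rng = np.random.default_rng(1)
        n, b, A = 64, 12, 3
        X = PixelMatrix(rng.normal(size=(n, b)), (8, 8))
        model = bl.fit_pca(X, A)
        h = bl.build_hyperspectrogram(model, X)
        assert h.signal.size == A * b + (A + 2) * n
        for name in ("score_pc1", "score_pc2", "score_pc3", "q_residual",
                     "hotelling_t2"):
            seg = h.segment(name)
            assert seg.size == n
            assert np.all(np.diff(seg) >= 0)
        assert np.array_equal(h.segment("loadings"),
                              model.loadings.ravel())

    @given(lines=st.integers(1, 6), samples=st.integers(1, 6),
           bands=st.integers(4, 10), A=st.integers(1, 3))
    def test_length_formula_property(self, lines, samples, bands, A):
        rng = np.random.default_rng(lines + 7 * samples + 31 * bands + A)
        n = lines * samples
        if A > min(n - 1, bands):  # T² needs strictly positive eigenvalues
            return
        X = PixelMatrix(rng.normal(size=(n, bands)), (lines, samples))
        h = bl.build_hyperspectrogram(bl.fit_pca(X, A), X)
        assert h.signal.size == A * bands + (A + 2) * n

    def test_histogram_variant_length(self):
        rng = np.random.default_rng(2)
        X = PixelMatrix(rng.normal(size=(36, 8)), (6, 6))
        model = bl.fit_pca(X, 2)
        h = bl.build_hyperspectrogram(model, X, distribution="histogram",
                                      n_bins=20)
        assert h.signal.size == 2 * 8 + 4 * 20

    def test_serialization_frame(self):
        rng = np.random.default_rng(3)
        X = PixelMatrix(rng.normal(size=(16, 6)), (4, 4))
        h = bl.build_hyperspectrogram(bl.fit_pca(X, 2), X)
        frame, seg_map = h.to_frame()
        assert len(frame) == h.signal.size
        assert seg_map[0]["name"] == "score_pc1"


class TestCompressionRatio:
    def test_instrument_frame_value(self):
        assert bl.compression_ratio(404, 384, 288, 3) == 57.5

    def test_desk_scale_value(self):
        assert bl.compression_ratio(64, 64, 288, 3) == 55.3

    def test_degenerate_dimensions(self):
        assert bl.compression_ratio(1, 1, 1, 1) == pytest.approx(1 / 6, abs=0.05)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            bl.compression_ratio(0, 10, 10, 1)


class TestScoreImage:
    def test_fold_unfold_consistency(self, small_cube):
        X = bl.unfold(small_cube)
        model = bl.fit_pca(X, 3)
        img = bl.score_image(model, X, 1)
        assert np.allclose(img.ravel(), model.scores(X)[:, 1])

    def test_rescaled_image_in_unit_interval(self, small_cube):
        X = bl.unfold(small_cube)
        img = bl.score_image(bl.fit_pca(X, 2), X, 0, rescale=True)
        assert img.min() == 0.0 and img.max() == 1.0

    def test_latent_bruise_contrast_in_pc2_or_pc3(self):
        cube, truth = bl.generate_hypercube(demo_config(), "L2", 1, seed=7)
        X = bl.unfold(cube)
        model = bl.fit_pca(X, 3)
        outside = truth.fruit_mask & ~truth.bruise_mask
        contrasts = [bl.mask_contrast(bl.score_image(model, X, pc),
                                      truth.bruise_mask, outside)
                     for pc in (1, 2)]
        assert max(contrasts) >= 2.0

    def test_sound_cube_shows_no_contrast(self):
        cube, truth = bl.generate_hypercube(demo_config(), "sound", 1, seed=7)
        X = bl.unfold(cube)
        model = bl.fit_pca(X, 3)
        disc = disc_mask(truth.fruit_mask.shape, (48, 48), 10) & truth.fruit_mask
        outside = truth.fruit_mask & ~disc
        contrasts = [bl.mask_contrast(bl.score_image(model, X, pc), disc,
                                      outside) for pc in (1, 2)]
        assert max(contrasts) < 2.0

    def test_bad_component_raises(self, small_cube):
        X = bl.unfold(small_cube)
        with pytest.raises(ValueError):
            bl.score_image(bl.fit_pca(X, 2), X, 2)
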