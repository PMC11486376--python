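"""FID / FID-STD / MSE / SSIM identities and cross-implementation checks."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings, strategies as st

from omicsdiff.metrics import (
    EmbeddingSet,
    embed_images,
    fid,
    fid_std,
    mse,
    ssim,
)


def _gauss_set(rng, n, d, mu=None, scale=1.0, tag="pixels"):
    f = rng.standard_normal((n, d)) * scale
    if mu is not None:
        f = f - f.mean(axis=0) + np.asarray(mu)
    return EmbeddingSet(f, tag)


class TestEmbedImages:
    def test_identical_images_zero_covariance(self):
        imgs = np.tile(np.arange(16.0).reshape(4, 4), (3, 1, 1))
        e = embed_images(imgs, "pixels")
        np.testing.assert_allclose(e.sigma, 0.0, atol=1e-12)

    def test_mean_matches_brute_force(self, rng):
        imgs = rng.uniform(0, 1, (5, 3, 3))
        e = embed_images(imgs, "pixels")
        brute = np.array([
            sum(imgs[i].ravel()[j] for i in range(5)) / 5 for j in range(9)
        ])
        np.testing.assert_allclose(e.mu, brute, atol=1e-12)

    def test_covariance_denominator_n_minus_1(self, rng):
        imgs = rng.uniform(0, 1, (6, 2, 2))
        e = embed_images(imgs, "pixels")
        flat = imgs.reshape(6, -1)
        centered = flat - flat.mean(axis=0)
        np.testing.assert_allclose(e.sigma, centered.T @ centered / 5, atol=1e-12)

    def test_pca_matches_eigendecomposition(self, rng):
        """PCA scores equal projection onto the top covariance eigenvectors
        (up to sign), and retain the leading eigenvalue variance."""
        imgs = rng.standard_normal((10, 4, 4))
        k = 3
        e = embed_images(imgs, "pca", n_components=k)
        flat = imgs.reshape(10, -1)
        centered = flat - flat.mean(axis=0)
        w, v = np.linalg.eigh(centered.T @ centered / 9)
        top = v[:, ::-1][:, :k]
        expected = centered @ top
        for j in range(k):
            assert (
                np.allclose(e.features[:, j], expected[:, j], atol=1e-8)
                or np.allclose(e.features[:, j], -expected[:, j], atol=1e-8)
            )
        np.testing.assert_allclose(
            e.features.var(axis=0, ddof=1), w[::-1][:k], atol=1e-8
        )

    def test_too_few_images(self):
        with pytest.raises(ValueError):
            embed_images(np.zeros((1, 4, 4)))

    def test_inception_requires_external_weights(self, rng):
        with pytest.raises(NotImplementedError):
            embed_images(rng.uniform(0, 1, (3, 4, 4)), "inception")


class TestFid:
    def test_identical_sets_score_zero(self, rng):
        e = _gauss_set(rng, 20, 4)
        assert fid(e, e) == pytest.approx(0.0, abs=1e-6)

    def test_mean_shift_closed_form(self, rng):
        """Equal covariances: the trace term cancels and FID = ||d||^2."""
        base = rng.standard_normal((30, 3))
        d = np.array([0.5, -1.0, 2.0])
        e1 = EmbeddingSet(base, "pixels")
        e2 = EmbeddingSet(base + d, "pixels")
        assert fid(e1, e2) == pytest.approx(float(d @ d), rel=1e-10)

    def test_matches_scipy_sqrtm(self, rng):
        """Cross-check against an independent matrix square root."""
        e1 = _gauss_set(rng, 40, 2)
        e2 = _gauss_set(rng, 35, 2, mu=[1.0, -0.5], scale=2.0)
        covmean = scipy.linalg.sqrtm(e1.sigma @ e2.sigma)
        expected = float(
            (e1.mu - e2.mu) @ (e1.mu - e2.mu)
            + np.trace(e1.sigma + e2.sigma - 2 * np.real(covmean))
        )
        assert fid(e1, e2) == pytest.approx(expected, abs=1e-8)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        e1 = _gauss_set(r, 12, 3)
        e2 = _gauss_set(r, 15, 3, scale=1.7)
        assert fid(e1, e2) == pytest.approx(fid(e2, e1), abs=1e-8)

    def test_monotone_in_mean_shift(self, rng):
        base = rng.standard_normal((25, 3))
        e1 = EmbeddingSet(base, "pixels")
        vals = [
            fid(e1, EmbeddingSet(base + s, "pixels")) for s in (0.1, 0.5, 1.0, 2.0)
        ]
        assert vals == sorted(vals)

    def test_extractor_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fid(_gauss_set(rng, 5, 2, tag="pixels"), _gauss_set(rng, 5, 2, tag="pca2"))


class TestFidStd:
    def test_identical_batches_zero(self, rng):
        real = _gauss_set(rng, 20, 3)
        g = _gauss_set(rng, 10, 3)
        assert fid_std(real, [g, g, g]) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_formula(self, rng):
        real = _gauss_set(rng, 20, 3)
        g1, g2 = _gauss_set(rng, 10, 3), _gauss_set(rng, 10, 3, scale=2.0)
        f1, f2 = fid(real, g1), fid(real, g2)
        assert fid_std(real, [g1, g2]) == pytest.approx(abs(f1 - f2) / np.sqrt(2))

    def test_matches_brute_force_sd(self, rng):
        real = _gauss_set(rng, 20, 3)
        batches = [_gauss_set(rng, 8, 3, scale=1 + 0.3 * i) for i in range(5)]
        vals = [fid(real, b) for b in batches]
        assert fid_std(real, batches) == pytest.approx(np.std(vals, ddof=1))

    def test_needs_two_batches(self, rng):
        with pytest.raises(ValueError):
            fid_std(_gauss_set(rng, 5, 2), [_gauss_set(rng, 5, 2)])


class TestMse:
    def test_identity_and_hand_example(self, rng):
        img = rng.uniform(0, 1, (4, 4))
        assert mse(img, img) == 0.0
        assert mse(np.array([0.0, 1.0]), np.array([1.0, 1.0])) == pytest.approx(0.5)

    def test_matches_brute_force(self, rng):
        a, b = rng.uniform(0, 1, (2, 5, 5))
        brute = sum(
            (a[i, j] - b[i, j]) ** 2 for i in range(5) for j in range(5)
        ) / 25
        assert mse(a, b) == pytest.approx(brute, rel=1e-12)

    def test_zero_iff_identical(self, rng):
        a = rng.uniform(0, 1, (3, 3))
        b = a.copy()
        b[0, 0] += 1e-9
        assert mse(a, b) > 0


class TestSsim:
    def test_self_similarity_is_one(self, rng):
        img = rng.uniform(0, 1, (8, 8))
        assert ssim(img, img, L=1.0, mode="global") == pytest.approx(1.0)
        assert ssim(img, img, L=1.0, mode="windowed") == pytest.approx(1.0)

    def test_constant_images_closed_form(self):
        """a=0 vs b=1 at L=1: variance terms cancel through c2 and the value
        reduces to c1 / (1 + c1) = 9.999e-5."""
        a = np.zeros((6, 6))
        b = np.ones((6, 6))
        got = ssim(a, b, L=1.0, k1=0.01, mode="global")
        assert got == pytest.approx(1e-4 / (1 + 1e-4), rel=1e-10)
        assert got == pytest.approx(9.999e-5, rel=1e-4)

    def test_windowed_matches_exhaustive_windows(self, rng):
        """Sliding-window mode equals materialising every 7x7 window and
        averaging the per-window statistic."""
        a, b = rng.uniform(0, 1, (2, 8, 8))
        got = ssim(a, b, L=1.0, mode="windowed", win_size=7)
        c1, c2 = 0.01**2, 0.03**2
        vals = []
        for i in range(2):
            for j in range(2):
                x = a[i : i + 7, j : j + 7].ravel()
                y = b[i : i + 7, j : j + 7].ravel()
                mx, my = x.mean(), y.mean()
                vx, vy = x.var(ddof=1), y.var(ddof=1)
                cov = ((x - mx) * (y - my)).sum() / 48
                vals.append(
                    (2 * mx * my + c1) * (2 * cov + c2)
                    / ((mx**2 + my**2 + c1) * (vx + vy + c2))
                )
        assert got == pytest.approx(np.mean(vals), rel=1e-12)

    def test_windowed_matches_skimage(self, rng):
        from skimage.metrics import structural_similarity

        a, b = rng.uniform(0, 1, (2, 16, 16))
        ours = ssim(a, b, L=1.0, mode="windowed", win_size=7)
        ref = structural_similarity(a, b, win_size=7, data_range=1.0,
                                    gaussian_weights=False)
        assert ours == pytest.approx(ref, abs=1e-3)

    def test_bounds(self, rng):
        a = rng.uniform(0, 1, (8, 8))
        b = 1 - a
        for mode in ("global", "windowed"):
            v = ssim(a, b, L=1.0, mode=mode)
            assert -1.0 <= v <= 1.0

    def test_invalid_inputs(self, rng):
        a = rng.uniform(0, 1, (4, 4))
        with pytest.raises(ValueError):
            ssim(a, a, L=0.0)
        with pytest.raises(ValueError):
            ssim(a, np.zeros((5, 5)))
        with pytest.raises(ValueError):
            ssim(a, a, mode="windowed", win_size=7)
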