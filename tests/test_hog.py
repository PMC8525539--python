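"""HOG descriptor pipeline and 2-D correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import gridsaccade as gs
from gridsaccade.hog import (GradientField, HOGParams, block_normalize,
                             cell_histograms, compute_gradients, corr2,
                             gamma_normalize, hog_descriptor, hog_hypothesis,
                             orientation_bin)


def _smooth(shape, seed=0):
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.random(shape), 2)
    return (img - img.min()) / (img.max() - img.min())


class TestGamma:
    def test_identity_exponent(self):
        img = np.random.default_rng(0).random((16, 16))
        np.testing.assert_array_equal(gamma_normalize(img, 1.0), img)

    def test_quarter_to_half(self):
        img = np.full((8, 8), 0.25)
        np.testing.assert_allclose(gamma_normalize(img, 0.5), 0.5)

    def test_square_matches_scalar_loop(self):
        img = np.random.default_rng(1).random((10, 10))
        out = gamma_normalize(img, 2.0)
        for i in range(10):
            for j in range(10):
                assert out[i, j] == img[i, j] ** 2

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            gamma_normalize(np.zeros((4, 4)), 0.0)


class TestGradients:
    def test_constant_image_zero_gradients(self):
        f = compute_gradients(np.full((20, 20), 0.7))
        assert np.all(f.gx == 0) and np.all(f.gy == 0)
        assert np.all(f.magnitude == 0)

    def test_horizontal_ramp(self):
        x = np.arange(440) / 440.0
        img = np.tile(x, (440, 1))
        f = compute_gradients(img)
        interior = f.gx[1:-1, 1:-1]
        np.testing.assert_allclose(interior, 2 / 440, atol=1e-12)
        np.testing.assert_allclose(f.gy[1:-1, 1:-1], 0, atol=1e-12)
        assert np.all(f.orientation[1:-1, 1:-1] == 0.0)

    def test_matches_double_loop_oracle(self):
        img = np.random.default_rng(2).random((8, 8))
        f = compute_gradients(img)
        pad = np.pad(img, 1, mode="edge")
        for y in range(8):
            for x in range(8):
                assert f.gx[y, x] == pad[y + 1, x + 2] - pad[y + 1, x]
                assert f.gy[y, x] == pad[y + 2, x + 1] - pad[y, x + 1]

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            compute_gradients(np.zeros((2, 5)))

    def test_orientation_folded_unsigned(self):
        img = np.random.default_rng(3).random((32, 32))
        f = compute_gradients(img)
        assert f.orientation.min() >= 0.0
        assert f.orientation.max() < 180.0
        np.testing.assert_allclose(f.magnitude, np.hypot(f.gx, f.gy))


class TestOrientationBin:
    @pytest.mark.parametrize("theta,expected", [
        (50.0, 3),      # a 40-60 degree orientation votes into the third bin
        (0.0, 1),
        (179.9, 9),
        (20.0, 2),
        (159.999, 8),
    ])
    def test_bin_assignment(self, theta, expected):
        assert orientation_bin(theta, 9) == expected

    def test_out_of_range_rejected(self):
        for theta in (-0.1, 180.0, 200.0):
            with pytest.raises(ValueError):
                orientation_bin(theta, 9)


class TestCellHistograms:
    def _field(self, mag, ori):
        return GradientField(gx=mag, gy=np.zeros_like(mag),
                             magnitude=mag, orientation=ori)

    def test_zero_field_all_zero(self):
        z = np.zeros((16, 16))
        grid = cell_histograms(self._field(z, z), HOGParams())
        assert np.all(grid == 0)

    def test_single_vote_lands_in_bin3(self):
        mag = np.zeros((16, 16))
        ori = np.zeros((16, 16))
        mag[3, 4] = 5.0
        ori[3, 4] = 50.0
        grid = cell_histograms(self._field(mag, ori), HOGParams())
        assert grid[0, 0, 2] == 5.0  # third bin, 0-based index 2
        grid[0, 0, 2] = 0.0
        assert np.all(grid == 0)

    def test_mass_conservation_random_fields(self):
        rng = np.random.default_rng(4)
        params = HOGParams(cell_size=4)
        for _ in range(100):
            mag = rng.random((16, 16))
            ori = rng.random((16, 16)) * 179.999
            grid = cell_histograms(self._field(mag, ori), params)
            per_cell = mag.reshape(4, 4, 4, 4).swapaxes(1, 2).sum(axis=(2, 3))
            np.testing.assert_allclose(grid.sum(axis=2), per_cell, rtol=1e-10)


class TestBlockNormalize:
    def test_zero_grid_zero_descriptor(self):
        grid = np.zeros((4, 4, 9))
        desc = block_normalize(grid, HOGParams())
        assert np.all(desc == 0)

    def test_three_four_five(self):
        grid = np.zeros((2, 2, 9))
        grid[0, 0, 0] = 3.0
        grid[0, 0, 1] = 4.0
        desc = block_normalize(grid, HOGParams())
        np.testing.assert_allclose(desc[:2], [0.6, 0.8], atol=1e-5)
        assert np.all(desc[2:] == 0)

    def test_norm_sweep(self):
        rng = np.random.default_rng(5)
        grid = rng.random((6, 6, 9))
        desc = block_normalize(grid, HOGParams())
        params = HOGParams()
        seg = desc.reshape(-1, params.block_size ** 2 * params.n_bins)
        norms = np.linalg.norm(seg, axis=1)
        assert np.all((norms >= 1 - 1e-6) & (norms <= 1.0))

    def test_block_larger_than_grid_rejected(self):
        with pytest.raises(ValueError):
            block_normalize(np.zeros((1, 1, 9)), HOGParams(block_size=2))


class TestDescriptor:
    def test_length_closed_form(self):
        img = _smooth((440, 440), 6)
        desc = hog_descriptor(img)
        assert desc.shape == (54 * 54 * 4 * 9,)
        assert gs.descriptor_length(440, HOGParams()) == 54 * 54 * 4 * 9

    def test_determinism(self):
        img = _smooth((128, 128), 7)
        np.testing.assert_array_equal(hog_descriptor(img), hog_descriptor(img))

    def test_mirror_symmetry(self):
        p = HOGParams(gamma=1.0)
        img = _smooth((64, 64), 8)
        d = hog_descriptor(img, p)
        dm = hog_descriptor(np.ascontiguousarray(img[:, ::-1]), p)
        blocks = 64 // p.cell_size - p.block_size + 1
        D = d.reshape(blocks, blocks, p.block_size, p.block_size, p.n_bins)
        pred = D[:, ::-1, :, ::-1, ::-1]
        np.testing.assert_allclose(
            pred, dm.reshape(pred.shape), atol=1e-12)

    def test_constant_offset_invariance_at_gamma_one(self):
        img = 0.3 * _smooth((64, 64), 9)
        p = HOGParams(gamma=1.0)
        np.testing.assert_allclose(hog_descriptor(img, p),
                                   hog_descriptor(img + 0.2, p), atol=1e-10)


class TestCorr2:
    def test_self_correlation(self):
        a = np.random.default_rng(10).random((12, 12))
        assert corr2(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_anticorrelation(self):
        a = np.random.default_rng(11).random((12, 12))
        assert corr2(a, 0.7 - a) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_two_pass_loop_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            a, b = rng.random((6, 6)), rng.random((6, 6))
            am, bm = a.mean(), b.mean()
            num = sa = sb = 0.0
            for i in range(6):
                for j in range(6):
                    num += (a[i, j] - am) * (b[i, j] - bm)
                    sa += (a[i, j] - am) ** 2
                    sb += (b[i, j] - bm) ** 2
            assert corr2(a, b) == pytest.approx(num / np.sqrt(sa * sb),
                                                abs=1e-12)

    def test_both_constant_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert corr2(np.ones((4, 4)), np.full((4, 4), 2.0)) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            corr2(np.zeros((3, 3)), np.zeros((4, 4)))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10 ** 6), st.floats(0.1, 5.0), st.floats(-2.0, 2.0))
    def test_symmetry_and_affine_invariance(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        a, b = rng.random(40), rng.random(40)
        c = corr2(a, b)
        assert -1.0 <= c <= 1.0
        assert corr2(b, a) == pytest.approx(c, abs=1e-12)
        assert corr2(scale * a + shift, b) == pytest.approx(c, abs=1e-9)


class TestHypothesis:
    def test_exact_match_wins_with_correlation_one(self, dataset):
        descs = {i: hog_descriptor(img) for i, img in dataset.gallery.items()}
        ident, c = hog_hypothesis(dataset.gallery["id03"], descs)
        assert ident == "id03"
        assert c == pytest.approx(1.0, abs=1e-12)

    def test_singleton_gallery_forced(self, dataset):
        descs = {"only": hog_descriptor(dataset.gallery["id00"])}
        ident, _ = hog_hypothesis(dataset.gallery["id05"], descs)
        assert ident == "only"

    def test_empty_gallery_rejected(self, dataset):
        with pytest.raises(ValueError):
            hog_hypothesis(dataset.gallery["id00"], {})

    def test_jittered_probe_recovers_identity(self, dataset):
        descs = {i: hog_descriptor(img) for i, img in dataset.gallery.items()}
        probe = next(p for p in dataset.probes if p.identity == "id04")
        probe_desc = hog_descriptor(probe.image)
        table = {i: corr2(probe_desc, d) for i, d in descs.items()}
        ident, c = hog_hypothesis(probe.image, descs)
        assert ident == max(sorted(table), key=lambda i: table[i])
        assert ident == "id04"
        assert c == pytest.approx(max(table.values()), abs=1e-12)
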