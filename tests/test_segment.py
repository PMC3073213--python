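import numpy as np
import pytest

import eoseg
from eoseg import (
    SegmentationMask,
    grey_error_image,
    morph_cleanup,
    overlay_boundaries,
    residual_map,
    threshold_dmap,
)
from eoseg.errors import DimensionError, ParameterError
from eoseg.io import SpectralCube
from eoseg.synthetic import table1_band_edges


def _cube(pixels):
    return SpectralCube(pixels, table1_band_edges(), kind="transmittance")


class TestResidualMap:
    def test_mean_cube_has_zero_errors_and_dmap(self, basis, band_pair):
        pixels = np.broadcast_to(basis.mean, (4, 4, basis.n_bands)).copy()
        rm = residual_map(_cube(pixels), basis, band_pair, 5)
        np.testing.assert_allclose(rm.errors, 0.0, atol=1e-12)
        np.testing.assert_allclose(rm.dmap, 0.0, atol=1e-12)

    def test_matches_per_pixel_loop_oracle(self, basis, band_pair, rng):
        pixels = rng.uniform(0.1, 1.0, size=(3, 3, basis.n_bands))
        rm = residual_map(_cube(pixels), basis, band_pair, 5)
        for i in range(3):
            for j in range(3):
                e = eoseg.spectral_error(basis, pixels[i, j], 5).error
                np.testing.assert_allclose(rm.errors[i, j], e, atol=1e-10)
                assert rm.dmap[i, j] == pytest.approx(
                    e[band_pair.r] - e[band_pair.s], abs=1e-10)

    def test_dmap_identity_with_error_planes(self, basis, band_pair, small_scene):
        rm = residual_map(small_scene.cube, basis, band_pair)
        np.testing.assert_array_equal(
            rm.dmap, rm.errors[:, :, band_pair.r] - rm.errors[:, :, band_pair.s])

    def test_eosinophil_pixels_dominate_dmap(self, basis, band_pair, small_scene):
        rm = residual_map(small_scene.cube, basis, band_pair)
        truth = small_scene.truth
        eos_mean = rm.dmap[truth.labels == truth.label_of("eosinophil")].mean()
        for cls in ("cytoplasm", "nucleus", "rbc", "fiber", "white"):
            other = rm.dmap[truth.labels == truth.label_of(cls)].mean()
            assert eos_mean > other

    def test_band_count_mismatch(self, basis, band_pair):
        cube = SpectralCube(np.ones((2, 2, 5)), table1_band_edges()[:5],
                            kind="transmittance")
        with pytest.raises(DimensionError):
            residual_map(cube, basis, band_pair)


class TestGreyErrorImage:
    def test_three_level_plane_hits_scaling_endpoints(self, basis, band_pair):
        rm = residual_map(_cube(np.ones((1, 3, 14))), basis, band_pair, 5)
        rm.errors[..., 0] = np.array([[-1.0, 0.0, 1.0]])
        img = grey_error_image(rm, 0)
        assert img[0, 0] == 0 and img[0, 2] == 255
        assert img[0, 1] in (127, 128)

    def test_matches_minmax_formula_oracle(self, basis, band_pair, rng):
        rm = residual_map(_cube(rng.uniform(0.2, 1.0, (5, 5, 14))), basis,
                          band_pair, 5)
        for band in (band_pair.r, band_pair.s):
            plane = rm.errors[:, :, band]
            expected = np.round(
                (plane - plane.min()) / (plane.max() - plane.min()) * 255)
            np.testing.assert_array_equal(grey_error_image(rm, band), expected)

    def test_constant_plane_is_mid_grey(self, basis, band_pair):
        rm = residual_map(_cube(np.ones((2, 2, 14))), basis, band_pair, 5)
        rm.errors[...] = 0.3
        assert np.all(grey_error_image(rm, 4) == 128)

    def test_eosinophils_darkest_at_s_brightest_at_r(self, basis, band_pair,
                                                     small_scene):
        """Target pixels occupy the extreme intensity decile of each
        single-band error image."""
        rm = residual_map(small_scene.cube, basis, band_pair)
        truth = small_scene.truth.labels == small_scene.truth.label_of("eosinophil")
        img_s = grey_error_image(rm, band_pair.s).astype(float)
        img_r = grey_error_image(rm, band_pair.r).astype(float)
        assert img_s[truth].mean() < np.percentile(img_s, 10)
        assert img_r[truth].mean() > np.percentile(img_r, 90)


def brute_force_otsu(values, nbins=256):
    """Exhaustive maximization of between-class variance over histogram
    splits; ties (empty-gap splits are exactly equivalent) go to the first
    split, so a small relative tolerance absorbs summation round-off."""
    counts, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    total = counts.sum()
    between = np.full(nbins, -np.inf)
    for split in range(1, nbins):
        w0 = counts[:split].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:split] * centers[:split]).sum() / w0
        mu1 = (counts[split:] * centers[split:]).sum() / w1
        between[split] = w0 * w1 * (mu0 - mu1) ** 2
    best = between.max()
    split = int(np.argmax(between >= best * (1 - 1e-12)))
    return centers[split - 1]


class TestThreshold:
    def _rm(self, dmap, basis, band_pair):
        rm = residual_map(_cube(np.ones((*dmap.shape, 14))), basis, band_pair, 5)
        rm.dmap = dmap
        return rm

    def test_fixed_threshold_keeps_exact_foreground(self, basis, band_pair):
        dmap = np.zeros((4, 4))
        dmap[1:3, 1:3] = 10.0
        mask = threshold_dmap(self._rm(dmap, basis, band_pair), "fixed", 5.0)
        np.testing.assert_array_equal(mask.binary, dmap > 5)
        assert mask.threshold_used == 5.0

    def test_all_negative_dmap_empty_at_zero(self, basis, band_pair):
        mask = threshold_dmap(self._rm(np.full((3, 3), -1.0), basis, band_pair),
                              "fixed", 0.0)
        assert not mask.binary.any()

    def test_otsu_matches_brute_force_oracle(self, basis, band_pair, rng):
        for _ in range(100):
            dmap = np.concatenate([
                rng.normal(0, 0.01, size=rng.integers(50, 200)),
                rng.normal(0.3, 0.05, size=rng.integers(20, 100)),
            ]).reshape(-1, 1)
            mask = threshold_dmap(self._rm(dmap, basis, band_pair))
            assert mask.threshold_used == pytest.approx(
                brute_force_otsu(dmap), abs=1e-8)

    def test_constant_dmap_warns_and_returns_empty(self, basis, band_pair):
        with pytest.warns(UserWarning, match="constant"):
            mask = threshold_dmap(self._rm(np.zeros((3, 3)), basis, band_pair))
        assert not mask.binary.any()

    def test_raising_fixed_threshold_never_adds_pixels(self, basis, band_pair, rng):
        rm = self._rm(rng.normal(size=(8, 8)), basis, band_pair)
        prev = threshold_dmap(rm, "fixed", -2.0).binary
        for t in np.linspace(-1.5, 2.0, 8):
            cur = threshold_dmap(rm, "fixed", float(t)).binary
            assert not np.any(cur & ~prev)
            prev = cur

    def test_phantom_otsu_f1(self, basis, band_pair, small_scene):
        rm = residual_map(small_scene.cube, basis, band_pair)
        mask = threshold_dmap(rm)
        truth = small_scene.truth.labels == small_scene.truth.label_of("eosinophil")
        tp = (mask.binary & truth).sum()
        f1 = 2 * tp / (2 * tp + (mask.binary & ~truth).sum()
                       + (~mask.binary & truth).sum())
        assert f1 >= 0.9


def brute_force_closing(mask, radius):
    """Dilation then erosion with a disk, out-of-image treated as background
    for dilation and as foreground for erosion (padding convention of the
    implementation under test, checked here independently)."""
    from skimage.morphology import disk
    fp = disk(radius).astype(bool)
    r = fp.shape[0] // 2
    h, w = mask.shape

    def sweep(m, combine, border):
        out = np.empty_like(m)
        for i in range(h):
            for j in range(w):
                vals = []
                for di in range(-r, r + 1):
                    for dj in range(-r, r + 1):
                        if not fp[di + r, dj + r]:
                            continue
                        ii, jj = i + di, j + dj
                        vals.append(m[ii, jj] if 0 <= ii < h and 0 <= jj < w
                                    else border)
                out[i, j] = combine(vals)
        return out

    return sweep(sweep(mask, any, False), all, True)


class TestMorphology:
    def test_closing_fills_interior_hole(self):
        from skimage.draw import disk as draw_disk
        mask = np.zeros((16, 16), dtype=bool)
        rr, cc = draw_disk((8, 8), 5)
        mask[rr, cc] = True
        mask[8, 8] = False
        out = morph_cleanup(SegmentationMask(mask, 0.0), radius=1, min_size=0)
        assert out.binary[8, 8]
        assert out.binary.sum() == len(rr)

    def test_isolated_pixel_removed_by_min_size(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        out = morph_cleanup(SegmentationMask(mask, 0.0), radius=0, min_size=5)
        assert not out.binary.any()

    def test_matches_brute_force_oracle_on_random_masks(self, rng):
        for _ in range(100):
            mask = rng.random((16, 16)) < rng.uniform(0.2, 0.6)
            out = morph_cleanup(SegmentationMask(mask, 0.0), radius=1, min_size=0)
            np.testing.assert_array_equal(out.binary,
                                          brute_force_closing(mask, 1))

    def test_idempotent(self, rng):
        mask = SegmentationMask(rng.random((32, 32)) < 0.4, 0.0)
        once = morph_cleanup(mask, radius=1, min_size=10)
        twice = morph_cleanup(once, radius=1, min_size=10)
        np.testing.assert_array_equal(once.binary, twice.binary)

    def test_empty_mask_passes_through(self):
        out = morph_cleanup(SegmentationMask(np.zeros((5, 5), bool), 0.0))
        assert not out.binary.any()

    def test_negative_radius_rejected(self):
        with pytest.raises(ParameterError):
            morph_cleanup(SegmentationMask(np.zeros((5, 5), bool), 0.0), radius=-1)


class TestOverlay:
    def test_empty_mask_leaves_image_unchanged(self, rng):
        rgb = rng.uniform(size=(6, 6, 3))
        out = overlay_boundaries(SegmentationMask(np.zeros((6, 6), bool), 0.0), rgb)
        np.testing.assert_array_equal(out, rgb)

    def test_full_mask_paints_only_border(self):
        rgb = np.zeros((5, 5, 3))
        out = overlay_boundaries(SegmentationMask(np.ones((5, 5), bool), 0.0),
                                 rgb, color=(1, 0, 0))
        painted = out[..., 0] == 1
        expected = np.ones((5, 5), bool)
        expected[1:-1, 1:-1] = False
        np.testing.assert_array_equal(painted, expected)

    def test_square_outline_matches_neighbourhood_oracle(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[3:6, 3:6] = True
        out = overlay_boundaries(SegmentationMask(mask, 0.0), np.zeros((9, 9, 3)),
                                 color=(0, 1, 0))
        painted = out[..., 1] == 1
        # oracle: mask pixels with at least one 8-neighbour outside the mask
        expected = np.zeros_like(mask)
        for i in range(9):
            for j in range(9):
                if not mask[i, j]:
                    continue
                nb = [mask[ii, jj]
                      for ii in range(max(i - 1, 0), min(i + 2, 9))
                      for jj in range(max(j - 1, 0), min(j + 2, 9))]
                expected[i, j] = not all(nb)
        np.testing.assert_array_equal(painted, expected)

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            overlay_boundaries(SegmentationMask(np.zeros((4, 4), bool), 0.0),
                               np.zeros((5, 5, 3)))


def test_end_to_end_determinism(basis, band_pair, small_scene):
    """Identical cube + model + settings must give a bit-identical mask."""
    def run():
        rm = residual_map(small_scene.cube, basis, band_pair)
        return morph_cleanup(threshold_dmap(rm), radius=1, min_size=20).binary

    np.testing.assert_array_equal(run(), run())
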