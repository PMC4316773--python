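"""Descriptor extraction: lengths, oracles, and invariances."""

import numpy as np
import pytest

import scenespace as sc
from scenespace import features as ft


def grating(size, cycles, theta):
    yy, xx = np.mgrid[0:size, 0:size] / size
    return 0.5 + 0.4 * np.sin(2 * np.pi * cycles * (xx * np.cos(theta) + yy * np.sin(theta)))


class TestGist:
    def test_default_length_is_512(self, rng):
        assert len(ft.gist_descriptor(rng.random((64, 64)))) == 512

    def test_length_is_configuration_product(self, rng):
        d = ft.gist_descriptor(rng.random((64, 64)), n_orientations=6,
                               n_scales=3, grid=2)
        assert len(d) == 6 * 3 * 4

    def test_constant_image_maps_to_zero(self):
        d = ft.gist_descriptor(np.full((64, 64), 0.37))
        assert np.abs(d.values).max() == 0.0

    @pytest.mark.parametrize("theta,expected_bin", [(0.0, 0), (np.pi / 2, 4)])
    def test_grating_energy_peaks_at_its_orientation_bin(self, theta, expected_bin):
        # oracle: the frequency vector of the grating lies at angle theta,
        # so the orientation bin nearest theta (bins at pi*o/8) must win
        d = ft.gist_descriptor(grating(64, 8, theta))
        energy = d.values.reshape(4, 8, 16).sum(axis=2)
        best_scale = energy.sum(axis=1).argmax()
        assert energy[best_scale].argmax() == expected_bin

    def test_non_square_rejected(self, rng):
        with pytest.raises(ValueError):
            ft.gist_descriptor(rng.random((64, 32)))


class TestHog:
    def test_pyramid_lengths_are_k_times_grid_cells(self, rng):
        img = rng.random((96, 96))
        blocks, _ = ft.hog_block_descriptors(img)
        cb = ft.train_codebook(blocks, 50, seed=0)
        levels = ft.hog_pyramid(img, codebook=cb)
        assert len(levels["L0"]) == 50
        assert len(levels["L1"]) == 50 * 4
        assert len(levels["L2"]) == 50 * 16

    def test_constant_image_has_zero_gradient_energy(self):
        cells = ft.hog_cell_descriptors(np.full((64, 64), 0.5))
        assert np.abs(cells).max() == 0.0

    def test_rotation_permutes_orientation_bins(self, rng):
        """90 deg rotation shifts signed orientation bins by a quarter turn
        and transposes the cell grid; checked cell-by-cell with 16 bins so
        the quarter turn is exactly 4 bins."""
        img = rng.random((48, 48))
        h = ft.hog_cell_descriptors(img, n_signed_bins=16, raw=True)
        hr = ft.hog_cell_descriptors(np.rot90(img), n_signed_bins=16, raw=True)
        ny, nx = h.shape[:2]
        for cy in range(ny):
            for cx in range(nx):
                np.testing.assert_allclose(
                    hr[cy, cx], np.roll(h[cx, nx - 1 - cy], -4), atol=1e-12)

    def test_missing_codebook_is_a_configuration_error(self, rng):
        with pytest.raises(ValueError, match="codebook"):
            ft.hog_pyramid(rng.random((64, 64)))

    def test_histograms_unit_norm(self, rng):
        img = rng.random((64, 64))
        blocks, _ = ft.hog_block_descriptors(img)
        cb = ft.train_codebook(blocks, 20, seed=0)
        for v in ft.hog_pyramid(img, codebook=cb).values():
            assert np.isclose(np.linalg.norm(v.values), 1.0)


class TestSsim:
    def test_matches_brute_force_at_one_point(self, rng):
        img = rng.random((40, 40))
        patch, radius = 5, 10
        descs, info = ft.ssim_descriptors(img, patch, radius, stride=13,
                                          n_radial=3, n_angular=8)
        # first kept sample point; recompute its descriptor with plain loops
        y, x = info["positions"][0]
        P = img[y - 2:y + 3, x - 2:x + 3]
        var_p = P.var()
        expected = np.zeros(24)
        edges = np.concatenate([[0.0], np.geomspace(2.0, radius + 1e-9, 3)])
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                rad = np.hypot(dy, dx)
                if rad > radius:
                    continue
                Q = img[y + dy - 2:y + dy + 3, x + dx - 2:x + dx + 3]
                sim = np.exp(-((P - Q) ** 2).sum() / (25 * var_p))
                rb = min(int(np.searchsorted(edges, rad, side="right")) - 1, 2)
                ab = int(((np.arctan2(dy, dx) + np.pi) / (2 * np.pi)) * 8) % 8
                k = rb * 8 + ab
                expected[k] = max(expected[k], sim)
        np.testing.assert_allclose(descs[0], expected, atol=1e-12)

    def test_periodic_texture_peaks_at_period_displacement(self, rng):
        tile = rng.random((8, 8))
        img = np.tile(tile, (8, 8))
        descs, info = ft.ssim_descriptors(img, 5, 12, stride=16,
                                          n_radial=3, n_angular=8)
        d = descs[0].reshape(3, 8)
        # displacement (0, 8) is period-aligned: similarity exactly 1 there.
        # radial bin of rad 8 with edges [0, 2, ~4.9, 12] is the outermost.
        assert np.isclose(d[2].max(), 1.0)

    def test_translated_texture_gives_identical_descriptors(self, rng):
        tile = rng.random((8, 8))
        img = np.tile(tile, (10, 10))
        descs, info = ft.ssim_descriptors(img, 5, 16, stride=8)
        pos = np.array(info["positions"])
        # points one period apart see the same neighborhood
        same_row = pos[pos[:, 0] == pos[0, 0]]
        a = descs[0]
        b = descs[np.where((pos == same_row[1]).all(axis=1))[0][0]]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_image_all_degenerate(self):
        descs, info = ft.ssim_descriptors(np.full((40, 40), 0.5), 5, 10, stride=8)
        assert descs.shape[0] == 0
        assert info["n_degenerate"] > 0

    def test_window_exits_are_skipped_and_counted(self, rng):
        descs, info = ft.ssim_descriptors(rng.random((40, 40)), 5, 10, stride=8)
        assert info["n_skipped"] > 0

    def test_small_image_rejected(self, rng):
        with pytest.raises(ValueError):
            ft.ssim_descriptors(rng.random((40, 40)), 5, 40)


class TestLocalColorFeatures:
    def test_rgb_sift_is_three_concatenated_channels(self, rng):
        img = rng.random((48, 48, 3))
        d = ft.local_color_features(img, "rgb_sift")
        assert d.shape[1] == 3 * 128

    def test_equal_channels_give_identical_channel_descriptors(self, rng):
        g = rng.random((48, 48))
        img = np.stack([g, g, g], axis=-1)
        d = ft.local_color_features(img, "rgb_sift")
        np.testing.assert_array_equal(d[:, :128], d[:, 128:256])
        np.testing.assert_array_equal(d[:, :128], d[:, 256:])

    def test_dense_sift_invariant_to_intensity_offset(self, rng):
        img = rng.random((48, 48)) * 0.5
        a = ft.local_color_features(img, "dense_sift")
        b = ft.local_color_features(img + 0.25, "dense_sift")
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_grayscale_rejected_for_color_variants(self, rng):
        for variant in ("hue_hist", "hue_sift", "rgb_sift"):
            with pytest.raises(ValueError):
                ft.local_color_features(rng.random((48, 48)), variant)

    def test_hue_samples_live_on_unit_circle(self, rng):
        d = ft.local_color_features(rng.random((48, 48, 3)), "hue_hist")
        np.testing.assert_allclose(np.hypot(d[:, 0], d[:, 1]), 1.0)


class TestCodebook:
    def test_k_points_k_clusters_recovers_the_points(self, rng):
        X = rng.random((5, 3))
        cb = ft.train_codebook(X, 5, seed=0)
        got = cb.centroids[np.lexsort(cb.centroids.T[::-1])]
        want = X[np.lexsort(X.T[::-1])]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_same_input_and_seed_identical_codebook(self, rng):
        X = rng.random((100, 4))
        a = ft.train_codebook(X, 7, seed=3)
        b = ft.train_codebook(X, 7, seed=3)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_two_separated_blobs_yield_blob_means(self, rng):
        blob1 = rng.normal(0, 0.05, (50, 2))
        blob2 = rng.normal(5, 0.05, (50, 2)) + [0, 5]
        cb = ft.train_codebook(np.vstack([blob1, blob2]), 2, seed=0)
        means = np.sort(np.vstack([blob1.mean(0), blob2.mean(0)]), axis=0)
        np.testing.assert_allclose(np.sort(cb.centroids, axis=0), means, atol=0.05)

    def test_fewer_points_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            ft.train_codebook(rng.random((4, 2)), 5, seed=0)


class TestBagOfWords:
    def test_histogram_length_is_k_and_unit_norm(self, rng):
        cb = ft.train_codebook(rng.random((60, 4)), 12, seed=1)
        h = ft.bow_histogram(rng.random((30, 4)), cb)
        assert len(h) == 12
        assert np.isclose(np.linalg.norm(h.values), 1.0)

    def test_all_descriptors_on_one_centroid_gives_one_hot(self, rng):
        cb = ft.Codebook(3, np.array([[0.0, 0], [5, 5], [9, 9]]), seed=0)
        h = ft.bow_histogram(np.full((10, 2), 5.01), cb)
        np.testing.assert_allclose(h.values, [0, 1, 0])

    def test_assignment_matches_exhaustive_search(self, rng):
        X = rng.random((200, 6))
        cb = ft.train_codebook(rng.random((50, 6)), 10, seed=2)
        got = ft.assign_words(X, cb)
        want = np.array([
            min(range(10), key=lambda k: float(((x - cb.centroids[k]) ** 2).sum()))
            for x in X])
        np.testing.assert_array_equal(got, want)

    def test_empty_set_yields_zero_vector_with_warning(self, caplog):
        cb = ft.Codebook(4, np.zeros((4, 3)) + np.arange(4)[:, None], seed=0)
        import logging
        with caplog.at_level(logging.WARNING):
            h = ft.bow_histogram(np.empty((0, 3)), cb)
        assert (h.values == 0).all() and len(h) == 4
        assert any("empty" in r.message for r in caplog.records)


class TestGeom:
    def test_uniform_map_gives_uniform_descriptor(self):
        maps = {c: np.full((32, 32), 0.5) for c in ft.GEOM_CLASSES}
        d = ft.geom_descriptor(maps)
        assert len(d["gnd"]) == 64
        np.testing.assert_allclose(d["gnd"].values, 0.5)
        assert len(d["all"]) == 4 * 64

    def test_half_plane_map_has_exact_block_means(self):
        m = np.zeros((64, 64))
        m[:32] = 1.0
        maps = {c: m for c in ft.GEOM_CLASSES}
        v = ft.geom_descriptor(maps)["sky"].values.reshape(8, 8)
        np.testing.assert_array_equal(v[:4], 1.0)
        np.testing.assert_array_equal(v[4:], 0.0)

    def test_random_map_matches_brute_force_block_average(self, rng):
        m = rng.random((40, 40))
        maps = {c: m for c in ft.GEOM_CLASSES}
        got = ft.geom_descriptor(maps)["vrt"].values.reshape(8, 8)
        want = m.reshape(8, 5, 8, 5).mean(axis=(1, 3))
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_out_of_range_values_rejected(self):
        maps = {c: np.full((16, 16), 0.5) for c in ft.GEOM_CLASSES}
        maps["gnd"] = np.full((16, 16), 1.5)
        with pytest.raises(ValueError):
            ft.geom_descriptor(maps)


class TestReweightAttributes:
    def _table(self, scores, cats):
        import pandas as pd
        return ft.AttributeScoreTable(scores=pd.DataFrame(np.asarray(scores, float)),
                                      categories=np.asarray(cats))

    def test_category_constant_attribute_unchanged(self):
        t = self._table([[1.0], [1.0], [1.0], [1.0]], [0, 0, 1, 1])
        out = ft.reweight_attributes(t)
        np.testing.assert_allclose(out.scores.to_numpy(), t.scores.to_numpy())

    def test_ln2_variance_column_scaled_by_two(self):
        m = np.sqrt(np.log(2.0))
        # attr0: category means equal (v=0); attr1: means +/-m (v=ln 2)
        t = self._table([[1.0, m], [1.0, m], [1.0, -m], [1.0, -m]], [0, 0, 1, 1])
        out = ft.reweight_attributes(t).scores.to_numpy()
        np.testing.assert_allclose(out[:, 0], 1.0)
        np.testing.assert_allclose(out[:, 1], 2.0 * np.array([m, m, -m, -m]))

    def test_within_column_ranking_preserved(self, rng):
        scores = rng.standard_normal((12, 6))
        t = self._table(scores, np.repeat(np.arange(4), 3))
        out = ft.reweight_attributes(t).scores.to_numpy()
        for c in range(6):
            np.testing.assert_array_equal(np.argsort(out[:, c]),
                                          np.argsort(scores[:, c]))

    def test_single_category_rejected(self):
        t = self._table([[1.0], [2.0]], [0, 0])
        with pytest.raises(ValueError):
            ft.reweight_attributes(t)
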