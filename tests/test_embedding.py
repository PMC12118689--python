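"""Feature augmentation, subsampling, embedding, density maxima, endmembers."""

import numpy as np
import pytest

from edxmix import (
    AnnotationClass,
    AnnotationSet,
    EnergyAxis,
    FeatureAugmentConfig,
    HyperspectralCube,
    augment_features,
    boxes_around,
    embed,
    endmembers_from_annotations,
    endmembers_from_boxes,
    find_histogram_maxima,
    flatten,
    histogram2d,
    subsample,
)
from edxmix.embedding import Embedding2D, Histogram2D, cosine_similarity_matrix


def _cube(counts):
    counts = np.asarray(counts, dtype=float)
    axis = EnergyAxis(0.0, 10.0, counts.shape[2])
    return HyperspectralCube(counts=counts, energy=axis, pixel_size_nm=1.0)


class TestAugmentFeatures:
    @pytest.mark.parametrize("n_channels,radii,expected", [(250, (1, 3, 5), 1000), (32, (1, 3), 96), (10, (), 10)])
    def test_feature_width(self, rng, n_channels, radii, expected):
        cube = _cube(rng.random((8, 8, n_channels)))
        t = augment_features(cube, FeatureAugmentConfig(blur_radii=radii))
        assert t.n_features == expected
        assert t.n_pixels == 64

    def test_empty_radii_is_identity(self, small_cube):
        t = augment_features(small_cube, FeatureAugmentConfig(blur_radii=()))
        base = flatten(small_cube)
        assert np.allclose(t.values, base.values)
        assert np.array_equal(t.origin, base.origin)

    def test_constant_cube_blurs_equal_base(self):
        cube = _cube(np.full((10, 10, 4), 5.0))
        t = augment_features(cube, FeatureAugmentConfig(blur_radii=(1, 3)))
        for block in range(1, 3):
            assert np.allclose(t.values[:, block * 4 : (block + 1) * 4], t.values[:, :4])


class TestSubsample:
    def test_fraction_one_identity_up_to_order(self, small_cube):
        t = flatten(small_cube)
        s = subsample(t, 1.0, seed=0)
        assert s.n_pixels == t.n_pixels
        assert {tuple(rc) for rc in s.origin} == {tuple(rc) for rc in t.origin}

    def test_twenty_percent_of_1000_is_200(self, rng):
        cube = _cube(rng.random((25, 40, 3)))
        s = subsample(flatten(cube), 0.2, seed=1)
        assert s.n_pixels == 200

    def test_seed_deterministic(self, small_cube):
        t = flatten(small_cube)
        s1 = subsample(t, 0.3, seed=5)
        s2 = subsample(t, 0.3, seed=5)
        assert np.array_equal(s1.origin, s2.origin)
        assert not np.array_equal(s1.origin, subsample(t, 0.3, seed=6).origin)

    def test_masked_pixels_never_sampled(self, rng):
        cube = _cube(rng.random((10, 10, 3)))
        mask = np.zeros((10, 10), dtype=bool)
        mask[:, :5] = True  # exclude the left half
        s = subsample(flatten(cube), 0.5, overlap=mask, seed=2)
        assert np.all(s.origin[:, 1] >= 5)

    def test_empty_pool_rejected(self, rng):
        cube = _cube(rng.random((4, 4, 2)))
        with pytest.raises(ValueError, match="empty"):
            subsample(flatten(cube), 0.5, overlap=np.ones((4, 4), dtype=bool))


class TestEmbed:
    def _three_cluster_table(self, rng, n_per=60):
        centers = np.array([[10.0, 0, 0, 0], [0, 10.0, 0, 0], [0, 0, 10.0, 0]])
        rows, labels = [], []
        for k, c in enumerate(centers):
            rows.append(c + rng.normal(0, 0.3, size=(n_per, 4)))
            labels += [k] * n_per
        values = np.vstack(rows)
        n = values.shape[0]
        origin = np.stack([np.arange(n) // 100, np.arange(n) % 100], axis=1)
        from edxmix import FlatPixelTable

        return FlatPixelTable(values=values, origin=origin), np.array(labels)

    @pytest.mark.parametrize("backend", ["umap", "pca"])
    def test_separated_clusters_stay_separated(self, rng, backend):
        from sklearn.metrics import silhouette_score

        table, labels = self._three_cluster_table(rng)
        emb = embed(table, backend=backend, seed=0)
        assert emb.coords.shape == (table.n_pixels, 2)
        assert silhouette_score(emb.coords, labels) > 0.5

    def test_minimum_rows_smoke_and_error(self, rng):
        from edxmix import FlatPixelTable

        vals = rng.random((10, 3))
        origin = np.stack([np.zeros(10, int), np.arange(10)], axis=1)
        t = FlatPixelTable(values=vals, origin=origin)
        emb = embed(t, backend="umap", seed=0)  # exactly at the minimum
        assert emb.coords.shape == (10, 2)
        with pytest.raises(ValueError, match="rows"):
            embed(t.take(np.arange(5)), backend="umap")

    def test_duplicate_rows_coincide_deterministic_backend(self, rng):
        from edxmix import FlatPixelTable

        base = rng.random((30, 5))
        vals = np.vstack([base, base[:3]])  # rows 30..32 duplicate 0..2
        n = vals.shape[0]
        origin = np.stack([np.arange(n) // 50, np.arange(n) % 50], axis=1)
        emb = embed(FlatPixelTable(values=vals, origin=origin), backend="pca")
        span = np.ptp(emb.coords, axis=0).max()
        for i in range(3):
            d = np.linalg.norm(emb.coords[30 + i] - emb.coords[i])
            assert d <= 1e-6 * span


class TestHistogram:
    def _emb(self, coords):
        from edxmix import FlatPixelTable

        n = len(coords)
        origin = np.stack([np.arange(n) // 1000, np.arange(n) % 1000], axis=1)
        table = FlatPixelTable(values=np.zeros((n, 1)), origin=origin)
        return Embedding2D(coords=np.asarray(coords, float), sample=table, backend="custom")

    def test_point_mass_single_bin(self):
        emb = self._emb([[1.0, 2.0]] * 17)
        h = histogram2d(emb, bins=8)
        assert h.counts.sum() == 17
        assert h.counts.max() == 17

    def test_counts_sum_to_n(self, rng):
        emb = self._emb(rng.random((500, 2)))
        h = histogram2d(emb, bins=16)
        assert h.counts.sum() == 500

    def test_four_corners_two_bins(self):
        emb = self._emb([[0, 0], [0, 1], [1, 0], [1, 1]])
        h = histogram2d(emb, bins=2)
        assert np.array_equal(h.counts, np.ones((2, 2)))


class TestHistogramMaxima:
    def _hist(self, counts):
        counts = np.asarray(counts, float)
        b = counts.shape[0]
        return Histogram2D(
            counts=counts,
            x_edges=np.arange(b + 1, dtype=float),
            y_edges=np.arange(counts.shape[1] + 1, dtype=float),
        )

    def test_single_blob_single_maximum(self):
        y, x = np.mgrid[0:21, 0:21]
        blob = np.exp(-((y - 10) ** 2 + (x - 10) ** 2) / 20.0) * 50
        pts = find_histogram_maxima(self._hist(blob), min_distance_bins=2)
        assert len(pts) == 1
        assert pts[0] == (10.5, 10.5)

    def test_two_blobs_two_maxima(self):
        y, x = np.mgrid[0:32, 0:32]
        h = np.exp(-((y - 8) ** 2 + (x - 8) ** 2) / 8.0) * 40 + np.exp(
            -((y - 24) ** 2 + (x - 24) ** 2) / 8.0
        ) * 30
        pts = find_histogram_maxima(self._hist(h), min_distance_bins=3)
        assert len(pts) == 2

    def test_matches_exhaustive_neighborhood_scan(self, rng):
        counts = rng.integers(0, 50, size=(32, 32)).astype(float)
        d = 2
        got = find_histogram_maxima(self._hist(counts), min_distance_bins=d, min_count=1)
        # oracle: explicit O(B^2 * window) scan for window maxima
        expect = []
        for i in range(32):
            for j in range(32):
                lo_i, hi_i = max(0, i - d), min(32, i + d + 1)
                lo_j, hi_j = max(0, j - d), min(32, j + d + 1)
                if counts[i, j] >= 1 and counts[i, j] == counts[lo_i:hi_i, lo_j:hi_j].max():
                    expect.append((i + 0.5, j + 0.5))
        # plateaus collapse to centroids in the implementation; with random
        # integer data ties at the window max within one neighbourhood are
        # possible, so compare as sets of nearby points
        assert len(got) <= len(expect)
        for g in got:
            assert any(abs(g[0] - e[0]) <= d and abs(g[1] - e[1]) <= d for e in expect)
        for e in expect:
            assert any(abs(g[0] - e[0]) <= d and abs(g[1] - e[1]) <= d for g in got)

    def test_bulk_exclusion_drops_global_mode(self):
        h = np.zeros((24, 24))
        h[10:14, 10:14] = 100.0  # central bulk plateau
        h[2, 2] = 30.0  # protrusion extremity
        pts = find_histogram_maxima(
            self._hist(h), min_distance_bins=2, exclude_central_bulk=True
        )
        assert pts == [(2.5, 2.5)]


class TestEndmemberAveraging:
    def test_box_with_one_pixel_returns_its_spectrum(self, rng):
        from edxmix import FlatPixelTable

        vals = rng.random((20, 6))
        origin = np.stack([np.arange(20), np.zeros(20, int)], axis=1)
        table = FlatPixelTable(values=vals, origin=origin)
        coords = np.zeros((20, 2))
        coords[7] = (5.0, 5.0)
        emb = Embedding2D(coords=coords, sample=table, backend="custom")
        ems = endmembers_from_boxes(table, [(4.5, 5.5, 4.5, 5.5)], emb)
        assert np.allclose(ems.spectra[0], vals[7])

    def test_empty_box_error_names_box(self, rng):
        from edxmix import FlatPixelTable

        table = FlatPixelTable(
            values=rng.random((5, 3)),
            origin=np.stack([np.arange(5), np.zeros(5, int)], axis=1),
        )
        emb = Embedding2D(coords=np.zeros((5, 2)), sample=table, backend="custom")
        with pytest.raises(ValueError, match="box 0"):
            endmembers_from_boxes(table, [(10, 11, 10, 11)], emb)

    def test_annotation_single_pixel_class(self, small_cube):
        ann = AnnotationSet(classes=[AnnotationClass("x", "red", [(2, 3)])])
        ems = endmembers_from_annotations(small_cube, ann)
        assert np.allclose(ems.spectra[0], small_cube.counts[2, 3])

    def test_annotations_on_noiseless_phantom_exact(self, phantom_noiseless):
        # noiseless cube: class-mean spectrum equals the exact known mixture
        spec, cube, gt = phantom_noiseless
        k = gt.class_labels.index("insulin")
        bg = gt.class_labels.index("background")
        pure = np.argwhere(gt.abundances[:, :, k] >= 0.95)[:20]
        ann = AnnotationSet(
            classes=[AnnotationClass("insulin", "red", [tuple(p) for p in pure])]
        )
        ems = endmembers_from_annotations(cube, ann)
        expect = spec.n_frames * (0.95 * gt.spectra[k] + 0.05 * gt.spectra[bg])
        assert np.allclose(ems.spectra[0], expect)

    def test_annotation_poisson_within_clt_bound(self, phantom_small):
        spec, cube, gt = phantom_small
        k = gt.class_labels.index("chromatin")
        pure = np.argwhere(gt.abundances[:, :, k] >= 0.9)
        pure = pure[:100]
        ann = AnnotationSet(
            classes=[AnnotationClass("chromatin", "green", [tuple(p) for p in pure])]
        )
        ems = endmembers_from_annotations(cube, ann)
        expect = spec.n_frames * (
            0.9 * gt.spectra[k] + 0.1 * gt.spectra[gt.class_labels.index("background")]
        )
        se = np.sqrt(np.maximum(expect, 1e-12) / len(pure))
        assert np.all(np.abs(ems.spectra[0] - expect) <= 4 * se + 1e-9)


class TestBoxesAround:
    def test_box_half_width_in_embedding_units(self):
        h = Histogram2D(
            counts=np.zeros((4, 4)),
            x_edges=np.arange(5, dtype=float),
            y_edges=np.arange(0, 10, 2, dtype=float),
        )
        (box,) = boxes_around(h, [(2.0, 4.0)], half_width_bins=2)
        assert box == (2.0 - 2.5, 2.0 + 2.5, 4.0 - 5.0, 4.0 + 5.0)
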