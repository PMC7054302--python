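"""The synthetic chart simulator: determinism, geometry, augmentation moments."""

import numpy as np
import pytest

from hyse import (
    AugmentationParams,
    BACKGROUND_LABEL,
    Hypercube,
    augment,
    make_reference_library,
    make_training_pool,
    normalize_reflectance,
    render_base_hypercube,
    render_tube_dataset,
    tube_geometry,
)
from hyse.baselines import pearson_slice_classifier
from hyse.benchmark import preprocess_slice_spectra
from hyse.simulate import SceneGeometry, planar_geometry

SMALL = (6, 32, 242)


class TestReferenceLibrary:
    def test_deterministic(self):
        a = make_reference_library(7, n_wavelengths=100)
        b = make_reference_library(7, n_wavelengths=100)
        np.testing.assert_array_equal(a.spectra, b.spectra)
        assert a.names == b.names

    def test_range_and_count(self, library):
        assert library.n_classes == 18
        assert library.spectra.min() >= 0.0
        assert library.spectra.max() <= 1.0

    def test_pairwise_correlations(self, library):
        corr = np.corrcoef(library.spectra)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        off = corr[~np.eye(18, dtype=bool)]
        assert off.max() < 0.99


class TestRenderSection:
    def test_deterministic(self, chart, library):
        a, _, _ = render_base_hypercube(chart, 1, library, seed=5, shape=SMALL)
        b, _, _ = render_base_hypercube(chart, 1, library, seed=5, shape=SMALL)
        np.testing.assert_array_equal(a.data, b.data)

    def test_section_out_of_range(self, chart, library):
        with pytest.raises(ValueError, match="section"):
            render_base_hypercube(chart, 6, library, shape=SMALL)

    def test_noiseless_limit_recovers_class_spectra(self, chart, library):
        """With noise/artifacts/mismatch off, normalization recovers each
        square's reference spectrum exactly (up to float rounding)."""
        cube, cal, lmap = render_base_hypercube(
            chart, 0, library, shape=SMALL, seed=2,
            noise_sd=0.0, artifact_fraction=0.0, mismatch_sd=0.0,
        )
        norm = normalize_reflectance(cube, cal)
        for (x, y) in [(0, 0), (0, 31), (5, 0), (5, 31), (2, 10)]:
            k = lmap.labels[x, y]
            np.testing.assert_allclose(
                norm.data[x, y], library.classes[k].spectrum, atol=1e-10
            )

    def test_label_map_matches_layout(self, chart, library):
        """Ground truth equals an independently computed quadrant mask."""
        nx, ny = SMALL[0], SMALL[1]
        _, _, lmap = render_base_hypercube(chart, 4, library, shape=SMALL)
        block = chart.section_squares(4)
        expected = np.empty((nx, ny), dtype=int)
        for x in range(nx):
            for y in range(ny):
                code = block[0 if x < nx // 2 else 1][0 if y < ny // 2 else 1]
                expected[x, y] = code if code < 18 else BACKGROUND_LABEL
        np.testing.assert_array_equal(lmap.labels, expected)

    def test_gray_squares_are_background(self, chart, library):
        _, _, lmap = render_base_hypercube(chart, 5, library, shape=SMALL)
        assert BACKGROUND_LABEL in np.unique(lmap.labels)

    def test_noiseless_separability(self, chart, library):
        """With noise off, nearest-reference classification is perfect."""
        cube, cal, lmap = render_base_hypercube(
            chart, 0, library, shape=SMALL, seed=3,
            noise_sd=0.0, artifact_fraction=0.0, mismatch_sd=0.0,
        )
        norm = normalize_reflectance(cube, cal)
        clf = pearson_slice_classifier(library.binned(121))
        for x in (0, 3):
            binned = preprocess_slice_spectra(norm.data[x], 121)
            labels = clf.classify_slice(binned).labels
            assert (labels == lmap.labels[x]).all()


class TestAugmentation:
    @staticmethod
    def _base(n=12, value=0.5):
        wl = np.linspace(400, 750, 10)
        return [Hypercube(np.full((2, 16, 10), value), wl) for _ in range(n)]

    def test_pool_bookkeeping(self):
        base = self._base(12)
        result = augment(base, AugmentationParams(n_augmented=300, seed=1))
        assert len(result.cubes) == 300
        assert len(base) + len(result.cubes) == 312
        assert len(result.manifest["bias"]) == 300

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            AugmentationParams(n_augmented=-1)

    def test_deterministic(self):
        base = self._base(3)
        p = AugmentationParams(n_augmented=5, seed=9)
        a = augment(base, p)
        b = augment(base, p)
        for ca, cb in zip(a.cubes, b.cubes):
            np.testing.assert_array_equal(ca.data, cb.data)
        assert a.manifest == b.manifest

    def test_degenerate_distributions_give_exact_field(self):
        """All SDs zero → the relative change is exactly b_mean + s_mean*u."""
        base = self._base(1)
        p = AugmentationParams(
            bias_sd=0.0, slope_sd=0.0, noise_sd=0.0, n_augmented=3, seed=4,
            under_illumination_prob=0.0,
        )
        result = augment(base, p)
        u = np.linspace(0, 1, 16)
        expected = 0.1 + 0.01 * u
        for cube in result.cubes:
            rel = cube.data / base[0].data - 1.0
            np.testing.assert_allclose(
                rel, np.broadcast_to(expected[None, :, None], rel.shape), atol=1e-6
            )

    def test_signed_field_magnitude(self):
        """With random signs the relative change still equals the drawn field."""
        base = self._base(1)
        p = AugmentationParams(bias_sd=0.0, slope_sd=0.0, noise_sd=0.0,
                               n_augmented=8, seed=11)
        result = augment(base, p)
        u = np.linspace(0, 1, 16)
        for cube, sb, ss in zip(
            result.cubes, result.manifest["sign_bias"], result.manifest["sign_slope"]
        ):
            expected = sb * 0.1 + ss * 0.01 * u
            rel = cube.data / base[0].data - 1.0
            np.testing.assert_allclose(
                rel, np.broadcast_to(expected[None, :, None], rel.shape), atol=1e-6
            )

    def test_moment_recovery(self):
        """Logged draws over 300 samples recover the stated means and SDs."""
        base = self._base(12)
        result = augment(base, AugmentationParams(n_augmented=300, seed=21))
        b = np.array(result.manifest["bias"])
        s = np.array(result.manifest["slope"])
        assert abs(b.mean() - 0.1) < 3 * 0.04 / np.sqrt(300)
        assert abs(s.mean() - 0.01) < 3 * 0.03 / np.sqrt(300)
        assert abs(b.std(ddof=1) - 0.04) < 4 * 0.04 / np.sqrt(2 * 299)
        assert abs(s.std(ddof=1) - 0.03) < 4 * 0.03 / np.sqrt(2 * 299)

    def test_under_illumination_bias(self):
        """Negative signs dominate at the stated 0.7 probability."""
        base = self._base(2)
        result = augment(base, AugmentationParams(n_augmented=300, seed=2))
        frac = np.mean(np.array(result.manifest["sign_bias"]) < 0)
        assert abs(frac - 0.7) < 4 * np.sqrt(0.7 * 0.3 / 300)

    def test_empty_base_rejected(self):
        with pytest.raises(ValueError):
            augment([], AugmentationParams(n_augmented=1))


class TestTrainingPool:
    def test_bookkeeping_and_provenance(self, library):
        pool = make_training_pool(
            library, n_replicates=2, n_augmented=10, seed=0, shape=(2, 16, 242)
        )
        assert len(pool) == 22
        kinds = [c.kind for c in pool.cubes]
        assert kinds.count("base") == 12
        assert kinds.count("augmented") == 10
        for entry in pool.cubes:
            assert 0 <= entry.base_id < 12
            # augmented cubes share the label map of their base measurement
            base = pool.cubes[entry.base_id]
            assert entry.label_map is base.label_map


class TestTubeGeometry:
    def test_disabled_attenuation_equals_planar(self, chart, library):
        geo = SceneGeometry(mode="tube", max_distance_factor=1.0,
                            blur_sigma_max=0.0, attenuation_enabled=False)
        a, _, _ = render_base_hypercube(chart, 0, library, geometry=geo,
                                        seed=6, shape=SMALL)
        b, _, _ = render_base_hypercube(chart, 0, library,
                                        geometry=planar_geometry(), seed=6, shape=SMALL)
        np.testing.assert_array_equal(a.data, b.data)

    def test_monotone_attenuation(self, chart, library):
        """The lumen-center (farthest) region is darker than the line edges."""
        cube, _, _ = render_base_hypercube(
            chart, 0, library, geometry=tube_geometry(), seed=6, shape=SMALL,
            noise_sd=0.0, artifact_fraction=0.0,
        )
        ny = SMALL[1]
        center = cube.data[:, ny // 2 - 2 : ny // 2 + 2, :].mean()
        edges = cube.data[:, :4, :].mean()
        assert center < edges

    def test_blur_schedule_logged(self, chart, library):
        geo = tube_geometry(blur_sigma_max=1.7)
        cube, _, _ = render_base_hypercube(chart, 0, library, geometry=geo,
                                           seed=6, shape=SMALL)
        sigmas = np.asarray(cube.meta["blur_sigma_per_y"])
        assert len(sigmas) == SMALL[1]
        np.testing.assert_allclose(sigmas.max(), 1.7, rtol=1e-12)
        assert cube.meta["max_blur_sigma"] == pytest.approx(1.7)

    def test_labels_unchanged_by_attenuation(self, chart, library):
        ds = render_tube_dataset(chart, library, seed=0, sections=[0], shape=SMALL)
        _, _, lmap_planar = render_base_hypercube(chart, 0, library, shape=SMALL)
        np.testing.assert_array_equal(ds.label_maps[0].labels, lmap_planar.labels)

    def test_distance_profile_monotone_toward_center(self):
        prof = tube_geometry().distance_profile(33)
        mid = 16
        assert np.all(np.diff(prof[: mid + 1]) >= 0)
        assert np.all(np.diff(prof[mid:]) <= 0)
        assert prof.max() == pytest.approx(1.15)
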