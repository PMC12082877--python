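"""Thresholding, size filtering, skeletons, shape descriptors, line profiles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage import measure
from skimage.morphology import skeletonize

from mitoquant.errors import CalibrationError, ConfigError, DegenerateImageError
from mitoquant.image import TwoChannelImage
from mitoquant.segmentation import (
    SegmentationConfig,
    calibrate_min_object_size,
    extract_line_profile,
    filter_and_count,
    label_and_filter,
    shape_metrics,
    skeleton_path_length,
    skeletonize_objects,
    summarize_morphology,
    threshold_channel,
)
from mitoquant.simulate import ImageSimConfig, _capsule_mask, generate_mito_image


def otsu_bruteforce(image):
    """Exhaustive 256-level between-class-variance maximizer."""
    image = np.ravel(image)
    counts, edges = np.histogram(image, bins=256, range=(image.min(), image.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_v = None, -1.0
    total = counts.sum()
    for k in range(1, 256):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, centers[k - 1]
    return best_t


def flood_fill_components(mask, connectivity):
    """Brute-force connected components by iterative flood fill."""
    mask = np.asarray(mask, bool)
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                 if (dy, dx) != (0, 0)]
    seen = np.zeros_like(mask, bool)
    comps = []
    for y, x in zip(*np.nonzero(mask)):
        if seen[y, x]:
            continue
        stack, comp = [(y, x)], set()
        seen[y, x] = True
        while stack:
            cy, cx = stack.pop()
            comp.add((cy, cx))
            for dy, dx in neigh:
                ny, nx = cy + dy, cx + dx
                if (0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]
                        and mask[ny, nx] and not seen[ny, nx]):
                    seen[ny, nx] = True
                    stack.append((ny, nx))
        comps.append(frozenset(comp))
    return set(comps)


class TestThreshold:
    def test_two_level_image_perfectly_separated(self):
        rng = np.random.default_rng(0)
        img = np.full((50, 50), 10.0)
        sig = rng.random((50, 50)) < 0.1
        img[sig] = 200.0
        mask = threshold_channel(img, SegmentationConfig())
        assert np.array_equal(mask, sig)

    def test_fixed_threshold(self):
        img = np.array([[50.0, 150.0], [150.0, 50.0]])
        cfg = SegmentationConfig(threshold_method="fixed", fixed_threshold=100)
        assert np.array_equal(threshold_channel(img, cfg), img > 100)

    def test_otsu_equals_bruteforce_on_bimodal_mixture(self):
        """On an integer-valued bimodal image (bin centers = intensity
        levels) the Otsu threshold and mask equal the exhaustive 256-level
        between-class-variance maximizer exactly."""
        rng = np.random.default_rng(5)
        vals = np.concatenate(
            [rng.normal(30, 5, 3000), rng.normal(150, 20, 1000)]
        )
        img = np.clip(np.rint(vals), 0, 255).reshape(80, 50)
        img[0, 0], img[0, 1] = 0.0, 255.0  # pin the histogram range
        mask = threshold_channel(img, SegmentationConfig())
        t = otsu_bruteforce(img)
        assert np.array_equal(mask, img > t)

    def test_otsu_variance_is_maximal_on_float_image(self):
        """On float images the chosen split attains the brute-force maximal
        binned between-class variance (thresholds inside an empty histogram
        gap are equivalent)."""
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(5)
        img = np.concatenate(
            [rng.normal(30, 5, 3000), rng.normal(150, 20, 1000)]
        ).reshape(80, 50)
        counts, edges = np.histogram(
            img, bins=256, range=(img.min(), img.max())
        )
        centers = (edges[:-1] + edges[1:]) / 2

        def binned_bcv(t):
            lo = counts[centers <= t]
            hi = counts[centers > t]
            clo, chi = centers[centers <= t], centers[centers > t]
            if lo.sum() == 0 or hi.sum() == 0:
                return 0.0
            mu0 = (lo * clo).sum() / lo.sum()
            mu1 = (hi * chi).sum() / hi.sum()
            return lo.sum() * hi.sum() * (mu0 - mu1) ** 2

        t_impl = threshold_otsu(img, nbins=256)
        t_oracle = otsu_bruteforce(img)
        assert binned_bcv(t_impl) == pytest.approx(binned_bcv(t_oracle), rel=1e-9)

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateImageError):
            threshold_channel(np.full((10, 10), 7.0), SegmentationConfig())


class TestSizeFilter:
    def test_boundary_rule_at_15_and_45(self):
        """Sizes {10, 15, 16, 44}: the 10 px object is background."""
        retained = filter_and_count([10, 15, 16, 44], 15, 45)
        assert [i for i, _ in retained] == [1, 2, 3]
        assert all(c == 1 for _, c in retained)

    def test_aggregate_ceiling_counts(self):
        """A 90 px aggregate counts as two organelles at a 45 px cap."""
        assert filter_and_count([90], 15, 45) == [(0, 2)]
        assert filter_and_count([46], 15, 45) == [(0, 2)]
        assert filter_and_count([45], 15, 45) == [(0, 1)]

    @given(st.lists(st.floats(0, 200, allow_nan=False), max_size=30))
    def test_filtering_is_idempotent(self, sizes):
        once = filter_and_count(sizes, 15, 45)
        kept = [sizes[i] for i, _ in once]
        twice = filter_and_count(kept, 15, 45)
        assert [c for _, c in once] == [c for _, c in twice]

    def test_connectivity_4_vs_8_on_diagonal_pixels(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        lab4 = measure.label(mask, connectivity=1)
        lab8 = measure.label(mask, connectivity=2)
        assert lab4.max() == 2 and lab8.max() == 1
        # and through the full operation
        cfg4 = SegmentationConfig(connectivity=4, min_size_px=1, max_size_px=45)
        cfg8 = SegmentationConfig(connectivity=8, min_size_px=1, max_size_px=45)
        assert len(label_and_filter(mask, cfg4)) == 2
        assert len(label_and_filter(mask, cfg8)) == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_labeling_equals_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(3)
        mask = rng.random((60, 60)) < 0.3
        skimage_conn = 1 if connectivity == 4 else 2
        labels = measure.label(mask, connectivity=skimage_conn)
        ours = {
            frozenset(zip(*np.nonzero(labels == k)))
            for k in range(1, labels.max() + 1)
        }
        assert ours == flood_fill_components(mask, connectivity)

    def test_empty_mask_gives_empty_set(self):
        assert label_and_filter(np.zeros((10, 10), bool), SegmentationConfig()) == []

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigError):
            SegmentationConfig(min_size_px=45, max_size_px=45)


class TestSkeleton:
    def test_thin_line_skeleton_is_itself(self):
        mask = np.zeros((5, 30), bool)
        mask[2, 5:25] = True
        sk, lengths = skeletonize_objects(mask)
        assert np.array_equal(sk, mask)
        assert lengths == {1: 19.0}

    def test_diagonal_line_length(self):
        mask = np.eye(10, dtype=bool)
        assert skeleton_path_length(mask) == pytest.approx(9 * math.sqrt(2))

    def test_corner_counts_axial_steps_only(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = mask[0, 1] = mask[1, 1] = True
        assert skeleton_path_length(mask) == 2.0

    def test_filled_disk_skeleton_much_shorter_than_perimeter(self):
        yy, xx = np.mgrid[:41, :41]
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        _, lengths = skeletonize_objects(disk)
        (length,) = lengths.values()
        assert 0 <= length < 2 * math.pi * 15 / 2

    def test_rectangle_skeleton_near_midline_length(self):
        """A 30x4 rectangle thins to roughly its 27-step midline."""
        mask = np.zeros((20, 50), bool)
        mask[8:12, 10:40] = True
        length = skeleton_path_length(skeletonize(mask))
        assert abs(length - 27) <= 2

    def test_empty_input(self):
        sk, lengths = skeletonize_objects(np.zeros((5, 5), bool))
        assert not sk.any() and lengths == {}


class TestShapeMetrics:
    @staticmethod
    def _props_of(mask):
        return measure.regionprops(measure.label(mask))[0]

    def test_disk_is_isotropic(self):
        yy, xx = np.mgrid[:81, :81]
        disk = (yy - 40) ** 2 + (xx - 40) ** 2 <= 30**2
        m = shape_metrics(self._props_of(disk))
        assert m["aspect_ratio"] == pytest.approx(1.0, abs=0.01)
        assert m["circularity"] == pytest.approx(1.0, abs=0.05)
        assert m["form_factor"] == pytest.approx(1.0, abs=0.06)

    def test_rectangle_matches_covariance_eigen_oracle(self):
        mask = np.zeros((20, 50), bool)
        mask[5:15, 10:40] = True
        m = shape_metrics(self._props_of(mask))
        ys, xs = np.nonzero(mask)
        cov = np.cov(np.vstack([ys, xs]), bias=True)
        evals = np.linalg.eigvalsh(cov)
        assert m["aspect_ratio"] == pytest.approx(
            math.sqrt(evals[1] / evals[0]), abs=1e-9
        )

    def test_elongation_is_definitional(self):
        """Moment axes of a 4:1 ellipse give aspect ratio 4."""
        yy, xx = np.mgrid[:61, :201]
        ell = ((yy - 30) / 12) ** 2 + ((xx - 100) / 48) ** 2 <= 1
        m = shape_metrics(self._props_of(ell))
        assert m["aspect_ratio"] == pytest.approx(4.0, rel=0.02)

    def test_single_pixel_is_degenerate(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        m = shape_metrics(self._props_of(mask))
        assert m["degenerate"] and math.isnan(m["aspect_ratio"])

    def test_degenerate_objects_counted_but_excluded_from_summaries(self):
        mask = np.zeros((30, 60), bool)
        mask[5, 5:25] = True   # 1-px line: degenerate moments? minor > 0 actually
        mask[20, 30] = True    # single pixel
        cfg = SegmentationConfig(min_size_px=1, max_size_px=45)
        objs = label_and_filter(mask, cfg)
        summary = summarize_morphology(objs)
        assert summary.mito_count == sum(o.count_contribution for o in objs)
        n_degen = sum(o.degenerate for o in objs)
        assert n_degen >= 1


class TestCapsuleLengthRecovery:
    @pytest.mark.parametrize("length_um", [0.7, 1.4, 2.2])
    def test_feret_size_matches_programmed_length(self, length_um):
        px = 0.7 / 15
        mask = _capsule_mask((140, 140), (70, 70), 0.4, length_um / px, 0.45 / px)
        p = measure.regionprops(measure.label(mask))[0]
        assert abs(p.feret_diameter_max - length_um / px) <= 2

    def test_object_count_on_sparse_noiseless_field(self):
        """Programmed non-touching objects are each counted exactly once."""
        cfg = ImageSimConfig(
            field_size_px=(360, 360),
            n_objects=25,
            length_range_um=(0.75, 2.05),
            allow_overlap=False,
            noise_poisson=False,
            noise_gaussian_sd=0.0,
            background_level=0.0,
            seed=5,
        )
        _, truth = generate_mito_image(cfg)
        mask = truth.imm_clean > 0
        objs = label_and_filter(mask, SegmentationConfig())
        summary = summarize_morphology(objs)
        assert summary.mito_count == 25

    def test_count_monotone_when_objects_added(self):
        counts = []
        for n in (5, 10, 15):
            cfg = ImageSimConfig(
                field_size_px=(300, 300),
                n_objects=n,
                allow_overlap=False,
                noise_poisson=False,
                noise_gaussian_sd=0.0,
                background_level=0.0,
                seed=9,
            )
            _, truth = generate_mito_image(cfg)
            objs = label_and_filter(truth.imm_clean > 0, SegmentationConfig())
            counts.append(summarize_morphology(objs).mito_count)
        assert counts[0] <= counts[1] <= counts[2]


class TestLineProfile:
    def test_constant_image_gives_flat_profile(self):
        img = TwoChannelImage(np.full((20, 20), 5.0), np.full((20, 20), 3.0))
        prof = extract_line_profile(img, (10, 2), (10, 17))
        assert np.allclose(prof.omm, 5.0) and np.allclose(prof.imm, 3.0)
        assert np.all(np.diff(prof.distance_um) > 0)

    def test_shell_object_gives_two_omm_peaks_flanking_imm(self):
        """A ring-shaped membrane around a filled core: the cross profile
        shows two OMM maxima straddling a single central IMM peak."""
        yy, xx = np.mgrid[:61, :61]
        r = np.hypot(yy - 30, xx - 30)
        imm = np.exp(-(r**2) / (2 * 6**2)) * 100
        omm = np.exp(-((r - 9) ** 2) / (2 * 2**2)) * 100
        img = TwoChannelImage(omm, imm)
        prof = extract_line_profile(img, (30, 5), (30, 55))
        imm_peak = np.argmax(prof.imm)
        left = np.argmax(prof.omm[:imm_peak])
        right = imm_peak + np.argmax(prof.omm[imm_peak:])
        assert left < imm_peak < right
        assert prof.omm[imm_peak] < prof.omm[left]
        assert prof.omm[imm_peak] < prof.omm[right]

    def test_degenerate_zero_length_profile(self):
        img = TwoChannelImage(np.ones((10, 10)), np.ones((10, 10)))
        prof = extract_line_profile(img, (4, 4), (4, 4))
        assert len(prof.omm) == 1 and prof.distance_um[0] == 0.0

    def test_out_of_bounds_endpoint_rejected(self):
        img = TwoChannelImage(np.ones((10, 10)), np.ones((10, 10)))
        with pytest.raises(ConfigError):
            extract_line_profile(img, (0, 0), (5, 20))


class TestCalibration:
    @staticmethod
    def _profile_from(y, step=1.0):
        n = len(y)
        img = TwoChannelImage(
            np.tile(y, (3, 1)), np.tile(y, (3, 1)), pixel_size_um=1.0
        )
        return extract_line_profile(img, (1, 0), (1, n - 1), step_px=step)

    def test_gaussian_peak_fwhm(self):
        sigma = 5.0
        x = np.arange(101)
        y = 100 * np.exp(-((x - 50) ** 2) / (2 * sigma**2))
        prof = self._profile_from(y)
        est = calibrate_min_object_size([prof])
        assert abs(est - 2.355 * sigma) <= 1.0

    def test_returns_smallest_width(self):
        x = np.arange(101)
        narrow = 100 * np.exp(-((x - 50) ** 2) / (2 * 5.1**2))
        wide = 100 * np.exp(-((x - 50) ** 2) / (2 * 7.6**2))
        est = calibrate_min_object_size(
            [self._profile_from(wide), self._profile_from(narrow)]
        )
        assert abs(est - 2.355 * 5.1) <= 1.0

    def test_flat_profile_fails_calibration(self):
        prof = self._profile_from(np.full(50, 3.0))
        with pytest.raises(CalibrationError):
            calibrate_min_object_size([prof])
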