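"""Segmentation pipeline stages: contracts, boundary cases, oracles."""

import warnings

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.measure import label as cc_label

from cellstates.segmentation import (
    CellCrop,
    DetectionRecord,
    DetectionStatus,
    FieldImage,
    SegmentationParams,
    adaptive_filter,
    adjust_contrast,
    binarize_and_fill,
    crop_at_centroid,
    detect_and_crop,
    erode_and_filter,
    resize_to_reference_magnification,
    suppress_duplicates,
)


def _record(r, c, area, status=DetectionStatus.KEPT):
    return DetectionRecord(
        centroid=(float(r), float(c)),
        area=float(area),
        bounding_box=(int(r) - 5, int(c) - 5, int(r) + 5, int(c) + 5),
        status=status,
    )


class TestAdjustContrast:
    def test_two_valued_image_maps_to_endpoints(self):
        img = np.array([[100, 200], [100, 200]], dtype=np.uint16)
        out = adjust_contrast(img, clip_percent=0.0)
        assert set(np.unique(out)) == {0.0, 65535.0}

    def test_full_range_image_unchanged_with_zero_clip(self):
        img = np.linspace(0, 65535, 256).reshape(16, 16)
        out = adjust_contrast(img, clip_percent=0.0)
        np.testing.assert_allclose(out, img, atol=1e-6)

    def test_monotone_ordering_preserved(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 65536, (50, 50)).astype(np.uint16)
        out = adjust_contrast(img)
        flat_in, flat_out = img.ravel(), out.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert (np.diff(flat_out[order]) >= 0).all()

    def test_constant_image_warns_and_passes_through(self):
        img = np.full((10, 10), 777, dtype=np.uint16)
        with pytest.warns(UserWarning, match="constant"):
            out = adjust_contrast(img)
        np.testing.assert_array_equal(out, img)


class TestAdaptiveFilter:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 5.0)
        np.testing.assert_allclose(adaptive_filter(img), img)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(1)
        img = 1000 + rng.normal(0, 50, (1000, 1000))
        out = adaptive_filter(img, window=5)
        assert out.var() < img.var()

    def test_step_edge_stays_put(self):
        img = np.zeros((40, 80))
        img[:, 40:] = 1000.0
        out = adaptive_filter(img, window=5)
        crossing = np.argmax(out[20] >= 500.0)
        assert abs(crossing - 40) < 2.5  # less than half the window

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            adaptive_filter(np.ones((10, 10)), window=4)


class TestBinarizeAndFill:
    def test_bright_ring_becomes_solid_disk(self):
        img = np.full((120, 120), 1000.0)
        rr, cc = draw_disk((60, 60), 40)
        outer = np.zeros((120, 120), bool)
        outer[rr, cc] = True
        rr, cc = draw_disk((60, 60), 34)
        inner = np.zeros((120, 120), bool)
        inner[rr, cc] = True
        img[outer & ~inner] = 20000.0
        mask = binarize_and_fill(img)
        labels = cc_label(mask)
        assert labels.max() == 1
        assert mask[60, 60]  # hollow interior was filled

    def test_noise_only_image_yields_empty_mask(self):
        rng = np.random.default_rng(3)
        img = 28000 + rng.normal(0, 350, (300, 300))
        with pytest.warns(UserWarning, match="noise floor"):
            mask = binarize_and_fill(img)
        assert not mask.any()

    def test_separated_cells_stay_separate(self):
        img = np.full((200, 200), 1000.0)
        for centre in ((60, 60), (60, 140)):  # 80 px apart > 2 * dilation
            rr, cc = draw_disk(centre, 30)
            img[rr, cc] = 20000.0
        mask = binarize_and_fill(img, dilation_radius=2)
        assert cc_label(mask).max() == 2


class TestErodeAndFilter:
    # disk(3) erosion shrinks a rectangle by 3 px per side, so pre-erosion
    # rectangles are sized to hit the post-erosion area cut exactly
    def test_area_below_threshold_removed_and_at_threshold_kept(self):
        mask = np.zeros((200, 220), bool)
        mask[20:72, 20:62] = True  # erodes to 46x36 = 1656 < 2000
        mask[100:150, 100:156] = True  # erodes to 44x50 = 2200 >= 2000
        labeled, records = erode_and_filter(mask)
        by_status = {}
        for r in records:
            by_status.setdefault(r.status, []).append(r)
        assert len(by_status[DetectionStatus.DEBRIS_REMOVED]) == 1
        assert by_status[DetectionStatus.DEBRIS_REMOVED][0].area == 1656
        assert len(by_status[DetectionStatus.KEPT]) == 1
        assert by_status[DetectionStatus.KEPT][0].area == 2200

    def test_exact_min_area_boundary(self):
        mask = np.zeros((100, 120), bool)
        mask[10:60, 10:56] = True  # erodes to 44x40 = 1760
        _, records = erode_and_filter(
            mask, SegmentationParams(min_object_area=1760)
        )
        assert records[0].status is DetectionStatus.KEPT
        _, records = erode_and_filter(
            mask, SegmentationParams(min_object_area=1761)
        )
        assert records[0].status is DetectionStatus.DEBRIS_REMOVED

    def test_small_pre_erosion_component_is_debris(self):
        mask = np.zeros((100, 100), bool)
        mask[10:35, 10:35] = True  # 625 px < 30*30
        _, records = erode_and_filter(mask)
        assert [r.status for r in records] == [DetectionStatus.DEBRIS_REMOVED]

    def test_dumbbell_splits_into_two(self):
        mask = np.zeros((200, 300), bool)
        for centre in ((100, 80), (100, 220)):
            rr, cc = draw_disk(centre, 40)
            mask[rr, cc] = True
        mask[100, 80:220] = True  # 1 px bridge
        assert cc_label(mask).max() == 1
        _, records = erode_and_filter(mask)
        kept = [r for r in records if r.status is DetectionStatus.KEPT]
        assert len(kept) == 2


class TestSuppressDuplicates:
    def test_largest_area_wins_between_close_pair(self):
        dets = [_record(100, 100, 2500), _record(103, 104, 2100)]
        suppress_duplicates(dets, duplicate_distance=30)
        statuses = {d.area: d.status for d in dets}
        assert statuses[2500] is DetectionStatus.KEPT
        assert statuses[2100] is DetectionStatus.DUPLICATE_MERGED

    def test_distant_detections_both_kept(self):
        dets = [_record(100, 100, 2500), _record(100, 200, 2100)]
        suppress_duplicates(dets, duplicate_distance=30)
        assert all(d.status is DetectionStatus.KEPT for d in dets)

    def test_mutually_close_cluster_keeps_exactly_one(self):
        rng = np.random.default_rng(4)
        dets = [
            _record(100 + rng.uniform(-5, 5), 100 + rng.uniform(-5, 5), 2000 + i)
            for i in range(7)
        ]
        suppress_duplicates(dets, duplicate_distance=30)
        kept = [d for d in dets if d.status is DetectionStatus.KEPT]
        assert len(kept) == 1
        assert kept[0].area == 2006  # largest


class TestCropAtCentroid:
    def test_window_arithmetic(self):
        img = np.arange(300 * 300, dtype=np.uint16).reshape(300, 300)
        det = _record(150, 150, 2500)
        crop = crop_at_centroid(img, det, crop_size=100)
        np.testing.assert_array_equal(crop.pixels, img[100:200, 100:200])

    def test_edge_rejection(self):
        img = np.zeros((300, 300), dtype=np.uint16)
        det = _record(20, 150, 2500)
        assert crop_at_centroid(img, det, crop_size=100) is None
        assert det.status is DetectionStatus.EDGE_REJECTED

    def test_boundary_inclusive_whole_image(self):
        img = np.arange(100 * 100, dtype=np.uint16).reshape(100, 100)
        det = _record(50, 50, 2500)
        crop = crop_at_centroid(img, det, crop_size=100)
        np.testing.assert_array_equal(crop.pixels, img)


class TestDetectAndCrop:
    def test_empty_field(self):
        rng = np.random.default_rng(6)
        img = (28000 + rng.normal(0, 350, (400, 400))).astype(np.uint16)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            crops, records = detect_and_crop(img)
        assert crops == [] and records == []

    def test_status_conservation(self, small_field):
        image, truth = small_field
        crops, records = detect_and_crop(image)
        statuses = [r.status for r in records]
        assert all(isinstance(s, DetectionStatus) for s in statuses)
        n_kept_with_crop = len(crops)
        n_kept = sum(1 for s in statuses if s is DetectionStatus.KEPT)
        assert n_kept == n_kept_with_crop
        assert len(records) == sum(
            statuses.count(s) for s in DetectionStatus
        )

    def test_recovers_separated_cells(self, small_field):
        image, truth = small_field
        crops, records = detect_and_crop(image)
        kept = [r for r in records if r.status is DetectionStatus.KEPT]
        assert len(kept) >= len(truth.cells) - 1
        for crop in crops:
            assert crop.pixels.shape == (100, 100)
            assert crop.pixels.dtype == np.uint16


class TestResize:
    def test_doubles_10x_images(self):
        img = FieldImage(np.zeros((500, 600), dtype=np.uint16), "10x", "f")
        out = resize_to_reference_magnification(img)
        assert out.pixels.shape == (1000, 1200)
        assert out.magnification == "20x"

    def test_identity_for_20x(self):
        img = FieldImage(np.zeros((50, 60), dtype=np.uint16), "20x", "f")
        assert resize_to_reference_magnification(img) is img

    def test_constant_stays_constant(self):
        img = FieldImage(np.full((40, 40), 1234, dtype=np.uint16), "10x")
        out = resize_to_reference_magnification(img)
        assert np.all(out.pixels == 1234)


class TestFieldImageIO:
    def test_tiff_round_trip(self, tmp_path, small_field):
        image, _ = small_field
        f = FieldImage(image, "20x", "phantom")
        f.to_tiff(tmp_path / "x.tif")
        back = FieldImage.from_tiff(tmp_path / "x.tif")
        np.testing.assert_array_equal(back.pixels, image)

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError, match="2-D"):
            FieldImage(np.zeros((4, 4, 3)))


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(filter_window=4)
        with pytest.raises(ValueError):
            SegmentationParams(crop_size=25)
        with pytest.raises(ValueError):
            SegmentationParams(erosion_radius=0)
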