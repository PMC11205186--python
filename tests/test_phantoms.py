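"""Phantom generator: morphology contracts, determinism, manifests."""

import numpy as np
import pytest
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk, opening

from cellstates.labels import BIOLOGICAL_LABELS, CellStateLabel as L
from cellstates.phantoms import (
    CLASS_DEFAULTS,
    PhantomCellSpec,
    PhantomGroundTruth,
    generate_field,
    generate_training_corpus,
    load_corpus,
    render_cell,
    sample_multiplet,
    sample_spec,
    save_corpus,
)

CANVAS = (160, 160)
CENTRE = (80.0, 80.0)


def _render_mask(spec):
    return render_cell(spec, CANVAS) != 0


class TestRenderCell:
    def test_mitosis_is_circular_with_bright_rim(self):
        spec = PhantomCellSpec(
            label=L.MITOSIS, centroid=CENTRE, major_axis=40, minor_axis=40,
            orientation=0.0, rim_brightness=14000, interior_brightness=3000,
        )
        patch = render_cell(spec, CANVAS)
        mask = patch != 0
        region = regionprops(mask.astype(int))[0]
        circularity = 4 * np.pi * region.area / region.perimeter**2
        assert circularity > 0.85
        rim = patch == 14000
        interior = (patch != 0) & ~rim
        assert patch[rim].max() > patch[interior].max()

    def test_senescence_is_large_and_dark(self):
        interphase_mean_area = np.pi * np.prod(
            [np.mean(CLASS_DEFAULTS[L.INTERPHASE]["major"]) / 2,
             np.mean(CLASS_DEFAULTS[L.INTERPHASE]["major"])
             * np.mean(CLASS_DEFAULTS[L.INTERPHASE]["ratio"]) / 2]
        )
        major = 2 * np.mean(CLASS_DEFAULTS[L.INTERPHASE]["major"])
        spec = PhantomCellSpec(
            label=L.SENESCENCE, centroid=CENTRE, major_axis=major,
            minor_axis=0.8 * major, orientation=0.3, rim_brightness=5000,
            interior_brightness=-6500,
        )
        patch = render_cell(spec, (400, 400))
        mask = patch != 0
        assert mask.sum() >= 2 * interphase_mean_area
        assert patch.min() < 0  # interior darker than background

    @pytest.mark.parametrize("bleb_count", [2, 4, 6])
    def test_apoptosis_blebs_countable_as_peripheral_protrusions(self, bleb_count):
        # brute-force oracle: a morphological opening wide enough to erase
        # bleb-scale bumps leaves the body; the difference splits into one
        # connected protrusion per bleb
        spec = PhantomCellSpec(
            label=L.APOPTOSIS, centroid=CENTRE, major_axis=60, minor_axis=56,
            orientation=0.4, rim_brightness=8000, interior_brightness=-2000,
            bleb_count=bleb_count,
        )
        mask = _render_mask(spec)
        assert cc_label(mask).max() == 1  # blebs connected to the body
        protrusions = mask & ~opening(mask, disk(9))
        regions = [r for r in regionprops(cc_label(protrusions)) if r.area >= 15]
        assert len(regions) == bleb_count

    def test_invalid_label_rejected_by_name(self):
        spec = PhantomCellSpec(
            label="blasto", centroid=CENTRE, major_axis=40, minor_axis=30,
            orientation=0.0, rim_brightness=1.0, interior_brightness=0.0,
        )
        with pytest.raises(ValueError, match="blasto"):
            render_cell(spec, CANVAS)

    @pytest.mark.parametrize(
        "kwargs, message",
        [
            (dict(label=L.MITOSIS, minor_axis=20), "near-circular"),
            (dict(label=L.APOPTOSIS, bleb_count=1), "bleb_count"),
            (dict(label=L.INTERPHASE, minor_axis=38), "oblong"),
            (dict(label=L.SENESCENCE, interior_brightness=10), "darker"),
        ],
    )
    def test_class_invariants_enforced(self, kwargs, message):
        base = dict(
            label=L.MITOSIS, centroid=CENTRE, major_axis=40, minor_axis=40,
            orientation=0.0, rim_brightness=9000, interior_brightness=-3000,
            bleb_count=3,
        )
        base.update(kwargs)
        with pytest.raises(ValueError, match=message):
            render_cell(PhantomCellSpec(**base), CANVAS)

    def test_deterministic_given_spec(self):
        rng = np.random.default_rng(5)
        spec = sample_spec(L.NECROSIS, rng, centroid=CENTRE)
        assert np.array_equal(render_cell(spec, CANVAS), render_cell(spec, CANVAS))


class TestIntensityContracts:
    def test_mitosis_rim_above_background_and_senescence_interior_below(self):
        rng = np.random.default_rng(7)
        mit = render_cell(sample_spec(L.MITOSIS, rng, CENTRE), CANVAS)
        sen = render_cell(sample_spec(L.SENESCENCE, rng, CENTRE), (400, 400))
        assert mit.max() > 0
        assert sen.min() < 0


class TestAreaOrdering:
    def test_mean_mask_areas_order_senescence_necrosis_interphase_apoptosis(self):
        rng = np.random.default_rng(42)
        means = {}
        for lab in (L.SENESCENCE, L.NECROSIS, L.INTERPHASE, L.APOPTOSIS):
            areas = [
                (render_cell(sample_spec(lab, rng, (200.0, 200.0)), (400, 400)) != 0).sum()
                for _ in range(100)
            ]
            means[lab] = np.mean(areas)
        assert means[L.SENESCENCE] > means[L.NECROSIS]
        assert means[L.NECROSIS] > means[L.INTERPHASE]
        assert means[L.INTERPHASE] > means[L.APOPTOSIS]


class TestGenerateField:
    def test_empty_field_is_background_only(self):
        image, truth = generate_field(0, seed=1, field_shape=(300, 300))
        assert truth.cells == []
        assert image.dtype == np.uint16
        assert abs(float(image.mean()) - 28000) < 200

    def test_count_conservation_all_interphase(self):
        image, truth = generate_field(
            10, class_mix={L.INTERPHASE: 1.0}, seed=3
        )
        assert len(truth.cells) == 10
        assert all(c.label is L.INTERPHASE for c in truth.cells)

    def test_same_seed_pixel_identical(self):
        a, _ = generate_field(8, seed=11)
        b, _ = generate_field(8, seed=11)
        assert np.array_equal(a, b)

    def test_centroids_inside_bounds(self):
        _, truth = generate_field(15, seed=9)
        for c in truth.cells:
            assert 0 <= c.centroid[0] < truth.image_shape[0]
            assert 0 <= c.centroid[1] < truth.image_shape[1]

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            generate_field(40, field_shape=(300, 300), seed=2, max_attempts=50)

    def test_bad_class_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_field(3, class_mix={L.MITOSIS: 0.5}, seed=1)

    def test_multiplet_members_touch(self):
        rng = np.random.default_rng(0)
        pair = sample_multiplet(rng, (200.0, 200.0))
        assert all(s.label is L.DISCARDED for s in pair)
        d = np.hypot(
            pair[0].centroid[0] - pair[1].centroid[0],
            pair[0].centroid[1] - pair[1].centroid[1],
        )
        assert d < (pair[0].minor_axis + pair[1].minor_axis) / 2


class TestManifest:
    def test_round_trip_lossless(self, tmp_path, small_field):
        _, truth = small_field
        path = tmp_path / "truth.csv"
        truth.to_csv(path)
        back = PhantomGroundTruth.from_csv(path)
        assert back.image_shape == truth.image_shape
        assert back.seed == truth.seed
        assert back.background_level == truth.background_level
        assert back.noise_sigma == truth.noise_sigma
        assert len(back.cells) == len(truth.cells)
        for a, b in zip(back.cells, truth.cells):
            assert a == b


class TestCorpus:
    def test_counts_and_shape(self):
        crops, labels = generate_training_corpus(1, seed=4)
        assert crops.shape == (6, 100, 100)
        assert crops.dtype == np.uint16
        assert len(set(labels)) == 6

    def test_balance_and_determinism(self, tiny_corpus):
        crops, labels = tiny_corpus
        counts = {l: labels.count(l) for l in set(labels)}
        assert all(v == 8 for v in counts.values())
        crops2, labels2 = generate_training_corpus(8, seed=202)
        assert np.array_equal(crops, crops2)
        assert labels == labels2

    def test_directory_round_trip(self, tmp_path, tiny_corpus):
        crops, labels = tiny_corpus
        save_corpus(tmp_path / "corpus", crops, labels)
        assert sorted(
            p.name for p in (tmp_path / "corpus").iterdir() if p.is_dir()
        ) == sorted(l.value for l in set(labels))
        back_crops, back_labels = load_corpus(tmp_path / "corpus")
        assert np.array_equal(np.sort(back_crops, axis=0), np.sort(crops, axis=0))
        assert sorted(l.value for l in back_labels) == sorted(l.value for l in labels)
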