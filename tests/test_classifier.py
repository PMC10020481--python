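import numpy as np
import pytest

from fibroquant.chartgen import default_table3_spec, generate_chart
from fibroquant.classifier import (
    ClassifierModel,
    SubCluster,
    TissueClass,
    build_model_from_points,
    classify_pixel,
    load_preset,
    model_from_colors_file,
    model_from_palette,
    preset_palette,
    segment_image,
    standard_kmeans,
)
from fibroquant.colorspace import HSVColor

from conftest import brute_force_nearest_center


def _image_with_colors(colors):
    """A 1-row image whose pixels are the given RGB colors."""
    return np.array([colors], dtype=np.uint8)


class TestBuildModelFromPoints:
    def test_minimal_model_one_point_per_class(self):
        img = _image_with_colors([(255, 255, 255), (200, 40, 60), (60, 80, 200)])
        model = build_model_from_points(
            img, [(0, 0, "background"), (0, 1, "healthy"), (0, 2, "fibrotic")]
        )
        assert len(model.subclusters) == 3
        assert [sc.parent for sc in model.subclusters] == [
            TissueClass.BACKGROUND,
            TissueClass.HEALTHY,
            TissueClass.FIBROTIC,
        ]

    def test_six_points_two_per_class_keeps_input_order(self):
        img = np.zeros((2, 3, 3), dtype=np.uint8)
        img[0] = [(250, 250, 250), (200, 40, 60), (60, 80, 200)]
        img[1] = [(240, 240, 240), (180, 60, 70), (80, 100, 190)]
        points = [
            (0, 0, "background"),
            (0, 1, "healthy"),
            (0, 2, "fibrotic"),
            (1, 0, "background"),
            (1, 1, "healthy"),
            (1, 2, "fibrotic"),
        ]
        model = build_model_from_points(img, points)
        assert len(model.subclusters) == 6
        parents = [int(sc.parent) for sc in model.subclusters]
        assert parents == [0, 1, 2, 0, 1, 2]
        assert sum(p == 1 for p in parents) == 2

    def test_out_of_bounds_point_names_the_point(self):
        img = _image_with_colors([(1, 2, 3)])
        with pytest.raises(ValueError, match="#0.*\\(5, 0\\)"):
            build_model_from_points(img, [(5, 0, "background")])

    def test_missing_class_names_the_class(self):
        img = _image_with_colors([(255, 255, 255), (200, 40, 60)])
        with pytest.raises(ValueError, match="fibrotic"):
            build_model_from_points(img, [(0, 0, "background"), (0, 1, "healthy")])

    def test_identical_color_in_two_classes_warns_but_builds(self):
        img = _image_with_colors([(100, 100, 100), (100, 100, 100), (60, 80, 200)])
        with pytest.warns(UserWarning, match="insertion order"):
            model = build_model_from_points(
                img, [(0, 0, "background"), (0, 1, "healthy"), (0, 2, "fibrotic")]
            )
        assert len(model.subclusters) == 3

    def test_median_patch_center(self):
        img = np.full((5, 5, 3), 100, dtype=np.uint8)
        img[2, 2] = (255, 0, 0)  # speckle at the sampled pixel
        img[0:2, 0:2] = (250, 250, 250)
        img[0:2, 3:5] = (60, 80, 200)
        model = build_model_from_points(
            img,
            [(0, 0, "background"), (2, 2, "healthy"), (0, 4, "fibrotic")],
            patch=3,
        )
        # median of the 3x3 patch suppresses the speckle
        healthy = model.subclusters[1].center
        assert healthy.saturation == pytest.approx(0.0)


class TestClassifyPixel:
    def test_exact_center_match_wins(self, basic_model):
        for sc in basic_model.subclusters:
            assert classify_pixel(basic_model, sc.center) == sc.parent

    def test_tie_breaks_to_earliest_inserted(self):
        model = ClassifierModel(
            subclusters=(
                SubCluster(TissueClass.BACKGROUND, HSVColor(0.0, 0.0, 0.0)),
                SubCluster(TissueClass.HEALTHY, HSVColor(0.0, 0.5, 0.5)),
                SubCluster(TissueClass.FIBROTIC, HSVColor(0.0, 0.0, 1.0)),
            )
        )
        # equidistant between background (v=0) and fibrotic (v=1)
        assert (
            classify_pixel(model, HSVColor(0.0, 0.0, 0.5)) == TissueClass.BACKGROUND
        )

    def test_nearest_of_three_centers(self, basic_model):
        # verified by evaluating all three distances by hand:
        # bg 0.975, healthy 0.388, fibrotic 0.144
        assert (
            classify_pixel(basic_model, HSVColor(230.0, 0.9, 0.9))
            == TissueClass.FIBROTIC
        )

    def test_incomplete_model_rejected(self):
        model = ClassifierModel(
            subclusters=(SubCluster(TissueClass.HEALTHY, HSVColor(0, 1, 1)),)
        )
        with pytest.raises(ValueError, match="background"):
            classify_pixel(model, HSVColor(0, 0, 1))


class TestSegmentImage:
    def test_pixels_equal_to_centers_get_their_parent(self):
        img = np.array(
            [
                [(255, 255, 255), (200, 40, 60)],
                [(60, 80, 200), (200, 40, 60)],
            ],
            dtype=np.uint8,
        )
        model = build_model_from_points(
            img, [(0, 0, "background"), (0, 1, "healthy"), (1, 0, "fibrotic")]
        )
        mask = segment_image(model, img)
        assert mask.tolist() == [[0, 1], [2, 1]]

    def test_matches_brute_force_oracle_on_random_images(self, basic_model, rng):
        for _ in range(6):
            img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
            assert np.array_equal(
                segment_image(basic_model, img),
                brute_force_nearest_center(img, basic_model),
            )

    def test_matches_oracle_with_multiple_subclusters(self, rng):
        model = model_from_palette(preset_palette("masson"))
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        assert np.array_equal(
            segment_image(model, img), brute_force_nearest_center(img, model)
        )

    def test_noise_free_chart_recovered_exactly(self):
        spec = default_table3_spec("masson", noise_sigma=0.0, seed=2)
        img, truth = generate_chart(spec)
        mask = segment_image(model_from_palette(spec.palette), img)
        assert np.array_equal(mask, truth)

    def test_total_partition(self, basic_model, rng):
        img = rng.integers(0, 256, size=(9, 13, 3), dtype=np.uint8)
        mask = segment_image(basic_model, img)
        counts = np.bincount(mask.ravel(), minlength=3)
        assert counts.sum() == 9 * 13
        assert set(np.unique(mask)) <= {0, 1, 2}

    def test_empty_image_rejected(self, basic_model):
        with pytest.raises(ValueError):
            segment_image(basic_model, np.zeros((0, 4, 3), dtype=np.uint8))

    def test_order_invariance_modulo_ties(self, rng):
        """Permuting sub-clusters relabels no pixel whose nearest distance is unique."""
        centers = rng.random((6, 3))
        centers[:, 0] *= 0.999
        subs = tuple(
            SubCluster(TissueClass(i % 3), HSVColor(c[0] * 360, c[1], c[2]))
            for i, c in enumerate(centers)
        )
        model = ClassifierModel(subclusters=subs)
        img = rng.integers(0, 256, size=(12, 12, 3), dtype=np.uint8)
        perm = rng.permutation(6)
        permuted = ClassifierModel(subclusters=tuple(subs[i] for i in perm))
        # generic random centers: ties have probability zero
        assert np.array_equal(segment_image(model, img), segment_image(permuted, img))

    def test_subclass_monotonicity(self, rng):
        """Adding a sub-cluster to class j never shrinks S_j."""
        img = rng.integers(0, 256, size=(20, 20, 3), dtype=np.uint8)
        model = model_from_palette(preset_palette("masson"))
        before = segment_image(model, img)
        for cls in TissueClass:
            grown = model.add_subcluster(
                SubCluster(cls, HSVColor(rng.random() * 360, rng.random(), rng.random()))
            )
            after = segment_image(grown, img)
            was_cls = before == int(cls)
            assert np.all(after[was_cls] == int(cls))
            assert (after == int(cls)).sum() >= was_cls.sum()

    def test_single_step_property_shuffle(self, basic_model, rng):
        """Output depends only on each pixel's color, never on image statistics."""
        img = rng.integers(0, 256, size=(10, 10, 3), dtype=np.uint8)
        mask = segment_image(basic_model, img)
        perm = rng.permutation(100)
        shuffled = img.reshape(-1, 3)[perm].reshape(10, 10, 3)
        shuffled_mask = segment_image(basic_model, shuffled)
        assert np.array_equal(shuffled_mask, mask.reshape(-1)[perm].reshape(10, 10))


class TestStandardKmeans:
    def test_perfectly_separable_colors(self):
        colors = [(255, 0, 0), (0, 255, 0), (0, 0, 255)]
        img = np.array([[colors[(r + c) % 3] for c in range(9)] for r in range(9)],
                       dtype=np.uint8)
        labels, centers = standard_kmeans(img, k=3, seed=0)
        # each distinct color forms one pure cluster
        for color in colors:
            sel = np.all(img == color, axis=-1)
            assert len(np.unique(labels[sel])) == 1
        assert centers.shape == (3, 3)

    def test_seeded_determinism(self, rng):
        img = rng.integers(0, 256, size=(24, 24, 3), dtype=np.uint8)
        l1, c1 = standard_kmeans(img, k=4, seed=7)
        l2, c2 = standard_kmeans(img, k=4, seed=7)
        assert np.array_equal(l1, l2)
        assert np.allclose(c1, c2)

    def test_too_few_distinct_colors(self):
        img = np.full((5, 5, 3), 42, dtype=np.uint8)
        with pytest.raises(ValueError, match="distinct colors"):
            standard_kmeans(img, k=3, seed=0)


class TestPresets:
    def test_masson_fibrotic_centers_are_blue(self):
        model = load_preset("masson")
        model.validate()
        fib = [sc.center.hue for sc in model.subclusters if sc.parent == TissueClass.FIBROTIC]
        assert fib and all(180.0 <= h <= 280.0 for h in fib)

    def test_picosirius_fibrotic_centers_are_red(self):
        model = load_preset("picosirius")
        fib = [sc.center.hue for sc in model.subclusters if sc.parent == TissueClass.FIBROTIC]
        assert fib and all(h >= 330.0 or h <= 30.0 for h in fib)

    def test_every_class_has_subclusters(self):
        for name in ("masson", "picosirius"):
            model = load_preset(name)
            parents = {sc.parent for sc in model.subclusters}
            assert parents == set(TissueClass)

    def test_unknown_preset_lists_available(self):
        with pytest.raises(ValueError, match="masson.*picosirius"):
            load_preset("hematoxylin")


class TestColorsFile:
    def test_rgb_colors_file(self, tmp_path):
        p = tmp_path / "colors.csv"
        p.write_text(
            "class,r,g,b\nbackground,250,250,250\nhealthy,200,40,60\nfibrotic,60,80,200\n"
        )
        model = model_from_colors_file(p)
        assert len(model.subclusters) == 3

    def test_hsv_colors_file(self, tmp_path):
        p = tmp_path / "colors.csv"
        p.write_text(
            "class,h,s,v\nbackground,0,0.02,0.97\nhealthy,350,0.6,0.8\nfibrotic,225,0.6,0.7\n"
        )
        model = model_from_colors_file(p)
        assert model.subclusters[2].center.hue == pytest.approx(225.0)

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "colors.csv"
        p.write_text("class,x,y\nbackground,1,2\n")
        with pytest.raises(ValueError, match="header"):
            model_from_colors_file(p)
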