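"""Synthetic scene generator: rendering, ground truth, determinism."""

import numpy as np
import pytest

from sicklenet import synthetic as syn

from oracles import binomial_99_interval, flood_fill_components


def _adhered_spec(centroid, kind="deformable_srbc", major=15.0, minor=12.0):
    extra = {"dimple_depth": 0.6} if kind == "deformable_srbc" else \
            {"sharpness": 1.3, "minor_axis": 8.0, "major_axis": 24.0}
    base = dict(object_class=kind, centroid=centroid, orientation=20.0,
                major_axis=major, minor_axis=minor)
    base.update(extra)
    return syn.CellSpec(**base)


class TestRenderScene:
    def test_empty_scene_has_empty_mask_and_table(self):
        scene = syn.render_scene(syn.SceneSpec(height=64, width=64, seed=1))
        assert not scene.mask.any()
        assert len(scene.objects) == 0
        assert scene.image.shape == (64, 64)

    def test_adhered_component_count_matches_specs(self):
        """3 deformable + 2 non-deformable cells produce exactly 5 label-1
        components (independent flood-fill oracle) and 5 adhered rows."""
        cells = [_adhered_spec((40, 40)), _adhered_spec((40, 120)),
                 _adhered_spec((120, 40)),
                 _adhered_spec((120, 120), "nondeformable_srbc"),
                 _adhered_spec((80, 200), "nondeformable_srbc")]
        scene = syn.render_scene(syn.SceneSpec(height=160, width=240,
                                               cells=cells, seed=5))
        assert len(flood_fill_components(scene.mask == 1)) == 5
        assert (scene.objects.object_class.isin(syn.ADHERED_CLASSES)).sum() == 5

    def test_rendering_is_bit_identical_under_seed(self):
        spec = syn.sample_scene_spec(np.random.default_rng(3), 128, 128)
        a = syn.render_scene(spec)
        b = syn.render_scene(spec)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_mask_labels_partition_object_classes(self):
        rng = np.random.default_rng(11)
        scene = syn.render_scene(syn.sample_scene_spec(rng, 256, 256))
        assert set(np.unique(scene.mask)) <= {0, 1, 2}
        n_adhered = scene.objects.object_class.isin(syn.ADHERED_CLASSES).sum()
        assert len(flood_fill_components(scene.mask == 1)) == n_adhered

    def test_label1_pixels_stay_near_adhered_centroids(self):
        """Mask consistency: every adhered pixel lies within the largest
        major axis of some adhered centroid."""
        rng = np.random.default_rng(13)
        scene = syn.render_scene(syn.sample_scene_spec(rng, 192, 192))
        adhered = scene.objects[
            scene.objects.object_class.isin(syn.ADHERED_CLASSES)]
        if len(adhered) == 0:
            pytest.skip("draw contained no adhered cells")
        rr, cc = np.nonzero(scene.mask == 1)
        dists = np.sqrt(
            (rr[:, None] - adhered.row.to_numpy()) ** 2
            + (cc[:, None] - adhered.col.to_numpy()) ** 2).min(axis=1)
        assert dists.max() <= adhered.major.max()

    def test_unplaceable_crowding_raises_overlap_error(self):
        cells = [_adhered_spec((32, 32), major=40.0, minor=36.0)
                 for _ in range(8)]
        spec = syn.SceneSpec(height=64, width=64, cells=cells, seed=0)
        with pytest.raises(syn.SceneOverlapError, match="cell #"):
            syn.render_scene(spec)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="minor_axis"):
            syn.CellSpec("wbc", (10, 10), major_axis=5, minor_axis=9).validate()
        with pytest.raises(ValueError, match="dimple"):
            syn.CellSpec("wbc", (10, 10), dimple_depth=0.5).validate()
        with pytest.raises(ValueError, match="bounds"):
            syn.CellSpec("wbc", (-1, 10)).validate(64, 64)


class TestDimpleContrast:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dimple_statistic_separates_subtypes(self, seed):
        """The central-disc minus annulus contrast exceeds half the
        configured dimple depth for deformable cells and stays below it
        for spindles."""
        rng = np.random.default_rng(seed)
        deform = syn.sample_cell_spec(rng, "deformable_srbc", 96, 96)
        spindle = syn.sample_cell_spec(rng, "nondeformable_srbc", 96, 96)
        threshold = 0.5 * deform.dimple_depth * syn.CELL_CONTRAST
        s1 = syn.render_scene(syn.SceneSpec(96, 96, [deform], seed=seed))
        s2 = syn.render_scene(syn.SceneSpec(96, 96, [spindle], seed=seed))
        d1 = syn.dimple_statistic(s1.image, s1_spec(s1, deform))
        d2 = syn.dimple_statistic(s2.image, s1_spec(s2, spindle))
        assert d1 >= threshold
        assert d2 < threshold


def s1_spec(scene, original):
    """Rebuild the spec at its (possibly relocated) rendered centroid."""
    row = scene.objects.iloc[0]
    from dataclasses import replace
    return replace(original, centroid=(row.row, row.col))


class TestMakeDataset:
    def test_zero_scenes_gives_empty_manifest(self):
        scenes, manifest = syn.make_dataset(0, seed=0)
        assert scenes == []
        assert len(manifest) == 0

    def test_manifests_identical_under_fixed_seed(self):
        _, m1 = syn.make_dataset(6, {"height": 96, "width": 96}, seed=9)
        _, m2 = syn.make_dataset(6, {"height": 96, "width": 96}, seed=9)
        assert m1.equals(m2)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            syn.make_dataset(-1)

    def test_class_mix_follows_requested_proportions(self):
        """50 scenes at 40% deformable: the pooled deformable fraction
        falls inside the 99% binomial interval around 0.40."""
        probs = {"deformable_srbc": 0.40, "nondeformable_srbc": 0.20,
                 "wbc": 0.15, "out_of_focus": 0.15, "debris": 0.10}
        _, manifest = syn.make_dataset(
            50, {"class_probs": probs, "height": 192, "width": 192}, seed=21)
        n = len(manifest)
        frac = (manifest["class"] == "deformable_srbc").mean()
        assert abs(frac - 0.40) <= binomial_99_interval(0.40, n)

    def test_dataset_written_to_disk_round_trips(self, tmp_path):
        scenes, manifest = syn.make_dataset(
            2, {"height": 64, "width": 64, "n_cells": (1, 2)}, seed=4,
            out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        from sicklenet.channel import read_image, read_mask
        img = read_image(tmp_path / "scene_0000.png")
        assert img.shape == (64, 64)
        np.testing.assert_array_equal(read_mask(tmp_path / "mask_0000.png"),
                                      scenes[0].mask)


class TestCropGroundTruth:
    def test_one_labeled_crop_per_adhered_cell(self):
        cells = [_adhered_spec((50, 50)), _adhered_spec((50, 130)),
                 _adhered_spec((130, 50), "nondeformable_srbc"),
                 _adhered_spec((130, 130)), _adhered_spec((90, 200))]
        scene = syn.render_scene(syn.SceneSpec(180, 240, cells, seed=2))
        crops = syn.crop_ground_truth(scene)
        assert len(crops) == 5
        assert sorted(label for _, label in crops) == sorted(
            c.object_class for c in cells)
        for crop, _ in crops:
            assert crop.pixels.shape == (32, 32)

    def test_centered_cell_crop_center_is_inside_footprint(self):
        cell = _adhered_spec((48, 48))
        scene = syn.render_scene(syn.SceneSpec(96, 96, [cell], seed=1))
        (crop, label), = syn.crop_ground_truth(scene)
        r, c = int(round(crop.centroid[0])), int(round(crop.centroid[1]))
        assert scene.mask[r, c] == 1
        assert label == "deformable_srbc"

    def test_scene_without_adhered_objects_yields_no_crops(self):
        cells = [syn.CellSpec("out_of_focus", (40, 40), major_axis=14,
                              minor_axis=13),
                 syn.CellSpec("wbc", (40, 90), major_axis=15, minor_axis=15)]
        scene = syn.render_scene(syn.SceneSpec(128, 128, cells, seed=0))
        assert syn.crop_ground_truth(scene) == []

    def test_border_cell_still_gets_full_crop(self):
        cell = _adhered_spec((9, 9), major=13.0, minor=11.0)
        scene = syn.render_scene(syn.SceneSpec(96, 96, [cell], seed=0))
        (crop, _), = syn.crop_ground_truth(scene)
        assert crop.pixels.shape == (32, 32)


class TestCropCorpus:
    def test_crop_dataset_covers_all_three_classes(self):
        crops, labels = syn.make_crop_dataset(120, seed=3)
        assert crops.shape == (120, 32, 32)
        assert set(labels) == {"deformable_srbc", "nondeformable_srbc",
                               "non_srbc"}

    def test_crop_dataset_deterministic(self):
        a, la = syn.make_crop_dataset(40, seed=5)
        b, lb = syn.make_crop_dataset(40, seed=5)
        np.testing.assert_array_equal(a, b)
        assert (la == lb).all()
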