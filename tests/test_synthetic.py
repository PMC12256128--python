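"""Generator contracts: determinism, exact bounding boxes, injection bookkeeping."""

import json

import numpy as np
import pytest
from sklearn.neighbors import NearestCentroid

import rpvaudit as ra
from rpvaudit.synthetic import (
    BACKGROUND_RGB,
    BBOX_AREA_BAND,
    parameter_distance,
)


class TestMakeSpeciesSet:
    def test_minimal_case_has_no_confusable_link(self):
        specs = ra.make_species_set(2, 0, seed=7)
        assert len(specs) == 2
        assert all(s.confusable_with is None for s in specs)

    def test_confusable_pair_bookkeeping(self):
        specs = ra.make_species_set(6, 2, seed=1)
        assert len(specs) == 6
        linked = [s for s in specs if s.confusable_with is not None]
        assert len(linked) == 4
        by_name = {s.species_name: s for s in specs}
        for s in linked:  # links are mutual
            assert by_name[s.confusable_with].confusable_with == s.species_name

    def test_deterministic_for_fixed_seed(self):
        assert ra.make_species_set(5, 1, seed=1) == ra.make_species_set(5, 1, seed=1)
        assert ra.make_species_set(5, 1, seed=1) != ra.make_species_set(5, 1, seed=2)

    def test_names_unique_and_parameters_distinct(self):
        specs = ra.make_species_set(8, 3, seed=11)
        names = [s.species_name for s in specs]
        assert len(set(names)) == 8
        for i, a in enumerate(specs):
            for b in specs[i + 1 :]:
                assert parameter_distance(a, b) > 0

    def test_confusable_pairs_closer_than_any_other_pair(self):
        specs = ra.make_species_set(6, 2, seed=1)
        by_name = {s.species_name: s for s in specs}
        conf_d = [
            parameter_distance(s, by_name[s.confusable_with])
            for s in specs
            if s.confusable_with
        ]
        other_d = [
            parameter_distance(a, b)
            for i, a in enumerate(specs)
            for b in specs[i + 1 :]
            if a.confusable_with != b.species_name
        ]
        assert max(conf_d) < min(other_d)

    @pytest.mark.parametrize("args", [(1, 0, 0), (6, 4, 0), (4, -1, 0)])
    def test_invalid_arguments_rejected(self, args):
        with pytest.raises(ValueError):
            ra.make_species_set(*args)


class TestRenderSpecimen:
    def test_background_uniform_outside_box(self, species6):
        img, box = ra.render_specimen(species6[0], np.random.default_rng(3), 128)
        outside = np.ones(img.shape[:2], dtype=bool)
        outside[box.y_min : box.y_max, box.x_min : box.x_max] = False
        assert (img[outside] == BACKGROUND_RGB).all()
        # and the box is tight: every edge row/column touches foreground
        inner = img[box.y_min : box.y_max, box.x_min : box.x_max]
        fg = (inner != BACKGROUND_RGB).any(axis=2)
        assert fg[0].any() and fg[-1].any() and fg[:, 0].any() and fg[:, -1].any()

    def test_label_strip_is_only_extra_foreground(self, species6):
        rng = np.random.default_rng(3)
        img, box = ra.render_specimen(species6[0], rng, 128, with_label_strip=True)
        outside = np.ones(img.shape[:2], dtype=bool)
        outside[box.y_min : box.y_max, box.x_min : box.x_max] = False
        strip_rows = slice(int(0.88 * 128), int(0.96 * 128))
        nonbg = (img != BACKGROUND_RGB).any(axis=2) & outside
        assert nonbg.any()
        assert np.flatnonzero(nonbg.any(axis=1)).min() >= strip_rows.start
        assert box.y_max <= strip_rows.start  # strip never overlaps the specimen

    def test_box_area_within_documented_jitter_band(self, species6):
        spec = ra.SpeciesSpec("t", 120.0, 4.0, 0.8, 0.5, None)
        rng = np.random.default_rng(5)
        nominal = (0.5 * 128) ** 2
        for _ in range(10):
            _, box = ra.render_specimen(spec, rng, 128)
            assert BBOX_AREA_BAND[0] * nominal <= box.area <= BBOX_AREA_BAND[1] * nominal

    def test_deterministic_for_fixed_rng_state(self, species6):
        img1, box1 = ra.render_specimen(species6[1], 99, 64, with_label_strip=True)
        img2, box2 = ra.render_specimen(species6[1], 99, 64, with_label_strip=True)
        assert box1 == box2
        assert (img1 == img2).all()

    def test_small_canvas_rejected(self, species6):
        with pytest.raises(ValueError):
            ra.render_specimen(species6[0], 0, canvas_size=16)


class TestGenerateDataset:
    def test_zero_rate_means_no_swaps(self, tmp_path, species6):
        ds = ra.generate_dataset(species6[:3], 4, 0.0, seed=2, out_dir=tmp_path)
        assert ds.ground_truth.injected_mislabels == []
        assert ds.ground_truth.assigned_labels == ds.ground_truth.true_labels

    def test_injection_count_and_swap_validity(self, small_dataset):
        gt = small_dataset.ground_truth
        total = len(gt.true_labels)
        assert total == 4 * 30
        assert len(gt.injected_mislabels) == round(0.05 * total) == 6
        for sid, true, assigned in gt.injected_mislabels:
            assert assigned != true
            assert gt.assigned_labels[sid] == assigned

    def test_six_by_eighty_at_three_percent_gives_14_swaps(self, tmp_path, species6):
        # round(0.03 * 480) = 14; recount from the written ground truth
        ds = ra.generate_dataset(species6, 80, 0.03, seed=11, out_dir=tmp_path,
                                 with_label_strip=False, canvas_size=48)
        gt = ra.GroundTruth.from_json(ds.ground_truth_path)
        swaps = [s for s in gt.true_labels if gt.assigned_labels[s] != gt.true_labels[s]]
        assert len(swaps) == 14

    def test_per_species_counts_and_catalog_consistency(self, small_dataset):
        records = ra.load_catalog(small_dataset.catalog_path)
        gt = small_dataset.ground_truth
        assert len(records) == len(gt.true_labels)
        by_true = {}
        for r in records:
            by_true[gt.true_labels[r.specimen_id]] = by_true.get(
                gt.true_labels[r.specimen_id], 0) + 1
            assert r.current_label == gt.assigned_labels[r.specimen_id]
        assert set(by_true.values()) == {30}

    def test_catalog_and_groundtruth_bytes_deterministic(self, tmp_path, species6):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        ds1 = ra.generate_dataset(species6[:3], 5, 0.2, seed=9, out_dir=d1, canvas_size=48)
        ds2 = ra.generate_dataset(species6[:3], 5, 0.2, seed=9, out_dir=d2, canvas_size=48)
        assert ds1.catalog_path.read_bytes() == ds2.catalog_path.read_bytes()
        assert ds1.ground_truth_path.read_bytes() == ds2.ground_truth_path.read_bytes()
        name = ds1.ground_truth.injected_mislabels[0][0] + ".png"
        assert (d1 / "images" / name).read_bytes() == (d2 / "images" / name).read_bytes()

    def test_invalid_rate_rejected(self, tmp_path, species6):
        with pytest.raises(ValueError):
            ra.generate_dataset(species6[:2], 3, 1.0, seed=1, out_dir=tmp_path)

    def test_swaps_prefer_confusable_partner(self, tmp_path):
        specs = ra.make_species_set(6, 3, seed=4)  # every species has a partner
        ds = ra.generate_dataset(specs, 20, 0.25, seed=4, out_dir=tmp_path,
                                 canvas_size=48, with_label_strip=False)
        by_name = {s.species_name: s for s in specs}
        to_partner = sum(
            1 for _, true, assigned in ds.ground_truth.injected_mislabels
            if by_name[true].confusable_with == assigned
        )
        n = len(ds.ground_truth.injected_mislabels)
        assert n == 30
        assert to_partner / n > 0.5  # nominal preference is 0.8


def test_mean_colour_nearest_centroid_separates_nonconfusable(small_dataset_arrays,
                                                              small_dataset):
    """Sanity floor: non-confusable species are trivially separable on colour."""
    ids, imgs, _ = small_dataset_arrays
    gt = small_dataset.ground_truth
    linked = {s.species_name for s in small_dataset.species if s.confusable_with}
    keep = [i for i, sid in enumerate(ids) if gt.true_labels[sid] not in linked]
    feats = np.array([imgs[i].reshape(-1, 3).mean(axis=0) for i in keep])
    y = np.array([gt.true_labels[ids[i]] for i in keep])
    assert len(set(y)) >= 2
    model = NearestCentroid().fit(feats, y)
    assert (model.predict(feats) == y).mean() > 0.9
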