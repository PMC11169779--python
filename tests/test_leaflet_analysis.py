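"""Cuspid-number determination, KNN refinement, naming and classification."""

import numpy as np
import pytest

from aortaseg.errors import EmptyStructureError, GeometryError, ValidationError
from aortaseg.leaflet_analysis import (
    classify_valve,
    confusion_and_accuracy,
    determine_cuspid_number,
    detect_raphe,
    keep_largest_component,
    name_leaflets,
    refine_leaflet_boundary,
    remove_small_components,
)
from aortaseg.preprocess import AugmentParams, augment
from aortaseg.volume import LABEL_LEAFLET, LabelVolume

from oracles import flood_fill_components, mean_silhouette


class TestKeepLargest:
    def test_matches_flood_fill_on_random_masks(self):
        """Largest surviving component equals the brute-force flood-fill
        maximum on random small masks, for both connectivities."""
        rng = np.random.default_rng(0)
        for trial in range(20):
            mask = rng.uniform(size=(16, 16, 16)) < 0.2
            if not mask.any():
                continue
            for conn in (6, 26):
                got = keep_largest_component(mask, connectivity=conn)
                labels, n = flood_fill_components(mask, connectivity=conn)
                counts = np.bincount(labels.ravel())[1:]
                assert got.sum() == counts.max()
                # the kept set is exactly one oracle component
                kept_ids = np.unique(labels[got])
                assert len(kept_ids) == 1
                assert counts[kept_ids[0] - 1] == counts.max()

    def test_small_piece_removed(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[2:7, 2:6, 2:7] = True  # 100 voxels
        mask[15, 15, 12:17] = True  # 5 voxels
        out = keep_largest_component(mask)
        assert out.sum() == 100 and not out[15, 15, 14]

    def test_single_component_unchanged(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[3:6, 3:6, 3:6] = True
        assert np.array_equal(keep_largest_component(mask), mask)

    def test_tie_broken_by_lexicographic_seed_voxel(self):
        mask = np.zeros((20, 10, 10), bool)
        mask[12:14, 2:7, 2] = True  # 10 voxels, seed voxel (12,2,2)
        mask[2:4, 2:7, 2] = True  # 10 voxels, seed voxel (2,2,2) wins the tie
        out = keep_largest_component(mask)
        assert out[2, 2, 2] and not out[12, 2, 2]

    def test_empty_mask_errors(self):
        with pytest.raises(EmptyStructureError, match="empty structure"):
            keep_largest_component(np.zeros((8, 8, 8), bool))


def test_remove_small_components_keeps_multiple_large_pieces():
    mask = np.zeros((24, 24, 24), bool)
    mask[2:6, 2:6, 2:6] = True
    mask[12:16, 12:16, 12:16] = True
    mask[20, 20, 20] = True  # scattered speck
    out = remove_small_components(mask, min_voxels=10)
    assert out.sum() == 2 * 64 and not out[20, 20, 20]


def _spherical_clouds(centers, n_each, radius, seed):
    rng = np.random.default_rng(seed)
    mask = np.zeros((40, 40, 40), bool)
    truth = {}
    for ci, c in enumerate(centers):
        placed = 0
        while placed < n_each:
            p = rng.normal(c, radius, 3).round().astype(int)
            if all(0 <= x < 40 for x in p) and not mask[tuple(p)]:
                mask[tuple(p)] = True
                truth[tuple(p)] = ci
                placed += 1
    idx = np.argwhere(mask)
    truth_labels = np.array([truth[tuple(i)] for i in idx])
    return mask, truth_labels


class TestDetermineCuspidNumber:
    def test_three_separated_clouds_select_k3(self):
        """Three well-separated clouds at 120 deg spacing: the true
        3-partition has the higher silhouette (verified exhaustively) and
        k-means recovers it up to relabelling."""
        R = 13
        centers = [
            (20 + R * np.cos(np.radians(a)), 20 + R * np.sin(np.radians(a)), 20)
            for a in (90, 210, 330)
        ]
        mask, truth = _spherical_clouds(centers, 80, 2.0, seed=5)
        k, assignment, sils = determine_cuspid_number(mask, (1, 1, 1), seed=0)
        assert k == 3
        coords = np.argwhere(mask).astype(float)
        # oracle: exhaustive silhouette of the construction's partitions
        sil3_true = mean_silhouette(coords, truth)
        sil2_merge = mean_silhouette(coords, np.where(truth == 2, 1, truth))
        assert sil3_true > sil2_merge
        # partition equals ground truth up to relabelling
        mapping = {}
        for c in range(3):
            vals, counts = np.unique(assignment[truth == c], return_counts=True)
            mapping[c] = vals[counts.argmax()]
        assert len(set(mapping.values())) == 3
        agree = np.mean([mapping[t] == a for t, a in zip(truth, assignment)])
        assert agree == 1.0

    def test_two_separated_clouds_select_k2(self):
        mask, truth = _spherical_clouds([(12, 20, 20), (28, 20, 20)], 120, 2.0, seed=6)
        k, assignment, sils = determine_cuspid_number(mask, (1, 1, 1), seed=0)
        assert k == 2
        coords = np.argwhere(mask).astype(float)
        assert mean_silhouette(coords, truth) > 0.5

    def test_determinism(self):
        mask, _ = _spherical_clouds([(12, 20, 20), (28, 20, 20)], 120, 2.0, seed=7)
        r1 = determine_cuspid_number(mask, (1, 1, 1), seed=3)
        r2 = determine_cuspid_number(mask, (1, 1, 1), seed=3)
        assert r1[0] == r2[0]
        assert np.array_equal(r1[1], r2[1])
        assert r1[2] == r2[2]

    def test_insufficient_voxels_rejected(self):
        mask = np.zeros((40, 40, 40), bool)
        mask[5:8, 5:8, 5:8] = True
        with pytest.raises(ValidationError, match="insufficient leaflet volume"):
            determine_cuspid_number(mask, (1, 1, 1), seed=0)


class TestRefineBoundary:
    def test_coherent_assignment_unchanged(self):
        mask = np.zeros((30, 30, 30), bool)
        mask[5:10, 5:25, 5:25] = True
        mask[20:25, 5:25, 5:25] = True
        idx = np.argwhere(mask)
        assignment = (idx[:, 0] >= 15).astype(np.int32)
        out = refine_leaflet_boundary(mask, assignment, 15, (1, 1, 1))
        assert np.array_equal(out, assignment)

    def test_deep_mislabeled_voxel_flipped(self):
        """A single wrong label inside a cluster is corrected by the
        majority of its nearest out-of-band neighbours."""
        mask = np.zeros((30, 30, 30), bool)
        mask[5:15, 5:15, 5:15] = True
        mask[20:28, 5:15, 5:15] = True
        idx = np.argwhere(mask)
        assignment = (idx[:, 0] >= 18).astype(np.int32)
        # flip one voxel deep inside cluster 0
        target = np.flatnonzero((idx == [9, 9, 9]).all(axis=1))[0]
        assignment[target] = 1
        out = refine_leaflet_boundary(mask, assignment, 15, (1, 1, 1))
        assert out[target] == 0
        # voxel set / partition-only invariant
        assert len(out) == len(assignment)

    def test_second_pass_converges(self, tav_case):
        img, lab, _ = tav_case
        mask = lab.data == LABEL_LEAFLET
        k, assignment, _ = determine_cuspid_number(mask, lab.spacing, seed=0)
        once = refine_leaflet_boundary(mask, assignment, 15, lab.spacing)
        twice = refine_leaflet_boundary(mask, once, 15, lab.spacing)
        changed = np.mean(once != twice)
        assert changed < 0.01

    def test_even_neighbors_rejected(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:8, 2:8, 2:8] = True
        with pytest.raises(ValidationError, match="odd"):
            refine_leaflet_boundary(mask, np.zeros(mask.sum(), np.int32), 10, (1, 1, 1))

    def test_too_few_reference_voxels_rejected(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[4:6, 4:6, 4:6] = True  # everything will be boundary band
        idx = np.argwhere(mask)
        assignment = (idx[:, 0] >= 5).astype(np.int32)
        with pytest.raises(ValidationError, match="reference voxels"):
            refine_leaflet_boundary(mask, assignment, 15, (1, 1, 1))


def _analyze(lab, img, seed=0):
    mask = lab.data == LABEL_LEAFLET
    k, assignment, _ = determine_cuspid_number(mask, lab.spacing, seed=seed)
    assignment = refine_leaflet_boundary(mask, assignment, 15, lab.spacing)
    names = name_leaflets(assignment, mask, lab)
    valve_class, raphe = classify_valve(k, mask, img, assignment)
    return k, assignment, names, valve_class, raphe


class TestNamingAndClassification:
    def test_tav_names_match_construction(self, tav_case):
        """The phantom places its cusps at the canonical angles; naming
        recovers each cusp's identity from its angular position."""
        img, lab, spec = tav_case
        k, assignment, names, valve_class, raphe = _analyze(lab, img)
        assert k == 3 and valve_class == "TAV" and not raphe
        assert sorted(names) == ["left-coronary", "non-coronary", "right-coronary"]
        mask = lab.data == LABEL_LEAFLET
        idx = np.argwhere(mask)
        layout = spec.cusp_layout()
        center = idx.mean(axis=0)
        for c in range(3):
            rel = idx[assignment == c].mean(axis=0) - center
            ang = np.degrees(np.arctan2(rel[1], rel[0])) % 360
            expected = min(layout, key=lambda nm: min(abs(layout[nm] - ang), 360 - abs(layout[nm] - ang)))
            assert names[c] == expected

    def test_bav_names_match_construction(self, bav0_case):
        img, lab, spec = bav0_case
        k, assignment, names, valve_class, raphe = _analyze(lab, img)
        assert k == 2 and valve_class == "BAV0" and not raphe
        assert sorted(names) == ["anterior", "posterior"]
        mask = lab.data == LABEL_LEAFLET
        idx = np.argwhere(mask)
        center = idx.mean(axis=0)
        for c in range(2):
            rel = idx[assignment == c].mean(axis=0) - center
            expected = "anterior" if rel[1] > 0 else "posterior"
            assert names[c] == expected

    def test_naming_stable_under_long_axis_rotation(self, tav_case):
        """A 10-degree rotation about the long axis must not change names."""
        img, lab, _ = tav_case
        _, _, names0, _, _ = _analyze(lab, img)
        ri, rl = augment(img, lab, AugmentParams(rotation_deg=(0, 0, 10), seed=0),
                         fill_value=-50.0)
        _, _, names1, _, _ = _analyze(rl, ri)
        assert sorted(names0) == sorted(names1)
        # same multiset and, cluster order aside, same angular identity:
        assert set(names0) == set(names1)

    def test_bav1_phantom_fires_raphe_detector(self, bav1_case):
        img, lab, _ = bav1_case
        k, _, names, valve_class, raphe = _analyze(lab, img)
        assert k == 2 and valve_class == "BAV1" and raphe

    def test_bav0_phantom_does_not_fire(self, bav0_case):
        img, lab, _ = bav0_case
        assert not detect_raphe(lab.data == LABEL_LEAFLET, lab.spacing)

    def test_k3_is_tav_by_definition(self, tav_case):
        img, lab, _ = tav_case
        assert classify_valve(3, lab.data == LABEL_LEAFLET, img) == ("TAV", False)

    def test_degenerate_axis_rejected(self):
        lab = LabelVolume(np.zeros((34, 34, 34), np.uint8), (1, 1, 1))
        mask = np.zeros((34, 34, 34), bool)
        mask[10:20, 10:20, 10:12] = True
        idx = np.argwhere(mask)
        with pytest.raises(GeometryError, match="degenerate"):
            name_leaflets((idx[:, 0] >= 15).astype(int), mask, lab)


class TestConfusionMatrix:
    def test_perfect_agreement(self):
        cm = confusion_and_accuracy(["TAV"] * 12 + ["BAV0"] * 8, ["TAV"] * 12 + ["BAV0"] * 8)
        assert cm.accuracy == 1.0
        assert np.trace(cm.counts) == 20

    def test_known_counts(self):
        """9 TAV->TAV, 1 TAV->BAV0, 10 BAV0->BAV0: 19/20 correct."""
        expert = ["TAV"] * 10 + ["BAV0"] * 10
        pred = ["TAV"] * 9 + ["BAV0"] + ["BAV0"] * 10
        cm = confusion_and_accuracy(pred, expert, classes=("TAV", "BAV0"))
        assert cm.counts.tolist() == [[9, 1], [0, 10]]
        assert cm.accuracy == pytest.approx(0.95)

    def test_rows_are_expert_columns_predicted(self):
        cm = confusion_and_accuracy(["BAV0"], ["TAV"], classes=("TAV", "BAV0"))
        assert cm.counts[0, 1] == 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            confusion_and_accuracy([], [])
        with pytest.raises(ValidationError):
            confusion_and_accuracy(["TAV"], ["TAV", "BAV0"])
        with pytest.raises(ValidationError):
            confusion_and_accuracy(["XYZ"], ["TAV"])

    def test_accuracy_one_iff_identical(self):
        rng = np.random.default_rng(3)
        classes = ("TAV", "BAV0", "BAV1")
        expert = [classes[i] for i in rng.integers(0, 3, 30)]
        pred = list(expert)
        assert confusion_and_accuracy(pred, expert).accuracy == 1.0
        pred[4] = "TAV" if pred[4] != "TAV" else "BAV0"
        assert confusion_and_accuracy(pred, expert).accuracy < 1.0
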