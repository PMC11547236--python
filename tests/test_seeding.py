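import numpy as np
import pytest

from bounti import (
    IntensityVolume,
    LabelVolume,
    dilate_seed,
    label_components,
    load_manual_seed,
    select_largest,
    threshold_mask,
)
from oracles import flood_components


def _volume(data):
    return IntensityVolume(np.asarray(data, dtype=np.uint16))


class TestThresholdMask:
    def test_zero_threshold_selects_everything(self):
        vol = _volume(np.random.default_rng(0).integers(0, 100, (3, 3, 3)))
        assert threshold_mask(vol, 0).mask.all()

    def test_max_threshold_selects_only_maxima(self):
        data = np.zeros((2, 2, 2), dtype=np.uint16)
        data[0, 0, 0] = 65535
        mask = threshold_mask(_volume(data), 65535).mask
        assert mask.sum() == 1 and mask[0, 0, 0]

    def test_comparison_is_inclusive(self):
        data = np.array([[[10, 20, 30]]])
        mask = threshold_mask(_volume(data), 20).mask
        assert mask.tolist() == [[[False, True, True]]]

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask(_volume(np.zeros((1, 1, 1))), 70000)


class TestLabelComponents:
    def test_empty_mask_yields_no_labels(self):
        mask = threshold_mask(_volume(np.zeros((3, 3, 3))), 1)
        labeled, sizes = label_components(mask)
        assert sizes == [] and not labeled.labels.any()

    def test_corner_contact_depends_on_connectivity(self):
        data = np.zeros((2, 2, 2), dtype=np.uint16)
        data[0, 0, 0] = data[1, 1, 1] = 100  # touch only at a corner
        mask = threshold_mask(_volume(data), 100)
        _, sizes26 = label_components(mask, connectivity=26)
        _, sizes6 = label_components(mask, connectivity=6)
        assert len(sizes26) == 1
        assert len(sizes6) == 2

    def test_edge_contact_separates_18_from_6(self):
        data = np.zeros((2, 2, 1), dtype=np.uint16)
        data[0, 0, 0] = data[1, 1, 0] = 100  # share an edge, not a face
        mask = threshold_mask(_volume(data), 100)
        assert len(label_components(mask, connectivity=18)[1]) == 1
        assert len(label_components(mask, connectivity=6)[1]) == 2

    def test_labels_ordered_by_descending_size(self):
        data = np.zeros((10, 10, 10), dtype=np.uint16)
        data[1:4, 1:4, 1:4] = 100  # 27-voxel cube
        data[6:8, 6:8, 6:8] = 100  # 8-voxel cube
        labeled, sizes = label_components(threshold_mask(_volume(data), 100))
        assert sizes == [27, 8]
        assert set(np.unique(labeled.labels[1:4, 1:4, 1:4])) == {1}
        assert set(np.unique(labeled.labels[6:8, 6:8, 6:8])) == {2}

    def test_size_ties_break_by_scan_order(self):
        data = np.zeros((1, 1, 5), dtype=np.uint16)
        data[0, 0, 0] = data[0, 0, 4] = 100  # two 1-voxel components
        labeled, sizes = label_components(threshold_mask(_volume(data), 100))
        assert sizes == [1, 1]
        assert labeled.labels[0, 0, 0] == 1  # first in scan order is label 1
        assert labeled.labels[0, 0, 4] == 2

    def test_agrees_with_flood_fill_on_random_masks(self):
        rng = np.random.default_rng(42)
        for conn in (6, 18, 26):
            data = (rng.random((7, 7, 7)) < 0.35).astype(np.uint16) * 100
            mask = threshold_mask(_volume(data), 100)
            labeled, sizes = label_components(mask, connectivity=conn)
            expected = flood_components(mask.mask, conn)
            assert len(sizes) == len(expected)
            assert sorted(sizes, reverse=True) == sorted(
                (len(c) for c in expected), reverse=True
            )
            # each oracle component carries exactly one label
            for comp in expected:
                labs = {int(labeled.labels[v]) for v in comp}
                assert len(labs) == 1 and 0 not in labs


class TestSelectLargest:
    def _three_components(self):
        data = np.zeros((3, 3, 9), dtype=np.uint16)
        data[0, 0, 0:5] = 100  # 5 voxels
        data[2, 2, 0:9] = 100  # 9 voxels
        data[1, 1, 7:9] = 100  # 2 voxels (may merge with the 9 under 26-conn)
        return _volume(data)

    def test_keeps_ns_largest_in_descending_order(self):
        data = np.zeros((3, 3, 9), dtype=np.uint16)
        data[0, 0, 0:5] = 100
        data[2, 0, 0:9] = 100
        data[0, 2, 0:2] = 100
        labeled, sizes = label_components(threshold_mask(_volume(data), 100))
        assert sizes == [9, 5, 2]
        seed = select_largest(labeled, sizes, ns=2)
        assert seed.segment_sizes == [9, 5]
        assert seed.num_segments == 2
        assert not (seed.labels.labels > 2).any()

    def test_saturates_with_warning_when_ns_exceeds_components(self):
        labeled, sizes = label_components(
            threshold_mask(self._three_components(), 100), connectivity=6
        )
        with pytest.warns(UserWarning, match="only"):
            seed = select_largest(labeled, sizes, ns=10)
        assert seed.num_segments == len(sizes) < 10

    def test_membership_never_changes_only_retention(self):
        labeled, sizes = label_components(
            threshold_mask(self._three_components(), 100), connectivity=6
        )
        seed = select_largest(labeled, sizes, ns=2)
        kept = seed.labels.labels > 0
        assert (labeled.labels[kept] > 0).all()
        assert ((labeled.labels > 0).sum() - kept.sum()) == sum(sizes[2:])

    def test_ns_below_one_rejected(self):
        labeled, sizes = label_components(threshold_mask(self._three_components(), 100))
        with pytest.raises(ValueError):
            select_largest(labeled, sizes, ns=0)


class TestDilateSeed:
    def _seed_from(self, labels):
        arr = np.asarray(labels, dtype=np.int32)
        sizes = np.bincount(arr.ravel())[1:].tolist()
        from bounti import Seed

        return Seed(labels=LabelVolume(arr), segment_sizes=sizes, provenance="auto")

    def test_single_voxel_grows_to_full_27_cube(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[2, 2, 2] = 1
        out = dilate_seed(self._seed_from(labels))
        assert out.segment_sizes == [27]
        assert (out.labels.labels[1:4, 1:4, 1:4] == 1).all()
        assert out.dilated

    def test_contested_midpoint_stays_background(self):
        labels = np.zeros((1, 1, 3), dtype=np.int32)
        labels[0, 0, 0] = 1
        labels[0, 0, 2] = 2
        out = dilate_seed(self._seed_from(labels))
        assert out.labels.labels[0, 0, 1] == 0  # claimed by both shells
        assert out.labels.labels[0, 0, 0] == 1
        assert out.labels.labels[0, 0, 2] == 2

    def test_empty_seed_stays_empty(self):
        out = dilate_seed(self._seed_from(np.zeros((3, 3, 3), dtype=np.int32)))
        assert not out.labels.labels.any()

    def test_original_labels_never_overwritten_and_disjoint(self):
        rng = np.random.default_rng(3)
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[rng.random((8, 8, 8)) < 0.05] = 1
        labels[(rng.random((8, 8, 8)) < 0.05) & (labels == 0)] = 2
        seed = self._seed_from(labels)
        out = dilate_seed(seed)
        original = labels > 0
        assert np.array_equal(out.labels.labels[original], labels[original])
        # superset per segment
        for k in (1, 2):
            assert ((labels == k) <= (out.labels.labels == k)).all()

    def test_mask_limit_restricts_claims(self):
        labels = np.zeros((1, 1, 3), dtype=np.int32)
        labels[0, 0, 0] = 1
        from bounti import BinaryMask

        limit = BinaryMask(mask=np.array([[[True, False, False]]]), threshold_used=0)
        out = dilate_seed(self._seed_from(labels), mask_limit=limit)
        assert out.labels.labels[0, 0, 1] == 0


class TestManualSeed:
    def test_preserve_keeps_touching_identities(self):
        labels = np.zeros((1, 1, 4), dtype=np.int32)
        labels[0, 0, 0:2] = 1
        labels[0, 0, 2:4] = 2  # touching label 1
        seed = load_manual_seed(LabelVolume(labels), mode="preserve", ns=2)
        assert seed.provenance == "manual_preserve"
        assert np.array_equal(seed.labels.labels, labels)

    def test_largest_merges_touching_labels_before_selection(self):
        labels = np.zeros((1, 1, 6), dtype=np.int32)
        labels[0, 0, 0:2] = 1
        labels[0, 0, 2:4] = 2  # touches 1 -> single 4-voxel component
        labels[0, 0, 5] = 3  # separate 1-voxel component
        seed = load_manual_seed(LabelVolume(labels), mode="largest", ns=1)
        assert seed.provenance == "manual_largest"
        assert seed.segment_sizes == [4]
        assert (seed.labels.labels[0, 0, 0:4] == 1).all()
        assert seed.labels.labels[0, 0, 5] == 0

    def test_preserve_on_disjoint_seed_is_identity(self):
        labels = np.zeros((2, 2, 2), dtype=np.int32)
        labels[0, 0, 0] = 1
        seed = load_manual_seed(LabelVolume(labels), mode="preserve", ns=1)
        assert np.array_equal(seed.labels.labels, labels)

    def test_empty_manual_seed_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            load_manual_seed(LabelVolume(np.zeros((2, 2, 2), dtype=np.int32)),
                             mode="preserve", ns=1)
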