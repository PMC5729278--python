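import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.measure import label as cc_label

from foamquant.imaging_io import merge_channels
from foamquant.segmentation import (
    EmptyForegroundError,
    LabelMap,
    SegmentationParams,
    ValidationError,
    build_seed_landscape,
    filter_cells,
    foreground_mask,
    segment_channel,
    watershed_labels,
)
from foamquant.synthetic import SyntheticSpec, generate_image

from conftest import disk_image


def two_disk_blob(r=15, separation=24, shape=(80, 100)):
    """Two overlapping disks forming one connected blob."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    centers = [(40, 50 - separation // 2), (40, 50 + separation // 2)]
    blob = np.zeros(shape, dtype=bool)
    for cy, cx in centers:
        blob |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return blob, centers


class TestForegroundMask:
    def test_disk_area_recovered(self, default_params):
        mask = foreground_mask(disk_image(radius=20), default_params)
        ideal = np.pi * 20**2
        assert abs(int(mask.sum()) - ideal) / ideal < 0.10

    def test_constant_image_yields_empty_mask(self, default_params):
        assert not foreground_mask(np.full((50, 50), 0.4), default_params).any()

    def test_small_objects_removed(self, default_params):
        img = disk_image(radius=2.5, noise_sd=0.0, size=64)
        assert not foreground_mask(img, default_params).any()


class TestSeedLandscape:
    def test_single_disk_single_seed(self, default_params):
        yy, xx = np.mgrid[:64, :64]
        blob = (yy - 32) ** 2 + (xx - 32) ** 2 <= 15**2
        land = build_seed_landscape(blob, h=1.0)
        assert cc_label(land.seed_mask, connectivity=2).max() == 1

    def test_merged_disks_yield_two_seeds(self):
        blob, _ = two_disk_blob()
        # oracle: regional maxima of the distance transform that stand
        # more than h above their saddle -> two distinct peaks
        dt = ndi.distance_transform_edt(blob)
        peak = ndi.maximum_filter(dt, size=3)
        n_peaks = cc_label((dt == peak) & (dt == dt.max()), connectivity=2).max()
        assert n_peaks == 2
        land = build_seed_landscape(blob, h=1.0)
        assert cc_label(land.seed_mask, connectivity=2).max() == 2

    def test_oversized_h_suppresses_all_seeds(self):
        blob, _ = two_disk_blob()
        land = build_seed_landscape(blob, h=1000.0)
        assert not land.seed_mask.any()
        assert watershed_labels(land).n_labels == 0

    def test_empty_foreground_raises(self):
        with pytest.raises(EmptyForegroundError, match="no foreground"):
            build_seed_landscape(np.zeros((10, 10), dtype=bool), h=1.0)

    @pytest.mark.parametrize("h_pair", [(0.5, 1.0), (1.0, 2.0), (2.0, 5.0)])
    def test_seed_count_monotone_in_h(self, h_pair):
        rng = np.random.default_rng(5)
        blob = np.zeros((120, 120), dtype=bool)
        yy, xx = np.mgrid[:120, :120]
        for _ in range(6):
            cy, cx, r = rng.integers(20, 100), rng.integers(20, 100), rng.integers(6, 16)
            blob |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        lo = cc_label(build_seed_landscape(blob, h_pair[0]).seed_mask, connectivity=2).max()
        hi = cc_label(build_seed_landscape(blob, h_pair[1]).seed_mask, connectivity=2).max()
        assert hi <= lo


class TestWatershed:
    def test_two_seed_blob_splits_along_nearest_seed_boundary(self):
        blob, centers = two_disk_blob()
        lm = watershed_labels(build_seed_landscape(blob, h=1.0))
        assert lm.n_labels == 2
        # oracle: assignment by nearest disk centre on the ideal geometry
        yy, xx = np.mgrid[: blob.shape[0], : blob.shape[1]]
        d = [np.hypot(yy - cy, xx - cx) for cy, cx in centers]
        oracle = np.where(d[0] < d[1], 1, 2)
        inside = lm.labels > 0
        direct = (lm.labels[inside] == oracle[inside]).mean()
        flipped = (lm.labels[inside] == (3 - oracle[inside])).mean()
        assert max(direct, flipped) > 0.99

    def test_single_seed_covers_foreground(self):
        yy, xx = np.mgrid[:64, :64]
        blob = (yy - 32) ** 2 + (xx - 32) ** 2 <= 12**2
        lm = watershed_labels(build_seed_landscape(blob, h=1.0))
        assert lm.n_labels == 1
        assert (lm.labels > 0).sum() == blob.sum()

    def test_ridge_pixels_are_background(self):
        blob, _ = two_disk_blob()
        lm = watershed_labels(build_seed_landscape(blob, h=1.0))
        ridge = blob & (lm.labels == 0)
        assert ridge.any()  # the split leaves a watershed line
        assert not (lm.labels[~blob] > 0).any()


class TestSegmentChannel:
    def test_separated_nuclei_counted_exactly(self, default_params):
        rng = np.random.default_rng(4)
        img = np.full((128, 128), 0.05)
        yy, xx = np.mgrid[:128, :128]
        for cy, cx in [(20, 20), (20, 100), (64, 60), (100, 20), (105, 100)]:
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 5**2] = 0.8
        img = np.clip(img + rng.normal(0, 0.02, img.shape), 0, 1)
        lm = segment_channel(img, default_params.h_blue, default_params, "nuclei")
        assert lm.n_labels == 5

    def test_fused_nuclei_split_by_distance_seeds(self, default_params):
        rng = np.random.default_rng(6)
        img = np.full((128, 128), 0.05)
        yy, xx = np.mgrid[:128, :128]
        for cy, cx in [(20, 20), (20, 100), (100, 20)]:
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 5**2] = 0.8
        # fourth and fifth nuclei fused into one blob
        for cx in (60, 69):
            img[(yy - 70) ** 2 + (xx - cx) ** 2 <= 5**2] = 0.8
        img = np.clip(img + rng.normal(0, 0.02, img.shape), 0, 1)
        lm = segment_channel(img, default_params.h_blue, default_params, "nuclei")
        assert lm.n_labels == 5

    def test_blank_channel_gives_zero_labels(self, default_params):
        lm = segment_channel(np.zeros((64, 64)), 0.6, default_params, "nuclei")
        assert lm.n_labels == 0


def _label_map(arr, source="candidates"):
    return LabelMap(labels=np.asarray(arr, dtype=np.int32), source=source)


class TestFilterCells:
    def _nucleus_inside(self, seg_shape=(20, 20)):
        cand = np.zeros(seg_shape, dtype=int)
        cand[5:15, 5:15] = 1
        nuc = np.zeros(seg_shape, dtype=int)
        nuc[8:12, 8:12] = 1
        return cand, nuc

    def test_mononucleate_interior_segment_retained(self, default_params):
        cand, nuc = self._nucleus_inside()
        out = filter_cells(_label_map(cand), _label_map(nuc, "nuclei"), default_params)
        assert out.n_labels == 1

    def test_multinucleate_segment_excluded(self, default_params):
        cand, nuc = self._nucleus_inside()
        nuc[12:14, 5:7] = 2  # second nucleus inside the same segment
        out = filter_cells(_label_map(cand), _label_map(nuc, "nuclei"), default_params)
        assert out.n_labels == 0

    def test_border_touching_segment_excluded(self, default_params):
        cand, nuc = self._nucleus_inside()
        cand[0, 5:15] = 1  # reach row 0
        out = filter_cells(_label_map(cand), _label_map(nuc, "nuclei"), default_params)
        assert out.n_labels == 0

    def test_nucleus_free_segment_excluded(self, default_params):
        cand, nuc = self._nucleus_inside()
        cand[16:19, 16:19] = 2  # extra segment with no nucleus
        out = filter_cells(_label_map(cand), _label_map(nuc, "nuclei"), default_params)
        assert out.n_labels == 1

    def test_majority_rule_assigns_straddling_nucleus_once(self, default_params):
        cand = np.zeros((20, 20), dtype=int)
        cand[2:18, 2:10] = 1
        cand[2:18, 10:18] = 2
        nuc = np.zeros((20, 20), dtype=int)
        nuc[8:12, 7:12] = 1  # 3 columns in segment 1, 2 in segment 2
        out = filter_cells(_label_map(cand), _label_map(nuc, "nuclei"), default_params)
        assert out.n_labels == 1
        # the retained segment is the majority holder (original label 1)
        assert set(np.unique(out.labels[cand == 1])) == {1}
        assert set(np.unique(out.labels[cand == 2])) == {0}

    def test_dimension_mismatch_rejected(self, default_params):
        with pytest.raises(ValidationError):
            filter_cells(
                _label_map(np.zeros((5, 5), dtype=int)),
                _label_map(np.zeros((6, 5), dtype=int), "nuclei"),
                default_params,
            )


class TestEndToEndSegmentation:
    def test_accepted_count_matches_ground_truth(self, segmented_mixed):
        _, truth, _, _, cells, counts = segmented_mixed
        assert cells.n_labels == truth.n_expected_accepted
        assert counts["accepted"] == truth.n_expected_accepted

    def test_binucleate_and_border_cells_always_excluded(self, segmented_mixed):
        _, truth, _, _, cells, _ = segmented_mixed
        rejected = truth.cells.loc[~truth.cells.expected_accepted, "cell_id"]
        for gid in rejected:
            gt_mask = truth.cell_labels == gid
            covered = cells.labels[gt_mask]
            # an accepted segment may graze a rejected cell's ground-truth
            # footprint, but never cover a substantial part of it
            assert (covered > 0).sum() < 0.25 * gt_mask.sum()

    def test_no_accepted_cell_touches_border(self, segmented_mixed):
        *_, cells, _ = segmented_mixed
        edge = np.concatenate(
            [cells.labels[0], cells.labels[-1], cells.labels[:, 0], cells.labels[:, -1]]
        )
        assert not (edge > 0).any()

    def test_relabeling_is_consecutive_bijection(self, segmented_mixed):
        *_, cells, _ = segmented_mixed
        ids = np.unique(cells.labels)
        np.testing.assert_array_equal(ids, np.arange(cells.n_labels + 1))

    def test_accepted_cells_each_contain_one_nucleus(self, segmented_mixed, default_params):
        _, _, nuclei, _, cells, _ = segmented_mixed
        for cid in cells.label_ids():
            seg_mask = cells.labels == cid
            count = 0
            for nid in np.unique(nuclei.labels[seg_mask]):
                if nid == 0:
                    continue
                nuc_mask = nuclei.labels == nid
                frac = (nuc_mask & seg_mask).sum() / nuc_mask.sum()
                if frac > default_params.nucleus_overlap_fraction:
                    count += 1
            assert count == 1

    def test_exact_count_across_seeds(self, default_params):
        for seed in (12, 19):
            spec = SyntheticSpec(
                n_cells=55, n_binucleate=2, n_border_touching=2, seed=seed
            )
            img, truth = generate_image(spec)
            nuclei = segment_channel(img.blue, default_params.h_blue, default_params, "nuclei")
            cand = segment_channel(
                merge_channels(img), default_params.h_merged, default_params, "candidates"
            )
            cells = filter_cells(cand, nuclei, default_params)
            assert cells.n_labels == truth.n_expected_accepted
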