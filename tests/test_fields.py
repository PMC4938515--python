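"""Majority resampling, mixed-pixel masking, segmentation, field filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra import numpy as hnp

from laiscape import (
    CropCalendar,
    filter_fields_by_size,
    mask_mixed_pixels,
    plausibility_filter,
    segment_fields,
    upscale_majority,
)
from laiscape.raster import Raster


def _lu(arr, res=5.0):
    return Raster(np.asarray(arr, np.int32), res, nodata=0, semantic="landuse")


# ----------------------------------------------------------------- oracles

def brute_force_mask(data, nodata=0):
    """Direct restatement of the rule: all 8 neighbors exist and match."""
    keep = np.zeros(data.shape, bool)
    for i in range(1, data.shape[0] - 1):
        for j in range(1, data.shape[1] - 1):
            block = data[i - 1 : i + 2, j - 1 : j + 2]
            keep[i, j] = data[i, j] != nodata and np.all(block == data[i, j])
    return keep


def flood_fill_labels(data, keep):
    """4-connected flood fill, label by row-major first pixel."""
    labels = np.zeros(data.shape, np.int32)
    nxt = 1
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            if keep[i, j] and labels[i, j] == 0:
                stack = [(i, j)]
                labels[i, j] = nxt
                while stack:
                    a, b = stack.pop()
                    for da, db in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                        x, y = a + da, b + db
                        if (
                            0 <= x < data.shape[0]
                            and 0 <= y < data.shape[1]
                            and keep[x, y]
                            and labels[x, y] == 0
                            and data[x, y] == data[a, b]
                        ):
                            labels[x, y] = nxt
                            stack.append((x, y))
                nxt += 1
    return labels


class TestMajorityUpscale:
    def test_uniform_block_and_strict_majority(self):
        data = np.array([[5, 5, 2, 2], [5, 2, 2, 2]])
        out = upscale_majority(_lu(data), 2)
        assert out.data.tolist() == [[5, 2]]
        assert out.resolution == 10.0

    def test_tie_breaks_to_lowest_code(self):
        out = upscale_majority(_lu([[2, 2], [5, 5]]), 2)
        assert out.data[0, 0] == 2

    def test_nodata_ignored_in_blocks(self):
        out = upscale_majority(_lu([[0, 0], [0, 7]]), 2)
        assert out.data[0, 0] == 7

    def test_factor_one_is_identity(self):
        lu = _lu([[1, 2], [3, 4]])
        assert upscale_majority(lu, 1) is lu

    def test_bad_factor_raises(self):
        with pytest.raises(ValueError):
            upscale_majority(_lu([[1]]), 0)

    def test_non_divisible_dimensions_padded(self):
        out = upscale_majority(_lu([[4, 4, 4], [4, 4, 4], [4, 4, 4]]), 2)
        assert out.data[0, 0] == 4 and out.data.shape == (2, 2)


class TestMixedPixelMask:
    def test_uniform_raster_keeps_interior(self):
        keep = mask_mixed_pixels(_lu(np.full((5, 5), 3)))
        expected = np.zeros((5, 5), bool)
        expected[1:-1, 1:-1] = True
        assert np.array_equal(keep.data, expected)

    def test_single_pixel_island_removed(self):
        data = np.full((5, 5), 3)
        data[2, 2] = 7
        assert not mask_mixed_pixels(_lu(data)).data[2, 2]

    def test_border_strip_removed_between_blocks(self):
        data = np.hstack([np.full((10, 10), 1), np.full((10, 10), 2)])
        keep = mask_mixed_pixels(_lu(data))
        assert not keep.data[:, 9].any() and not keep.data[:, 10].any()
        assert keep.data[1:-1, 1:9].all() and keep.data[1:-1, 11:-1].all()

    @settings(max_examples=40, deadline=None)
    @given(
        hnp.arrays(
            np.int32,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=3, max_side=20),
            elements=hst.integers(0, 3),
        )
    )
    def test_matches_brute_force_oracle(self, data):
        keep = mask_mixed_pixels(_lu(data))
        assert np.array_equal(keep.data, brute_force_mask(data))

    def test_kept_pixels_have_uniform_neighborhood(self, midseason_scene):
        _, truth, _ = midseason_scene
        keep = mask_mixed_pixels(truth.landuse)
        ii, jj = np.nonzero(keep.data)
        data = truth.landuse.data
        for i, j in zip(ii[::997], jj[::997]):
            assert np.all(data[i - 1 : i + 2, j - 1 : j + 2] == data[i, j])


class TestSegmentation:
    def test_two_blocks_give_two_fields(self):
        data = np.hstack([np.full((10, 10), 1), np.full((10, 10), 2)])
        lu = _lu(data)
        fm = segment_fields(lu, mask_mixed_pixels(lu))
        assert fm.n_fields == 2
        assert sorted(fm.records["code"]) == [1, 2]

    def test_l_shaped_region_is_one_field(self):
        data = np.full((12, 12), 9)
        data[:8, :4] = 1
        data[6:8, :10] = 1
        lu = _lu(data)
        keep = Raster(data == 1, 5.0, nodata=False, semantic="mask")
        fm = segment_fields(lu, keep)
        assert (fm.records["code"] == 1).sum() == 1

    @settings(max_examples=30, deadline=None)
    @given(
        hnp.arrays(
            np.int32,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=3, max_side=30),
            elements=hst.integers(0, 2),
        )
    )
    def test_labels_match_flood_fill_oracle(self, data):
        lu = _lu(data)
        keep = mask_mixed_pixels(lu)
        fm = segment_fields(lu, keep)
        oracle = flood_fill_labels(data, keep.data)
        assert np.array_equal(fm.labels.data, oracle)

    def test_record_consistency(self, midseason_scene):
        _, truth, _ = midseason_scene
        keep = mask_mixed_pixels(truth.landuse)
        fm = segment_fields(truth.landuse, keep)
        labels = fm.labels.data
        for rec in fm.records.iloc[::37].itertuples():
            sel = labels == rec.id
            assert sel.sum() == rec.pixels
            assert rec.area_m2 == rec.pixels * truth.landuse.resolution ** 2
            assert np.all(truth.landuse.data[sel] == rec.code)


class TestSizeFilter:
    def _toy(self, areas_m2, res=5.0):
        import pandas as pd

        sizes = [int(a / res**2) for a in areas_m2]
        width = max(sizes)
        data = np.zeros((len(sizes), width), np.int32)
        for i, s in enumerate(sizes):
            data[i, :s] = i + 1
        labels = Raster(data, res, 0, "labels")
        records = pd.DataFrame(
            {
                "id": np.arange(1, len(sizes) + 1),
                "code": 1,
                "pixels": sizes,
                "area_m2": [s * res**2 for s in sizes],
                "row": 0.0,
                "col": 0.0,
            }
        )
        from laiscape.fields import FieldMap

        return FieldMap(labels=labels, records=records)

    def test_median_threshold_is_inclusive(self):
        fm, report = filter_fields_by_size(self._toy([1000, 2250, 9000]), "median")
        assert list(fm.records["area_m2"]) == [9000.0]
        assert report["n_removed"] == 2

    def test_zero_threshold_keeps_everything(self):
        fm, report = filter_fields_by_size(self._toy([1000, 2000]), 0.0)
        assert fm.n_fields == 2 and report["area_removed_pct"] == 0.0

    def test_equal_areas_with_median_removes_all(self):
        fm, _ = filter_fields_by_size(self._toy([2000, 2000, 2000]), "median")
        assert fm.n_fields == 0

    def test_area_percentages_conserve(self):
        fm0 = self._toy([500, 1500, 2500, 4000, 8000])
        fm, report = filter_fields_by_size(fm0, 2000.0)
        kept_pct = 100.0 * fm.total_area() / fm0.total_area()
        assert kept_pct + report["area_removed_pct"] == pytest.approx(100.0)

    def test_negative_threshold_raises(self):
        with pytest.raises(ValueError):
            filter_fields_by_size(self._toy([1000]), -5.0)


class TestPlausibilityFilter:
    CAL = CropCalendar({3: [(1.0, 120.0, 0.3)], 1: []})

    def test_winter_lai_on_maize_excluded(self):
        lai = Raster(np.array([[2.0]]), 5.0, semantic="lai")
        lu = _lu([[3]])
        keep = plausibility_filter(lai, lu, self.CAL, 53)  # late February
        assert not keep.data[0, 0]

    def test_zero_lai_always_kept(self):
        lai = Raster(np.array([[0.0]]), 5.0, semantic="lai")
        keep = plausibility_filter(lai, _lu([[3]]), self.CAL, 53)
        assert keep.data[0, 0]

    def test_uncovered_date_means_no_constraint(self):
        lai = Raster(np.array([[5.0]]), 5.0, semantic="lai")
        keep = plausibility_filter(lai, _lu([[3]]), self.CAL, 200)
        assert keep.data[0, 0]

    def test_code_missing_from_calendar_raises(self):
        lai = Raster(np.array([[1.0]]), 5.0, semantic="lai")
        with pytest.raises(KeyError):
            plausibility_filter(lai, _lu([[7]]), self.CAL, 53)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            CropCalendar({3: [(1.0, 100.0, 0.3), (50.0, 150.0, 1.0)]})
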