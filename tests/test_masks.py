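"""ROI metadata parsing, rectangle-mask construction, pair preparation."""
import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgaca.masks import (MetadataError, ROIRecord, build_roi_mask,
                         build_volume_masks, load_mask_image, parse_metadata,
                         prepare_pair, save_mask_image)

HEADER = "volume_filename,roi_x,roi_y,roi_z,roi_height,roi_width,roi_depth"


def record(**kw):
    base = dict(volume_filename="vol001.jpeg", roi_x=10, roi_y=20, roi_z=3,
                roi_height=4, roi_width=5, roi_depth=6)
    base.update(kw)
    return ROIRecord(**base)


class TestParseMetadata:
    def test_single_row_maps_fields(self):
        csv = io.StringIO(HEADER + "\nvol001.jpeg,10,20,3,4,5,6\n")
        (rec,) = parse_metadata(csv)
        assert rec == record()

    def test_header_only_gives_empty_list(self):
        assert parse_metadata(io.StringIO(HEADER + "\n")) == []

    def test_missing_column_names_it(self):
        csv = io.StringIO(HEADER.replace(",roi_depth", "") + "\nv,1,1,1,1,1\n")
        with pytest.raises(MetadataError, match="roi_depth"):
            parse_metadata(csv)

    def test_non_numeric_field_reports_row(self):
        csv = io.StringIO(HEADER + "\nv.jpeg,1,2,3,4,5,6\nw.jpeg,1,2,x,4,5,6\n")
        with pytest.raises(MetadataError, match="row 1"):
            parse_metadata(csv)

    def test_negative_extent_rejected(self):
        csv = io.StringIO(HEADER + "\nv.jpeg,1,2,3,-4,5,6\n")
        with pytest.raises(MetadataError, match="roi_height"):
            parse_metadata(csv)

    def test_row_order_preserved(self):
        csv = io.StringIO(HEADER + "\nb.jpeg,1,1,0,1,1,1\na.jpeg,2,2,0,2,2,1\n")
        recs = parse_metadata(csv)
        assert [r.volume_filename for r in recs] == ["b.jpeg", "a.jpeg"]


class TestBuildRoiMask:
    def test_filled_rectangle_half_open(self):
        mask = build_roi_mask(record(roi_x=10, roi_y=20, roi_width=5,
                                     roi_height=4), (128, 128))
        assert mask.sum() == 20
        assert mask[20:24, 10:15].all()
        assert mask[19, 10] == 0 and mask[24, 10] == 0
        assert mask[20, 9] == 0 and mask[20, 15] == 0

    def test_degenerate_rectangle_is_empty(self):
        assert build_roi_mask(record(roi_width=0), (64, 64)).sum() == 0
        assert build_roi_mask(record(roi_height=0), (64, 64)).sum() == 0

    def test_full_frame_roi_is_all_ones(self):
        mask = build_roi_mask(record(roi_x=0, roi_y=0, roi_width=32,
                                     roi_height=48), (48, 32))
        assert mask.all()

    def test_out_of_bounds_errors_not_clips(self):
        with pytest.raises(MetadataError, match="exceeds"):
            build_roi_mask(record(roi_x=125, roi_width=5), (128, 128))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(x=st.integers(0, 40), y=st.integers(0, 40),
           w=st.integers(0, 24), h=st.integers(0, 24))
    def test_foreground_count_identity(self, x, y, w, h):
        mask = build_roi_mask(record(roi_x=x, roi_y=y, roi_width=w,
                                     roi_height=h), (64, 64))
        assert int(mask.sum()) == w * h


class TestVolumeMasks:
    def test_z_extent_selects_slices(self):
        masks = build_volume_masks(record(roi_z=2, roi_depth=3), 8, (64, 64))
        nonempty = [i for i, m in enumerate(masks) if m.any()]
        assert nonempty == [2, 3, 4]

    def test_control_depth_zero_all_empty(self):
        masks = build_volume_masks(record(roi_depth=0), 4, (64, 64))
        assert len(masks) == 4 and not any(m.any() for m in masks)

    def test_volume_foreground_total(self):
        rec = record(roi_z=1, roi_depth=4, roi_width=7, roi_height=3)
        masks = build_volume_masks(rec, 6, (64, 64))
        assert sum(int(m.sum()) for m in masks) == 4 * 7 * 3

    def test_z_overflow_errors(self):
        with pytest.raises(MetadataError, match="z-extent"):
            build_volume_masks(record(roi_z=3, roi_depth=3), 5, (64, 64))


class TestPreparePair:
    def test_resize_and_normalize(self, rng):
        image = rng.integers(0, 256, (320, 320, 3), dtype=np.uint8)
        mask = np.zeros((320, 320), dtype=np.uint8)
        mask[40:200, 80:240] = 1
        img, msk = prepare_pair(image, mask)
        assert img.shape == (128, 128, 3) and msk.shape == (128, 128)
        assert img.min() >= 0.0 and img.max() <= 1.0
        assert set(np.unique(msk)) <= {0, 1}

    def test_extreme_values_map_to_unit_range(self):
        image = np.zeros((64, 64, 3), dtype=np.uint8)
        image[:32] = 255
        img, _ = prepare_pair(image, np.zeros((64, 64)), (64, 64))
        assert img.max() == 1.0 and img.min() == 0.0

    def test_constant_mask_survives_resize(self):
        ones = np.ones((320, 320), dtype=np.uint8)
        _, msk = prepare_pair(np.zeros((320, 320, 3), dtype=np.uint8), ones)
        assert msk.all() and msk.shape == (128, 128)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            prepare_pair(np.zeros((8, 8, 3), dtype=np.uint8),
                         np.zeros((8, 8)), (0, 8))


class TestMaskIO:
    def test_png_round_trip_is_lossless(self, tmp_path, rng):
        mask = (rng.random((40, 40)) > 0.5).astype(np.uint8)
        path = tmp_path / "m.png"
        save_mask_image(mask, path)
        np.testing.assert_array_equal(load_mask_image(path), mask)

    @pytest.mark.parametrize("size", [(2, 2), (3, 5), (8, 8), (16, 4)])
    def test_jpeg_round_trip_preserves_rectangle_count(self, tmp_path, size):
        h, w = size
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[5:5 + h, 7:7 + w] = 1
        path = tmp_path / "m.jpeg"
        save_mask_image(mask, path, jpeg_quality=95)
        assert int(load_mask_image(path).sum()) == h * w

    def test_binary_values_map_exactly(self, tmp_path):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[::2] = 1
        path = tmp_path / "m.png"
        save_mask_image(mask, path)
        loaded = load_mask_image(path)
        assert set(np.unique(loaded)) == {0, 1}

    def test_unreadable_file_raises_with_path(self, tmp_path):
        bad = tmp_path / "nope.png"
        with pytest.raises(OSError, match="nope.png"):
            load_mask_image(bad)

    def test_build_write_reload_round_trip(self, tmp_path):
        for w, h in [(1, 1), (2, 3), (10, 10), (30, 7)]:
            mask = build_roi_mask(record(roi_x=3, roi_y=4, roi_width=w,
                                         roi_height=h), (48, 48))
            path = tmp_path / f"r{w}x{h}.png"
            save_mask_image(mask, path)
            np.testing.assert_array_equal(load_mask_image(path), mask)
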