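import numpy as np
import pytest
import tifffile

from mitoshape.ijroi import OVAL, POLYGON, RECT, read_imagej_roi, roi_to_mask, write_imagej_roi
from mitoshape.imaging_io import (
    CalibratedImage,
    CalibrationError,
    CellRegion,
    ImageStack,
    apply_cell_region,
    load_cell_regions,
    load_stack,
    regions_from_label_mask,
    z_project,
)


def _write_stack(path, data, pixel_size=None):
    kwargs = {}
    if pixel_size is not None:
        kwargs = dict(resolution=(1 / pixel_size, 1 / pixel_size),
                      imagej=True, metadata={"unit": "um"})
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, **kwargs)


class TestCalibratedImage:
    @pytest.mark.parametrize("bad", [0.0, -0.1, np.nan, np.inf])
    def test_rejects_bad_pixel_size(self, bad):
        with pytest.raises(ValueError):
            CalibratedImage(np.ones((4, 4)), bad)

    def test_rejects_negative_and_nonfinite_intensities(self):
        with pytest.raises(ValueError):
            CalibratedImage(np.full((3, 3), -1.0), 0.1)
        with pytest.raises(ValueError):
            CalibratedImage(np.full((3, 3), np.nan), 0.1)

    def test_rejects_wrong_dimensionality(self):
        with pytest.raises(ValueError):
            CalibratedImage(np.ones((2, 2, 2)), 0.1)


class TestLoadStack:
    def test_override_reads_back_frames_and_pixel_size(self, tmp_path, rng):
        data = rng.integers(0, 1000, size=(5, 64, 64)).astype(np.uint16)
        path = tmp_path / "stack.tif"
        _write_stack(path, data)
        stack = load_stack(path, pixel_size_override=0.1)
        assert len(stack) == 5
        assert stack.pixel_size == 0.1
        np.testing.assert_array_equal(stack.frames[3].pixels, data[3])

    def test_pixel_size_from_imagej_metadata(self, tmp_path):
        path = tmp_path / "cal.tif"
        _write_stack(path, np.ones((8, 8)), pixel_size=0.25)
        stack = load_stack(path)
        assert stack.pixel_size == pytest.approx(0.25, rel=1e-6)

    def test_override_wins_over_metadata(self, tmp_path):
        path = tmp_path / "cal.tif"
        _write_stack(path, np.ones((8, 8)), pixel_size=0.25)
        assert load_stack(path, pixel_size_override=0.5).pixel_size == 0.5

    def test_missing_calibration_raises(self, tmp_path):
        path = tmp_path / "nocal.tif"
        _write_stack(path, np.ones((8, 8), dtype=np.uint16))
        with pytest.raises(CalibrationError):
            load_stack(path)

    def test_negative_override_rejected(self, tmp_path):
        path = tmp_path / "x.tif"
        _write_stack(path, np.ones((8, 8), dtype=np.uint16))
        with pytest.raises(ValueError):
            load_stack(path, pixel_size_override=-0.1)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_stack(tmp_path / "absent.tif", pixel_size_override=0.1)


def _stack_of(arrays, ps=0.1):
    return ImageStack(tuple(CalibratedImage(a, ps) for a in arrays))


class TestZProject:
    def test_max_projection_takes_per_pixel_maximum(self):
        a = np.zeros((4, 4)); a[0, 0] = 3
        b = np.zeros((4, 4)); b[0, 0] = 7
        out = z_project(_stack_of([a, b]))
        assert out.pixels[0, 0] == 7
        assert out.pixel_size == 0.1

    def test_single_frame_identity(self, rng):
        a = rng.random((6, 6))
        np.testing.assert_array_equal(z_project(_stack_of([a])).pixels, a)

    def test_all_zero_frames(self):
        out = z_project(_stack_of([np.zeros((3, 3))] * 4))
        assert not out.pixels.any()

    def test_commutes_with_frame_permutation(self, rng):
        frames = [rng.random((5, 5)) for _ in range(4)]
        fwd = z_project(_stack_of(frames)).pixels
        rev = z_project(_stack_of(frames[::-1])).pixels
        np.testing.assert_array_equal(fwd, rev)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            ImageStack(())


class TestApplyCellRegion:
    def test_full_region_is_identity(self, rng):
        img = CalibratedImage(rng.random((5, 5)), 0.1)
        region = CellRegion(np.ones((5, 5), bool), "c1")
        np.testing.assert_array_equal(apply_cell_region(img, region).pixels, img.pixels)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            CellRegion(np.zeros((5, 5), bool), "c1")

    def test_shape_mismatch(self, rng):
        img = CalibratedImage(rng.random((5, 5)), 0.1)
        region = CellRegion(np.ones((6, 6), bool), "c1")
        with pytest.raises(ValueError):
            apply_cell_region(img, region)

    def test_blob_clipped_at_boundary_and_idempotent(self):
        img = np.zeros((10, 10)); img[4:6, 3:8] = 100.0
        mask = np.zeros((10, 10), bool); mask[:, :5] = True
        ci = CalibratedImage(img, 0.1)
        out = apply_cell_region(ci, CellRegion(mask, "c"))
        assert out.pixels[4, 3] == 100 and out.pixels[4, 6] == 0
        twice = apply_cell_region(out, CellRegion(mask, "c"))
        np.testing.assert_array_equal(twice.pixels, out.pixels)


class TestCellRegionLoading:
    def test_label_mask_split(self):
        labels = np.zeros((8, 8), int)
        labels[1:3, 1:3] = 1
        labels[5:7, 5:7] = 3
        regions = regions_from_label_mask(labels)
        assert [r.cell_id for r in regions] == ["cell1", "cell3"]
        assert regions[0].mask.sum() == 4

    def test_label_mask_tiff(self, tmp_path):
        labels = np.zeros((8, 8), np.uint8); labels[2:5, 2:5] = 2
        path = tmp_path / "cells.tif"
        tifffile.imwrite(path, labels)
        regions = load_cell_regions(path, (8, 8))
        assert len(regions) == 1 and regions[0].mask.sum() == 9

    @pytest.mark.parametrize("roi_type,kwargs,expected_area", [
        (RECT, dict(top=2, left=3, bottom=6, right=8), 20),
        (OVAL, dict(top=2, left=2, bottom=12, right=12), None),
    ])
    def test_rect_and_oval_roi_roundtrip(self, tmp_path, roi_type, kwargs, expected_area):
        raw = write_imagej_roi(roi_type, **kwargs)
        path = tmp_path / "cell.roi"
        path.write_bytes(raw)
        (region,) = load_cell_regions(path, (16, 16))
        if expected_area is not None:
            assert region.mask.sum() == expected_area
        else:  # oval inscribed in a 10x10 box: close to pi * 5^2
            assert region.mask.sum() == pytest.approx(np.pi * 25, rel=0.1)

    def test_polygon_roi_roundtrip(self, tmp_path):
        xs = [2, 10, 10, 2]
        ys = [3, 3, 8, 8]
        raw = write_imagej_roi(POLYGON, xs, ys)
        roi = read_imagej_roi(raw)
        mask = roi_to_mask(roi, (16, 16))
        # filled rectangle spanning the polygon
        assert mask[5, 5] and not mask[0, 0]
        assert mask.sum() >= 8 * 5

    def test_roi_zip(self, tmp_path):
        import zipfile
        path = tmp_path / "cells.zip"
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("a.roi", write_imagej_roi(RECT, top=0, left=0, bottom=4, right=4))
            zf.writestr("b.roi", write_imagej_roi(RECT, top=6, left=6, bottom=9, right=9))
        regions = load_cell_regions(path, (12, 12))
        assert [r.cell_id for r in regions] == ["a", "b"]

    def test_garbage_roi_rejected(self):
        with pytest.raises(ValueError):
            read_imagej_roi(b"not a roi file at all")
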