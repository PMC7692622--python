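"""Unit tests for image ingestion, ROI extraction and normalization."""

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pytest

from pdacolor.images import (
    ImageRecord,
    ROISpec,
    default_roi_layout,
    extract_roi_means,
    load_image,
    normalize_to_control,
    samples_from_images,
    to_grayscale,
)


def record_from_array(pixels):
    return ImageRecord(path="<mem>", pixels=np.asarray(pixels, float), bit_depth=8)


class TestLoadImage:
    def test_8bit_white_png_scales_to_one(self, tmp_path):
        path = tmp_path / "white.png"
        iio.imwrite(path, np.full((8, 8, 3), 255, dtype=np.uint8))
        rec = load_image(path)
        assert rec.bit_depth == 8
        assert np.all(rec.pixels == 1.0)

    def test_16bit_black_tiff_scales_to_zero(self, tmp_path):
        path = tmp_path / "black.tiff"
        iio.imwrite(path, np.zeros((8, 8), dtype=np.uint16))
        rec = load_image(path)
        assert rec.bit_depth == 16
        assert rec.n_channels == 1
        assert np.all(rec.pixels == 0.0)

    def test_write_then_read_preserves_means(self, tmp_path, rng):
        raw = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        path = tmp_path / "well.png"
        iio.imwrite(path, raw)
        rec = load_image(path)
        np.testing.assert_allclose(
            rec.pixels.mean(axis=(0, 1)), raw.mean(axis=(0, 1)) / 255.0, atol=1e-6
        )

    def test_manifest_metadata_attached(self, tmp_path):
        path = tmp_path / "w.png"
        iio.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8))
        rec = load_image(path, {"trial": 1, "condition": "25 uM",
                                "concentration_uM": 25.0})
        assert rec.trial == 1 and rec.concentration_uM == 25.0

    def test_unknown_concentration_is_none(self, tmp_path):
        path = tmp_path / "w.png"
        iio.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8))
        rec = load_image(path, {"trial": 0, "condition": "x",
                                "concentration_uM": float("nan")})
        assert rec.concentration_uM is None


class TestExtractROIMeans:
    def test_uniform_image_means_equal_value(self):
        rec = record_from_array(np.full((10, 10, 3), 0.4))
        df = extract_roi_means(rec, [ROISpec(0, 0, 4, 4), ROISpec(5, 5, 5, 5)])
        np.testing.assert_allclose(df[["r", "g", "b"]].to_numpy(), 0.4)

    def test_half_split_symmetry(self):
        pixels = np.empty((10, 10, 3))
        pixels[:, :5] = 0.2
        pixels[:, 5:] = 0.8
        rec = record_from_array(pixels)
        df = extract_roi_means(rec, [ROISpec(0, 0, 10, 10)])
        np.testing.assert_allclose(df.loc[0, ["r", "g", "b"]].astype(float), 0.5)

    def test_matches_brute_force_pixel_loop(self, rng):
        pixels = rng.uniform(size=(20, 24, 3))
        rec = record_from_array(pixels)
        rois = [ROISpec(1, 2, 5, 7), ROISpec(10, 0, 6, 6), ROISpec(3, 15, 8, 9)]
        df = extract_roi_means(rec, rois)
        for k, roi in enumerate(rois):
            acc = np.zeros(3)
            count = 0
            for i in range(roi.row, roi.row + roi.height):
                for j in range(roi.col, roi.col + roi.width):
                    acc += pixels[i, j]
                    count += 1
            np.testing.assert_allclose(
                df.loc[k, ["r", "g", "b"]].astype(float), acc / count, rtol=1e-12
            )

    def test_well_row_is_mean_of_roi_means(self, rng):
        rec = record_from_array(rng.uniform(size=(12, 12, 3)))
        rois = [ROISpec(0, 0, 4, 4), ROISpec(4, 4, 4, 4), ROISpec(8, 8, 4, 4)]
        df = extract_roi_means(rec, rois)
        well = df[df.roi == "well"][["r", "g", "b"]].to_numpy()[0]
        np.testing.assert_allclose(
            well, df[df.roi != "well"][["r", "g", "b"]].mean().to_numpy()
        )

    def test_order_invariance(self, rng):
        rec = record_from_array(rng.uniform(size=(12, 12, 3)))
        rois = [ROISpec(0, 0, 4, 4), ROISpec(4, 4, 4, 4)]
        a = extract_roi_means(rec, rois)
        b = extract_roi_means(rec, rois[::-1])
        np.testing.assert_allclose(
            np.sort(a[["r"]].to_numpy(), axis=0), np.sort(b[["r"]].to_numpy(), axis=0)
        )

    def test_split_roi_recombines_area_weighted(self, rng):
        rec = record_from_array(rng.uniform(size=(16, 16, 3)))
        whole = extract_roi_means(rec, [ROISpec(2, 2, 10, 8)])
        top = extract_roi_means(rec, [ROISpec(2, 2, 4, 8)])
        bottom = extract_roi_means(rec, [ROISpec(6, 2, 6, 8)])
        recombined = (4 * top.loc[0, ["r", "g", "b"]].astype(float)
                      + 6 * bottom.loc[0, ["r", "g", "b"]].astype(float)) / 10
        np.testing.assert_allclose(
            whole.loc[0, ["r", "g", "b"]].astype(float), recombined, rtol=1e-12
        )

    def test_out_of_bounds_rejected(self):
        rec = record_from_array(np.zeros((8, 8, 3)))
        with pytest.raises(ValueError, match="bounds"):
            extract_roi_means(rec, [ROISpec(4, 4, 8, 8)])


class TestToGrayscale:
    def test_white_is_one_under_both_methods(self):
        assert to_grayscale((1, 1, 1), "luma601") == pytest.approx(1.0)
        assert to_grayscale((1, 1, 1), "mean") == pytest.approx(1.0)

    def test_pure_red_luma_weight(self):
        assert to_grayscale((1, 0, 0), "luma601") == pytest.approx(0.299)

    def test_mean_method(self):
        assert to_grayscale((0.2, 0.4, 0.6), "mean") == pytest.approx(0.4)

    def test_gray_input_invariant_to_method(self, rng):
        v = float(rng.uniform(0.1, 0.9))
        for method in ("luma601", "mean"):
            assert to_grayscale((v, v, v), method) == pytest.approx(v)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown grayscale method"):
            to_grayscale((1, 1, 1), "lightness")


class TestNormalizeToControl:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["trial", "concentration_uM",
                                           "r", "g", "b", "gray"])

    def test_elementwise_division_by_control(self):
        df = self.table([
            [0, 0.0, 0.5, 0.5, 0.5, 0.5],
            [0, 25.0, 0.25, 0.4, 0.1, 0.3],
        ])
        out = normalize_to_control(df)
        np.testing.assert_allclose(
            out.loc[1, ["r", "g", "b"]].astype(float), [0.5, 0.8, 0.2]
        )

    def test_control_row_becomes_one(self):
        df = self.table([[0, 0.0, 0.5, 0.4, 0.3, 0.4],
                         [0, 25.0, 0.5, 0.4, 0.3, 0.4]])
        out = normalize_to_control(df)
        np.testing.assert_allclose(out.loc[1, ["r", "g", "b", "gray"]].astype(float), 1.0)

    def test_idempotent(self, rng):
        rows = []
        for trial in range(3):
            for conc in (0.0, 25.0, 50.0):
                rows.append([trial, conc, *rng.uniform(0.2, 0.9, size=4)])
        df = self.table(rows)
        once = normalize_to_control(df)
        twice = normalize_to_control(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_per_trial_reference(self):
        df = self.table([
            [0, 0.0, 0.5, 0.5, 0.5, 0.5], [0, 25.0, 0.25, 0.25, 0.25, 0.25],
            [1, 0.0, 0.8, 0.8, 0.8, 0.8], [1, 25.0, 0.4, 0.4, 0.4, 0.4],
        ])
        out = normalize_to_control(df)
        # both trials' treated rows normalize to 0.5 despite different raw scales
        np.testing.assert_allclose(out.loc[[1, 3], "r"].astype(float), 0.5)

    def test_missing_control_rejected(self):
        df = self.table([[0, 25.0, 0.5, 0.5, 0.5, 0.5]])
        with pytest.raises(ValueError, match="no control"):
            normalize_to_control(df)

    def test_zero_control_rejected(self):
        df = self.table([[0, 0.0, 0.0, 0.5, 0.5, 0.5],
                         [0, 25.0, 0.2, 0.2, 0.2, 0.2]])
        with pytest.raises(ValueError, match="non-positive"):
            normalize_to_control(df)


class TestDefaultROILayout:
    def test_three_squares_within_bounds_nonoverlapping(self):
        shape = (96, 96)
        rois = default_roi_layout(shape, n_rois=3)
        assert len(rois) == 3
        covered = np.zeros(shape, dtype=int)
        for roi in rois:
            roi.check_within(shape)
            covered[roi.slices] += 1
            assert roi.height * roi.width >= 0.10 * shape[0] * shape[1]
        assert covered.max() == 1  # non-overlapping


class TestSamplesFromImages:
    def test_extracts_tidy_table_with_gray(self, tmp_path, rng):
        paths, rows = [], []
        for trial in range(2):
            for conc in (0.0, 50.0):
                img = (rng.uniform(0.3, 0.9, size=(32, 32, 3)) * 255).astype(np.uint8)
                name = f"t{trial}_c{conc:g}.png"
                iio.imwrite(tmp_path / name, img)
                rows.append({"image_path": name, "trial": trial,
                             "condition": f"{conc:g} uM", "concentration_uM": conc})
        manifest = pd.DataFrame(rows)
        samples = samples_from_images(manifest, root=tmp_path)
        # 3 ROIs + 1 well row per image
        assert len(samples) == 4 * 4
        assert samples.attrs["grayscale_method"] == "luma601"
        expected = to_grayscale(samples[["r", "g", "b"]].to_numpy())
        np.testing.assert_allclose(samples["gray"].to_numpy(), expected)
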