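"""Image and workbook IO: round trips, layout conventions, error reporting."""

import numpy as np
import pandas as pd
import pytest

from gelflq.gel_io import (
    read_gel_image,
    read_profile_workbook,
    read_score_table,
    write_gel_image,
    write_profile_workbook,
    write_score_table,
)
from gelflq.model import GelImage, PeakShift, ScoreRecord
from gelflq.synthetic import GelGeometry, LaneSpec, calibration_from_law, synth_gel_image


class TestGelImages:
    def test_identity_read(self, tmp_path):
        pixels = np.array([[0, 255], [10, 20]], dtype=np.uint8)
        path = tmp_path / "gel.png"
        write_gel_image(GelImage(pixels, 8), path)
        img = read_gel_image(path)
        assert img.bit_depth == 8
        assert np.array_equal(img.pixels, pixels)

    def test_invert_maps_to_max_minus_v(self, tmp_path):
        pixels = np.array([[0, 255], [10, 20]], dtype=np.uint8)
        path = tmp_path / "gel.png"
        write_gel_image(GelImage(pixels, 8), path)
        img = read_gel_image(path, invert=True)
        assert img.pixels.tolist() == [[255, 0], [245, 235]]

    def test_16bit_synthetic_round_trip(self, tmp_path, law_cal):
        spec = LaneSpec(band_sizes=(2000.0,), band_amplitudes=(1500.0,), seed=6)
        image = synth_gel_image([spec], GelGeometry(length=64), law_cal, seed=6)
        path = tmp_path / "gel.tif"
        write_gel_image(image, path)
        back = read_gel_image(path)
        assert back.bit_depth == 16
        assert np.array_equal(back.pixels, image.pixels)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_gel_image(tmp_path / "absent.tif")

    def test_color_image_rejected_with_property_named(self, tmp_path):
        import imageio.v3 as iio

        rgb = np.zeros((4, 4, 3), dtype=np.uint8)
        rgb[..., 0] = 200  # genuinely colored
        path = tmp_path / "color.png"
        iio.imwrite(path, rgb)
        with pytest.raises(ValueError, match="multi-channel"):
            read_gel_image(path)

    def test_grayscale_saved_as_rgb_accepted(self, tmp_path):
        import imageio.v3 as iio

        gray = np.random.default_rng(0).integers(0, 255, size=(4, 4), dtype=np.uint8)
        path = tmp_path / "gray3.png"
        iio.imwrite(path, np.stack([gray] * 3, axis=-1))
        img = read_gel_image(path)
        assert np.array_equal(img.pixels, gray)


def workbook_frame(n=60, n_background=1, seed=0):
    rng = np.random.default_rng(seed)
    cols = {"distance": np.arange(n, dtype=float)}
    if n_background:
        cols["background"] = rng.uniform(0, 50, n)
    cols["ladder"] = rng.uniform(0, 500, n)
    cols["control"] = rng.uniform(0, 500, n)
    for label in ("d2", "d4", "d7", "d10"):
        cols[label] = rng.uniform(0, 500, n)
    return pd.DataFrame(cols)


class TestProfileWorkbooks:
    def test_protocol_layout_parsed(self, tmp_path):
        frame = workbook_frame()
        path = tmp_path / "gel.xlsx"
        frame.to_excel(path, index=False)
        run = read_profile_workbook(path)
        assert len(run.background_lanes) == 1
        assert run.ladder is not None and run.control is not None
        assert list(run.samples) == ["d2", "d4", "d7", "d10"]
        assert run.lane_length == 60

    def test_headerless_csv_uses_positional_order(self, tmp_path):
        frame = workbook_frame()
        path = tmp_path / "gel.csv"
        frame.to_csv(path, index=False, header=False)
        run = read_profile_workbook(path)
        assert len(run.background_lanes) == 1
        assert run.control is not None
        assert len(run.samples) == 4

    def test_flip_reverses_profiles(self, tmp_path):
        path = tmp_path / "toy.csv"
        path.write_text("distance,ladder,control\n0,1,10\n1,2,20\n2,3,30\n")
        run = read_profile_workbook(path, flip=True)
        assert run.control.values.tolist() == [30.0, 20.0, 10.0]
        assert run.ladder.values.tolist() == [3.0, 2.0, 1.0]

    def test_column_order_override(self, tmp_path):
        frame = workbook_frame(n_background=0)
        path = tmp_path / "gel.csv"
        frame.to_csv(path, index=False, header=False)
        order = ["distance", "ladder", "control", "a", "b", "c", "d"]
        run = read_profile_workbook(path, column_order=order)
        assert list(run.samples) == ["a", "b", "c", "d"]
        assert run.background_lanes == []

    def test_trailing_empty_rows_and_columns_ignored(self, tmp_path):
        frame = workbook_frame()
        path = tmp_path / "padded.csv"
        body = frame.to_csv(index=False).rstrip("\n")
        padded = "\n".join(line + ",," for line in body.splitlines())
        padded += "\n" + ",," * 3 + "\n\n"
        path.write_text(padded)
        run = read_profile_workbook(path)
        assert run.lane_length == 60
        assert len(run.samples) == 4

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("distance,ladder,control\n0,1,10\n1,oops,20\n2,3,30\n")
        with pytest.raises(ValueError, match=r"row 3, column 2"):
            read_profile_workbook(path)

    def test_non_uniform_distance_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("distance,ladder,control\n0,1,10\n1,2,20\n5,3,30\n")
        with pytest.raises(ValueError, match="uniformly spaced"):
            read_profile_workbook(path)

    def test_too_few_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("distance,ladder\n0,1\n1,2\n")
        with pytest.raises(ValueError, match="profile columns"):
            read_profile_workbook(path)

    def test_workbook_round_trip(self, tmp_path, ivt_experiment):
        _, runs, _ = ivt_experiment
        run = runs[0]
        path = tmp_path / "roundtrip.csv"
        write_profile_workbook(run, path)
        back = read_profile_workbook(path)
        assert list(back.samples) == list(run.samples)
        for label in run.samples:
            assert np.allclose(back.samples[label].values, run.samples[label].values)
        assert np.allclose(back.control.values, run.control.values)
        assert np.allclose(back.ladder.values, run.ladder.values)


def fake_record(i, two_peak=False):
    peaks = (100.0 + i, 80.0 + i) if two_peak else (100.0 + i / 3.0,)
    degs = tuple(x / 7.0 for x in peaks)
    return ScoreRecord(
        condition=f"t{i}",
        peak_aucs=peaks,
        degradation_aucs=degs,
        peak_aucs_norm=tuple(x / 100.0 for x in peaks),
        degradation_aucs_norm=tuple(x / 10.0 for x in degs),
        preservation_raw=1.0 / (1 + i),
        preservation_norm=1.0 / (1 + i / 2.0),
        combined_norm=np.pi / (3 + i),
        high_mw_auc=0.123 * i,
        mw_max=None if two_peak else 2118.9 - i,
        peak_shift=None if two_peak else PeakShift(2000.0 - i, 2118.9),
        peak_index=None if two_peak else 250 - i,
    )


class TestScoreTables:
    def test_single_record_two_lines(self, tmp_path):
        path = tmp_path / "scores.csv"
        write_score_table([fake_record(0)], path)
        assert len(path.read_text().strip().splitlines()) == 2

    def test_round_trip_full_precision(self, tmp_path):
        path = tmp_path / "scores.csv"
        records = [fake_record(i) for i in range(5)]
        write_score_table(records, path)
        frame = read_score_table(path)
        for i, rec in enumerate(records):
            assert frame.loc[i, "peak_auc_1"] == rec.peak_aucs[0]  # bitwise
            assert frame.loc[i, "preservation_norm"] == rec.preservation_norm
            assert frame.loc[i, "combined_norm"] == rec.combined_norm
            assert frame.loc[i, "peak_shift_nt"] == rec.peak_shift.shift

    def test_two_peak_records_fill_both_slots(self, tmp_path):
        path = tmp_path / "scores.csv"
        write_score_table([fake_record(1, two_peak=True)], path)
        frame = read_score_table(path)
        assert frame.loc[0, "n_peaks"] == 2
        assert not np.isnan(frame.loc[0, "peak_auc_2"])
        assert np.isnan(frame.loc[0, "mw_max_nt"])

    def test_empty_records_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no score records"):
            write_score_table([], tmp_path / "scores.csv")
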