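import numpy as np
import pytest

from hsidefect.hypercube import (
    BoundingBox,
    CalibrationPair,
    CalibrationError,
    DimensionError,
    EnviFormatError,
    Hypercube,
    WavelengthGrid,
    WavelengthRangeError,
    correct_reflectance,
    extract_roi_spectrum,
    load_annotations,
    load_voc_annotations,
    nearest_band_index,
    read_envi,
    save_annotations,
    synthesize_pseudocolor,
    write_envi,
)


def small_cube(rng=None, shape=(2, 2, 3), calibrated=False):
    rng = rng or np.random.default_rng(0)
    grid = WavelengthGrid(np.array([400.0, 500.0, 600.0][: shape[2]]))
    values = rng.random(shape)
    return Hypercube(values, grid, calibrated=calibrated)


class TestWavelengthGrid:
    def test_default_grid(self):
        grid = WavelengthGrid.default()
        assert len(grid) == 360
        assert grid.wavelengths_nm[0] == pytest.approx(382.3)
        assert np.allclose(np.diff(grid.wavelengths_nm), 1.8)

    def test_not_increasing_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            WavelengthGrid(np.array([500.0, 400.0]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            WavelengthGrid(np.array([]))


class TestBoundingBox:
    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(5, 5, 5, 9)

    def test_area(self):
        assert BoundingBox(0, 0, 10, 10).area == 100


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    def test_round_trip_identity(self, tmp_path, interleave):
        cube = small_cube()
        write_envi(cube, tmp_path / "cube.hdr", interleave=interleave)
        back = read_envi(tmp_path / "cube.hdr")
        np.testing.assert_array_equal(back.values, cube.values)
        np.testing.assert_array_equal(
            back.grid.wavelengths_nm, cube.grid.wavelengths_nm
        )

    def test_bil_360_bands(self, tmp_path):
        grid = WavelengthGrid.default()
        cube = Hypercube(np.zeros((2, 3, 360)), grid)
        write_envi(cube, tmp_path / "c.hdr", interleave="bil")
        assert len(read_envi(tmp_path / "c.hdr").grid) == 360

    def test_single_band(self, tmp_path):
        cube = Hypercube(np.ones((3, 4, 1)), WavelengthGrid(np.array([500.0])))
        write_envi(cube, tmp_path / "c.hdr")
        np.testing.assert_array_equal(read_envi(tmp_path / "c.hdr").values, cube.values)

    def test_missing_wavelength_block(self, tmp_path):
        write_envi(small_cube(), tmp_path / "c.hdr")
        text = (tmp_path / "c.hdr").read_text()
        stripped = "\n".join(
            line for line in text.splitlines() if not line.startswith("wavelength =")
        )
        (tmp_path / "c.hdr").write_text(stripped)
        with pytest.raises(EnviFormatError, match="wavelength"):
            read_envi(tmp_path / "c.hdr")

    def test_wavelength_count_mismatch(self, tmp_path):
        write_envi(small_cube(), tmp_path / "c.hdr")
        text = (tmp_path / "c.hdr").read_text().replace(
            "wavelength = { 400, 500, 600 }", "wavelength = { 400, 500 }"
        )
        (tmp_path / "c.hdr").write_text(text)
        with pytest.raises(DimensionError):
            read_envi(tmp_path / "c.hdr")

    def test_grid_mismatch_rejected_before_write(self):
        with pytest.raises(DimensionError):
            Hypercube(np.zeros((2, 2, 4)), WavelengthGrid(np.array([400.0, 500.0])))

    def test_calibrated_flag_survives(self, tmp_path):
        cube = small_cube(calibrated=True)
        write_envi(cube, tmp_path / "c.hdr")
        assert read_envi(tmp_path / "c.hdr").calibrated


class TestCorrectReflectance:
    def test_white_identity(self):
        raw = small_cube()
        cal = CalibrationPair(np.zeros_like(raw.values), raw.values.copy())
        raw2 = Hypercube(raw.values.copy(), raw.grid)
        out = correct_reflectance(raw2, cal)
        np.testing.assert_allclose(out.values, 1.0)
        assert out.calibrated

    def test_black_identity(self):
        v = np.full((2, 2, 3), 7.0)
        grid = WavelengthGrid(np.array([400.0, 500.0, 600.0]))
        out = correct_reflectance(
            Hypercube(v, grid), CalibrationPair(v.copy(), v + 5.0)
        )
        np.testing.assert_allclose(out.values, 0.0)

    def test_midpoint_value(self):
        grid = WavelengthGrid(np.array([500.0]))
        raw = Hypercube(np.full((1, 1, 1), 50.0), grid)
        cal = CalibrationPair(np.full((1, 1, 1), 10.0), np.full((1, 1, 1), 90.0))
        assert correct_reflectance(raw, cal).values[0, 0, 0] == pytest.approx(0.5)

    def test_affine_invariance(self, rng):
        raw_values = rng.random((3, 3, 4)) * 100
        black = rng.random((3, 3, 4)) * 10
        white = black + 50 + rng.random((3, 3, 4)) * 10
        grid = WavelengthGrid(np.array([400.0, 500.0, 600.0, 700.0]))
        base = correct_reflectance(
            Hypercube(raw_values, grid), CalibrationPair(black, white)
        )
        for scale in (0.5, 3.0, 117.0):
            scaled = correct_reflectance(
                Hypercube(raw_values * scale, grid),
                CalibrationPair(black * scale, white * scale),
            )
            np.testing.assert_allclose(scaled.values, base.values, atol=1e-12)

    def test_nonpositive_denominator_reports_count(self):
        grid = WavelengthGrid(np.array([500.0]))
        raw = Hypercube(np.ones((2, 2, 1)), grid)
        black = np.ones((2, 2, 1))
        white = np.ones((2, 2, 1))
        white[0, 0, 0] = 2.0  # 3 bad elements remain
        with pytest.raises(CalibrationError, match="3 element"):
            correct_reflectance(raw, CalibrationPair(black, white))

    def test_already_calibrated_rejected(self):
        cube = small_cube(calibrated=True)
        with pytest.raises(ValueError, match="calibrated"):
            correct_reflectance(
                cube, CalibrationPair(np.zeros_like(cube.values), np.ones_like(cube.values))
            )

    def test_clipping(self):
        grid = WavelengthGrid(np.array([500.0]))
        raw = Hypercube(np.full((1, 1, 1), 200.0), grid)
        cal = CalibrationPair(np.full((1, 1, 1), 0.0), np.full((1, 1, 1), 100.0))
        assert correct_reflectance(raw, cal).values.max() == 1.0

    def test_per_band_references_broadcast(self):
        grid = WavelengthGrid(np.array([400.0, 500.0]))
        raw = Hypercube(np.full((2, 2, 2), 5.0), grid)
        cal = CalibrationPair(np.zeros((1, 1, 2)), np.full((1, 1, 2), 10.0))
        np.testing.assert_allclose(correct_reflectance(raw, cal).values, 0.5)


class TestNearestBandIndex:
    def test_first_band(self, grid_full):
        assert nearest_band_index(grid_full, 382.3) == 0

    def test_576_is_index_108(self, grid_full):
        # oracle: exhaustive argmin over the enumerated grid
        w = grid_full.wavelengths_nm
        assert int(np.argmin(np.abs(w - 576.0))) == 108
        assert nearest_band_index(grid_full, 576.0) == 108

    def test_962_matches_brute_force(self, grid_full):
        w = grid_full.wavelengths_nm
        expected = int(np.argmin(np.abs(w - 962.0)))
        assert nearest_band_index(grid_full, 962.0) == expected

    def test_tie_breaks_high(self, grid_full):
        # 430 nm sits exactly between bands 26 (429.1) and 27 (430.9)
        w = grid_full.wavelengths_nm
        assert abs(w[26] - 430.0) == pytest.approx(abs(w[27] - 430.0), abs=1e-9)
        assert nearest_band_index(grid_full, 430.0) == 27

    def test_out_of_range(self, grid_full):
        with pytest.raises(WavelengthRangeError):
            nearest_band_index(grid_full, 2000.0)

    def test_random_targets_match_argmin_oracle(self, grid_full, rng):
        w = grid_full.wavelengths_nm
        targets = rng.uniform(w[0], w[-1], size=1000)
        for t in targets:
            assert nearest_band_index(grid_full, t) == int(np.argmin(np.abs(w - t)))


class TestPseudocolor:
    def grid3(self):
        return WavelengthGrid(np.array([430.0, 576.0, 962.0]))

    def test_constant_cube_maps_to_zero(self):
        cube = Hypercube(np.full((2, 2, 3), 0.5), self.grid3(), calibrated=True)
        img = synthesize_pseudocolor(cube, (0, 1, 2))
        assert img.dtype == np.uint8
        np.testing.assert_array_equal(img, 0)

    def test_gradient_band_spans_full_range(self):
        values = np.zeros((1, 4, 3))
        values[0, :, 0] = [0.1, 0.2, 0.3, 0.4]
        cube = Hypercube(values, self.grid3(), calibrated=True)
        img = synthesize_pseudocolor(cube, (0, 1, 2))
        # band 0 (shortest wavelength) -> blue channel
        assert img[0, 0, 2] == 0 and img[0, 3, 2] == 255

    def test_hand_computed_scaling(self):
        values = np.zeros((1, 3, 3))
        values[0, :, 0] = [0.0, 0.25, 1.0]
        values[0, :, 1] = [0.2, 0.2, 0.6]
        values[0, :, 2] = [0.5, 0.5, 0.5]
        cube = Hypercube(values, self.grid3(), calibrated=True)
        img = synthesize_pseudocolor(cube, (0, 1, 2))
        # R channel = band 2 (962 nm): zero range -> 0
        np.testing.assert_array_equal(img[0, :, 0], [0, 0, 0])
        # G channel = band 1: (0.2,0.2,0.6) -> (0, 0, 255)
        np.testing.assert_array_equal(img[0, :, 1], [0, 0, 255])
        # B channel = band 0: (0-0)/1*255=0, 0.25*255=63.75 -> 64, 255
        np.testing.assert_array_equal(img[0, :, 2], [0, 64, 255])

    def test_duplicate_bands_rejected(self):
        cube = Hypercube(np.zeros((2, 2, 3)), self.grid3(), calibrated=True)
        with pytest.raises(ValueError, match="distinct"):
            synthesize_pseudocolor(cube, (0, 0, 1))

    def test_uncalibrated_rejected(self):
        cube = Hypercube(np.zeros((2, 2, 3)), self.grid3())
        with pytest.raises(ValueError, match="calibrated"):
            synthesize_pseudocolor(cube, (0, 1, 2))


class TestExtractRoiSpectrum:
    def test_singleton_mean(self, rng):
        cube = small_cube(rng, shape=(4, 4, 3), calibrated=True)
        spectrum = extract_roi_spectrum(cube, BoundingBox(2, 1, 3, 2))
        np.testing.assert_array_equal(spectrum, cube.values[1, 2, :])

    def test_constant_region(self):
        cube = Hypercube(
            np.full((4, 4, 3), 0.3),
            WavelengthGrid(np.array([400.0, 500.0, 600.0])),
            calibrated=True,
        )
        np.testing.assert_allclose(
            extract_roi_spectrum(cube, BoundingBox(0, 0, 4, 4)), 0.3
        )

    def test_2x2_hand_mean(self):
        values = np.zeros((2, 2, 1))
        values[:, :, 0] = [[0.1, 0.2], [0.3, 0.4]]
        cube = Hypercube(values, WavelengthGrid(np.array([500.0])), calibrated=True)
        got = extract_roi_spectrum(cube, BoundingBox(0, 0, 2, 2))
        assert got[0] == pytest.approx((0.1 + 0.2 + 0.3 + 0.4) / 4)

    def test_union_is_weighted_mean(self, rng):
        cube = small_cube(rng, shape=(6, 8, 3), calibrated=True)
        a = BoundingBox(0, 0, 3, 6)  # 18 px
        b = BoundingBox(3, 0, 8, 6)  # 30 px
        u = BoundingBox(0, 0, 8, 6)
        sa = extract_roi_spectrum(cube, a)
        sb = extract_roi_spectrum(cube, b)
        su = extract_roi_spectrum(cube, u)
        np.testing.assert_allclose(su, (18 * sa + 30 * sb) / 48, atol=1e-12)

    def test_out_of_bounds_rejected(self):
        cube = small_cube(calibrated=True)
        with pytest.raises(ValueError, match="bounds"):
            extract_roi_spectrum(cube, BoundingBox(0, 0, 5, 5))


class TestAnnotations:
    def test_json_round_trip(self, tmp_path):
        truths = [("CBC", BoundingBox(1, 2, 5, 9)), ("CBB", BoundingBox(0, 0, 3, 3))]
        save_annotations(truths, tmp_path / "a.json")
        assert load_annotations(tmp_path / "a.json") == truths

    def test_voc_import_converts_coordinates(self, tmp_path):
        xml = """<annotation><object><name>CBC</name>
        <bndbox><xmin>2</xmin><ymin>3</ymin><xmax>10</xmax><ymax>12</ymax></bndbox>
        </object></annotation>"""
        (tmp_path / "a.xml").write_text(xml)
        [(label, box)] = load_voc_annotations(tmp_path / "a.xml")
        assert label == "CBC"
        assert box.as_tuple() == (1, 2, 10, 12)
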