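"""Grid arithmetic, ENVI round-trips, radiometric calibration, segmentation."""

import numpy as np
import pytest

import leafspec as ls
from leafspec.cube import average_reference_frame
from leafspec.grid import WavelengthGrid, modeling_window_grid, vnir_grid


class TestWavelengthGrid:
    def test_vnir_grid_definition(self):
        grid = vnir_grid()
        assert len(grid) == 856
        assert grid.sampling_interval == pytest.approx(0.727)
        assert grid.centers[0] == pytest.approx(380.0)

    def test_modeling_window_has_646_channels(self):
        grid = modeling_window_grid()
        assert len(grid) == 646
        assert grid.centers[0] == pytest.approx(430.163)
        # topmost channel of the inclusive crop is dropped by convention
        assert grid.centers[-1] == pytest.approx(380.0 + 0.727 * 714)

    def test_rejects_non_uniform_spacing(self):
        with pytest.raises(ValueError, match="uniform"):
            WavelengthGrid(np.array([400.0, 401.0, 403.0]))

    def test_rejects_decreasing(self):
        with pytest.raises(ValueError, match="increasing"):
            WavelengthGrid(np.array([410.0, 400.0]))


class TestCropWindow:
    def test_full_grid_window_is_identity(self):
        cube = ls.HyperCube(np.zeros((4, 4, 856)), vnir_grid())
        out = ls.crop_window(cube, 300.0, 1100.0)
        assert out.shape == cube.shape

    def test_paper_window_on_vnir_grid(self):
        cube = ls.HyperCube(np.zeros((2, 2, 856)), vnir_grid())
        out = ls.crop_modeling_window(cube)
        assert out.shape[2] == 646

    def test_single_channel_window(self):
        cube = ls.HyperCube(np.zeros((2, 2, 856)), vnir_grid())
        out = ls.crop_window(cube, 430.0, 430.2)
        assert out.shape[2] == 1
        assert out.grid.centers[0] == pytest.approx(430.163)

    def test_empty_window_raises(self):
        cube = ls.HyperCube(np.zeros((2, 2, 856)), vnir_grid())
        with pytest.raises(ValueError, match="no channels"):
            ls.crop_window(cube, 10.0, 20.0)

    def test_crops_tables_too(self, small_grid):
        table = ls.SpectraTable(np.random.default_rng(0).random((5, 60)), small_grid)
        out = ls.crop_window(table, 520.0, 560.0)
        assert out.n_channels == len(out.grid) == 21


class TestRadiometricCorrect:
    @pytest.fixture()
    def refs(self, small_grid):
        rng = np.random.default_rng(3)
        shape = (4, 5, 60)
        dark = ls.HyperCube(rng.uniform(90, 110, shape), small_grid)
        white = ls.HyperCube(dark.values + rng.uniform(800, 1200, shape), small_grid)
        return white, dark

    def test_raw_equals_white_gives_ones(self, refs, small_grid):
        white, dark = refs
        out = ls.radiometric_correct(white, white, dark)
        assert out.calibrated
        np.testing.assert_allclose(out.values, 1.0)

    def test_raw_equals_dark_gives_zeros(self, refs, small_grid):
        white, dark = refs
        out = ls.radiometric_correct(dark, white, dark)
        np.testing.assert_allclose(out.values, 0.0)

    def test_midpoint_gives_half(self, refs, small_grid):
        white, dark = refs
        mid = ls.HyperCube((white.values + dark.values) / 2, small_grid)
        out = ls.radiometric_correct(mid, white, dark)
        np.testing.assert_allclose(out.values, 0.5)

    @pytest.mark.parametrize("gain", [0.5, 3.0, 17.0])
    def test_common_gain_invariance(self, refs, small_grid, gain):
        white, dark = refs
        rng = np.random.default_rng(5)
        raw = ls.HyperCube(
            dark.values + rng.random((4, 5, 60)) * (white.values - dark.values),
            small_grid,
        )
        base = ls.radiometric_correct(raw, white, dark)
        scaled = ls.radiometric_correct(
            ls.HyperCube(raw.values * gain, small_grid),
            ls.HyperCube(white.values * gain, small_grid),
            ls.HyperCube(dark.values * gain, small_grid),
        )
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-9)

    def test_zero_denominator_names_band_and_pixel(self, refs, small_grid):
        white, dark = refs
        bad_white = ls.HyperCube(white.values.copy(), small_grid)
        bad_white.values[2, 3, 10] = dark.values[2, 3, 10]
        with pytest.raises(ValueError, match=r"row=2, col=3.*band 10"):
            ls.radiometric_correct(dark, bad_white, dark)

    def test_column_reference_averaging(self, refs, small_grid):
        white, _ = refs
        frame = average_reference_frame(white)
        assert np.ptp(frame.values, axis=(0, 1)).max() == 0
        np.testing.assert_allclose(
            frame.values[0, 0], white.values.mean(axis=(0, 1))
        )


class TestEnviRoundTrip:
    def test_bit_exact_float32_roundtrip(self, tmp_path, small_grid):
        rng = np.random.default_rng(8)
        cube = ls.HyperCube(
            rng.random((6, 7, 60)).astype(np.float32).astype(float),
            small_grid,
            calibrated=True,
        )
        ls.write_envi(cube, tmp_path / "leaf.hdr")
        back = ls.read_envi(tmp_path / "leaf.hdr")
        np.testing.assert_array_equal(back.values, cube.values)
        np.testing.assert_allclose(back.grid.centers, small_grid.centers)
        assert back.calibrated


class TestSegmentationAndRoi:
    @pytest.fixture()
    def leaf_cube(self, small_grid):
        cfg = ls.SimulationConfig(seed=2, grid=small_grid, planted_bands=((540.0, 6.0, 0.05),))
        return ls.simulate_cube(cfg, shape=(24, 32))

    def test_mask_recovers_planted_ellipse(self, leaf_cube):
        cube, truth = leaf_cube
        mask = ls.segment_leaf(cube, threshold=0.1, nir_window=(500.0, 620.0))
        np.testing.assert_array_equal(mask.values, truth.mask.values)

    def test_threshold_zero_full_frame(self, leaf_cube):
        cube, _ = leaf_cube
        mask = ls.segment_leaf(cube, threshold=0.0, nir_window=(500.0, 620.0))
        assert mask.values.all()

    def test_threshold_above_max_warns_empty(self, leaf_cube):
        cube, _ = leaf_cube
        with pytest.warns(UserWarning, match="no foreground"):
            mask = ls.segment_leaf(cube, threshold=2.0, nir_window=(500.0, 620.0))
        assert mask.n_pixels == 0

    def test_roi_mean_single_pixel(self, leaf_cube, small_grid):
        cube, _ = leaf_cube
        mask = np.zeros(cube.shape[:2], dtype=bool)
        mask[12, 16] = True
        np.testing.assert_array_equal(
            ls.roi_mean_spectrum(cube, ls.LeafMask(mask)), cube.values[12, 16]
        )

    def test_roi_mean_two_pixels(self, leaf_cube):
        cube, _ = leaf_cube
        mask = np.zeros(cube.shape[:2], dtype=bool)
        mask[12, 16] = mask[13, 17] = True
        expected = (cube.values[12, 16] + cube.values[13, 17]) / 2
        np.testing.assert_allclose(
            ls.roi_mean_spectrum(cube, ls.LeafMask(mask)), expected
        )

    def test_roi_mean_empty_mask_raises(self, leaf_cube):
        cube, _ = leaf_cube
        with pytest.raises(ValueError, match="empty mask"):
            ls.roi_mean_spectrum(cube, ls.LeafMask(np.zeros(cube.shape[:2], bool)))

    def test_constant_field_mean_matches_generator(self, small_grid):
        cfg = ls.SimulationConfig(
            seed=4, grid=small_grid, noise_sd=0.003, drift_sd=0.0,
            planted_bands=((540.0, 6.0, 0.05),),
        )
        cube, truth = ls.simulate_cube(cfg, shape=(24, 32), constant_concentration=3.0)
        mean = ls.roi_mean_spectrum(cube, truth.mask)
        lam = small_grid.centers
        expected = cfg.baseline_level - 3.0 * 0.05 * np.exp(
            -((lam - 540.0) ** 2) / (2 * 6.0**2)
        )
        n = truth.mask.n_pixels
        assert np.abs(mean - expected).max() < 5 * cfg.noise_sd / np.sqrt(n)
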