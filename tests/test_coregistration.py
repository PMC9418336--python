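"""Coregistration: references, displacement estimation, warping, tiling."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from smallfield import coregistration as coreg
from smallfield import synthetic
from smallfield.core import DisplacementField, MonthlySeries


@pytest.fixture(scope="module")
def textured_reference():
    """Clean, textured seasonal reference from an undisplaced scene."""
    truth = synthetic.make_scene(192, seed=3, cloud_fraction=0.0,
                                 constant_shifts=[(0.0, 0.0)] * 12)
    series = synthetic.render_monthly_series(truth, noise_sd=0.0, seed=0)
    return coreg.build_seasonal_reference(series)[0]


def shifted(ref, dy, dx):
    rows, cols = np.meshgrid(np.arange(ref.composite.shape[0], dtype=float),
                             np.arange(ref.composite.shape[1], dtype=float),
                             indexing="ij")
    return ndimage.map_coordinates(ref.composite, [rows - dy, cols - dx],
                                   order=1, mode="nearest")


class TestSeasonalReference:
    def test_identical_months_reproduce_any_month(self):
        img = np.random.default_rng(0).uniform(0.1, 0.5, (12, 32, 32))
        img[:4] = img[0]
        series = MonthlySeries(
            np.stack([np.stack([img[m]] * 4) for m in range(12)]),
            np.arange(1, 13), np.ones((12, 32, 32), bool))
        ref = coreg.build_seasonal_reference(series)[0]
        np.testing.assert_allclose(ref.composite, img[0], rtol=1e-6)

    def test_median_ignores_masked_observations(self):
        data = np.zeros((12, 4, 1, 1), np.float32)
        data[:4, 2, 0, 0] = [0.2, 0.4, 0.6, 0.9]
        valid = np.ones((12, 1, 1), bool)
        valid[3] = False  # mask the 0.9
        series = MonthlySeries(data, np.arange(1, 13), valid)
        ref = coreg.build_seasonal_reference(series)[0]
        assert ref.composite[0, 0] == pytest.approx(0.4)
        assert ref.count[0, 0] == 3

    def test_fully_masked_pixel_flagged_undefined(self):
        data = np.full((12, 4, 2, 2), 0.3, np.float32)
        valid = np.ones((12, 2, 2), bool)
        valid[:4, 0, 0] = False
        series = MonthlySeries(data, np.arange(1, 13), valid)
        ref = coreg.build_seasonal_reference(series)[0]
        assert np.isnan(ref.composite[0, 0])
        assert not ref.defined[0, 0]
        assert ref.defined[1, 1]

    def test_windows_must_partition_the_year(self, series):
        with pytest.raises(ValueError):
            coreg.build_seasonal_reference(series, ((0, 1, 2, 3),
                                                    (4, 5, 6, 7)))


class TestEstimateDisplacement:
    def test_identity_recovers_zero_field(self, textured_reference):
        cfg = coreg.CoregConfig(pixel_size=4.77)
        fld = coreg.estimate_displacement(textured_reference.composite,
                                          textured_reference, cfg)
        assert np.all(fld.magnitude < 0.1)

    @pytest.mark.parametrize("shift", [(3, -2), (9, 4), (-15, 15)])
    def test_known_shift_recovered_below_half_pixel(self, textured_reference,
                                                    shift):
        cfg = coreg.CoregConfig(pixel_size=4.77)
        tgt = shifted(textured_reference, *shift)
        fld = coreg.estimate_displacement(tgt, textured_reference, cfg)
        interior = (slice(24, -24),) * 2
        mae = np.mean(np.hypot(fld.dy[interior] - shift[0],
                               fld.dx[interior] - shift[1]))
        assert mae < 0.5

    def test_offsets_clamped_to_max_offset(self, textured_reference):
        # a true shift of ~150 m must come back capped at 100 m
        cfg = coreg.CoregConfig(max_offset_m=100.0, pixel_size=4.77)
        shift_px = 150.0 / 4.77
        tgt = shifted(textured_reference, shift_px, 0.0)
        fld = coreg.estimate_displacement(tgt, textured_reference, cfg)
        cap = 100.0 / 4.77
        assert np.all(fld.magnitude <= cap + 1e-9)

    def test_textureless_target_warns_and_returns_zero(self,
                                                       textured_reference):
        flat = np.full_like(textured_reference.composite, 0.3)
        with pytest.warns(UserWarning, match="textureless"):
            fld = coreg.estimate_displacement(flat, textured_reference,
                                              coreg.CoregConfig())
        assert np.all(fld.magnitude == 0.0)

    def test_insufficient_overlap_rejected(self, textured_reference):
        ref = coreg.SeasonalReference(
            np.where(np.arange(192)[:, None] < 20,
                     textured_reference.composite, np.nan),
            textured_reference.count, 0, (0, 1, 2, 3))
        with pytest.raises(ValueError, match="overlap"):
            coreg.estimate_displacement(np.full((192, 192), np.nan), ref,
                                        coreg.CoregConfig())


class TestApplyDisplacement:
    def test_zero_field_is_bit_identical(self, series):
        zero = DisplacementField(np.zeros(series.shape),
                                 np.zeros(series.shape))
        out = coreg.apply_displacement(series, zero)
        assert np.array_equal(out.data, series.data)
        assert np.array_equal(out.valid, series.valid)

    def test_constant_integer_shift_equals_roll(self, series):
        fld = DisplacementField(np.full(series.shape, 2.0),
                                np.full(series.shape, -3.0))
        out = coreg.apply_displacement(series, fld)
        rolled = np.roll(series.data[0, 2], (3, -2), axis=(0, 1))
        interior = (slice(5, -5),) * 2
        np.testing.assert_allclose(out.data[0, 2][interior],
                                   rolled[interior], atol=1e-6)

    def test_round_trip_warp_near_identity(self, series):
        dy = np.full(series.shape, 1.7)
        dx = np.full(series.shape, -2.3)
        fwd = coreg.apply_displacement(series, DisplacementField(dx, dy))
        back = coreg.apply_displacement(fwd, DisplacementField(-dx, -dy))
        interior = (slice(6, -6),) * 2
        dev = np.abs(back.data[:, :, interior[0], interior[1]].astype(float)
                     - series.data[:, :, interior[0], interior[1]])
        assert dev.mean() < 0.01  # bilinear interpolation tolerance


class TestCoregisterSeries:
    def test_constant_misregistration_corrected(self):
        shifts = [(0.0, 0.0)] * 12
        shifts[5] = (4.0, -3.0)
        truth = synthetic.make_scene(128, seed=11, cloud_fraction=0.0,
                                     constant_shifts=shifts)
        series = synthetic.render_monthly_series(truth, noise_sd=0.01,
                                                 seed=1)
        cfg = coreg.CoregConfig(pixel_size=4.77, block_size=32)
        corrected, fields = coreg.coregister_series(series, cfg)
        interior = (slice(16, -16),) * 2
        err = np.hypot(fields[5].dy[interior] - 4.0,
                       fields[5].dx[interior] + 3.0)
        assert err.mean() < 0.75  # reference blends 3 clean + 1 shifted month

    def test_tiled_matches_untiled_on_constant_shift(self):
        shifts = [(0.0, 0.0)] * 12
        shifts[2] = (3.0, 2.0)
        truth = synthetic.make_scene(128, seed=13, cloud_fraction=0.0,
                                     constant_shifts=shifts)
        series = synthetic.render_monthly_series(truth, noise_sd=0.0, seed=1)
        cfg = coreg.CoregConfig(pixel_size=4.77, block_size=32)
        cfg_tiled = coreg.CoregConfig(pixel_size=4.77, block_size=32,
                                      tile_size=64, tile_buffer=32)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, whole = coreg.coregister_series(series, cfg)
            _, tiled = coreg.coregister_series(series, cfg_tiled)
        interior = (slice(16, -16),) * 2
        dev = np.hypot(whole[2].dy[interior] - tiled[2].dy[interior],
                       whole[2].dx[interior] - tiled[2].dx[interior])
        assert dev.mean() < 0.35

    def test_buffer_must_cover_max_offset(self):
        with pytest.raises(ValueError, match="buffer"):
            coreg.CoregConfig(max_offset_m=100.0, pixel_size=4.77,
                              tile_size=64, tile_buffer=4)

    def test_edge_pixel_noise_contrast_on_jittered_scene(self):
        """Misregistration inflates noise at field edges; correction must
        bring the mean edge-pixel noise back down."""
        from smallfield import tsnoise

        truth = synthetic.make_scene(96, seed=21, max_shift_px=4.0,
                                     cloud_fraction=0.0)
        series = synthetic.render_monthly_series(truth, noise_sd=0.005,
                                                 seed=2)
        before = tsnoise.noise_map(series).values
        cfg = coreg.CoregConfig(pixel_size=4.77, block_size=32)
        corrected, _ = coreg.coregister_series(series, cfg)
        after = tsnoise.noise_map(corrected).values
        codes = truth.class_map.codes.astype(int)
        edge = (np.abs(np.diff(codes, axis=0, prepend=codes[:1]))
                + np.abs(np.diff(codes, axis=1, prepend=codes[:, :1]))) > 0
        assert np.nanmean(after[edge]) < np.nanmean(before[edge])
        # and most edge pixels individually improve
        assert np.mean(after[edge] <= before[edge]) > 0.5
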