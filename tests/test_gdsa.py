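"""ROI segmentation and the GDSA mean-difference metric."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

import epidwatch as ew

from conftest import SMALL_MATRIX


class TestSegmentRoi:
    def test_uniform_image_selects_every_pixel(self, make_image):
        img = make_image(pixels=np.full(SMALL_MATRIX, 0.8))
        roi = ew.segment_roi(img)
        assert roi.pixel_count == img.pixels.size
        assert roi.mask.all()

    def test_all_zero_image_is_degenerate(self, make_image):
        img = make_image(pixels=np.zeros(SMALL_MATRIX))
        with pytest.raises(ew.DegenerateFieldError):
            ew.segment_roi(img)

    def test_tiny_roi_is_degenerate(self, make_image):
        pixels = np.zeros(SMALL_MATRIX)
        pixels[40:44, 40:44] = 1.0  # 16 bright pixels < min_roi_pixels
        with pytest.raises(ew.DegenerateFieldError):
            ew.segment_roi(make_image(pixels=pixels))

    def test_matches_brute_force_pixelwise_oracle(self, make_image, geometry):
        # synthetic square field with a Gaussian penumbra
        rows, cols = SMALL_MATRIX
        pixels = np.zeros(SMALL_MATRIX)
        pixels[24:72, 20:76] = 1.0
        pixels = gaussian_filter(pixels, 3.0)
        img = make_image(pixels=pixels)
        params = ew.RoiParams()
        roi = ew.segment_roi(img, params)

        smoothed = gaussian_filter(pixels, params.smoothing_sigma_px)
        threshold = params.dose_threshold_fraction * smoothed.max()
        pr, pc = geometry.pixel_pitch_mm
        expected = np.zeros(SMALL_MATRIX, dtype=bool)
        for i in range(rows):
            for j in range(cols):
                # central differences, one-sided at the borders
                if 0 < i < rows - 1:
                    gr = (smoothed[i + 1, j] - smoothed[i - 1, j]) / 2.0
                else:
                    gr = smoothed[min(i + 1, rows - 1), j] - smoothed[max(i - 1, 0), j]
                if 0 < j < cols - 1:
                    gc = (smoothed[i, j + 1] - smoothed[i, j - 1]) / 2.0
                else:
                    gc = smoothed[i, min(j + 1, cols - 1)] - smoothed[i, max(j - 1, 0)]
                v = smoothed[i, j]
                if v <= 0:
                    continue
                rel = 100.0 * np.hypot(gr / pr, gc / pc) / v
                expected[i, j] = (
                    v >= threshold and rel <= params.gradient_limit_percent_per_mm
                )
        assert np.array_equal(roi.mask, expected)

    @pytest.mark.parametrize("lo,hi", [(0.4, 0.6), (0.5, 0.7)])
    def test_dose_threshold_monotonicity(self, make_image, lo, hi):
        pixels = gaussian_filter(
            np.pad(np.ones((48, 48)), 24), 4.0
        )
        img = make_image(pixels=pixels)
        n_lo = ew.segment_roi(img, ew.RoiParams(dose_threshold_fraction=lo)).pixel_count
        n_hi = ew.segment_roi(img, ew.RoiParams(dose_threshold_fraction=hi)).pixel_count
        assert n_hi <= n_lo

    @pytest.mark.parametrize("lo,hi", [(1.0, 3.0), (3.0, 8.0)])
    def test_gradient_limit_monotonicity(self, make_image, lo, hi):
        pixels = gaussian_filter(np.pad(np.ones((48, 48)), 24), 4.0)
        img = make_image(pixels=pixels)
        n_lo = ew.segment_roi(
            img, ew.RoiParams(gradient_limit_percent_per_mm=lo)
        ).pixel_count
        n_hi = ew.segment_roi(
            img, ew.RoiParams(gradient_limit_percent_per_mm=hi)
        ).pixel_count
        assert n_hi >= n_lo


class TestGdsaMean:
    def test_baseline_vs_itself_is_exactly_zero(self, make_image):
        img = make_image(pixels=np.random.default_rng(0).uniform(0.5, 2, SMALL_MATRIX))
        roi = ew.RoiMask(np.ones(SMALL_MATRIX, dtype=bool), img.pixels.size)
        assert ew.gdsa_mean(img, img, roi) == 0.0

    def test_two_pixel_hand_computed_oracle(self, make_image):
        base = np.ones(SMALL_MATRIX)
        frac = np.ones(SMALL_MATRIX)
        base[0, 0], base[0, 1] = 100.0, 200.0
        frac[0, 0], frac[0, 1] = 110.0, 190.0
        mask = np.zeros(SMALL_MATRIX, dtype=bool)
        mask[0, 0] = mask[0, 1] = True
        roi = ew.RoiMask(mask, 2)
        # per-pixel: +10 % and -5 % -> mean +2.5 %
        assert ew.gdsa_mean(
            make_image(pixels=frac), make_image(pixels=base), roi
        ) == pytest.approx(2.5, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        c=st.floats(min_value=0.05, max_value=20.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_homogeneity_uniform_scaling(self, c, seed):
        rng = np.random.default_rng(seed)
        pixels = rng.uniform(0.2, 2.0, (16, 16))
        geom = ew.ImagingGeometry(matrix=(16, 16))
        when = dt.datetime(2021, 3, 1, 20)
        base = ew.EpidImage(pixels, "P", "PL", "F", when, geom)
        frac = ew.EpidImage(c * pixels, "P", "PL", "F", when, geom)
        mask = rng.uniform(size=(16, 16)) < 0.5
        mask[0, 0] = True  # non-empty
        roi = ew.RoiMask(mask, int(mask.sum()))
        assert ew.gdsa_mean(frac, base, roi) == pytest.approx(
            100.0 * (c - 1.0), rel=1e-9, abs=1e-9
        )

    def test_zero_baseline_pixel_in_roi_rejected(self, make_image):
        base = np.ones(SMALL_MATRIX)
        base[5, 5] = 0.0
        roi = ew.RoiMask(np.ones(SMALL_MATRIX, dtype=bool), base.size)
        with pytest.raises(ew.ZeroBaselineError):
            ew.gdsa_mean(make_image(), make_image(pixels=base), roi)


class TestCourseGdsa:
    def test_single_fraction_course(self, phantom, make_config):
        series, _ = ew.generate_course(phantom, make_config(n_fractions=1))
        (rec,) = ew.course_gdsa(series)
        assert rec.gdsa_percent == 0.0
        assert rec.status == "complete"

    def test_two_fields_scaled_fraction(self, phantom, make_config):
        config = make_config(n_fractions=2, field_ids=("F1", "F2"))
        series, _ = ew.generate_course(
            phantom, config, [ew.ErrorInjection(ew.SPIKE, 2, 2.0)]
        )
        recs = ew.course_gdsa(series)
        assert recs[1].gdsa_percent == pytest.approx(2.0, abs=1e-9)
        assert recs[1].n_fields == 2

    def test_missing_field_marks_fraction_omitted(self, phantom, make_config):
        config = make_config(n_fractions=4, field_ids=("F1", "F2"))
        series, _ = ew.generate_course(phantom, config)
        series.fractions[2].images.pop()  # beam interruption at fraction 3
        recs = ew.course_gdsa(series)
        assert recs[2].status == "omitted"
        assert np.isnan(recs[2].gdsa_percent)
        # omitted records contribute to no flags or summaries
        assert ew.flag_type_a(recs) == []
        days = ew.daily_summaries(recs)
        assert series.fractions[2].date not in [s.date for s in days]

    def test_noise_free_course_matches_ground_truth(self, phantom, make_config):
        config = make_config(
            n_fractions=6,
            output_drift_percent_per_fraction=0.5,
            thickness_drift_cm_per_fraction=-0.1,
        )
        series, truth = ew.generate_course(phantom, config)
        recs = ew.course_gdsa(series)
        for rec, expected in zip(recs, truth.expected_gdsa):
            assert rec.gdsa_percent == pytest.approx(expected, abs=0.05)

    def test_records_csv_round_trip(self, phantom, make_config, tmp_path):
        series, _ = ew.generate_course(phantom, make_config(n_fractions=3))
        recs = ew.course_gdsa(series)
        path = ew.write_records_csv(recs, tmp_path / "records.csv")
        back = ew.read_records_csv(path)
        assert [r.fraction_index for r in back] == [1, 2, 3]
        assert back[0].patient_id == recs[0].patient_id
        assert back[1].gdsa_percent == pytest.approx(recs[1].gdsa_percent, abs=1e-5)
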