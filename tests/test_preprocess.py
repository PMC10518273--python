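"""Preprocessing chain: merge, trim, smoothing, LSNV, segment isolation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cartispec.preprocess import (DEFAULT_TRIM_WINDOWS, PreprocessConfig,
                                  lsnv_normalize, merge_detectors,
                                  preprocess_pipeline, savgol_smooth,
                                  segment_slices, trim_spectrum)
from conftest import make_record


def _vis(value=1.0):
    wl = np.arange(350.0, 1101.0, 5.0)
    return make_record(wl, np.full(wl.size, value))


def _nir(value=1.0):
    wl = np.arange(1000.0, 2501.0, 10.0)
    return make_record(wl, np.full(wl.size, value))


class TestMerge:
    def test_cutover_partition(self):
        merged = merge_detectors(_vis(), _nir(), cutover_nm=1050.0)
        assert np.all(np.diff(merged.wavelengths) > 0)
        assert merged.wavelengths[merged.wavelengths <= 1050].max() == 1050.0
        # everything <= cutover came from the 5-nm vis grid
        below = merged.wavelengths[merged.wavelengths <= 1050]
        assert np.all(below % 5 == 0)
        above = merged.wavelengths[merged.wavelengths > 1050]
        assert np.all(above % 10 == 0)

    def test_constant_identity(self):
        merged = merge_detectors(_vis(1.0), _nir(1.0))
        np.testing.assert_array_equal(merged.intensities,
                                      np.ones(merged.wavelengths.size))

    def test_step_discontinuity_preserved(self):
        merged = merge_detectors(_vis(1.0), _nir(2.0), cutover_nm=1050.0)
        lo = merged.intensities[merged.wavelengths <= 1050]
        hi = merged.intensities[merged.wavelengths > 1050]
        assert np.all(lo == 1.0) and np.all(hi == 2.0)

    def test_errors(self):
        wl = np.arange(350.0, 901.0, 5.0)
        vis = make_record(wl, np.ones(wl.size))
        with pytest.raises(ValueError, match="overlap"):
            merge_detectors(vis, _nir())
        other = _nir()
        other.donor_id = "D99"
        with pytest.raises(ValueError, match="metadata"):
            merge_detectors(_vis(), other)


class TestTrim:
    def test_default_windows_retained_count(self):
        wl = np.arange(350.0, 2501.0, 1.0)
        rec = make_record(wl, np.zeros(wl.size))
        out = trim_spectrum(rec)
        assert out.wavelengths.size == 1001 + 331

    def test_degenerate_window(self):
        wl = np.arange(350.0, 2501.0, 1.0)
        out = trim_spectrum(make_record(wl, np.zeros(wl.size)), [(500, 500)])
        assert out.wavelengths.size == 1
        assert out.wavelengths[0] == 500.0

    def test_postcondition_and_idempotence(self):
        wl = np.arange(350.0, 2501.0, 0.7)
        rec = make_record(wl, np.sin(wl))
        out = trim_spectrum(rec)
        inside = ((out.wavelengths >= 400) & (out.wavelengths <= 1400)) \
            | ((out.wavelengths >= 1520) & (out.wavelengths <= 1850))
        assert inside.all()
        again = trim_spectrum(out)
        np.testing.assert_array_equal(again.wavelengths, out.wavelengths)

    def test_empty_result_is_error(self):
        wl = np.arange(350.0, 391.0, 1.0)
        with pytest.raises(ValueError):
            trim_spectrum(make_record(wl, np.zeros(wl.size)))


class TestSavgol:
    def test_polynomial_reproduction(self):
        wl = np.arange(400.0, 900.0, 2.0)
        y = 3.0 - 0.002 * wl + 1e-5 * wl**2
        out = savgol_smooth(make_record(wl, y), window=11, polyorder=2)
        np.testing.assert_allclose(out.intensities, y, atol=1e-9)

    def test_constant_unchanged(self):
        wl = np.arange(400.0, 900.0, 2.0)
        out = savgol_smooth(make_record(wl, np.full(wl.size, 7.0)))
        np.testing.assert_allclose(out.intensities, 7.0)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(1)
        wl = np.arange(400.0, 1400.0, 1.0)
        y = rng.normal(size=wl.size)
        out = savgol_smooth(make_record(wl, y), window=11, polyorder=2)
        assert out.intensities.var() < y.var()

    def test_parameter_errors(self):
        wl = np.arange(400.0, 500.0, 1.0)
        rec = make_record(wl, np.zeros(wl.size))
        with pytest.raises(ValueError):
            savgol_smooth(rec, window=10)
        with pytest.raises(ValueError):
            savgol_smooth(rec, window=5, polyorder=5)

    def test_segments_filtered_independently(self):
        # huge values in the second segment must not bleed into the first
        wl = np.concatenate([np.arange(400.0, 700.0, 2.0),
                             np.arange(1520.0, 1850.0, 2.0)])
        rng = np.random.default_rng(2)
        y = np.concatenate([rng.normal(size=150), np.full(165, 1e6)])
        rec = make_record(wl, y)
        assert len(segment_slices(wl)) == 2
        out = savgol_smooth(rec, window=11, polyorder=2)
        alone = savgol_smooth(make_record(wl[:150], y[:150]), 11, 2)
        np.testing.assert_array_equal(out.intensities[:150], alone.intensities)


class TestLsnv:
    def test_single_window_is_snv(self):
        wl = np.arange(400.0, 600.0, 1.0)
        rng = np.random.default_rng(3)
        out = lsnv_normalize(make_record(wl, rng.normal(2, 5, wl.size)),
                             window_nm=500.0)
        assert out.intensities.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.intensities.std() == pytest.approx(1.0, abs=1e-12)

    @given(a=st.floats(0.1, 50.0), b=st.floats(-10.0, 10.0))
    def test_affine_invariance(self, a, b):
        wl = np.arange(400.0, 800.0, 2.0)
        y = np.sin(wl / 37.0) + 0.1 * np.cos(wl / 11.0)
        out1 = lsnv_normalize(make_record(wl, y), 150.0)
        out2 = lsnv_normalize(make_record(wl, a * y + b), 150.0)
        np.testing.assert_allclose(out2.intensities, out1.intensities,
                                   atol=1e-9)

    def test_windows_independently_centred(self):
        wl = np.arange(400.0, 800.0, 1.0)
        y = np.where(wl < 600, 5.0, -3.0) + np.sin(wl)
        out = lsnv_normalize(make_record(wl, y), 200.0)
        first = out.intensities[wl < 600]
        second = out.intensities[wl >= 600]
        assert first.mean() == pytest.approx(0.0, abs=1e-12)
        assert second.mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_spread_window_is_error(self):
        wl = np.arange(400.0, 500.0, 1.0)
        with pytest.raises(ValueError, match="zero standard deviation"):
            lsnv_normalize(make_record(wl, np.full(wl.size, 2.0)), 200.0)


class TestPipeline:
    def test_disabled_steps_identity(self):
        wl = np.arange(400.0, 1800.0, 5.0)
        rec = make_record(wl, np.sin(wl / 100))
        out = preprocess_pipeline([rec], PreprocessConfig(steps=()))
        np.testing.assert_array_equal(out[0].intensities, rec.intensities)
        np.testing.assert_array_equal(out[0].wavelengths, rec.wavelengths)

    def test_record_count_and_metadata_preserved_at_study_scale(self):
        wl = np.arange(380.0, 1901.0, 10.0)
        rng = np.random.default_rng(4)
        records = [
            make_record(wl, rng.normal(1.0, 0.1, wl.size),
                        donor_id=f"D{i % 17:02d}", sample_id=f"S{i // 3}",
                        replicate=i % 3 + 1, oarsi_grade=i % 6)
            for i in range(927)
        ]
        out = preprocess_pipeline(records, PreprocessConfig())
        assert len(out) == 927
        for before, after in zip(records, out):
            assert (before.donor_id, before.sample_id, before.replicate,
                    before.oarsi_grade) == \
                   (after.donor_id, after.sample_id, after.replicate,
                    after.oarsi_grade)
        gap = (out[0].wavelengths > 1400) & (out[0].wavelengths < 1520)
        assert not gap.any()

    def test_invalid_configuration(self):
        with pytest.raises(ValueError):
            PreprocessConfig(sg_window=10).validate()
        with pytest.raises(ValueError):
            PreprocessConfig(trim_windows=((400, 1400), (1300, 1850))).validate()
        with pytest.raises(ValueError):
            PreprocessConfig(steps=("trim", "detrend")).validate()
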