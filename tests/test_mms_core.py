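import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from facemms import errors
from facemms.mms_core import (
    GluedSpeedSeries,
    deviation_series,
    empirical_gamma_mean,
    extract_peaks,
    glue_region,
    local_minima,
    mms_standardize,
)
from facemms.stochastic_signatures import fit_gamma_mle


class TestGlue:
    @pytest.mark.parametrize(
        "region,expected", [("V1", 3900), ("V2", 2550), ("V3", 3750)]
    )
    def test_glued_lengths(self, td_speed, partition, region, expected):
        """26/17/25 landmarks x 150 frames give the region frame totals."""
        assert len(glue_region(td_speed, region, partition)) == expected

    def test_glue_order_recorded_ascending(self, td_speed, partition):
        glued = glue_region(td_speed, "V2", partition)
        assert glued.landmarks == tuple(sorted(partition["V2"]))

    def test_permuted_order_same_multiset(self, td_speed, partition, rng):
        ref = glue_region(td_speed, "V1", partition)
        order = tuple(rng.permutation(list(partition["V1"])))
        shuffled = glue_region(td_speed, "V1", partition, order=order)
        np.testing.assert_allclose(
            np.sort(ref.values), np.sort(shuffled.values)
        )

    def test_bad_order_rejected(self, td_speed, partition):
        with pytest.raises(errors.IncompleteRegionError):
            glue_region(td_speed, "V1", partition, order=(1, 2, 3))


class TestPeaks:
    def test_simple_sequence(self):
        peaks = extract_peaks(np.array([0.0, 1.0, 0.0, 2.0, 0.0]))
        np.testing.assert_array_equal(peaks.indices, [1, 3])
        np.testing.assert_array_equal(peaks.amplitudes, [1.0, 2.0])

    def test_monotone_has_no_peaks(self):
        assert len(extract_peaks(np.arange(10.0))) == 0

    def test_plateau_yields_first_index(self):
        peaks = extract_peaks(np.array([0.0, 2.0, 2.0, 2.0, 1.0]))
        np.testing.assert_array_equal(peaks.indices, [1])

    def test_endpoints_never_peaks(self):
        # the high endpoint 5.0 does not count; only index 1 is a peak
        peaks = extract_peaks(np.array([1.0, 3.0, 2.0, 5.0]))
        np.testing.assert_array_equal(peaks.indices, [1])

    def test_too_short_rejected(self):
        with pytest.raises(errors.InsufficientDataError):
            extract_peaks(np.array([1.0, 2.0]))

    def test_random_long_series_many_peaks(self, rng):
        """A glued-length random series yields well over 100 peaks."""
        peaks = extract_peaks(rng.gamma(4.0, 0.5, 3900))
        assert len(peaks) >= 100

    def test_region_speed_peak_yield(self, td_speed, partition):
        for region in partition.names():
            glued = glue_region(td_speed, region, partition)
            assert len(extract_peaks(glued.values)) > 100


class TestLocalMinima:
    def test_interior_and_boundary_minima(self):
        idx = local_minima(np.array([0.0, 2.0, 1.0, 3.0, 0.5]))
        np.testing.assert_array_equal(idx, [0, 2, 4])

    def test_flat_boundary_counts(self):
        idx = local_minima(np.array([1.0, 1.0, 2.0, 1.5]))
        assert 0 in idx  # plateau running into the start


class TestGammaMean:
    def test_known_gamma_mean_recovered(self, rng):
        amp = rng.gamma(4.0, 0.5, 1000)
        assert 1.8 <= empirical_gamma_mean(amp) <= 2.2  # true mean 2.0

    def test_exponential_mean_recovered(self, rng):
        amp = rng.exponential(1.0, 2000)
        assert 0.9 <= empirical_gamma_mean(amp) <= 1.1

    def test_constant_amplitudes_degenerate(self):
        with pytest.raises(errors.DegenerateFitError):
            empirical_gamma_mean(np.full(100, 3.0))

    def test_too_few_peaks_rejected(self):
        with pytest.raises(errors.InsufficientDataError):
            empirical_gamma_mean(np.abs(np.arange(10)) + 1.0)

    def test_many_nonpositive_rejected(self, rng):
        amp = rng.gamma(4.0, 0.5, 200)
        amp[:30] = 0.0
        with pytest.raises(errors.DataQualityError):
            empirical_gamma_mean(amp)


class TestDeviation:
    def test_series_at_mean_gives_zeros(self):
        glued = GluedSpeedSeries("V1", (0,), np.full(5, 1.3))
        np.testing.assert_array_equal(deviation_series(glued, 1.3), 0.0)

    def test_direct_evaluation(self):
        glued = GluedSpeedSeries("V1", (0,), np.array([0.0, 2.0]))
        np.testing.assert_array_equal(deviation_series(glued, 1.0), [1.0, 1.0])

    def test_length_preserved(self, rng):
        glued = GluedSpeedSeries("V1", (0,), rng.gamma(2.0, 1.0, 321))
        assert deviation_series(glued, 2.0).shape == (321,)

    def test_nonpositive_mean_rejected(self):
        glued = GluedSpeedSeries("V1", (0,), np.ones(5))
        with pytest.raises(errors.DomainError):
            deviation_series(glued, 0.0)


class TestMMSStandardize:
    def test_stated_formula(self):
        # peaks 2 and 4; flanking minima (1, 0) and (0, 1) respectively:
        # spike_1 = 2/(2 + 0.5) = 0.8, spike_3 = 4/(4 + 0.5) = 8/9
        dev = np.array([1.0, 2.0, 0.0, 4.0, 1.0])
        mms = mms_standardize(dev)
        np.testing.assert_array_equal(mms.spike_positions, [1, 3])
        assert mms.spike_values[0] == pytest.approx(0.8)
        assert mms.spike_values[1] == pytest.approx(8.0 / 9.0)

    def test_zero_minima_give_unit_spike(self):
        mms = mms_standardize(np.array([0.0, 2.0, 0.0]))
        assert mms.spike_values[0] == pytest.approx(1.0)

    def test_boundary_peak_single_minimum(self):
        # only a right minimum exists for the first peak
        dev = np.array([1.0, 3.0, 1.0, 2.0, 1.5])
        mms = mms_standardize(dev)
        assert mms.spike_values[0] == pytest.approx(3.0 / 4.0)

    def test_full_series_support_is_peak_set(self, td_speed, partition):
        glued = glue_region(td_speed, "V2", partition)
        g_mu = empirical_gamma_mean(extract_peaks(glued.values))
        mms = mms_standardize(deviation_series(glued, g_mu))
        support = np.flatnonzero(mms.full_series)
        np.testing.assert_array_equal(support, np.sort(mms.spike_positions))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            float,
            st.integers(10, 60),
            elements=st.floats(0.0, 100.0, allow_nan=False),
        )
    )
    def test_spikes_always_in_unit_interval(self, dev):
        """Every spike of any non-negative deviation series lies in (0, 1]."""
        mms = mms_standardize(dev)
        assert np.all(mms.spike_values > 0.0)
        assert np.all(mms.spike_values <= 1.0)


class TestInvariances:
    def test_shuffle_invariance_of_signature(self, td_speed, partition, rng):
        """Permuting the glue order leaves peak multiset and fit unchanged."""
        ref = glue_region(td_speed, "V1", partition)
        order = tuple(rng.permutation(list(partition["V1"])))
        shuf = glue_region(td_speed, "V1", partition, order=order)
        p_ref = extract_peaks(ref.values)
        p_shuf = extract_peaks(shuf.values)
        # same multiset up to the few boundary samples at new segment joins
        ref_sorted, shuf_sorted = np.sort(p_ref.amplitudes), np.sort(p_shuf.amplitudes)
        assert abs(len(p_ref) - len(p_shuf)) <= 2 * len(partition["V1"])
        sig_ref = fit_gamma_mle(ref_sorted[ref_sorted > 0])
        sig_shuf = fit_gamma_mle(shuf_sorted[shuf_sorted > 0])
        assert sig_ref.shape == pytest.approx(sig_shuf.shape, rel=0.1)
        assert sig_ref.scale == pytest.approx(sig_shuf.scale, rel=0.1)

    @pytest.mark.parametrize("c", [0.1, 10.0])
    def test_scale_equivariance(self, td_speed, partition, c):
        """Scaling speeds by c scales the Gamma mean by c; spikes unchanged."""
        glued = glue_region(td_speed, "V3", partition)
        scaled = GluedSpeedSeries("V3", glued.landmarks, c * glued.values)
        g_mu = empirical_gamma_mean(extract_peaks(glued.values))
        g_mu_c = empirical_gamma_mean(extract_peaks(scaled.values))
        assert g_mu_c == pytest.approx(c * g_mu, rel=1e-6)
        mms = mms_standardize(deviation_series(glued, g_mu))
        mms_c = mms_standardize(deviation_series(scaled, g_mu_c))
        np.testing.assert_allclose(
            mms_c.spike_values, mms.spike_values, rtol=1e-6
        )
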