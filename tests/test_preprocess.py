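import numpy as np
import pytest
from numpy.polynomial.legendre import legval
from scipy.signal import butter, freqz

from arcsync.preprocess import (
    PreprocessConfig,
    apply_component_rejection,
    average_reference,
    bandpass,
    csd_matrix,
    csd_transform,
    detect_bad_channels,
    downsample_bin,
    interpolate_spherical,
    preprocess_cohort,
    znorm_time,
)


def fibonacci_sphere(n):
    i = np.arange(n)
    phi = np.pi * (3 - np.sqrt(5)) * i
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - z**2)
    return np.c_[r * np.cos(phi), r * np.sin(phi), z]


class TestBandpass:
    fs = 1000.0

    def _attenuation_db(self, freq):
        t = np.arange(int(self.fs * 20)) / self.fs
        x = np.sin(2 * np.pi * freq * t)[None, :]
        y = bandpass(x, self.fs)
        core = slice(int(5 * self.fs), int(15 * self.fs))  # avoid edge transients
        return 20 * np.log10(np.std(y[0, core]) / np.std(x[0, core]))

    def test_stopband_sinusoid_attenuated(self):
        assert self._attenuation_db(0.1) < -20

    def test_passband_sinusoid_preserved(self):
        # forward-backward filtering doubles the analytic magnitude response
        b, a = butter(3, [1 / 500, 40 / 500], btype="band")
        _, h = freqz(b, a, worN=[2 * np.pi * 10 / self.fs])
        expected = np.abs(h[0]) ** 2
        t = np.arange(int(self.fs * 20)) / self.fs
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        y = bandpass(x, self.fs)
        core = slice(int(5 * self.fs), int(15 * self.fs))
        ratio = np.std(y[0, core]) / np.std(x[0, core])
        assert abs(ratio - expected) < 0.05

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass(np.zeros((2, 500)), self.fs), 0)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros((1, 100)), 60.0, band_hz=(1, 40))


class TestBadChannels:
    def test_inflated_channel_flagged(self, rng):
        data = rng.standard_normal((16, 2000))
        data[5] *= 10
        assert detect_bad_channels(data) == [5]

    def test_identical_channels_yield_empty_list(self):
        data = np.tile(np.sin(np.linspace(0, 10, 500)), (5, 1))
        assert detect_bad_channels(data) == []

    def test_flat_channel_flagged_as_low_outlier(self, rng):
        data = rng.standard_normal((16, 2000))
        data[3] = 0.0
        assert detect_bad_channels(data) == [3]

    def test_too_few_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_bad_channels(rng.standard_normal((2, 100)))

    def test_labels_returned_when_given(self, rng):
        data = rng.standard_normal((16, 2000))
        data[2] *= 10
        names = [f"ch{i}" for i in range(16)]
        assert detect_bad_channels(data, channel_names=names) == ["ch2"]


class TestInterpolation:
    pos32 = fibonacci_sphere(32)

    def test_constant_field_reproduced(self):
        data = np.full((32, 10), 7.5)
        out = interpolate_spherical(data, self.pos32, bad=[4, 17])
        assert np.allclose(out, 7.5, atol=1e-6)

    def test_empty_bad_list_is_identity(self, rng):
        data = rng.standard_normal((32, 20))
        assert np.array_equal(interpolate_spherical(data, self.pos32, bad=[]), data)

    def test_smooth_field_recovered_within_tolerance(self):
        # zonal degree-2 harmonic: smooth dipolar-like field
        field = legval(self.pos32[:, 2], [0, 0, 1.0])
        data = np.tile(field[:, None], (1, 3))
        out = interpolate_spherical(data, self.pos32, bad=[10])
        err = abs(out[10, 0] - field[10])
        assert err < 0.1 * (field.max() - field.min())

    def test_too_few_good_channels_rejected(self, rng):
        data = rng.standard_normal((8, 10))
        with pytest.raises(ValueError):
            interpolate_spherical(data, fibonacci_sphere(8), bad=[0, 1, 2, 3],
                                  n_neighbors=6)


class TestCsd:
    pos = fibonacci_sphere(64)

    def test_constant_input_maps_to_zero(self):
        data = np.full((64, 5), 3.3)
        out = csd_transform(data, self.pos)
        assert np.abs(out).max() < 1e-6 * 3.3

    def test_operator_rows_sum_to_zero(self):
        T = csd_matrix(self.pos)
        assert np.abs(T.sum(axis=1)).max() < 1e-8

    @pytest.mark.parametrize("degree", [2, 3])
    def test_zonal_harmonic_is_eigenfunction(self, degree):
        """Surface Laplacian scales P_n by ~ n(n+1) on a dense montage."""
        dense = fibonacci_sphere(200)
        coeff = np.zeros(degree + 1)
        coeff[degree] = 1.0
        field = legval(dense[:, 2], coeff)
        out = csd_transform(field[:, None], dense).ravel()
        assert np.corrcoef(field, out)[0, 1] > 0.999
        scale = (out @ field) / (field @ field)
        assert abs(scale - degree * (degree + 1)) / (degree * (degree + 1)) < 0.05

    def test_duplicate_positions_rejected(self):
        bad = self.pos.copy()
        bad[1] = bad[0]
        with pytest.raises(ValueError):
            csd_matrix(bad)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            csd_matrix(fibonacci_sphere(5))


class TestDownsample:
    def test_1000hz_binned_by_5_gives_200hz_sample_count(self):
        data = np.zeros((2, 10_000))  # 10 s at 1 kHz
        out = downsample_bin(data, 5)
        assert out.shape == (2, 2000)  # 10 s at 200 Hz

    def test_constant_preserved(self):
        assert np.allclose(downsample_bin(np.full((1, 20), 4.2), 5), 4.2)

    def test_bin_means(self):
        out = downsample_bin(np.arange(1.0, 11.0)[None, :], 5)
        assert np.allclose(out, [[3.0, 8.0]])

    def test_factor_larger_than_series_rejected(self):
        with pytest.raises(ValueError):
            downsample_bin(np.zeros((1, 4)), 10)


class TestZnorm:
    def test_affine_invariance(self, rng):
        x = rng.standard_normal((3, 500))
        assert np.allclose(znorm_time(3.0 * x + 7.0), znorm_time(x))

    def test_output_moments(self, rng):
        z = znorm_time(rng.standard_normal((4, 1000)) * 5 + 2)
        assert np.abs(z.mean(axis=1)).max() < 1e-12
        assert np.abs(z.std(axis=1) - 1).max() < 1e-12

    def test_two_point_population_convention(self):
        assert np.allclose(znorm_time(np.array([[0.0, 2.0]])), [[-1.0, 1.0]])

    def test_zero_variance_channel_named(self):
        data = np.vstack([np.random.default_rng(0).standard_normal(100), np.zeros(100)])
        with pytest.raises(ValueError, match="flat"):
            znorm_time(data, channel_names=["ok", "flat"])


class TestChain:
    def test_average_reference_zeroes_cross_channel_mean(self, rng):
        out = average_reference(rng.standard_normal((6, 300)))
        assert np.abs(out.mean(axis=0)).max() < 1e-12

    def test_component_rejection_removes_chosen_source(self, rng):
        mixing = rng.standard_normal((6, 6))
        sources = rng.standard_normal((6, 400))
        data = mixing @ sources
        cleaned = apply_component_rejection(data, mixing, [2])
        kept = sources.copy()
        kept[2] = 0
        assert np.allclose(cleaned, mixing @ kept, atol=1e-8)

    def test_full_chain_preserves_alignment(self, tiny_cohort):
        cohort, _, _ = tiny_cohort
        out = preprocess_cohort(cohort, PreprocessConfig(bin_factor=5))
        assert out.data.shape == (
            cohort.n_subjects,
            cohort.n_channels,
            cohort.n_samples // 5,
        )
        assert out.fs_hz == cohort.fs_hz / 5
        assert out.channel_names == cohort.channel_names
        # final z-norm: re-running znorm is the identity
        assert np.allclose(znorm_time(out.data[0]), out.data[0])
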