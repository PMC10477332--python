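import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miqfs import (approximate_entropy, c0_complexity, decompose_bands,
                   extract_feature_matrix, higuchi_fd, hjorth, psd_mean)
from miqfs.containers import EpochSet
from miqfs.eeg_features import BAND_NAMES, DegenerateSignalError, hjorth_activity
from naive_reference import (apen_naive, c0_naive, higuchi_naive,
                             hjorth_naive, psd_mean_naive)

FS = 256.0


class TestDecomposeBands:
    def test_pure_alpha_tone_lands_in_alpha_band(self):
        t = np.arange(2560) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        bands = decompose_bands(x, FS).as_dict()
        energy = {k: float(np.sum(v ** 2)) for k, v in bands.items()}
        assert energy["alpha"] / sum(energy.values()) >= 0.90

    def test_zero_signal_gives_zero_bands(self):
        bands = decompose_bands(np.zeros(512), FS)
        for name in BAND_NAMES:
            assert np.all(getattr(bands, name) == 0.0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.sampled_from([512, 1280, 2560]))
    def test_bands_sum_to_original_epoch(self, seed, n):
        x = np.random.default_rng(seed).standard_normal(n)
        bands = decompose_bands(x, FS)
        total = sum(bands.as_dict().values())
        assert np.linalg.norm(total - x) <= 1e-8 * np.linalg.norm(x)

    def test_band_series_have_input_length(self):
        x = np.random.default_rng(0).standard_normal(640)
        for series in decompose_bands(x, FS).as_dict().values():
            assert series.shape == x.shape

    def test_too_short_epoch_errors_with_minimum(self):
        with pytest.raises(ValueError, match="64"):
            decompose_bands(np.ones(32), FS)


class TestApproximateEntropy:
    def test_constant_series_is_zero(self):
        assert approximate_entropy(np.ones(100), m=2, r=0.2) == 0.0

    def test_periodic_series_near_zero_and_matches_oracle(self):
        x = np.tile([0.0, 1.0], 50)
        val = approximate_entropy(x, m=2, r=0.1)
        assert abs(val - apen_naive(x, 2, 0.1)) <= 1e-9
        assert abs(val) < 1e-3

    def test_noise_more_entropic_than_sinusoid(self):
        n = 1024
        noise = np.random.default_rng(7).standard_normal(n)
        tone = np.sin(2 * np.pi * 5 * np.arange(n) / FS)
        apen_noise = approximate_entropy(noise, 2, 0.2 * np.std(noise))
        apen_tone = approximate_entropy(tone, 2, 0.2 * np.std(tone))
        assert apen_noise > apen_tone

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.arange(3), m=2, r=0.2)
        with pytest.raises(ValueError):
            approximate_entropy(np.arange(50), m=2, r=0.0)


class TestPsdMean:
    @pytest.mark.parametrize("x, expected", [
        ([1, 0, 0, 0], 1.0),
        ([1, 1, 1, 1], 4.0),
        (np.zeros(8), 0.0),
    ])
    def test_known_values(self, x, expected):
        assert psd_mean(x) == pytest.approx(expected, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            psd_mean([])


class TestHjorth:
    def test_ramp_activity(self):
        activity, mobility, complexity = hjorth([1, 2, 3])
        assert activity == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert mobility == 0.0 and complexity == 0.0

    def test_alternating_series_matches_oracle(self):
        x = [1.0, -1.0, 1.0, -1.0]
        assert hjorth(x) == pytest.approx(hjorth_naive(x), abs=1e-12)
        # frozen from the naive oracle under centered population variance
        assert hjorth(x)[1] == pytest.approx(np.sqrt(32.0 / 9.0), abs=1e-12)
        assert hjorth(x)[2] == pytest.approx(1.125, abs=1e-12)

    def test_constant_signal(self):
        assert hjorth_activity(np.full(10, 3.3)) == 0.0
        with pytest.raises(DegenerateSignalError):
            hjorth(np.full(10, 3.3))


class TestC0Complexity:
    def test_on_bin_sinusoid_is_fully_regular(self):
        x = np.sin(2 * np.pi * 8 * np.arange(128) / 128)
        assert c0_complexity(x) <= 1e-10

    def test_constant_nonzero_is_zero(self):
        assert c0_complexity(np.full(64, 2.0)) == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_strictly_inside_unit_interval(self):
        x = np.random.default_rng(3).standard_normal(1024)
        val = c0_complexity(x)
        assert 0.0 < val < 1.0

    def test_all_zero_errors(self):
        with pytest.raises(DegenerateSignalError):
            c0_complexity(np.zeros(16))


class TestHiguchiFd:
    def test_straight_line_dimension_one(self):
        assert higuchi_fd(np.arange(1000.0), 8) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_dimension_two(self):
        x = np.random.default_rng(11).standard_normal(4096)
        assert higuchi_fd(x, 8) == pytest.approx(2.0, abs=0.1)

    def test_scaling_invariance(self):
        x = np.random.default_rng(5).standard_normal(512)
        assert higuchi_fd(3.7 * x, 8) == pytest.approx(higuchi_fd(x, 8),
                                                       abs=1e-12)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            higuchi_fd(np.arange(50.0), 8)


@pytest.fixture(scope="module")
def short_series():
    rng = np.random.default_rng(99)
    return [rng.standard_normal(n) for n in (32, 45, 64)]


class TestAgainstNaiveOracles:
    """Vectorized/jitted features must match literal loop references."""

    def test_apen_matches(self, short_series):
        for x in short_series:
            r = 0.2 * np.std(x)
            assert abs(approximate_entropy(x, 2, r)
                       - apen_naive(x, 2, r)) <= 1e-9

    def test_psd_matches(self, short_series):
        for x in short_series:
            assert abs(psd_mean(x) - psd_mean_naive(x)) <= 1e-9

    def test_hjorth_matches(self, short_series):
        for x in short_series:
            assert np.allclose(hjorth(x), hjorth_naive(x), atol=1e-9)

    def test_c0_matches(self, short_series):
        for x in short_series:
            assert abs(c0_complexity(x) - c0_naive(x)) <= 1e-9

    def test_higuchi_matches(self, short_series):
        for x in short_series:
            assert abs(higuchi_fd(x, 3) - higuchi_naive(x, 3)) <= 1e-9


@pytest.fixture(scope="module")
def epochs():
    rng = np.random.default_rng(42)
    data = rng.standard_normal((3, 19, 512))
    return EpochSet(data=data, fs=FS, labels=[0, 1, 0])


class TestExtractFeatureMatrix:

    @pytest.mark.parametrize("families, n_cols", [
        (("PSD",), 95),
        (("CO",), 95),
        (("Hjorth",), 285),
        (("CO", "ApEn", "FD", "Hjorth", "PSD"), 665),
    ])
    def test_table_one_layout(self, epochs, families, n_cols):
        F = extract_feature_matrix(epochs, families)
        assert F.values.shape == (3, n_cols)
        assert len(set(F.names)) == n_cols

    def test_values_finite_and_names_deterministic(self, epochs):
        F1 = extract_feature_matrix(epochs, ("PSD", "CO"))
        F2 = extract_feature_matrix(epochs, ("CO", "PSD"))
        assert np.all(np.isfinite(F1.values))
        assert F1.names == F2.names  # canonical family order

    def test_degenerate_policy(self):
        data = np.zeros((1, 2, 512))
        epochs = EpochSet(data=data, fs=FS, labels=[0])
        with pytest.raises(DegenerateSignalError):
            extract_feature_matrix(epochs, ("ApEn",))
        with pytest.warns(UserWarning):
            F = extract_feature_matrix(epochs, ("ApEn",),
                                       on_degenerate="zero")
        assert np.all(F.values == 0.0)

    def test_empty_family_set_errors(self, epochs):
        with pytest.raises(ValueError):
            extract_feature_matrix(epochs, ())
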