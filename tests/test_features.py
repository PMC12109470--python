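"""Feature estimators against brute-force oracles and analytic limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegmdd import (
    BANDS_STANDARD,
    FEATURE_CATEGORIES,
    FEATURE_NAMES,
    band_powers,
    build_feature_table,
    c0_complexity,
    center_frequencies,
    epoch_recording,
    feature_vector,
    higuchi_fd,
    hurst_rs,
    qc_epochs,
    sample_entropy,
    shannon_entropy,
    temporal_stats,
    tf_energy,
    welch_psd,
)
from eegmdd.features import _sampen_pair_counts, higuchi_curve_lengths
from conftest import clean_effect, quick_cohort_table


# ---------------------------------------------------------------------------
# Independent oracles (pure numpy, no shared code with the implementation)
# ---------------------------------------------------------------------------

def sampen_counts_oracle(x, m, r):
    """Exhaustive pair enumeration over embedding templates."""
    n = len(x)
    tm = np.array([x[i:i + m] for i in range(n - m)])
    tm1 = np.array([x[i:i + m + 1] for i in range(n - m)])
    A = B = 0
    for i in range(len(tm)):
        for j in range(i + 1, len(tm)):
            if np.max(np.abs(tm[i] - tm[j])) <= r:
                B += 1
            if np.max(np.abs(tm1[i] - tm1[j])) <= r:
                A += 1
    return A, B


def higuchi_lengths_oracle(x, kmax):
    """Direct summation of the curve-length definition (1-indexed m)."""
    x = np.asarray(x, float)
    n = len(x)
    out = []
    for k in range(1, kmax + 1):
        lm = []
        for m in range(1, k + 1):
            nseg = (n - m) // k
            total = sum(
                abs(x[m - 1 + i * k] - x[m - 1 + (i - 1) * k])
                for i in range(1, nseg + 1)
            )
            lm.append(total * (n - 1) / (nseg * k) / k if nseg >= 1 else 0.0)
        out.append(np.mean(lm))
    return np.array(out)


# ---------------------------------------------------------------------------
# Oracle equivalence (property-based)
# ---------------------------------------------------------------------------

@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    data=st.lists(st.floats(-1e3, 1e3, allow_nan=False, width=32),
                  min_size=12, max_size=100),
    m=st.integers(1, 3),
    r_factor=st.floats(0.05, 0.8),
)
def test_sample_entropy_matches_bruteforce_oracle(data, m, r_factor):
    x = np.asarray(data, float)
    sd = x.std()
    r = r_factor * sd if sd > 0 else 0.1
    A, B = _sampen_pair_counts(np.ascontiguousarray(x), m, r)
    A_o, B_o = sampen_counts_oracle(x, m, r)
    assert (A, B) == (A_o, B_o)
    if A > 0 and B > 0:
        assert sample_entropy(x, m=m, r=r) == pytest.approx(
            -math.log(A_o / B_o), abs=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    data=st.lists(st.floats(-1e3, 1e3, allow_nan=False, width=32),
                  min_size=20, max_size=100),
    kmax=st.integers(2, 8),
)
def test_higuchi_lengths_match_direct_summation(data, kmax):
    x = np.asarray(data, float)
    if len(x) < 2 * kmax:
        kmax = len(x) // 2
    np.testing.assert_allclose(
        higuchi_curve_lengths(x, kmax), higuchi_lengths_oracle(x, kmax),
        rtol=0, atol=1e-10)


# ---------------------------------------------------------------------------
# Analytic limits
# ---------------------------------------------------------------------------

class TestAnalyticLimits:
    def test_constant_series_limits(self):
        x = np.full(512, 3.0)
        assert sample_entropy(x, m=2, r=0.2) == 0.0
        assert shannon_entropy(x) == 0.0
        assert higuchi_fd(x) == 1.0
        assert hurst_rs(x) == 0.5

    def test_straight_line_is_one_dimensional(self):
        x = np.linspace(0.0, 1.0, 2048)
        assert higuchi_fd(x) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_dimension_near_two(self):
        vals = [higuchi_fd(np.random.default_rng(s).standard_normal(4096))
                for s in range(20)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.1)

    def test_white_noise_hurst_near_half(self):
        vals = [hurst_rs(np.random.default_rng(s).standard_normal(8192))
                for s in range(20)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.1)

    def test_random_walk_is_persistent(self):
        vals = [
            hurst_rs(np.cumsum(np.random.default_rng(s).standard_normal(8192)))
            for s in range(20)
        ]
        assert np.mean(vals) >= 0.85

    def test_noise_more_entropic_than_tone(self):
        t = np.arange(2048) / 256.0
        tone = np.sin(2 * np.pi * 10 * t)
        tone *= 1.0 / tone.std()
        for s in range(20):
            noise = np.random.default_rng(s).standard_normal(2048)
            se_n = sample_entropy(noise, m=2, r=0.2 * noise.std())
            se_t = sample_entropy(tone, m=2, r=0.2 * tone.std())
            assert se_n > se_t

    def test_pure_tone_concentrates_in_alpha(self):
        t = np.arange(32 * 256) / 256.0
        x = np.sin(2 * np.pi * 10 * t)
        psd = welch_psd(x, 256.0)
        _, _, rel = band_powers(psd, BANDS_STANDARD)
        assert rel["alpha"] >= 0.95
        centroid, argmax = center_frequencies(psd)
        assert centroid == pytest.approx(10.0, abs=0.5)
        assert argmax == pytest.approx(10.0, abs=0.25)


# ---------------------------------------------------------------------------
# Spectral details
# ---------------------------------------------------------------------------

class TestSpectral:
    def test_white_noise_total_power_matches_variance(self):
        # Parseval consistency, averaged over seeds
        ratios = []
        for s in range(20):
            x = np.random.default_rng(s).standard_normal(32 * 256)
            psd = welch_psd(x, 256.0)
            total = band_powers(psd)[1]
            ratios.append(total / x.var())
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_equal_tones_give_symmetric_band_powers(self):
        t = np.arange(32 * 256) / 256.0
        x = np.sin(2 * np.pi * 6 * t) + np.sin(2 * np.pi * 25 * t)
        _, _, rel = band_powers(welch_psd(x, 256.0))
        assert rel["theta"] == pytest.approx(rel["beta2"], rel=0.10)

    def test_relative_powers_sum_below_one(self):
        x = np.random.default_rng(3).standard_normal(16 * 256)
        _, _, rel = band_powers(welch_psd(x, 256.0))
        assert 0 < sum(rel.values()) <= 1 + 1e-9

    def test_centroid_of_two_equal_lines(self):
        t = np.arange(64 * 256) / 256.0
        x = np.sin(2 * np.pi * 8 * t) + np.sin(2 * np.pi * 12 * t)
        centroid, _ = center_frequencies(welch_psd(x, 256.0))
        assert centroid == pytest.approx(10.0, abs=0.5)

    def test_argmax_tie_breaks_low(self):
        from eegmdd import PSDEstimate

        psd = PSDEstimate(freqs=np.array([1.0, 2.0, 3.0]),
                          power=np.array([5.0, 1.0, 5.0]),
                          segment_length=4, hop=2, n_segments=1)
        _, argmax = center_frequencies(psd)
        assert argmax == 1.0

    def test_signal_shorter_than_segment_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(np.zeros(100), 256.0, segment_seconds=4.0)


class TestTemporal:
    def test_peak_is_max_abs(self):
        assert temporal_stats(np.array([1.0, -5.0, 3.0, 4.0]))[2] == 5.0

    def test_normal_sample_moments(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        skew, kurt, _, flag = temporal_stats(x)
        assert abs(skew) <= 0.1
        assert abs(kurt) <= 0.2
        assert not flag

    def test_constant_series_flagged(self):
        skew, kurt, peak, flag = temporal_stats(np.full(100, 2.5))
        assert (skew, kurt, peak) == (0.0, 0.0, 2.5)
        assert flag


class TestEntropy:
    def test_square_wave_entropy_ln2(self):
        x = np.tile([1.0, -1.0], 256)
        assert shannon_entropy(x, n_bins=16) == pytest.approx(math.log(2))

    def test_uniform_bins_reach_maximum(self):
        n_bins = 32
        x = np.repeat(np.arange(n_bins, dtype=float), 8)
        assert shannon_entropy(x, n_bins=n_bins) == pytest.approx(
            math.log(n_bins))


class TestC0:
    def test_unit_tone_literal_amplitude_one(self):
        t = np.arange(1024) / 256.0
        x = np.sin(2 * np.pi * 16 * t)  # grid frequency for N=1024
        assert c0_complexity(x, "paper_literal") == pytest.approx(1.0,
                                                                  abs=1e-6)

    def test_pure_tone_standard_mode_regular(self):
        t = np.arange(1024) / 256.0
        x = np.sin(2 * np.pi * 16 * t)
        assert c0_complexity(x, "standard") <= 0.01

    def test_zero_signal_both_modes(self):
        z = np.zeros(64)
        assert c0_complexity(z, "paper_literal") == 0.0
        assert c0_complexity(z, "standard") == 0.0


class TestTFEnergy:
    def test_zero_signal(self):
        assert tf_energy(np.zeros(1024), 256.0) == (0.0, 0.0)

    def test_quadratic_scaling(self):
        x = np.random.default_rng(1).standard_normal(2048)
        m1, x1 = tf_energy(x, 256.0)
        m2, x2 = tf_energy(3.0 * x, 256.0)
        assert m2 == pytest.approx(9.0 * m1, rel=1e-9)
        assert x2 == pytest.approx(9.0 * x1, rel=1e-9)

    def test_stationary_tone_max_stable_across_windows(self):
        from scipy.signal import spectrogram

        t = np.arange(8 * 256) / 256.0
        x = np.sin(2 * np.pi * 10 * t)
        _, _, sxx = spectrogram(x, fs=256.0, window="hann", nperseg=256,
                                noverlap=128, detrend=False, mode="psd")
        per_window_max = sxx.max(axis=0)
        assert per_window_max.max() <= 1.1 * per_window_max.min()


# ---------------------------------------------------------------------------
# Scale behaviour and assembly
# ---------------------------------------------------------------------------

class TestScaleBehaviour:
    def test_scale_invariant_and_covariant_features(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(2048) + 0.3 * np.sin(
            2 * np.pi * 10 * np.arange(2048) / 256.0)
        c = 7.0
        f1 = feature_vector(x, 256.0)
        f2 = feature_vector(c * x, 256.0)
        for name in ("skewness", "kurtosis", "sample_entropy", "higuchi_fd",
                     "hurst", "shannon_entropy", "center_freq_relative",
                     "center_freq_absolute"):
            assert f2[name] == pytest.approx(f1[name], rel=1e-6, abs=1e-9), name
        assert f2["peak"] == pytest.approx(c * f1["peak"], rel=1e-9)
        for name in ("total_power", "alpha_power", "mean_tf_energy",
                     "max_tf_energy"):
            assert f2[name] == pytest.approx(c ** 2 * f1[name], rel=1e-9), name

    def test_relative_band_powers_scale_invariant(self):
        x = np.random.default_rng(6).standard_normal(2048)
        rel1 = band_powers(welch_psd(x, 256.0))[2]
        rel2 = band_powers(welch_psd(5 * x, 256.0))[2]
        for band in rel1:
            assert rel2[band] == pytest.approx(rel1[band], rel=1e-9)


class TestFeatureTable:
    def test_schema_decomposition(self):
        assert len(FEATURE_NAMES) == 19
        assert [len(v) for v in FEATURE_CATEGORIES.values()] == [9, 3, 5, 2]

    def test_table_has_95_columns(self):
        table = quick_cohort_table(1, 1, seed=3, effect=clean_effect(),
                                   duration=9.0, window=8.0)
        assert table.n_features == 95
        assert table.n_rows == 2  # one retained epoch per subject

    def test_identical_epochs_give_identical_rows(self):
        from eegmdd import Recording

        rng = np.random.default_rng(8)
        sig = rng.standard_normal(8 * 128) * 5
        data = np.tile(sig, (19, 1))
        from eegmdd import STANDARD_CHANNELS

        rec = Recording("s", "HC", 128.0, list(STANDARD_CHANNELS), data)
        eps = qc_epochs(epoch_recording(rec, 8.0, 1.0))
        table = build_feature_table([eps])
        row = table.values.iloc[0]
        # all channels identical → every region's feature equals every
        # other region's (mean of identical per-channel values)
        for feat in FEATURE_NAMES:
            vals = [row[f"{region}__{feat}"]
                    for region in ("Frontal", "Central", "Left Temporal")]
            assert max(vals) == pytest.approx(min(vals), rel=1e-12)

    def test_missing_region_channel_is_named(self):
        from eegmdd import Recording

        rec = Recording("s", "HC", 128.0, ["Fp1", "Fp2", "F3"],
                        np.random.default_rng(0).standard_normal((3, 1024)))
        eps = epoch_recording(rec, 8.0, 1.0)
        with pytest.raises(ValueError, match="F4"):
            build_feature_table([eps])

    def test_determinism(self):
        t1 = quick_cohort_table(1, 1, seed=4, effect=clean_effect(),
                                duration=9.0, window=8.0)
        t2 = quick_cohort_table(1, 1, seed=4, effect=clean_effect(),
                                duration=9.0, window=8.0)
        np.testing.assert_array_equal(t1.X(), t2.X())
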