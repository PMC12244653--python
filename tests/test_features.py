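"""Feature library contracts: closed-form and brute-force oracles,
invariance properties, validity filtering, robust sigmoid scaling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from flywake import SynthConfig, generate_epoch, generate_study
from flywake import features as F
from flywake.synth import EpochSet

finite_series = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=10, max_size=60
).map(np.array).filter(lambda x: np.std(x) > 1e-6)


def brute_ac(x, k):
    """Independent autocorrelation oracle: explicit sum form."""
    x = np.asarray(x, float)
    d = x - x.mean()
    return sum(d[t] * d[t + k] for t in range(len(x) - k)) / sum(d * d)


class TestAcLag:
    def test_lag_zero_is_one(self, rng):
        assert F.ac_lag(rng.normal(size=50), 0) == 1.0

    def test_alternating_closed_form(self):
        x = np.tile([1.0, -1.0], 5)
        assert F.ac_lag(x, 1) == pytest.approx(-0.9)   # -(N-1)/N

    def test_constant_is_missing(self):
        assert math.isnan(F.ac_lag(np.full(20, 3.0), 1))

    @given(finite_series, st.integers(1, 5))
    def test_matches_brute_force(self, x, k):
        assert F.ac_lag(x, k) == pytest.approx(brute_ac(x, k), abs=1e-9)

    @given(finite_series)
    def test_affine_invariance(self, x):
        assert F.ac_lag(2.5 * x + 7, 2) == pytest.approx(F.ac_lag(x, 2),
                                                         abs=1e-8)

    def test_ar1_closed_form(self, rng):
        acs = [F.ac_lag(generate_epoch(30.0, 1.0, 2250, 1000.0, rng), 30)
               for _ in range(150)]
        assert np.mean(acs) == pytest.approx(math.exp(-1), abs=0.05)


class TestStatAv:
    def test_hand_oracle(self):
        assert F.statav_local(np.array([0.0, 0, 2, 2]), 2) == \
            pytest.approx(math.sqrt(6) / 2)

    def test_iid_noise_well_below_one(self, rng):
        vals = [F.statav_local(rng.normal(size=5000), 250) for _ in range(10)]
        assert np.mean(vals) < 0.25    # ~ window_len^-0.5 scale

    def test_drifting_mean_exceeds_stationary(self, rng):
        base = rng.normal(size=2000)
        drift = base + np.linspace(0, 20, 2000)
        assert F.statav_local(drift, 250) > F.statav_local(base, 250)

    def test_constant_missing(self):
        assert math.isnan(F.statav_local(np.zeros(1000), 250))


class TestDistributionStats:
    def test_hand_values(self):
        assert F.distribution_stats(np.array([3.0, -3.0]))["rms"] == 3.0
        assert F.distribution_stats(np.array([1.0, 2, 3]))[
            "standard_deviation"] == pytest.approx(1.0)

    def test_gaussian_kurtosis(self, rng):
        m4 = F.distribution_stats(rng.normal(size=200_000))["moment_4"]
        assert m4 == pytest.approx(3.0, abs=0.1)

    @given(finite_series)
    def test_rms_scales_sd_translates(self, x):
        d = F.distribution_stats(x)
        d2 = F.distribution_stats(2 * x)
        assert d2["rms"] == pytest.approx(2 * d["rms"], rel=1e-9)
        d3 = F.distribution_stats(x + 5)
        assert d3["standard_deviation"] == pytest.approx(
            d["standard_deviation"], rel=1e-9)


class TestPoincare:
    def test_constant_zero(self):
        out = F.poincare_sd(np.zeros(10))
        assert out["sd1"] == 0.0 and out["sd2"] == 0.0

    def test_alternating_hand_oracle(self):
        x = np.tile([0.0, 1.0], 5)          # diffs alternate +-1
        diffs = (x[1:] - x[:-1]) / math.sqrt(2)
        assert F.poincare_sd(x)["sd1"] == pytest.approx(np.std(diffs, ddof=1))

    def test_iid_both_near_sigma(self, rng):
        x = rng.normal(0, 2.0, 100_000)
        out = F.poincare_sd(x)
        assert out["sd1"] == pytest.approx(2.0, rel=0.02)
        assert out["sd2"] == pytest.approx(2.0, rel=0.02)


class TestSpectral:
    def test_sinusoid_concentrated_low_band(self):
        t = np.arange(4096) / 1000.0
        x = np.sin(2 * np.pi * 10 * t)
        out = F.spectral_summaries(x, 1000.0, n_bands=2)
        total = out["band_area_1_of_2"] + out["band_area_2_of_2"]
        assert out["band_area_1_of_2"] >= 0.99 * total

    def test_white_noise_median_edge_near_half_nyquist(self, rng):
        vals = [F.spectral_summaries(rng.normal(size=8192), 1000.0,
                                     edge_percents=(50,))["edge_freq_50"]
                for _ in range(10)]
        assert np.mean(vals) == pytest.approx(250.0, rel=0.1)

    def test_amplitude_scaling_law(self, rng):
        x = rng.normal(size=2250)
        a = F.spectral_summaries(x, 1000.0)
        b = F.spectral_summaries(2 * x, 1000.0)
        assert b["band_area_1_of_2"] == pytest.approx(
            4 * a["band_area_1_of_2"], rel=1e-9)
        assert b["log_band_area_1_of_2"] == pytest.approx(
            a["log_band_area_1_of_2"] + math.log(4), abs=1e-9)
        for pc in (5, 10, 25, 95):
            assert b[f"edge_freq_{pc}"] == a[f"edge_freq_{pc}"]

    def test_zero_signal_missing_log_and_edge(self):
        out = F.spectral_summaries(np.zeros(256), 1000.0)
        assert math.isnan(out["log_band_area_1_of_2"])
        assert math.isnan(out["edge_freq_95"])


class TestEntropyComplexity:
    def test_periodic_lz_decreases_with_length(self):
        vals = [F.lz_complexity(np.tile([0.0, 1.0], n)) for n in (64, 256, 1024)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 0.1

    def test_fair_coin_lz_near_one(self, rng):
        x = rng.integers(0, 2, 8192).astype(float)
        assert F.lz_complexity(x) == pytest.approx(1.0, abs=0.1)

    def test_monotone_perm_entropy_zero(self):
        assert F.perm_entropy(np.arange(100.0)) == 0.0

    def test_perm_entropy_iid_near_one(self, rng):
        assert F.perm_entropy(rng.normal(size=50_000)) == \
            pytest.approx(1.0, abs=0.01)

    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=10,
                    max_size=60, unique=True).map(np.array)
           .filter(lambda x: np.diff(np.sort(x)).min() > 1e-4 * np.ptp(x)))
    def test_perm_entropy_affine_invariance(self, x):
        """Ordinal patterns, hence the entropy, survive a positive affine
        map (given values separated enough that the map preserves order
        in floating point)."""
        assert F.perm_entropy(3 * x + 1) == pytest.approx(F.perm_entropy(x))

    def test_constant_conventions(self):
        c = np.full(300, 2.0)
        assert math.isnan(F.sample_entropy(c))
        assert math.isnan(F.approx_entropy(c))
        assert F.perm_entropy(c) == 0.0
        assert F.lz_complexity(c) < 0.1

    def test_sampen_regular_vs_random(self, rng):
        t = np.arange(500)
        regular = np.sin(2 * np.pi * t / 50)
        random = rng.normal(size=500)
        assert F.sample_entropy(regular) < F.sample_entropy(random)

    def test_apen_regular_vs_random(self, rng):
        t = np.arange(500)
        regular = np.sin(2 * np.pi * t / 50)
        random = rng.normal(size=500)
        assert F.approx_entropy(regular) < F.approx_entropy(random)

    def test_sampen_matches_naive_oracle(self, rng):
        """Brute-force O(N^2) re-count of matching template pairs."""
        x = rng.normal(size=120)
        m, r = 2, 0.2 * np.std(x, ddof=1)

        def naive_count(mm):
            n = len(x) - mm + 1
            tot = 0
            for i in range(n):
                for j in range(n):
                    if i != j and max(abs(x[i + k] - x[j + k])
                                      for k in range(mm)) <= r:
                        tot += 1
            return tot

        b = naive_count(2)        # templates of length m over x[:-1]
        # match definition: B excludes the last point so A and B use the
        # same template count
        n1 = len(x) - 1
        b = 0
        for i in range(n1 - m + 1):
            for j in range(n1 - m + 1):
                if i != j and max(abs(x[i + k] - x[j + k])
                                  for k in range(m)) <= r:
                    b += 1
        a = naive_count(m + 1)
        expected = -math.log(a / b)
        assert F.sample_entropy(x, m, r) == pytest.approx(expected, abs=1e-9)


class TestLocalExtrema:
    def test_constant_zero(self):
        assert F.local_extrema_stats(np.zeros(200), 50)["stdmax"] == 0.0

    def test_spike_monotonicity(self, rng):
        x = rng.normal(0, 0.1, 200)
        spiked = x.copy()
        spiked[25] += 10.0
        assert F.local_extrema_stats(spiked, 50)["stdmax"] > \
            F.local_extrema_stats(x, 50)["stdmax"]

    def test_four_window_brute_force(self):
        x = np.arange(8.0)
        out = F.local_extrema_stats(x, 2)
        maxima = [1.0, 3.0, 5.0, 7.0]
        assert out["stdmax"] == pytest.approx(np.std(maxima, ddof=1))
        assert out["meanmin"] == pytest.approx(np.mean([0.0, 2, 4, 6]))


class TestBoxCorrDim:
    def test_line_segment_dimension_one(self, rng):
        x = np.linspace(0, 1, 2250) + rng.normal(0, 1e-4, 2250)
        assert F.box_corr_dim(x, delay=5) == pytest.approx(1.0, abs=0.3)

    def test_iid_noise_fills_embedding(self, rng):
        assert F.box_corr_dim(rng.uniform(size=2250)) > 2.0

    def test_two_delays_both_finite(self, rng):
        x = np.sin(2 * np.pi * np.arange(2250) / 100) + \
            rng.normal(0, 0.01, 2250)
        for delay in (3, 11):
            assert np.isfinite(F.box_corr_dim(x, delay=delay))

    def test_slow_acf_returns_missing(self):
        assert math.isnan(F.box_corr_dim(np.linspace(0, 1, 2250)))


class TestRegistryAndMatrix:
    PAPER_NAMES = [
        "AC_29", "AC_30", "AC_31", "AC_32", "AC_33", "AC_34",
        "StatAvl250", "rms", "standard_deviation", "DN_Moments_raw_4",
        "MD_rawHRVmeas_SD1", "MD_rawHRVmeas_SD2",
        "SP_Summaries_welch_rect_logarea_2_1", "SP_Summaries_fft_area_5_1",
        "SP_Summaries_welch_wmax_5", "SP_Summaries_welch_wmax_95",
        "EN_SampEn", "EN_PermEn", "EN_MS_LZcomplexity", "ApEn",
        "ST_LocalExtrema_n50_stdmax", "NL_BoxCorrDim_50_ac_5_minr13",
    ]

    def test_registry_covers_reported_features(self):
        names = {d.name for d in F.default_registry()}
        missing = set(self.PAPER_NAMES) - names
        assert not missing

    def test_registry_determinism(self, rng):
        x = rng.normal(size=2250)
        for fdef in F.fast_registry():
            assert fdef.compute(x, 1000.0) == fdef.compute(x, 1000.0)

    def _tiny_epochset(self, data):
        n = len(data)
        meta = pd.DataFrame({
            "dataset_id": ["d"] * n, "fly_id": ["f"] * n,
            "condition": ["wake"] * n, "channel": [1] * n,
            "epoch": range(n)})
        return EpochSet(np.asarray(data, float), meta, 1000.0)

    def test_mean_feature_matrix(self):
        mean_def = F.FeatureDef("epoch_mean", "distribution",
                                lambda x, fs: float(np.mean(x)))
        es = self._tiny_epochset([[1.0] * 10, [2.0] * 10, [3.0] * 10])
        fm = F.extract_matrix(es, [mean_def])
        assert list(fm.values["epoch_mean"]) == [1.0, 2.0, 3.0]

    def test_constant_feature_invalid(self):
        const_def = F.FeatureDef("always_7", "distribution",
                                 lambda x, fs: 7.0)
        es = self._tiny_epochset(np.random.default_rng(0).normal(size=(4, 30)))
        fm = F.extract_matrix(es, [const_def])
        assert not fm.validity.loc[1, "always_7"]

    def test_all_nan_feature_invalid(self):
        nan_def = F.FeatureDef("broken", "distribution",
                               lambda x, fs: math.nan)
        es = self._tiny_epochset(np.random.default_rng(0).normal(size=(4, 30)))
        fm = F.extract_matrix(es, [nan_def])
        assert not fm.validity.loc[1, "broken"]

    def test_varying_feature_valid_and_inf_propagated(self):
        def spiky(x, fs):
            return math.inf if x[0] > 0 else float(x[0])
        es = self._tiny_epochset([[1.0] * 10, [-2.0] * 10, [3.0] * 10])
        fm = F.extract_matrix(es, [F.FeatureDef("spiky", "distribution",
                                                spiky)])
        assert fm.validity.loc[1, "spiky"]
        assert np.isposinf(fm.values["spiky"].iloc[0])


class TestRobustSigmoid:
    def test_reference_median_maps_to_half_before_rescale(self, rng):
        ref = rng.normal(size=1001)
        m = np.median(ref)
        out = F.robust_sigmoid_scale(np.array([m]), ref)
        # after min-max by reference range, the median sits mid-range-ish
        assert 0.3 < out[0] < 0.7

    def test_self_scaling_spans_unit_interval(self, rng):
        ref = rng.normal(size=100)
        out = F.robust_sigmoid_scale(ref, ref)
        assert out.min() == 0.0 and out.max() == 1.0
        assert ((out >= 0) & (out <= 1)).all()

    def test_extreme_outlier_clipped_to_upper_bound(self, rng):
        ref = rng.normal(size=100)
        q = np.subtract(*np.percentile(ref, [75, 25]))
        v = np.array([np.median(ref) + 1000 * q])
        out = F.robust_sigmoid_scale(v, ref)
        assert out[0] <= 1.0 and out[0] > 0.95

    def test_zero_iqr_flags_missing(self):
        out = F.robust_sigmoid_scale(np.array([1.0, 2.0]), np.full(10, 5.0))
        assert np.isnan(out).all()

    @given(finite_series)
    def test_monotone_in_values(self, ref):
        v = np.sort(ref)
        out = F.robust_sigmoid_scale(v, ref)
        if np.isnan(out).all():            # zero-IQR reference is flagged
            assert np.subtract(*np.percentile(ref, [75, 25])) == 0.0
        else:
            assert (np.diff(out) >= -1e-12).all()
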