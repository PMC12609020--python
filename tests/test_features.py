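"""Per-IMF features, band aggregation and statistical screening."""

import numpy as np
import pandas as pd
import pytest

from vagdfa import features
from vagdfa.dfa import DualScalingFit


def _fit(bp_ratio=0.1, alpha1=0.6, alpha2=0.8):
    return DualScalingFit(
        alpha1=alpha1, alpha2=alpha2, r2_1=0.95, r2_2=0.95,
        bp_index=5, bp_scale=100.0, bp_ratio=bp_ratio, rss_total=0.0,
    )


class TestCentroidFrequency:
    def test_pure_tone(self):
        t = np.arange(8192) / 1000.0
        cf = features.centroid_frequency(np.sin(2 * np.pi * 100 * t), 1000.0)
        assert abs(cf - 100.0) < 2.0

    def test_equal_power_two_tones_average(self):
        t = np.arange(8192) / 1000.0
        x = np.sin(2 * np.pi * 100 * t) + np.sin(2 * np.pi * 300 * t)
        assert abs(features.centroid_frequency(x, 1000.0) - 200.0) < 5.0

    def test_white_noise_centroid_at_half_nyquist(self):
        cfs = [
            features.centroid_frequency(np.random.default_rng(s).standard_normal(2**13), 1000.0)
            for s in range(20)
        ]
        assert abs(np.mean(cfs) - 250.0) < 10.0

    def test_all_zero_flagged_non_finite(self):
        assert np.isnan(features.centroid_frequency(np.zeros(1024), 1000.0))


class TestMeanInstantaneousFrequency:
    def test_pure_tone(self):
        t = np.arange(4096) / 1000.0
        mif = features.mean_instantaneous_frequency(np.sin(2 * np.pi * 50 * t), 1000.0)
        assert abs(mif - 50.0) < 1.0

    def test_linear_chirp_mean(self):
        from scipy.signal import chirp

        fs, dur = 1000.0, 4.0
        t = np.arange(int(fs * dur)) / fs
        x = chirp(t, f0=10, f1=110, t1=dur, method="linear")
        mif = features.mean_instantaneous_frequency(x, fs)
        assert abs(mif - 60.0) < 3.0

    def test_amplitude_modulated_carrier(self):
        fs = 1000.0
        t = np.arange(8192) / fs
        x = (1 + 0.1 * np.sin(2 * np.pi * 2 * t)) * np.sin(2 * np.pi * 80 * t)
        mif = features.mean_instantaneous_frequency(x, fs)
        assert abs(mif - 80.0) < 3.0

    def test_all_zero_flagged_non_finite(self):
        assert np.isnan(features.mean_instantaneous_frequency(np.zeros(1024), 1000.0))


class TestEnergy:
    def test_toy_vector(self):
        assert features.energy(np.array([1.0, 2.0, 3.0])) == 14.0

    def test_zeros(self):
        assert features.energy(np.zeros(10)) == 0.0

    def test_concatenation_additivity(self, rng):
        x, y = rng.standard_normal(100), rng.standard_normal(50)
        assert np.isclose(
            features.energy(np.r_[x, y]), features.energy(x) + features.energy(y)
        )


class TestBandAggregation:
    def test_band_membership_by_index_only(self):
        assert [features.band_of_imf(i) for i in range(1, 11)] == (
            ["high"] * 3 + ["mid"] * 3 + ["low"] * 4
        )
        with pytest.raises(ValueError):
            features.band_of_imf(11)

    def test_identical_rows_give_common_value(self):
        rows = [
            features.ImfFeatureRow(i, 100.0, 90.0, 5.0, features.band_of_imf(i))
            for i in range(1, 11)
        ]
        fits = [_fit(bp_ratio=0.2)] * 10
        vec = features.aggregate_band_features(rows, fits)
        assert np.allclose(vec, [100, 90, 5, 0.2] * 3)

    def test_band_mean_of_energies(self):
        rows = [
            features.ImfFeatureRow(i, 0.0, 0.0, float(i), features.band_of_imf(i))
            for i in range(1, 11)
        ]
        vec = features.aggregate_band_features(rows, [_fit()] * 10)
        assert vec[features.FEATURE_NAMES.index("high_E")] == 2.0  # mean of 1,2,3

    def test_permutation_within_band_invariant(self):
        rows = [
            features.ImfFeatureRow(i, float(10 * i), 1.0, 1.0, features.band_of_imf(i))
            for i in range(1, 11)
        ]
        fits = [_fit()] * 10
        v1 = features.aggregate_band_features(rows, fits)
        v2 = features.aggregate_band_features(rows[::-1], fits)
        assert np.allclose(v1, v2)

    def test_all_missing_band_flagged_nan(self):
        rows = [
            features.ImfFeatureRow(
                i, float("nan") if i <= 3 else 1.0, 1.0, 1.0, features.band_of_imf(i)
            )
            for i in range(1, 11)
        ]
        vec = features.aggregate_band_features(rows, [_fit()] * 10)
        assert np.isnan(vec[features.FEATURE_NAMES.index("high_CF")])


class TestLilliefors:
    def test_type1_error_near_nominal(self):
        """Rejection rate at 0.05 on normal data: 0.05 +- 0.02 (desk-scale reps)."""
        rng = np.random.default_rng(0)
        rejections = sum(
            features.lilliefors_test(rng.standard_normal(50), mc_reps=400,
                                     seed=int(rng.integers(2**31))) < 0.05
            for _ in range(200)
        )
        assert abs(rejections / 200 - 0.05) <= 0.03

    def test_power_against_exponential(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            features.lilliefors_test(rng.exponential(size=100), mc_reps=400,
                                     seed=int(rng.integers(2**31))) < 0.05
            for _ in range(50)
        )
        assert rejections / 50 >= 0.9

    def test_agrees_with_statsmodels_reference(self):
        """Cross-check p-values against the table-based reference implementation."""
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        rng = np.random.default_rng(2)
        for sample in (rng.standard_normal(80), rng.exponential(size=80)):
            p_mc = features.lilliefors_test(sample, mc_reps=4000, seed=3)
            _, p_sm = sm_lilliefors(sample, dist="norm")
            assert (p_mc < 0.05) == (p_sm < 0.05) or abs(p_mc - p_sm) < 0.05

    def test_p_monotone_in_distance(self):
        """More non-normal sample (larger KS distance) -> smaller p, same null."""
        rng = np.random.default_rng(3)
        base = rng.standard_normal(60)
        skewed = np.exp(rng.standard_normal(60))
        assert features.lilliefors_test(skewed, 2000, seed=5) <= features.lilliefors_test(
            base, 2000, seed=5
        )

    def test_zero_variance_flagged(self):
        assert np.isnan(features.lilliefors_test(np.full(10, 2.0), seed=0))


class TestMannWhitney:
    def test_exact_enumeration_small_sample(self):
        u, p = features.mann_whitney_u(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert u in (0.0, 9.0)
        assert np.isclose(p, 0.1)

    def test_identical_samples_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert features.mann_whitney_u(a, a.copy())[1] == 1.0

    def test_label_swap_symmetry(self, rng):
        a, b = rng.standard_normal(20), rng.standard_normal(25) + 0.5
        u_ab, p_ab = features.mann_whitney_u(a, b)
        u_ba, p_ba = features.mann_whitney_u(b, a)
        assert np.isclose(u_ab + u_ba, a.size * b.size)
        assert np.isclose(p_ab, p_ba)

    def test_brute_force_enumeration_oracle(self):
        """Exact p equals enumeration over all label assignments (n small)."""
        from itertools import combinations
        from scipy.stats import rankdata

        a = np.array([0.3, 1.7, 2.2, 0.9])
        b = np.array([2.5, 3.1, 1.1])
        u_obs, p_obs = features.mann_whitney_u(a, b)
        pooled = np.r_[a, b]
        ranks = rankdata(pooled)
        n_a = a.size

        def u_of(idx):
            r = ranks[list(idx)].sum()
            return r - n_a * (n_a + 1) / 2

        us = [u_of(c) for c in combinations(range(pooled.size), n_a)]
        # two-sided: distance from the mean of the null U distribution
        mu = a.size * b.size / 2
        extreme = sum(abs(u - mu) >= abs(u_obs - mu) - 1e-9 for u in us)
        assert np.isclose(p_obs, extreme / len(us))


class TestScreening:
    def test_planted_feature_kept_noise_near_alpha(self):
        rng = np.random.default_rng(0)
        kept_planted, noise_kept, noise_total = 0, 0, 0
        n_runs = 40
        for _ in range(n_runs):
            n = 40
            data = {name: rng.standard_normal(2 * n) for name in features.FEATURE_NAMES}
            group = np.array(["HC"] * n + ["OA"] * n)
            data["mid_E"][group == "OA"] += 1.0
            table = pd.DataFrame({**data, "group": group})
            scr = features.screen_features(table, mc_reps=50, seed=int(rng.integers(2**31)))
            kept = dict(zip(scr["feature"], scr["kept"]))
            kept_planted += kept["mid_E"]
            for name in features.FEATURE_NAMES:
                if name != "mid_E":
                    noise_kept += kept[name]
                    noise_total += 1
        assert kept_planted / n_runs >= 0.95
        assert noise_kept / noise_total < 0.12

    def test_kept_iff_mw_p_below_alpha(self):
        rng = np.random.default_rng(1)
        data = {name: rng.standard_normal(60) for name in features.FEATURE_NAMES}
        group = np.array(["HC"] * 30 + ["OA"] * 30)
        data["high_CF"][group == "OA"] += 2.0
        table = pd.DataFrame({**data, "group": group})
        scr = features.screen_features(table, mc_reps=50, seed=2)
        assert (scr["kept"] == (scr["mw_p"] < 0.05)).all()
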