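"""Dual-scaling DFA: profile, fluctuation, window grid and breakpoint fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vagdfa import dfa, synthetic
from vagdfa.experiments import brute_force_dual_fit


def naive_fluctuation(y, n):
    """Independent brute-force F(n): explicit per-segment polyfit."""
    m = len(y) // n
    sq = []
    for s in range(m):
        seg = np.asarray(y[s * n : (s + 1) * n], float)
        t = np.arange(n, dtype=float)
        coef = np.polyfit(t, seg, 1)
        sq.extend((seg - np.polyval(coef, t)) ** 2)
    return float(np.sqrt(np.mean(sq)))


class TestProfile:
    def test_cumulative_centered_sum(self):
        assert np.allclose(dfa.dfa_profile(np.array([1.0, 2.0, 3.0])), [-1, -1, 0])

    def test_profile_ends_at_zero(self, rng):
        y = dfa.dfa_profile(rng.standard_normal(257))
        assert abs(y[-1]) < 1e-9

    def test_constant_signal_gives_zero_profile(self):
        assert np.allclose(dfa.dfa_profile(np.full(64, 3.3)), 0.0)


class TestFluctuation:
    def test_exactly_linear_profile_detrends_to_zero(self):
        y = 2.5 * np.arange(512) + 1.0
        for n in (4, 16, 64):
            assert dfa.fluctuation(y, n) < 1e-10

    def test_matches_naive_implementation(self, rng):
        y = dfa.dfa_profile(rng.standard_normal(2**12))
        for n in (4, 16, 33, 100):
            assert abs(dfa.fluctuation(y, n) - naive_fluctuation(y, n)) < 1e-12

    def test_invariant_to_increment_mean_shift(self, rng):
        x = rng.standard_normal(1024)
        y1 = dfa.dfa_profile(x)
        y2 = dfa.dfa_profile(x + 7.0)
        assert abs(dfa.fluctuation(y1, 16) - dfa.fluctuation(y2, 16)) < 1e-10

    @pytest.mark.parametrize("n", [3, 600])
    def test_window_out_of_range_rejected(self, n, rng):
        with pytest.raises(ValueError):
            dfa.fluctuation(rng.standard_normal(1024), n)


class TestWindowGrid:
    def test_log_spacing_for_long_cycle(self):
        grid = dfa.window_grid(1000.0, 100000)
        assert grid[0] == 100 and grid[-1] == 2000
        ratios = grid[1:] / grid[:-1].astype(float)
        assert abs(np.median(ratios) - 20 ** (1 / 29)) < 0.02

    def test_duplicates_removed_after_rounding(self):
        grid = dfa.window_grid(100.0, 10000)
        assert grid[0] == 10 and grid[-1] == 200
        assert np.all(np.diff(grid) > 0)

    def test_minimum_window_clamped(self):
        grid = dfa.window_grid(30.0, 10000)
        assert grid[0] >= 4

    def test_grid_exceeding_signal_rejected(self):
        with pytest.raises(ValueError):
            dfa.window_grid(1000.0, 3000)


class TestCleanLoglog:
    def test_drops_zero_fluctuation_points(self):
        w = np.arange(10, 40)
        f = np.ones(30)
        f[5] = 0.0
        log_n, log_f = dfa.clean_loglog(w, f)
        assert log_n.size == 29

    def test_identity_when_all_finite(self):
        w = np.arange(10, 20).astype(float)
        f = np.linspace(1, 2, 10)
        log_n, log_f = dfa.clean_loglog(w, f)
        assert np.allclose(log_n, np.log(w)) and np.allclose(log_f, np.log(f))

    def test_too_few_survivors_rejected(self):
        w = np.arange(10, 20)
        f = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ValueError):
            dfa.clean_loglog(w, f)


class TestDualFit:
    def test_exact_two_line_input_recovered(self):
        log_n = np.linspace(1, 6, 30)
        knot = 11  # 0-based index of the knot point
        log_f = np.where(
            np.arange(30) <= knot,
            0.5 * log_n,
            0.5 * log_n[knot] + 1.2 * (log_n - log_n[knot]),
        )
        fit = dfa.dual_fit(log_n, log_f)
        # the knot point lies on both lines; ties break to the smaller split
        assert fit.bp_index in (knot, knot + 1)
        assert abs(fit.alpha1 - 0.5) < 1e-12 and abs(fit.alpha2 - 1.2) < 1e-12
        assert fit.rss_total < 1e-20
        assert fit.r2_1 > 1 - 1e-12 and fit.r2_2 > 1 - 1e-12

    def test_single_line_tie_broken_to_smallest_split(self):
        log_n = np.linspace(0, 5, 20)
        log_f = 0.8 * log_n + 0.3
        fit = dfa.dual_fit(log_n, log_f)
        assert fit.bp_index == 3  # smallest admissible split
        assert abs(fit.alpha1 - 0.8) < 1e-12 and abs(fit.alpha2 - 0.8) < 1e-12

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        log_n = np.cumsum(rng.uniform(0.05, 0.5, 20))
        log_f = rng.normal(size=20)
        fit = dfa.dual_fit(log_n, log_f)
        i, a1, a2, rss = brute_force_dual_fit(log_n, log_f)
        assert fit.bp_index == i
        assert abs(fit.alpha1 - a1) < 1e-10 and abs(fit.alpha2 - a2) < 1e-10
        assert abs(fit.rss_total - rss) < 1e-10

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_two_segments_never_worse_than_one_line(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(8, 30))
        log_n = np.cumsum(rng.uniform(0.05, 0.5, k))
        log_f = rng.normal(size=k)
        fit = dfa.dual_fit(log_n, log_f)
        single = np.polyfit(log_n, log_f, 1)
        resid = log_f - np.polyval(single, log_n)
        assert fit.rss_total <= float(resid @ resid) + 1e-12

    def test_degenerate_abscissa_rejected(self):
        log_n = np.r_[np.linspace(0, 1, 6), np.linspace(0, 1, 6)]
        with pytest.raises(ValueError):
            dfa.dual_fit(np.sort(log_n), np.arange(12, dtype=float))


class TestDfaDualPerImf:
    def test_fgn_as_imf_recovers_both_slopes(self):
        """fGn H=0.5 injected as an IMF: alpha1 and alpha2 both 0.5 +- 0.1."""
        a1s, a2s = [], []
        for s in range(20):
            x = synthetic.generate_fgn(0.5, 2**14, seed=s)
            fits = dfa.dfa_dual_per_imf([x], cycle_len=1000.0)
            a1s.append(fits[0].alpha1)
            a2s.append(fits[0].alpha2)
        assert abs(np.mean(a1s) - 0.5) < 0.1 and abs(np.mean(a2s) - 0.5) < 0.1

    def test_brownian_imf_slopes_near_three_halves(self):
        a1s, a2s = [], []
        for s in range(20):
            x = np.cumsum(np.random.default_rng(s).standard_normal(2**14))
            fits = dfa.dfa_dual_per_imf([x], cycle_len=1000.0)
            a1s.append(fits[0].alpha1)
            a2s.append(fits[0].alpha2)
        assert abs(np.mean(a1s) - 1.5) < 0.1 and abs(np.mean(a2s) - 1.5) < 0.1

    def test_zero_imf_yields_missing_fit(self, rng):
        fits = dfa.dfa_dual_per_imf([rng.standard_normal(2**13), np.zeros(2**13)], 800.0)
        assert fits[0] is not None and fits[1] is None

    def test_bp_ratio_uses_signal_length(self, rng):
        x = rng.standard_normal(2**13)
        fits = dfa.dfa_dual_per_imf([x], cycle_len=800.0)
        assert np.isclose(fits[0].bp_ratio, fits[0].bp_scale / x.size)

    def test_persistent_signal_fluctuation_monotone(self):
        """F(n) grows with n for persistent signals (Spearman rho > 0.9)."""
        from scipy.stats import spearmanr

        x = synthetic.generate_fgn(0.8, 2**13, seed=4)
        y = dfa.dfa_profile(x)
        grid = dfa.window_grid(800.0, x.size)
        f_n = [dfa.fluctuation(y, int(n)) for n in grid]
        rho = spearmanr(grid, f_n).statistic
        assert rho > 0.9
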