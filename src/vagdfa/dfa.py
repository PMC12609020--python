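"""Detrended fluctuation analysis with dual-scaling (crossover) fits.

Classical DFA-1 measures how the root-mean-square fluctuation ``F(n)`` of the
linearly detrended cumulative profile grows with window size ``n``.  A single
power law ``F(n) ~ n^alpha`` characterises monofractal signals (``alpha = 0.5``
for white noise, ``1.0`` for 1/f noise, ``1.5`` for Brownian motion).  Many
physiological series instead show two scaling regimes — a short-scale exponent
``alpha1`` and a long-scale exponent ``alpha2`` separated by a crossover
(breakpoint) scale.  This module fits both regimes with an exhaustive
two-segment least-squares search over the log-log curve and reports the
breakpoint location, which is itself a discriminative feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DualScalingFit",
    "dfa_profile",
    "fluctuation",
    "window_grid",
    "clean_loglog",
    "dual_fit",
    "dfa_exponent",
    "dfa_dual",
    "dfa_dual_per_imf",
]

#: minimum number of log-log points on each side of a candidate breakpoint
MIN_SEGMENT_POINTS = 3


@dataclass(frozen=True)
class DualScalingFit:
    """Two-segment power-law fit of a DFA log-log curve.

    ``alpha1``/``alpha2`` are the short- and long-scale slopes, ``r2_1``/``r2_2``
    the per-segment coefficients of determination.  ``bp_scale`` is the window
    size (samples) at the selected breakpoint and ``bp_ratio`` that scale
    relative to the analysed signal length (NaN when the length is unknown).
    """

    alpha1: float
    alpha2: float
    r2_1: float
    r2_2: float
    bp_index: int
    bp_scale: float
    bp_ratio: float
    rss_total: float


def dfa_profile(x: np.ndarray) -> np.ndarray:
    """Cumulative sum of the mean-centred series, Y(k) = sum_{i<=k}(x_i - xbar)."""
    x = np.asarray(x, dtype=float)
    return np.cumsum(x - x.mean())


def fluctuation(y: np.ndarray, n: int) -> float:
    """RMS fluctuation of profile ``y`` around per-segment linear trends.

    The profile is cut into ``floor(N/n)`` non-overlapping segments from the
    start; the tail remainder is discarded.  A least-squares line is removed
    from each segment and F(n) is the RMS residual over all covered samples.
    """
    y = np.asarray(y, dtype=float)
    N = y.size
    if not 4 <= n <= N // 2:
        raise ValueError(f"window size n={n} outside [4, {N // 2}]")
    m = N // n
    seg = y[: m * n].reshape(m, n)
    # closed-form linear detrend, shared abscissa for every segment
    t = np.arange(n, dtype=float)
    t_c = t - t.mean()
    denom = float(t_c @ t_c)
    slope = (seg @ t_c) / denom
    resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * t_c
    return float(np.sqrt(np.mean(resid**2)))


def window_grid(cycle_len: float, signal_len: int, n_windows: int = 30) -> np.ndarray:
    """Adaptive log-spaced DFA window grid tied to the movement-cycle length.

    Windows span 0.1 of one cycle up to two full cycles so that the short-scale
    regime probes intra-cycle structure and the long-scale regime spans whole
    cycles, independent of movement tempo.  Values are rounded to integers,
    clamped to >= 4 and deduplicated.
    """
    if cycle_len <= 40:
        n_min = 4.0
    else:
        n_min = 0.1 * cycle_len
    n_max = 2.0 * cycle_len
    if n_max > signal_len / 2:
        raise ValueError(
            f"maximum window 2*cycle_len={n_max:.0f} exceeds signal_len/2={signal_len / 2:.0f}"
        )
    grid = np.unique(
        np.clip(np.round(np.geomspace(n_min, n_max, n_windows)).astype(int), 4, None)
    )
    if grid.size < 8:
        raise ValueError(f"only {grid.size} unique windows after rounding; grid too coarse")
    return grid


def clean_loglog(windows: np.ndarray, f_n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zero/non-finite F(n) points and return natural-log pairs."""
    windows = np.asarray(windows, dtype=float)
    f_n = np.asarray(f_n, dtype=float)
    if windows.shape != f_n.shape:
        raise ValueError("windows and f_n must have equal length")
    keep = np.isfinite(f_n) & (f_n > 0) & np.isfinite(windows) & (windows > 0)
    if keep.sum() < 2 * MIN_SEGMENT_POINTS:
        raise ValueError(
            f"only {int(keep.sum())} usable log-log points; need >= {2 * MIN_SEGMENT_POINTS}"
        )
    return np.log(windows[keep]), np.log(f_n[keep])


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares line; returns (slope, intercept, rss, r2)."""
    xm, ym = x.mean(), y.mean()
    xc = x - xm
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("degenerate abscissa (repeated log n values)")
    slope = float(xc @ (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - slope * x - intercept
    rss = float(resid @ resid)
    tss = float(((y - ym) ** 2).sum())
    r2 = 1.0 if tss == 0.0 else 1.0 - rss / tss
    return slope, intercept, rss, r2


def dual_fit(
    log_n: np.ndarray, log_f: np.ndarray, signal_len: int | None = None
) -> DualScalingFit:
    """Exhaustive two-segment linear fit of the log-log fluctuation curve.

    Every split leaving at least three points per segment is evaluated; the
    split with the smallest summed residual sum of squares wins, ties broken
    toward the smallest split index.  Slopes are the scaling exponents
    ``alpha1`` (short scales) and ``alpha2`` (long scales).
    """
    log_n = np.asarray(log_n, dtype=float)
    log_f = np.asarray(log_f, dtype=float)
    k = log_n.size
    if k < 2 * MIN_SEGMENT_POINTS:
        raise ValueError("need at least 6 points for a two-segment fit")
    if np.any(np.diff(log_n) <= 0):
        raise ValueError("log_n must be strictly increasing")

    best: tuple[float, int] | None = None
    for i in range(MIN_SEGMENT_POINTS, k - MIN_SEGMENT_POINTS + 1):
        _, _, rss1, _ = _ols_line(log_n[:i], log_f[:i])
        _, _, rss2, _ = _ols_line(log_n[i:], log_f[i:])
        total = rss1 + rss2
        if best is None or total < best[0] - 1e-15:
            best = (total, i)
    assert best is not None
    rss_total, i = best
    a1, _, _, r2_1 = _ols_line(log_n[:i], log_f[:i])
    a2, _, _, r2_2 = _ols_line(log_n[i:], log_f[i:])
    bp_scale = math.exp(log_n[i - 1])
    bp_ratio = bp_scale / signal_len if signal_len else float("nan")
    return DualScalingFit(
        alpha1=a1,
        alpha2=a2,
        r2_1=r2_1,
        r2_2=r2_2,
        bp_index=i,
        bp_scale=bp_scale,
        bp_ratio=bp_ratio,
        rss_total=rss_total,
    )


def dfa_exponent(x: np.ndarray, windows: np.ndarray) -> float:
    """Single power-law DFA exponent (one line through the whole log-log curve)."""
    y = dfa_profile(x)
    f_n = np.array([fluctuation(y, int(n)) for n in windows])
    log_n, log_f = clean_loglog(np.asarray(windows, float), f_n)
    slope, _, _, _ = _ols_line(log_n, log_f)
    return slope


def dfa_dual(x: np.ndarray, windows: np.ndarray) -> DualScalingFit:
    """Full dual-scaling DFA of one series on a given window grid."""
    x = np.asarray(x, dtype=float)
    y = dfa_profile(x)
    f_n = np.array([fluctuation(y, int(n)) for n in windows])
    log_n, log_f = clean_loglog(np.asarray(windows, float), f_n)
    return dual_fit(log_n, log_f, signal_len=x.size)


def dfa_dual_per_imf(imfs, cycle_len: float) -> list[DualScalingFit | None]:
    """Dual-scaling DFA for each IMF of a decomposition, on a shared grid.

    ``imfs`` may be an :class:`~vagdfa.emd.ImfDecomposition` or a plain list of
    equal-length arrays.  IMFs whose fluctuation curve cannot be fitted (e.g.
    all-zero padding components) yield ``None``.
    """
    arrays = getattr(imfs, "imfs", imfs)
    fits: list[DualScalingFit | None] = []
    grid: np.ndarray | None = None
    for imf in arrays:
        imf = np.asarray(imf, dtype=float)
        try:
            if grid is None:
                grid = window_grid(cycle_len, imf.size)
            fits.append(dfa_dual(imf, grid))
        except ValueError:
            fits.append(None)
    return fits
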