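"""Per-IMF frequency/energy features, band aggregation and screening.

Each IMF is summarised by three descriptors:

* **CF** — centroid frequency, the PSD-weighted mean frequency
  (Welch estimate, Hann window);
* **MIF** — mean instantaneous frequency from the Hilbert analytic-signal
  phase derivative;
* **E** — energy, the sum of squared samples.

IMFs are grouped by index into three physiological bands — high (IMF 1-3,
articular-surface microvibrations), mid (IMF 4-6, musculoskeletal
interaction) and low (IMF 7-10, gross movement dynamics) — and each band
contributes the mean CF, MIF, E and DFA breakpoint ratio, yielding a fixed
12-feature vector per recording.

Screening uses the Lilliefors normality test (reported only) and the
Mann-Whitney U test as the keep/drop gate at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from scipy.stats import norm

from .dfa import DualScalingFit

__all__ = [
    "BANDS",
    "FEATURE_NAMES",
    "ImfFeatureRow",
    "band_of_imf",
    "centroid_frequency",
    "mean_instantaneous_frequency",
    "energy",
    "imf_feature_rows",
    "aggregate_band_features",
    "lilliefors_test",
    "mann_whitney_u",
    "screen_features",
    "build_feature_table",
]

#: band name -> 1-based IMF indices
BANDS: dict[str, tuple[int, ...]] = {
    "high": (1, 2, 3),
    "mid": (4, 5, 6),
    "low": (7, 8, 9, 10),
}

#: fixed feature order: (high, mid, low) x (CF, MIF, E, BR)
FEATURE_NAMES: list[str] = [
    f"{band}_{param}" for band in ("high", "mid", "low") for param in ("CF", "MIF", "E", "BR")
]


@dataclass(frozen=True)
class ImfFeatureRow:
    imf_index: int
    cf_hz: float
    mif_hz: float
    energy: float
    band: str


def band_of_imf(index: int) -> str:
    """Band membership is a function of the 1-based IMF index only."""
    for band, members in BANDS.items():
        if index in members:
            return band
    raise ValueError(f"IMF index {index} outside 1..10")


def centroid_frequency(x: np.ndarray, fs_hz: float) -> float:
    """PSD-weighted mean frequency, sum(f P(f)) / sum(P(f)).

    P(f) is a Welch estimate with a Hann window, segment length
    ``min(1024, n)`` and 50% overlap.  All-zero input yields NaN.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("need >= 64 samples")
    if not np.any(x):
        return float("nan")
    nperseg = min(1024, x.size)
    f, p = sps.welch(x, fs=fs_hz, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    total = p.sum()
    if total <= 0:
        return float("nan")
    return float((f * p).sum() / total)


def mean_instantaneous_frequency(x: np.ndarray, fs_hz: float) -> float:
    """Mean derivative of the analytic-signal phase, in Hz.

    5% of samples at each edge are excluded (the Hilbert transform is
    unreliable there) and negative instantaneous frequencies — artefacts of
    near-zero analytic amplitude — are clipped to 0 before averaging.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("need >= 64 samples")
    if not np.any(x):
        return float("nan")
    analytic = sps.hilbert(x)
    phase = np.unwrap(np.angle(analytic))
    inst = np.diff(phase) * fs_hz / (2 * np.pi)
    edge = max(int(0.05 * inst.size), 1)
    core = inst[edge:-edge]
    return float(np.mean(np.clip(core, 0.0, None)))


def energy(x: np.ndarray) -> float:
    """Signal energy: sum of squared samples."""
    x = np.asarray(x, dtype=float)
    return float(x @ x)


def imf_feature_rows(imfs, fs_hz: float) -> list[ImfFeatureRow]:
    """CF/MIF/E rows for the (up to 10) IMFs of one decomposition."""
    arrays = getattr(imfs, "imfs", imfs)
    rows = []
    for i, imf in enumerate(arrays, start=1):
        if i > 10:
            break
        rows.append(
            ImfFeatureRow(
                imf_index=i,
                cf_hz=centroid_frequency(imf, fs_hz),
                mif_hz=mean_instantaneous_frequency(imf, fs_hz),
                energy=energy(imf),
                band=band_of_imf(i),
            )
        )
    return rows


def aggregate_band_features(
    rows: list[ImfFeatureRow], fits: list[DualScalingFit | None]
) -> np.ndarray:
    """Band-wise means of CF, MIF, E and breakpoint ratio -> 12-vector.

    Order follows :data:`FEATURE_NAMES`.  A band whose members are all
    non-finite (or whose fits are all missing) produces NaN entries.
    """
    by_index = {r.imf_index: r for r in rows}
    fit_by_index = {i + 1: f for i, f in enumerate(fits)}
    out = []
    for band in ("high", "mid", "low"):
        members = [i for i in BANDS[band] if i in by_index]
        cf = [by_index[i].cf_hz for i in members]
        mif = [by_index[i].mif_hz for i in members]
        en = [by_index[i].energy for i in members]
        br = [
            fit_by_index[i].bp_ratio
            for i in members
            if fit_by_index.get(i) is not None and np.isfinite(fit_by_index[i].bp_ratio)
        ]
        for vals in (cf, mif, en):
            finite = [v for v in vals if np.isfinite(v)]
            out.append(float(np.mean(finite)) if finite else float("nan"))
        out.append(float(np.mean(br)) if br else float("nan"))
    return np.array(out)


def build_feature_table(
    per_recording: list[tuple[dict, list[ImfFeatureRow], list[DualScalingFit | None]]]
) -> pd.DataFrame:
    """Assemble the cohort feature table (one row per recording).

    ``per_recording`` holds ``(metadata_dict, imf_rows, dfa_fits)`` triples;
    metadata must include at least ``subject_id`` and ``group``.
    """
    records = []
    for meta, rows, fits in per_recording:
        vec = aggregate_band_features(rows, fits)
        rec = dict(meta)
        rec.update(dict(zip(FEATURE_NAMES, vec)))
        records.append(rec)
    return pd.DataFrame(records)


def lilliefors_test(
    sample: np.ndarray, mc_reps: int = 2000, seed: int | None = None
) -> float:
    """Lilliefors normality test with a seeded Monte-Carlo null.

    The statistic is the KS distance between the standardized sample and the
    standard normal CDF; the p-value is the add-one-corrected fraction of
    ``mc_reps`` standard-normal samples of the same size whose statistic is at
    least as large.  Zero-variance samples return NaN.
    """
    sample = np.asarray(sample, dtype=float)
    n = sample.size
    if n < 4:
        raise ValueError("need n >= 4")
    if sample.std(ddof=1) == 0:
        return float("nan")
    d_obs = _lilliefors_statistic(sample[None, :])[0]
    rng = np.random.default_rng(seed)
    null = _lilliefors_statistic(rng.standard_normal((mc_reps, n)))
    return float((1 + np.sum(null >= d_obs)) / (mc_reps + 1))


def _lilliefors_statistic(samples: np.ndarray) -> np.ndarray:
    """Row-wise KS distance to the normal with estimated mean/sd."""
    n = samples.shape[1]
    z = np.sort(
        (samples - samples.mean(axis=1, keepdims=True))
        / samples.std(axis=1, ddof=1, keepdims=True),
        axis=1,
    )
    cdf = norm.cdf(z)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    return np.maximum(np.abs(cdf - grid_hi), np.abs(cdf - grid_lo)).max(axis=1)


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for small pooled samples without ties
    (``n_a + n_b <= 12``); otherwise the normal approximation with midrank tie
    correction and continuity correction.  All-tied input yields p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def screen_features(
    table: pd.DataFrame,
    label_col: str = "group",
    positive: str = "OA",
    alpha: float = 0.05,
    mc_reps: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-feature normality report and Mann-Whitney keep/drop gate.

    Returns a DataFrame with one row per feature column: Lilliefors p per
    group (reported, not gating), the U statistic, the two-sided p-value, and
    ``kept = (p < alpha)``.
    """
    feature_cols = [c for c in FEATURE_NAMES if c in table.columns]
    ga = table[table[label_col] == positive]
    gb = table[table[label_col] != positive]
    rng = np.random.default_rng(seed)
    rows = []
    for col in feature_cols:
        xa = ga[col].dropna().to_numpy()
        xb = gb[col].dropna().to_numpy()
        lp_a = lilliefors_test(xa, mc_reps, int(rng.integers(2**31))) if xa.size >= 4 else np.nan
        lp_b = lilliefors_test(xb, mc_reps, int(rng.integers(2**31))) if xb.size >= 4 else np.nan
        u, p = mann_whitney_u(xa, xb)
        rows.append(
            {
                "feature": col,
                "lilliefors_p_a": lp_a,
                "lilliefors_p_b": lp_b,
                "mw_u": u,
                "mw_p": p,
                "kept": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)
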