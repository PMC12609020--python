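"""Desk-scale reference experiments validating the pipeline.

Each function runs one self-contained study on synthetic data with a known
ground truth — exponent recovery on canonical noises, breakpoint-search oracle
equivalence, planted-crossover recovery, decomposition completeness,
feature-formula checks, statistical-screening operating characteristics, and
the two classification paths on cohorts with planted group effects — and
returns a small dict of measured quantities.  All randomness derives from the
single ``seed`` argument.  Problem sizes are chosen so the full battery runs
in a few minutes on one CPU; docs/methods.md records the sizes used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify, dfa, emd, features, io, scalogram, synthetic
from .cnn import AugmentationSpec, CnnConfig, apply_threshold, train_cv

__all__ = [
    "dfa_exponent_recovery",
    "brute_force_dual_fit",
    "dual_fit_oracle_check",
    "crossover_recovery",
    "emd_completeness",
    "feature_formula_checks",
    "screening_keep_rates",
    "nca_planted_rates",
    "lilliefors_type1_error",
    "feature_path_cv",
    "cnn_smoke",
    "metric_identity_checks",
]


def _recovery_grid(n: int) -> np.ndarray:
    """Default window grid for exponent-recovery studies: 16 .. n/8."""
    return np.unique(np.geomspace(16, n // 8, 30).astype(int))


def dfa_exponent_recovery(n: int = 2**14, n_seeds: int = 20, seed: int = 0) -> dict:
    """Mean DFA exponent on white / 1-f / Brownian noise (alpha = 0.5/1.0/1.5)."""
    grid = _recovery_grid(n)
    ss = np.random.SeedSequence(seed).spawn(n_seeds)
    alphas = {"white": [], "pink": [], "brown": []}
    for s in ss:
        child = int(s.generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(child)
        alphas["white"].append(dfa.dfa_exponent(rng.standard_normal(n), grid))
        alphas["pink"].append(dfa.dfa_exponent(synthetic.generate_one_over_f(n, child), grid))
        alphas["brown"].append(dfa.dfa_exponent(np.cumsum(rng.standard_normal(n)), grid))
    return {k: float(np.mean(v)) for k, v in alphas.items()} | {"n": n, "n_seeds": n_seeds}


def brute_force_dual_fit(log_n: np.ndarray, log_f: np.ndarray) -> tuple[int, float, float, float]:
    """Independent exhaustive two-segment search (np.polyfit based).

    Returns (split index, alpha1, alpha2, total RSS); ties go to the smallest
    split.  Used as the oracle for :func:`vagdfa.dfa.dual_fit`.
    """
    k = len(log_n)
    best = None
    for i in range(3, k - 2):
        c1 = np.polyfit(log_n[:i], log_f[:i], 1)
        c2 = np.polyfit(log_n[i:], log_f[i:], 1)
        r1 = log_f[:i] - np.polyval(c1, log_n[:i])
        r2 = log_f[i:] - np.polyval(c2, log_n[i:])
        rss = float(r1 @ r1 + r2 @ r2)
        if best is None or rss < best[3] - 1e-15:
            best = (i, float(c1[0]), float(c2[0]), rss)
    assert best is not None
    return best


def dual_fit_oracle_check(n_clouds: int = 100, n_points: int = 20, seed: int = 0) -> dict:
    """Agreement between dual_fit and the brute-force oracle on random clouds."""
    rng = np.random.default_rng(seed)
    split_mismatches = 0
    max_slope_diff = 0.0
    for _ in range(n_clouds):
        log_n = np.cumsum(rng.uniform(0.05, 0.5, n_points))
        log_f = rng.normal(size=n_points)
        fit = dfa.dual_fit(log_n, log_f)
        i, a1, a2, _ = brute_force_dual_fit(log_n, log_f)
        if fit.bp_index != i:
            split_mismatches += 1
        max_slope_diff = max(max_slope_diff, abs(fit.alpha1 - a1), abs(fit.alpha2 - a2))
    # exact recovery on a noiseless piecewise-linear curve
    log_n = np.linspace(1, 6, 30)
    bp = 12
    log_f = np.where(
        np.arange(30) < bp,
        0.5 * log_n,
        0.5 * log_n[bp - 1] + 1.2 * (log_n - log_n[bp - 1]),
    )
    exact = dfa.dual_fit(log_n, log_f)
    return {
        "split_mismatches": split_mismatches,
        "max_slope_diff": max_slope_diff,
        "exact_bp_index": exact.bp_index,
        "exact_alpha1": exact.alpha1,
        "exact_alpha2": exact.alpha2,
        "exact_rss": exact.rss_total,
        "n_clouds": n_clouds,
    }


def crossover_recovery(
    n_seeds: int = 20,
    H_short: float = 0.5,
    H_long: float = 0.9,
    crossover_s: float = 0.5,
    fs_hz: float = 1000.0,
    n: int = 2**15,
    seed: int = 0,
) -> dict:
    """Fraction of seeds where the fitted breakpoint is within 2x of the plant."""
    grid = _recovery_grid(n)
    planted = crossover_s * fs_hz
    hits = 0
    a1s, a2s = [], []
    base = np.random.SeedSequence(seed).spawn(n_seeds)
    for s in base:
        child = int(s.generate_state(1)[0] % 2**31)
        x = synthetic.generate_crossover_series(H_short, H_long, crossover_s, fs_hz, n, child)
        fit = dfa.dfa_dual(x, grid)
        if 0.5 <= fit.bp_scale / planted <= 2.0:
            hits += 1
        a1s.append(fit.alpha1)
        a2s.append(fit.alpha2)
    return {
        "hit_rate": hits / n_seeds,
        "alpha1_mean": float(np.mean(a1s)),
        "alpha2_mean": float(np.mean(a2s)),
        "n_seeds": n_seeds,
    }


def emd_completeness(n_signals: int = 10, n: int = 2048, seed: int = 0) -> dict:
    """Max relative reconstruction residual of EMD, and EEMD(0, 1) == EMD."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_signals):
        x = rng.standard_normal(n)
        d = emd.emd(x)
        worst = max(worst, float(np.max(np.abs(d.reconstruct() - x)) / np.max(np.abs(x))))
    x = rng.standard_normal(n)
    de = emd.emd(x)
    d0 = emd.eemd(x, noise_ratio=0.0, ensemble=1, seed=0)
    diff = max(
        float(np.max(np.abs(d0.imfs[i] - de.imfs[i]))) for i in range(len(de.imfs))
    )
    diff = max(diff, float(np.max(np.abs(d0.residue - de.residue))))
    return {"max_rel_residual": worst, "eemd_emd_max_diff": diff, "n_signals": n_signals}


def feature_formula_checks(fs_hz: float = 1000.0, n: int = 8192) -> dict:
    """Energy on the toy vector; CF and MIF errors on pure tones."""
    t = np.arange(n) / fs_hz
    cf = features.centroid_frequency(np.sin(2 * np.pi * 100 * t), fs_hz)
    mif = features.mean_instantaneous_frequency(np.sin(2 * np.pi * 50 * t), fs_hz)
    return {
        "energy_123": features.energy(np.array([1.0, 2.0, 3.0])),
        "cf_tone_error_hz": abs(cf - 100.0),
        "mif_tone_error_hz": abs(mif - 50.0),
    }


def _feature_frame(rng: np.random.Generator, n_per_group: int, shift: float) -> pd.DataFrame:
    """12-feature cohort with one group-shifted feature (high_E) and 11 noise."""
    n = 2 * n_per_group
    data = {name: rng.standard_normal(n) for name in features.FEATURE_NAMES}
    group = np.array(["HC"] * n_per_group + ["OA"] * n_per_group)
    data["high_E"][group == "OA"] += shift
    return pd.DataFrame({**data, "group": group})


def screening_keep_rates(
    n_runs: int = 100, n_per_group: int = 40, shift: float = 1.0, seed: int = 0
) -> dict:
    """Mann-Whitney gate: planted-feature keep rate and noise false-keep rate."""
    rng = np.random.default_rng(seed)
    kept_planted = 0
    noise_keeps = 0
    noise_total = 0
    for _ in range(n_runs):
        table = _feature_frame(rng, n_per_group, shift)
        scr = features.screen_features(table, mc_reps=200, seed=int(rng.integers(2**31)))
        kept = dict(zip(scr["feature"], scr["kept"]))
        kept_planted += kept["high_E"]
        for name in features.FEATURE_NAMES:
            if name != "high_E":
                noise_keeps += kept[name]
                noise_total += 1
    return {
        "planted_keep_rate": kept_planted / n_runs,
        "noise_keep_rate": noise_keeps / noise_total,
        "n_runs": n_runs,
    }


def nca_planted_rates(n_runs: int = 50, n: int = 60, p: int = 12, seed: int = 0) -> dict:
    """NCA weight concentration with and without an informative feature."""
    rng = np.random.default_rng(seed)
    informative_wins = 0
    null_max_below = 0
    for _ in range(n_runs):
        y = rng.permutation(np.repeat([0, 1], n // 2))
        X = rng.standard_normal((n, p))
        X[:, 0] = y  # feature identical to the label
        res = classify.nca_weights(X, y, seed=int(rng.integers(2**31)))
        informative_wins += res.weights[0] > 0.5
        Xn = rng.standard_normal((n, p))
        resn = classify.nca_weights(Xn, y, seed=int(rng.integers(2**31)))
        null_max_below += resn.weights.max() < 0.3
    return {
        "informative_weight_rate": informative_wins / n_runs,
        "null_max_below_rate": null_max_below / n_runs,
        "n_runs": n_runs,
    }


def lilliefors_type1_error(
    n_reps: int = 500, n: int = 50, level: float = 0.05, seed: int = 0
) -> dict:
    """Empirical rejection rate of the Monte-Carlo Lilliefors test under H0."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        sample = rng.standard_normal(n)
        p = features.lilliefors_test(sample, mc_reps=2000, seed=int(rng.integers(2**31)))
        rejections += p < level
    return {"type1_error": rejections / n_reps, "n_reps": n_reps}


def feature_path_cv(
    n_per_group: int = 40,
    fs_hz: float = 1000.0,
    cycle_s: float = 1.0,
    ensemble: int = 2,
    seed: int = 0,
) -> dict:
    """Full feature path on a synthetic cohort with planted group effects.

    Cohort -> preprocess -> EEMD -> per-IMF features + dual-scaling DFA ->
    Mann-Whitney screening -> NCA selection -> stratified 5-fold RBF-SVM.
    Also reports the chance-level accuracy with permuted labels.
    """
    spec = synthetic.CohortSpec(
        n_per_group=n_per_group,
        fs_hz=fs_hz,
        n_cycles=10,
        cycle_s=cycle_s,
        profiles=synthetic.default_profiles(fs_hz),
        seed=seed,
    )
    recordings, _ = synthetic.generate_cohort(spec)
    table_input = []
    ss = np.random.SeedSequence(seed + 1).spawn(len(recordings))
    for rec, s in zip(recordings, ss):
        pre = io.preprocess(rec)
        d = emd.eemd(
            pre.samples,
            noise_ratio=0.01,
            ensemble=ensemble,
            max_imf=10,
            seed=int(s.generate_state(1)[0] % 2**31),
        )
        fits = dfa.dfa_dual_per_imf(d, pre.cycle_len)
        rows = features.imf_feature_rows(d, fs_hz)
        meta = {"subject_id": rec.meta.subject_id, "group": rec.meta.group}
        table_input.append((meta, rows, fits))
    table = features.build_feature_table(table_input)
    screening = features.screen_features(table, mc_reps=200, seed=seed)
    kept = list(screening.loc[screening["kept"], "feature"]) or list(screening["feature"])
    X = table[kept].to_numpy()
    finite = np.all(np.isfinite(X), axis=1)
    X, y = X[finite], table["group"].to_numpy()[finite]
    nca = classify.nca_weights(X, y, seed=seed)
    selected = classify.select_by_weight(nca)
    X_sel = X[:, list(selected)]
    report = classify.svm_rbf_cv(X_sel, y, k=5, seed=seed)
    null_accs = []
    rng = np.random.default_rng(seed + 2)
    for _ in range(3):
        null = classify.svm_rbf_cv(X_sel, rng.permutation(y), k=5, seed=seed)
        null_accs.append(null.mean["accuracy"])
    return {
        "accuracy": report.mean["accuracy"],
        "accuracy_sd": report.sd["accuracy"],
        "auc": report.mean["auc"],
        "null_accuracy": float(np.mean(null_accs)),
        "n_kept": len(kept),
        "n_selected": len(selected),
        "n_per_group": n_per_group,
    }


def _separable_scalograms(
    n_per_class: int, resolution: int, fs_hz: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Tone-burst vs broadband-noise scalogram images, visually separable."""
    rng = np.random.default_rng(seed)
    grid = scalogram.default_scale_grid(fs_hz)
    n = 2048
    t = np.arange(n) / fs_hz
    images, labels = [], []
    for _ in range(n_per_class):
        x = np.sin(2 * np.pi * 150 * t) * (1 + 0.3 * rng.standard_normal())
        x *= np.abs(np.sin(np.pi * t / 0.5))
        x += 0.1 * rng.standard_normal(n)
        images.append(scalogram.to_rgb_image(scalogram.cwt_magnitude(x, grid), resolution).pixels)
        labels.append("HC")
        y = rng.standard_normal(n)
        images.append(scalogram.to_rgb_image(scalogram.cwt_magnitude(y, grid), resolution).pixels)
        labels.append("OA")
    return np.stack(images), np.array(labels)


def cnn_smoke(
    n_per_class: int = 40, resolution: int = 128, epochs: int = 3, seed: int = 0
) -> dict:
    """Compact-CNN CV on separable synthetic scalograms, plus threshold checks."""
    images, labels = _separable_scalograms(n_per_class, resolution, 1000.0, seed)
    config = CnnConfig(epochs=epochs, batch=16, seed=seed)
    report = train_cv(images, labels, config, AugmentationSpec(), k=5)
    return {
        "accuracy": report.mean["accuracy"],
        "auc": report.mean["auc"],
        "threshold_070": apply_threshold(0.70),
        "threshold_069": apply_threshold(0.69),
        "n_per_class": n_per_class,
        "epochs": epochs,
    }


def _concordance_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Brute-force pairwise concordance AUC with ties counted 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (pos.size * neg.size))


def metric_identity_checks(n_sets: int = 50, seed: int = 0) -> dict:
    """Trapezoidal-vs-concordance AUC agreement and hand-checked metrics."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_sets):
        n = int(rng.integers(20, 200))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        auc, _ = classify.roc_auc(scores, labels)
        worst = max(worst, abs(auc - _concordance_auc(scores, labels)))
    m = classify.metrics_from_confusion(tp=9, fn=1, tn=8, fp=2)
    return {
        "auc_max_abs_diff": worst,
        "sensitivity_9182": m["sensitivity"],
        "specificity_9182": m["specificity"],
        "precision_9182": m["precision"],
        "f1_9182": m["f1"],
        "n_sets": n_sets,
    }
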