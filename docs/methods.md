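# Methods

## Signal model and preprocessing

A VAG recording is a single-channel acoustic time series captured at the knee
during ten flexion–extension cycles, in an open (OKC) or closed (CKC) kinetic
chain. Preprocessing trims the recording to the active-motion portion, removes
sub-10 Hz baseline, and normalizes amplitude:

* **Cycle segmentation.** The rectified signal is smoothed with a 0.25 s
  moving average; envelope peaks (minimum separation 0.5 s, prominence at
  least 0.15 of the envelope range, height at least 0.2 of the maximum) mark
  cycle centres, and the envelope minima between consecutive peaks mark cycle
  boundaries. The prominence floor suppresses spurious within-cycle peaks that
  the raw peak-picking recipe admits on noisy envelopes. Fewer detected cycles
  than requested is flagged, not fatal.
* **High-pass filter.** 4th-order Butterworth, 10 Hz cutoff, causal single
  pass by default. A zero-phase (forward–backward) variant is selectable when
  burst timing must not be delayed; it doubles the effective order.
* **Normalization.** Min–max to [0, 1]. A constant (dead-channel) input maps
  to 0.5 everywhere with a `degenerate` flag, so batch runs survive.

Order of operations: trim → filter → normalize. The sampling rate is a
required metadata field (manifest column or WAV header); the synthetic module
defaults to 4 kHz so 600 Hz band structure sits well inside Nyquist.

## EEMD

Sifting extracts one IMF by iterated envelope-mean subtraction: cubic splines
through maxima/minima with a two-point mirror extension at the boundaries.
Iteration stops when Huang's criterion SD = Σ(h_{k-1}−h_k)²/Σh_{k-1}² < 0.2
*and* the IMF condition |#extrema − #zero-crossings| ≤ 1 holds, or after 50
iterations. The SD criterion alone stops too early on broadband components
and leaves extrema/zero-crossing mismatches of O(10); the combined rule keeps
both properties while adding only a few iterations. EMD is complete by
construction (Σ IMFs + residue = input to machine precision) and the test
suite asserts it at 1e-9 relative.

EEMD decomposes `ensemble` noise-perturbed copies (added white noise at
`noise_ratio` = 0.01 of the signal SD; 100 realizations by default) and
averages IMFs element-wise after zero-padding every realization's IMF list to
`max_imf` = 10, so realizations with different IMF counts align. With
`noise_ratio=0, ensemble=1` the result is bit-identical to plain EMD. The
residue is excluded from all downstream features.

## Dual-scaling DFA

For a series x, the profile Y(k) = Σ_{i≤k}(x_i − x̄) is cut into ⌊N/n⌋
non-overlapping windows from the start (tail remainder discarded), each
linearly detrended (DFA-1); F(n) is the RMS residual over covered samples.
The window grid is adaptive: 30 log-spaced integer sizes from 0.1 to 2
movement cycles, clamped to ≥ 4 and deduplicated, shared across the ten IMFs
of a recording so exponents are comparable across subjects regardless of
movement tempo.

After dropping zero/non-finite F(n) points, the log–log curve is fitted with
every admissible two-segment split (≥ 3 points per side); the split with
minimal summed RSS wins, ties broken toward the smaller index for determinism.
Slopes give α₁ (short scales) and α₂ (long scales); `bp_scale` is the window
size at the split and `bp_ratio = bp_scale / N` expresses the breakpoint as a
fraction of the signal. When data lie exactly on two lines the knot point
belongs to both, so the two RSS-zero splits tie and the smaller wins — the
fitted slopes are unaffected. Natural logs are used; slopes are
base-invariant.

Validated recoveries (20 seeds, n = 2^14, windows 16..n/8): white noise
α = 0.50, 1/f noise 0.99, Brownian motion 1.50; the two-segment search agrees
with an independently coded exhaustive oracle on every random instance.

## Synthetic cohorts

`generate_recording` builds: cyclic envelope (1−m) + m·|sin(πt/T)| with
modulation depth m = 0.9 × [three band-passed Gaussian carriers (default
centres 600/200/50 Hz, ±35 % bandwidth, relative powers from the group
profile) + Poisson-rate damped 600–900 Hz bursts ("clicks", 10 ms,
2 ms decay)] + an additive fluctuation component with two scaling regimes.

The fluctuation component is fGn(H_short) plus the cumulative sum of a
low-pass-filtered (cutoff 1/crossover_s) fGn(H_long); the slow part's
amplitude is calibrated so both parts have equal F(n) at the planted scale,
which pins the DFA crossover there. fGn itself is exact (circulant embedding
of the analytic autocovariance; spectral synthesis fallback with a warning if
the embedding fails). The component's RMS is 0.35 of the band-noise RMS —
large enough to carry the scaling structure into the IMFs, small enough that
envelope minima stay visible to the cycle detector.

Default group profiles encode the contrasts the pipeline is meant to detect:
OA has a higher click rate (6 vs 0.5 /s), a larger high-band energy share
(0.45 vs 0.15), stiffer short-scale control (H_short 0.85 vs 0.60) and a
later crossover (0.60 vs 0.25 s). Per-(subject, channel) seeds are derived by
hashing, so enlarging a cohort never reshuffles existing subjects.

What the generator does **not** emulate: biomechanically realistic joint
acoustics, sensor coupling, inter-subject variability beyond seed noise,
artifacts, or encoder-measured joint angles. Passing tests therefore
demonstrate that the pipeline recovers planted statistical structure, not
clinical performance.

## Feature path

CF uses a Welch PSD (Hann, segment min(1024, n), 50 % overlap). MIF averages
the analytic-signal phase derivative, excluding 5 % of samples at each edge
and clipping negative instantaneous frequencies (artefacts of near-zero
amplitude) to zero. Energy is Σx². Band membership is a function of IMF index
only (1–3/4–6/7–10); each band contributes its mean CF, MIF, E and breakpoint
ratio → 12 features in fixed order.

Screening: Lilliefors normality per group is computed with a seeded
Monte-Carlo null (KS distance to the normal with estimated moments; add-one
corrected p) — reported, but not gating, since the group comparison is the
nonparametric Mann–Whitney U regardless (exact enumeration when the pooled
sample is ≤ 12 without ties, otherwise tie-corrected normal approximation
with continuity correction). Features with two-sided p ≥ 0.05 are dropped.
No multiple-testing correction is applied, and screening runs on the full
dataset before cross-validation — a deliberate mirror of the reference
workflow whose optimistic bias is acknowledged here.

NCA uses the feature-weighting form: distances d_ij = Σ_k w_k²|x_ik−x_jk| on
standardized features, leave-one-out soft-neighbour objective Σ p_i − λΣw_k²
(λ = 1/n), gradient ascent from w = 1 with step halving, 200 iterations.
Reported weights are |w| normalized to sum 1, so a flat profile over 12
features sits at 0.083 and the 0.05 cutoff removes features carrying under
~60 % of average importance. An empty selection falls back to the top 3 by
weight with a warning. SVM: RBF kernel, C = 1, gamma = "scale",
standardization fitted inside each training fold, stratified 5-fold CV with a
fixed seed; ROC/AUC from the signed decision values.

## Image path

The CWT uses a complex Morlet wavelet (pywt `cmor2.0-0.9549`: Gaussian
envelope exp(−t²/2), carrier ≈ 6 rad/sample at scale 1) over 64 log-spaced
scales spanning pseudo-frequencies 5 Hz to fs/2.5, mapped analytically as
f = 0.9549·fs/scale. One grid per run, hashed into every image's metadata.
Magnitudes are min–max normalized per image, mapped through a pinned
256-entry jet lookup table (computed from the classic piecewise-linear
breakpoints, so images are bit-exact across platforms), and bilinearly
resized to 128² or 256². Channels K1–K3 are summed before transformation. A
zero (empty-reconstruction) signal yields a uniform mid-colormap image with a
flag, keeping cohort sizes balanced.

The CNN is implemented in numpy: 3 × [Conv 3×3 'same' → BatchNorm → ReLU →
MaxPool 2×2] with 16/32/64 filters, Dropout 0.4, one dense layer, softmax
over {HC, OA}; Adam (1e-3), batch 32, L2 0.01 on weights, 30 epochs by
default. Filter counts, dense width and learning rate are declared defaults
(only "increasing filters" and the optimizer are fixed by the reference
design). Training folds are augmented on the fly (rotation ±10°, scale
0.9–1.1, translation ±5 px, horizontal flip); validation folds are never
touched (asserted by hashing). Decision rule: HC iff P(HC) ≥ 0.7 — the
boundary case 0.70 is HC, since only probabilities *below* the threshold go
to OA. All layers carry explicit backward passes; conv/dense gradients are
verified against numeric differentiation in the test suite.

## Problem sizes and numerical choices

The validation battery (tests and `scripts/acceptance.py`) uses desk-scale
problem sizes chosen once: exponent recovery at n = 2^14 over 20 seeds;
breakpoint oracle on 100 random 20-point clouds; crossover recovery at
n = 2^15, 20 seeds; screening characteristics over 100 runs of 40 + 40
samples (planted shift 1 pooled SD); NCA over 50 runs (n = 60, p = 12);
Lilliefors calibration over 2000 replicates (binomial SE ≈ 0.005); the
end-to-end cohort at 40 recordings per group, fs = 1 kHz, ten 1 s cycles,
EEMD ensemble 2; the CNN check at 40 images per class, 128², 3 epochs.
The pipeline defaults remain the full-scale settings (fs 4 kHz, 3 s cycles,
ensemble 100, 30 epochs).

Other numerical choices: sifting cap 50; DFA needs ≥ 6 clean log–log points
(else the fit is flagged missing for that IMF); strict inequalities at the
reconstruction gates (α > 0.5, R² > 0.9); max-pool backward routes gradient
to every tied maximum; softmax is max-stabilised; all stochastic stages
(EEMD noise, MC nulls, NCA init order, CV splits, CNN init, dropout,
augmentation) derive from a single run seed.

## Known limitations

* EMD/EEMD quality depends on extrema interpolation; mirror extension tames
  but does not eliminate boundary swings on short signals.
* Dual-segment DFA always reports a breakpoint, even for single-regime
  signals (where the two slopes then agree); `bp_ratio` is only meaningful
  when the slopes differ.
* Screening-before-CV leaks label information into feature selection, as in
  the reference workflow; reported CV metrics on small cohorts are optimistic.
* The synthetic generator's group contrasts are strong by design; perfect
  separation on it says nothing about clinical effect sizes.
* The numpy CNN is CPU-bound; at 256² with 30 epochs it is slow — the
  defaults suit overnight runs, the reduced settings suit smoke validation.
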