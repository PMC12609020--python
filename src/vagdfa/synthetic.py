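"""Synthetic vibroarthrographic (VAG) cohorts.

Clinical VAG recordings are knee-joint vibration signals captured by skin
microphones during repeated flexion-extension.  The generator here emulates
only the statistical structure the analysis pipeline measures:

* a cyclic amplitude envelope (``|sin(pi t / cycle_s)|``, one hump per
  movement cycle),
* three band-limited noise carriers (high / mid / low frequency) with
  group-dependent relative energies and centre frequencies,
* short damped high-frequency bursts ("clicks") at a Poisson rate, standing in
  for crepitus events,
* an additive fluctuation component with two scaling regimes (distinct
  short/long-scale Hurst behaviour and a planted crossover scale), so the
  dual-scaling DFA stage has a known ground truth.

Group differences (healthy controls ``HC`` vs osteoarthritis ``OA``) are
expressed purely through these profile parameters.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import RawRecording, RecordingMeta

__all__ = [
    "GroupProfile",
    "CohortSpec",
    "generate_fgn",
    "generate_one_over_f",
    "generate_crossover_series",
    "generate_recording",
    "generate_cohort",
    "default_profiles",
]


@dataclass(frozen=True)
class GroupProfile:
    """Statistical fingerprint of one subject group.

    ``band_energy`` are relative powers (high, mid, low); ``band_centers_hz``
    the corresponding carrier centre frequencies.  ``H_short``/``H_long`` set
    the Hurst behaviour of the additive fluctuation component below/above the
    ``crossover_s`` scale (seconds).  ``click_rate_hz`` is the expected number
    of damped high-frequency bursts per second and ``mod_depth`` the depth of
    the cyclic amplitude modulation.
    """

    band_energy: tuple[float, float, float]
    band_centers_hz: tuple[float, float, float]
    H_short: float
    H_long: float
    crossover_s: float
    click_rate_hz: float = 0.0
    mod_depth: float = 1.0
    fluct_amp: float = 0.35  # RMS of fluctuation component relative to band noise

    def __post_init__(self) -> None:
        hi, mid, lo = self.band_centers_hz
        if not hi > mid > lo:
            raise ValueError("band_centers_hz must be ordered high > mid > low")
        for h in (self.H_short, self.H_long):
            if not 0.0 < h < 1.0:
                raise ValueError("Hurst exponents must lie in (0, 1)")
        if min(self.band_energy) < 0:
            raise ValueError("band energies must be nonnegative")
        if not 0.0 <= self.mod_depth <= 1.0:
            raise ValueError("mod_depth must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Size, sampling and group profiles of a synthetic cohort."""

    n_per_group: int
    fs_hz: float = 4000.0
    n_cycles: int = 10
    cycle_s: float = 3.0
    channels: tuple[str, ...] = ("K1",)
    chain: str = "CKC"
    profiles: dict[str, GroupProfile] = field(default_factory=lambda: default_profiles())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        dur = self.n_cycles * self.cycle_s
        for g, p in self.profiles.items():
            if p.crossover_s >= dur / 2:
                raise ValueError(f"profile {g}: crossover_s must be < duration/2")


def default_profiles(fs_hz: float = 4000.0) -> dict[str, GroupProfile]:
    """Study-condition profiles for the two groups.

    OA joints produce more high-frequency crepitus (higher click rate and
    high-band share), stiffer short-scale control (higher ``H_short``) and a
    crossover at a larger fraction of the recording, mirroring the qualitative
    group contrasts the pipeline is meant to detect.  Band centres are placed
    at 600/200/50 Hz when Nyquist allows, otherwise scaled down proportionally.
    """
    scale = min(1.0, fs_hz / 4000.0)
    centers = (600.0 * scale, 200.0 * scale, 50.0 * scale)
    hc = GroupProfile(
        band_energy=(0.15, 0.30, 0.55),
        band_centers_hz=centers,
        H_short=0.60,
        H_long=0.85,
        crossover_s=0.25,
        click_rate_hz=0.5,
        mod_depth=0.9,
    )
    oa = GroupProfile(
        band_energy=(0.45, 0.30, 0.25),
        band_centers_hz=centers,
        H_short=0.85,
        H_long=0.60,
        crossover_s=0.60,
        click_rate_hz=6.0,
        mod_depth=0.9,
    )
    return {"HC": hc, "OA": oa}


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------


def _fgn_autocov(H: float, n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    return 0.5 * (
        np.abs(k + 1) ** (2 * H) - 2 * np.abs(k) ** (2 * H) + np.abs(k - 1) ** (2 * H)
    )


def generate_fgn(H: float, n: int, seed: int) -> np.ndarray:
    """Exact stationary fractional Gaussian noise via circulant embedding.

    Embeds the length-``n`` fGn autocovariance in a circulant matrix of size
    ``2(n-1)`` (Davies-Harte); its FFT eigenvalues give an exact sampler.  If
    the embedding is not positive semi-definite (possible for H near 1 at
    small n) a spectral-synthesis approximation is used with a warning.
    Output has (population) unit variance by construction.
    """
    if not 0.0 < H < 1.0:
        raise ValueError("H must lie in (0, 1)")
    if n < 16:
        raise ValueError("n must be >= 16")
    rng = np.random.default_rng(seed)
    gamma = _fgn_autocov(H, n)
    # circulant first row: gamma_0..gamma_{n-1}, gamma_{n-2}..gamma_1
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        warnings.warn(
            "circulant embedding not positive semi-definite; "
            "falling back to spectral synthesis",
            RuntimeWarning,
        )
        return _fgn_spectral(H, n, rng)
    lam = np.clip(lam, 0.0, None)
    m = row.size
    # Re(FFT(sqrt(lam/m) g)) with iid complex standard normal g has exactly the
    # circulant covariance whose first row is `row`
    g = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    z = np.fft.fft(np.sqrt(lam / m) * g).real
    return z[:n]


def _fgn_spectral(H: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Approximate fGn by shaping white noise with PSD ~ f^(1-2H)."""
    freqs = np.fft.rfftfreq(2 * n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** ((1 - 2 * H) / 2.0)
    phase = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    x = np.fft.irfft(amp * phase, n=2 * n)[:n]
    return x / x.std()


def generate_one_over_f(n: int, seed: int) -> np.ndarray:
    """Unit-variance 1/f (pink) noise via spectral synthesis (alpha = 1 target)."""
    return _fgn_spectral(1.0, n, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# planted dual-scaling series
# ---------------------------------------------------------------------------


def generate_crossover_series(
    H_short: float,
    H_long: float,
    crossover_s: float | None,
    fs_hz: float,
    n: int,
    seed: int,
) -> np.ndarray:
    """Series with two DFA scaling regimes separated at a planted scale.

    The short-scale regime is fGn with Hurst ``H_short`` (DFA slope ~ H_short).
    The long-scale regime is the cumulative sum of a low-pass filtered
    (cutoff ``1/crossover_s`` Hz) fGn with Hurst ``H_long``, whose DFA slope
    exceeds 1 (integrated noise).  The long component's amplitude is calibrated
    so both components have equal fluctuation F(n) at the planted scale
    ``crossover_s * fs_hz`` samples, which pins the crossover there.

    With ``crossover_s=None`` no filtering or integration is applied and the
    result is a plain unit-variance mixture of the two fGns (a single-regime
    series when ``H_short == H_long``).
    """
    from . import dfa

    ss = np.random.SeedSequence(seed).spawn(2)
    short = generate_fgn(H_short, n, seed=int(ss[0].generate_state(1)[0] % 2**31))
    long_raw = generate_fgn(H_long, n, seed=int(ss[1].generate_state(1)[0] % 2**31))

    if crossover_s is None:
        mix = short + long_raw
        return mix / mix.std()

    bp_samples = crossover_s * fs_hz
    if not 8 <= bp_samples <= n / 4:
        raise ValueError(
            f"crossover at {bp_samples:.0f} samples outside representable range [8, n/4]"
        )
    cutoff = 1.0 / crossover_s
    sos = sps.butter(4, cutoff, btype="low", fs=fs_hz, output="sos")
    slow = np.cumsum(sps.sosfiltfilt(sos, long_raw))
    slow -= slow.mean()

    n_star = int(round(bp_samples))
    f_short = dfa.fluctuation(dfa.dfa_profile(short), n_star)
    f_slow = dfa.fluctuation(dfa.dfa_profile(slow), n_star)
    slow *= f_short / f_slow
    out = short + slow
    return out / out.std()


# ---------------------------------------------------------------------------
# recordings and cohorts
# ---------------------------------------------------------------------------


def _band_noise(center_hz: float, fs_hz: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed around ``center_hz`` (±35%)."""
    lo = max(center_hz * 0.65, 1.0)
    hi = min(center_hz * 1.35, 0.49 * fs_hz)
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs_hz, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _clicks(rate_hz: float, fs_hz: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Poisson train of exponentially damped 600-900 Hz tone bursts."""
    out = np.zeros(n)
    if rate_hz <= 0:
        return out
    n_events = rng.poisson(rate_hz * n / fs_hz)
    dur = int(0.01 * fs_hz)  # 10 ms burst
    t = np.arange(dur) / fs_hz
    f_hi = min(900.0, 0.45 * fs_hz)
    f_lo = min(600.0, 0.30 * fs_hz)
    for _ in range(n_events):
        start = rng.integers(0, max(n - dur, 1))
        f = rng.uniform(f_lo, f_hi)
        burst = np.exp(-t / 0.002) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        out[start : start + dur] += burst * rng.uniform(2.0, 4.0)
    return out


def generate_recording(
    profile: GroupProfile, spec: CohortSpec, subject_id: str, seed: int,
    group: str = "HC", channel: str = "K1",
) -> RawRecording:
    """One synthetic VAG recording of ``spec.n_cycles`` flexion-extension cycles."""
    rng = np.random.default_rng(seed)
    fs = spec.fs_hz
    n = int(round(spec.n_cycles * spec.cycle_s * fs))
    t = np.arange(n) / fs

    energies = np.asarray(profile.band_energy, dtype=float)
    total = energies.sum()
    if total > 0:
        energies = energies / total
    carrier = np.zeros(n)
    for e, c in zip(energies, profile.band_centers_hz):
        if e > 0:
            carrier += np.sqrt(e) * _band_noise(c, fs, n, rng)
    carrier += _clicks(profile.click_rate_hz, fs, n, rng)

    envelope = 1.0 - profile.mod_depth + profile.mod_depth * np.abs(
        np.sin(np.pi * t / spec.cycle_s)
    )
    x = envelope * carrier

    fluct = generate_crossover_series(
        profile.H_short,
        profile.H_long,
        profile.crossover_s,
        fs,
        n,
        seed=int(np.random.SeedSequence(seed + 1).generate_state(1)[0] % 2**31),
    )
    rms = x.std() if x.std() > 0 else 1.0
    x = x + profile.fluct_amp * rms * fluct

    meta = RecordingMeta(
        subject_id=subject_id, group=group, channel=channel, chain=spec.chain, fs_hz=fs
    )
    return RawRecording(samples=x, meta=meta)


def _subject_seed(base_seed: int, group: str, subject: str, channel: str) -> int:
    """Stable per-(subject, channel) seed so cohorts extend without reshuffling."""
    digest = hashlib.sha256(f"{base_seed}|{group}|{subject}|{channel}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % 2**31


def generate_cohort(spec: CohortSpec) -> tuple[list[RawRecording], "pandas.DataFrame"]:
    """Full balanced cohort plus a manifest table in the signal-io dialect."""
    import pandas as pd

    recordings: list[RawRecording] = []
    rows = []
    for group in sorted(spec.profiles):
        profile = spec.profiles[group]
        for i in range(spec.n_per_group):
            subject = f"s{i:03d}"
            for channel in spec.channels:
                seed = _subject_seed(spec.seed, group, subject, channel)
                rec = generate_recording(
                    profile, spec, subject_id=subject, seed=seed,
                    group=group, channel=channel,
                )
                recordings.append(rec)
                rows.append(
                    {
                        "path": f"{group}_{subject}_{spec.chain}_{channel}.csv",
                        "subject_id": subject,
                        "group": group,
                        "chain": spec.chain,
                        "channel": channel,
                        "fs_hz": spec.fs_hz,
                    }
                )
    return recordings, pd.DataFrame(rows)
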