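"""Reading, writing and preprocessing of VAG recordings.

Recordings are one-channel acoustic time series from contact microphones
placed around the knee (channels K1-K3), captured while the subject performs
ten flexion-extension cycles in an open (OKC) or closed (CKC) kinetic chain.
Preprocessing follows the standard sequence: trim to the active-motion cycles,
remove sub-10 Hz baseline with a fourth-order Butterworth high-pass, and
min-max normalize to [0, 1].
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile
from scipy.ndimage import uniform_filter1d

__all__ = [
    "RecordingMeta",
    "RawRecording",
    "PreprocessedSignal",
    "read_recording",
    "read_manifest",
    "parse_filename",
    "detect_cycles",
    "remove_low_frequency",
    "normalize_unit_interval",
    "preprocess",
    "write_signal",
]

GROUPS = ("HC", "OA")
CHANNELS = ("K1", "K2", "K3")
CHAINS = ("OKC", "CKC")

_FILENAME_RE = re.compile(
    r"^(?P<group>HC|OA)_(?P<subject>[^_]+)_(?P<chain>OKC|CKC)_(?P<channel>K[123])$"
)


@dataclass(frozen=True)
class RecordingMeta:
    subject_id: str
    group: str
    channel: str
    chain: str
    fs_hz: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.chain not in CHAINS:
            raise ValueError(f"unknown chain {self.chain!r}; expected one of {CHAINS}")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")


@dataclass(frozen=True)
class RawRecording:
    samples: np.ndarray
    meta: RecordingMeta

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", samples)


@dataclass(frozen=True)
class PreprocessedSignal:
    """Trimmed, high-passed, [0, 1]-normalized signal with cycle bookkeeping."""

    samples: np.ndarray
    cycle_bounds: list[tuple[int, int]]
    cycle_len: float
    meta: RecordingMeta
    degenerate: bool = False
    incomplete_cycles: bool = False


def parse_filename(path: str | Path) -> dict[str, str]:
    """Recover labels from a ``<group>_<subject>_<chain>_<channel>`` file name."""
    stem = Path(path).stem
    m = _FILENAME_RE.match(stem)
    if m is None:
        raise ValueError(
            f"cannot parse labels from file name {stem!r}; "
            "expected <group>_<subject>_<chain>_<channel>"
        )
    return {
        "group": m["group"],
        "subject_id": m["subject"],
        "chain": m["chain"],
        "channel": m["channel"],
    }


def _read_samples(path: Path) -> tuple[np.ndarray, float | None]:
    if path.suffix.lower() == ".wav":
        fs, data = wavfile.read(path)
        data = np.asarray(data, dtype=float)
        if data.ndim != 1:
            raise ValueError(f"{path}: expected a 1-channel WAV file")
        return data, float(fs)
    try:
        data = np.loadtxt(path, dtype=float, delimiter=None, ndmin=1)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric content") from exc
    if data.ndim != 1:
        raise ValueError(f"{path}: expected a single numeric column")
    return data, None


def read_recording(path: str | Path, manifest_row: dict | None = None) -> RawRecording:
    """Load one recording from delimited text or 1-channel WAV.

    When ``manifest_row`` is given it is authoritative for all metadata;
    otherwise labels are parsed from the file name and ``fs_hz`` must come from
    the WAV header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    samples, wav_fs = _read_samples(path)
    if manifest_row is not None:
        meta = RecordingMeta(
            subject_id=str(manifest_row["subject_id"]),
            group=str(manifest_row["group"]),
            channel=str(manifest_row["channel"]),
            chain=str(manifest_row["chain"]),
            fs_hz=float(manifest_row["fs_hz"]),
        )
    else:
        labels = parse_filename(path)
        if wav_fs is None:
            raise ValueError(f"{path}: fs_hz unknown; provide a manifest row for text files")
        meta = RecordingMeta(fs_hz=wav_fs, **labels)
    return RawRecording(samples=samples, meta=meta)


def read_manifest(path: str | Path):
    """Load a manifest CSV (columns: path,subject_id,group,chain,channel,fs_hz)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"path", "subject_id", "group", "chain", "channel", "fs_hz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def detect_cycles(
    x: np.ndarray, fs_hz: float, n_cycles: int = 10
) -> tuple[list[tuple[int, int]], bool]:
    """Segment the active-motion portion into movement cycles.

    The rectified signal is smoothed with a 0.25 s moving average; envelope
    peaks at least 0.5 s apart mark cycle centres and the envelope minima
    between consecutive peaks (slope sign changes) mark cycle boundaries.
    Returns up to ``n_cycles`` ordered non-overlapping ``(start, end)`` index
    pairs and a flag that is True when fewer than ``n_cycles`` were found.
    """
    x = np.asarray(x, dtype=float)
    if x.size < fs_hz:
        raise ValueError("need at least one second of signal")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    env = uniform_filter1d(np.abs(x - x.mean()), size=max(int(0.25 * fs_hz), 1))
    if env.max() <= 0 or env.std() < 1e-12 * max(env.max(), 1.0):
        return [], True
    min_sep = max(int(0.5 * fs_hz), 1)
    prominence = 0.15 * (env.max() - env.min())
    peaks, _ = sps.find_peaks(
        env, distance=min_sep, height=0.2 * env.max(), prominence=prominence
    )
    if peaks.size == 0:
        return [], True
    bounds = []
    # leading boundary: envelope minimum before the first peak
    lead = max(peaks[0] - min_sep, 0)
    starts = [lead + int(np.argmin(env[lead : peaks[0] + 1]))]
    for a, b in zip(peaks[:-1], peaks[1:]):
        starts.append(a + int(np.argmin(env[a : b + 1])))
    tail_end = min(peaks[-1] + min_sep, x.size - 1)
    starts.append(peaks[-1] + int(np.argmin(env[peaks[-1] : tail_end + 1])))
    for s, e in zip(starts[:-1], starts[1:]):
        if e > s:
            bounds.append((int(s), int(e)))
    bounds = bounds[:n_cycles]
    return bounds, len(bounds) < n_cycles


def remove_low_frequency(
    x: np.ndarray,
    fs_hz: float,
    order: int = 4,
    cutoff_hz: float = 10.0,
    zero_phase: bool = False,
) -> np.ndarray:
    """Butterworth high-pass (default: causal single pass, 4th order, 10 Hz)."""
    if not fs_hz > 2 * cutoff_hz:
        raise ValueError("cutoff must be below Nyquist")
    sos = sps.butter(order, cutoff_hz, btype="high", fs=fs_hz, output="sos")
    x = np.asarray(x, dtype=float)
    return sps.sosfiltfilt(sos, x) if zero_phase else sps.sosfilt(sos, x)


def normalize_unit_interval(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min-max map to [0, 1]; constant input maps to all 0.5 with a flag."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 0.5), True
    return (x - lo) / (hi - lo), False


def preprocess(
    rec: RawRecording, n_cycles: int = 10, zero_phase: bool = False
) -> PreprocessedSignal:
    """Trim to detected cycles, high-pass above 10 Hz, normalize to [0, 1]."""
    bounds, incomplete = detect_cycles(rec.samples, rec.meta.fs_hz, n_cycles=n_cycles)
    if bounds:
        t0, t1 = bounds[0][0], bounds[-1][1]
        trimmed = rec.samples[t0:t1]
        rel_bounds = [(s - t0, e - t0) for s, e in bounds]
    else:
        trimmed = rec.samples
        rel_bounds = []
    filtered = remove_low_frequency(trimmed, rec.meta.fs_hz, zero_phase=zero_phase)
    normalized, degenerate = normalize_unit_interval(filtered)
    if rel_bounds:
        cycle_len = float(np.mean([e - s for s, e in rel_bounds]))
    else:
        cycle_len = float(normalized.size)
    return PreprocessedSignal(
        samples=normalized,
        cycle_bounds=rel_bounds,
        cycle_len=cycle_len,
        meta=rec.meta,
        degenerate=degenerate,
        incomplete_cycles=incomplete,
    )


def write_signal(path: str | Path, signal: PreprocessedSignal) -> None:
    """Persist a preprocessed signal as delimited text plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, signal.samples, fmt="%.9g")
    sidecar = {
        "subject_id": signal.meta.subject_id,
        "group": signal.meta.group,
        "channel": signal.meta.channel,
        "chain": signal.meta.chain,
        "fs_hz": signal.meta.fs_hz,
        "cycle_bounds": signal.cycle_bounds,
        "cycle_len": signal.cycle_len,
        "degenerate": signal.degenerate,
        "incomplete_cycles": signal.incomplete_cycles,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
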