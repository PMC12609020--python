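"""CWT scalograms and fixed-size jet-colormap RGB images.

Signals (raw or reconstructed) are transformed with a complex Morlet wavelet
(carrier angular frequency ~6, i.e. centre frequency 0.9549 cycles/sample at
scale 1) over 64 logarithmically spaced scales whose pseudo-frequencies span
5 Hz to fs/2.5.  The magnitude matrix is min-max normalized per image, mapped
through a pinned 256-entry jet lookup table and bilinearly resized to a square
resolution (128 or 256), so every image in a run is produced by the identical
scale grid and colour mapping.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "WAVELET",
    "CENTER_FREQ_CYCLES",
    "ScaleGrid",
    "ScalogramImage",
    "default_scale_grid",
    "combine_channels",
    "cwt_magnitude",
    "jet_lut",
    "to_rgb_image",
    "save_png",
]

#: complex Morlet: bandwidth 2.0 (Gaussian envelope exp(-t^2/2)),
#: centre frequency 6/(2*pi) ~ 0.9549 cycles per sample at scale 1
WAVELET = "cmor2.0-0.9549"
CENTER_FREQ_CYCLES = 0.9549
N_SCALES = 64
F_MIN_HZ = 5.0


@dataclass(frozen=True)
class ScaleGrid:
    scales: np.ndarray
    pseudo_freqs_hz: np.ndarray
    wavelet_id: str
    fs_hz: float

    @property
    def grid_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.wavelet_id.encode())
        h.update(np.asarray(self.scales, float).tobytes())
        h.update(np.float64(self.fs_hz).tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class ScalogramImage:
    pixels: np.ndarray  # (res, res, 3) uint8
    source_id: str
    resolution: int
    grid_hash: str
    degenerate: bool = False


def default_scale_grid(fs_hz: float, n_scales: int = N_SCALES) -> ScaleGrid:
    """Log-spaced scales covering pseudo-frequencies [5 Hz, fs/2.5]."""
    f_max = fs_hz / 2.5
    if f_max <= F_MIN_HZ:
        raise ValueError("sampling rate too low for the default frequency span")
    freqs = np.geomspace(F_MIN_HZ, f_max, n_scales)
    scales = CENTER_FREQ_CYCLES * fs_hz / freqs
    return ScaleGrid(scales=scales, pseudo_freqs_hz=freqs, wavelet_id=WAVELET, fs_hz=fs_hz)


def combine_channels(*channels: np.ndarray) -> np.ndarray:
    """Element-wise sum of the sensor channels (K1+K2+K3).

    Unequal lengths are truncated to the shortest with a warning.
    """
    arrays = [np.asarray(c, dtype=float) for c in channels]
    n = min(a.size for a in arrays)
    if any(a.size != n for a in arrays):
        import warnings

        warnings.warn("channel lengths differ; truncating to the shortest")
    return np.sum([a[:n] for a in arrays], axis=0)


def cwt_magnitude(x: np.ndarray, grid: ScaleGrid) -> np.ndarray:
    """|CWT| matrix (scales x time) on the shared grid."""
    x = np.asarray(x, dtype=float)
    if x.size < 256:
        raise ValueError("need >= 256 samples")
    coef, _ = pywt.cwt(
        x, grid.scales, grid.wavelet_id, sampling_period=1.0 / grid.fs_hz, method="fft"
    )
    return np.abs(coef)


def jet_lut() -> np.ndarray:
    """Pinned 256-entry jet lookup table (classic blue-cyan-yellow-red ramp)."""
    v = np.linspace(0.0, 1.0, 256)
    r = np.clip(1.5 - np.abs(4 * v - 3), 0, 1)
    g = np.clip(1.5 - np.abs(4 * v - 2), 0, 1)
    b = np.clip(1.5 - np.abs(4 * v - 1), 0, 1)
    return np.round(np.stack([r, g, b], axis=1) * 255).astype(np.uint8)


_JET = jet_lut()


def _bilinear_resize(m: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = m.shape
    interp = RegularGridInterpolator(
        (np.arange(h), np.arange(w)), m, method="linear", bounds_error=False, fill_value=None
    )
    yi = np.linspace(0, h - 1, out_h)
    xi = np.linspace(0, w - 1, out_w)
    yy, xx = np.meshgrid(yi, xi, indexing="ij")
    return interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(out_h, out_w)


def to_rgb_image(
    m: np.ndarray, resolution: int, source_id: str = "", grid_hash: str = ""
) -> ScalogramImage:
    """Min-max normalize, map through the jet LUT, bilinear-resize to square.

    A constant matrix (e.g. the scalogram of an all-zero reconstruction) maps
    to the mid-colormap value everywhere and sets the ``degenerate`` flag.
    """
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite entries in scalogram matrix")
    lo, hi = m.min(), m.max()
    degenerate = hi == lo
    if degenerate:
        resized = np.full((resolution, resolution), 0.5)
    else:
        norm = (m - lo) / (hi - lo)
        resized = np.clip(_bilinear_resize(norm, resolution, resolution), 0.0, 1.0)
    idx = np.round(resized * 255).astype(np.intp)
    pixels = _JET[idx]
    return ScalogramImage(
        pixels=pixels,
        source_id=source_id,
        resolution=resolution,
        grid_hash=grid_hash,
        degenerate=degenerate,
    )


def save_png(image: ScalogramImage, path) -> None:
    from PIL import Image

    Image.fromarray(image.pixels, mode="RGB").save(path, format="PNG")
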