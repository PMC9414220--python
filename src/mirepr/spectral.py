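"""Short-time Fourier spectrograms and their 8-bit image rendering.

The transform follows the conventions of :func:`scipy.signal.spectrogram`
with a 1 s sliding window and 90% overlap at 160 Hz: 160-sample segments
every 16 samples, a Tukey(0.25) taper by default, one-sided power spectral
density.  A 640-sample epoch therefore yields an 81 x 31 power matrix
(81 = 160/2 + 1 frequency bins, 31 = floor((640-160)/16) + 1 frames).

Rendering maps power through log(1+P), per-image min-max normalization and
a perceptually uniform colormap to RGB, then resizes bilinearly.  The
transform itself fixes none of these display choices, so they are explicit
parameters recorded in dataset manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from typing import Optional, Tuple, Union

import numpy as np
from PIL import Image
from scipy import signal as _signal

__all__ = ["SpectrogramParams", "stft_power", "render_power_image"]


@dataclass(frozen=True)
class SpectrogramParams:
    """Sliding-window transform and rendering parameters."""

    window_seconds: float = 1.0
    overlap_fraction: float = 0.9
    window_shape: Union[str, Tuple] = ("tukey", 0.25)
    fs: float = 160.0
    power_scale: str = "log"        # 'log' -> log(1+P) before normalizing
    colormap: str = "viridis"
    image_size: Tuple[int, int] = (32, 32)   # single-channel images, (W, H)

    def __post_init__(self):
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        n = self.window_seconds * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window_seconds * fs must be an integer")
        if self.power_scale not in ("linear", "log"):
            raise ValueError("power_scale must be 'linear' or 'log'")

    @property
    def nperseg(self) -> int:
        return int(round(self.window_seconds * self.fs))

    @property
    def noverlap(self) -> int:
        return int(round(self.nperseg * self.overlap_fraction))

    @property
    def step(self) -> int:
        return self.nperseg - self.noverlap

    def digest(self) -> str:
        payload = asdict(self)
        payload["window_shape"] = list(np.atleast_1d(self.window_shape))
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def stft_power(x: np.ndarray, params: Optional[SpectrogramParams] = None
               ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sided PSD spectrogram of a 1D signal.

    Returns ``(freqs, times, power)`` with power shaped
    [n_freq x n_frames].  No detrending is applied — the raw signal goes
    into the window untouched.
    """
    params = params or SpectrogramParams()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError(f"expected a 1D signal, got shape {x.shape}")
    if x.size < params.nperseg:
        raise ValueError(
            f"signal length {x.size} is shorter than the "
            f"{params.nperseg}-sample window")
    freqs, times, power = _signal.spectrogram(
        x, fs=params.fs, window=params.window_shape,
        nperseg=params.nperseg, noverlap=params.noverlap,
        detrend=False, scaling="density", mode="psd")
    return freqs, times, power


def render_power_image(power: np.ndarray,
                       params: Optional[SpectrogramParams] = None,
                       size: Optional[Tuple[int, int]] = None) -> np.ndarray:
    """Render a nonnegative power matrix as an 8-bit RGB array.

    ``size`` is (width, height); ``None`` keeps the native matrix size.
    Normalization is per image, so non-constant inputs span the full 8-bit
    range.  Frequency increases downward (row 0 = lowest frequency at the
    top of the rendered block).
    """
    params = params or SpectrogramParams()
    p = np.asarray(power, dtype=np.float64)
    if params.power_scale == "log":
        p = np.log1p(p)
    lo, hi = p.min(), p.max()
    norm = (p - lo) / (hi - lo) if hi > lo else np.zeros_like(p)
    from matplotlib import colormaps

    rgba = colormaps[params.colormap](norm)[..., :3]
    # final per-image stretch so non-constant images span the full 8-bit
    # range regardless of the colormap's own endpoints
    lo, hi = rgba.min(), rgba.max()
    if hi > lo:
        rgba = (rgba - lo) / (hi - lo)
    rgb = (rgba * 255.0 + 0.5).astype(np.uint8)
    if size is not None and size != (rgb.shape[1], rgb.shape[0]):
        img = Image.fromarray(rgb, mode="RGB").resize(size, Image.BILINEAR)
        rgb = np.asarray(img)
    return rgb
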