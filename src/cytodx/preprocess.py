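"""Image normalisation: resize, contrast stretch, per-channel median filter.

Raw smear photographs vary in resolution, illumination and noise.  Every
image is first brought to a fixed square working resolution, then each
color channel is linearly stretched between two intensity percentiles
(saturating the tails), and finally median-filtered channel by channel to
suppress impulse noise while keeping nuclear edges sharp.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import median_filter
from skimage.transform import resize as _sk_resize

__all__ = ["PreprocessConfig", "resize", "adjust_intensity", "median_filter_rgb", "run", "load_image"]


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: tuple[int, int] = (1024, 1024)  # (height, width)
    stretch_low_pct: float = 1.0
    stretch_high_pct: float = 99.0
    median_kernel: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.stretch_low_pct < self.stretch_high_pct <= 100.0:
            raise ValueError("need 0 <= stretch_low_pct < stretch_high_pct <= 100")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if min(self.target_size) < 1:
            raise ValueError("target_size must be positive")


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {img.shape}")
    if img.size == 0:
        raise ValueError("empty image")
    return img


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG into an 8-bit RGB array (alpha dropped)."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] == 4:
        img = img[..., :3]
    return _check_rgb(img).astype(np.uint8)


def resize(img: np.ndarray, target_size: tuple[int, int] = (1024, 1024)) -> np.ndarray:
    """Resample to the fixed square working size (aspect is not preserved).

    Bilinear with anti-aliasing on downscale, so high-frequency content is
    band-limited before decimation and does not alias into the texture
    features downstream.
    """
    img = _check_rgb(img)
    if img.shape[:2] == tuple(target_size):
        return img.astype(np.uint8, copy=True)
    out = _sk_resize(
        img.astype(float),
        (*target_size, 3),
        order=1,
        anti_aliasing=img.shape[0] > target_size[0] or img.shape[1] > target_size[1],
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def adjust_intensity(img: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Per-channel linear percentile stretch to the full 8-bit range.

    The ``stretch_low_pct`` / ``stretch_high_pct`` percentile values map to
    0 and 255; intensities outside saturate.  A degenerate channel (all
    pixels equal) is returned unchanged.
    """
    img = _check_rgb(img)
    out = np.empty_like(img, dtype=np.uint8)
    for c in range(3):
        ch = img[..., c].astype(float)
        lo = np.percentile(ch, cfg.stretch_low_pct)
        hi = np.percentile(ch, cfg.stretch_high_pct)
        if hi <= lo:
            out[..., c] = img[..., c]
            continue
        stretched = (ch - lo) / (hi - lo) * 255.0
        out[..., c] = np.clip(np.rint(stretched), 0, 255).astype(np.uint8)
    return out


def median_filter_rgb(img: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Median filter applied to R, G and B independently (reflect edges)."""
    img = _check_rgb(img)
    k = cfg.median_kernel
    out = np.empty_like(img)
    for c in range(3):
        out[..., c] = median_filter(img[..., c], size=k, mode="reflect")
    return out


def run(img: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Full preprocessing chain: resize, stretch, median filter."""
    return median_filter_rgb(adjust_intensity(resize(img, cfg.target_size), cfg), cfg)
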