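"""First-order statistics over a 256-bin intensity histogram (F21-F69).

Seven statistics — mean, standard deviation, smoothness 1 - 1/(1+var),
variance, skewness, kurtosis (excess), energy — computed from the
normalized 256-bin histogram of the masked pixel values of each of seven
color components (R, G, B, H, S, V, gray), all on the 0-255 scale.  For
integer-valued components the histogram route agrees with direct moments
of the pixel list exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["histogram_256", "fos_statistics", "FOS_STAT_NAMES"]

FOS_STAT_NAMES = ["mean", "std", "smoothness", "variance", "skewness", "kurtosis", "energy"]


def histogram_256(values: np.ndarray) -> np.ndarray:
    """Normalized 256-bin histogram; values are rounded to levels 0..255."""
    v = np.rint(np.asarray(values, dtype=float)).astype(int)
    v = np.clip(v, 0, 255)
    counts = np.bincount(v, minlength=256).astype(float)
    return counts / counts.sum()


def fos_statistics(p: np.ndarray) -> np.ndarray:
    """The seven first-order statistics of a normalized histogram.

    With sigma = 0 (single occupied bin) skewness and kurtosis are defined
    as 0, so constant regions yield finite features.
    """
    p = np.asarray(p, dtype=float)
    levels = np.arange(p.size, dtype=float)
    mean = float(np.sum(levels * p))
    var = float(np.sum((levels - mean) ** 2 * p))
    std = np.sqrt(var)
    smooth = 1.0 - 1.0 / (1.0 + var)
    if std > 0:
        skew = float(np.sum((levels - mean) ** 3 * p)) / std**3
        kurt = float(np.sum((levels - mean) ** 4 * p)) / std**4 - 3.0
    else:
        skew = 0.0
        kurt = 0.0
    energy = float(np.sum(p**2))
    return np.array([mean, std, smooth, var, skew, kurt, energy])
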