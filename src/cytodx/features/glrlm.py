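"""Gray-level run-length matrix (GLRLM) texture statistics (F158-F201).

A run is a maximal sequence of consecutive in-mask pixels sharing one
quantized gray level along an orientation's scan lines; runs truncate at
the mask boundary.  Eleven statistics per orientation, with the same
8-level 1-based quantization as the cooccurrence features.
"""

from __future__ import annotations

import numpy as np

from .glcm import NG, quantize_gray

__all__ = ["GLRLM_STAT_NAMES", "run_length_matrix", "glrlm_statistics", "extract_runs"]

GLRLM_STAT_NAMES = [
    "short_run_emphasis",
    "long_run_emphasis",
    "low_gray_run_emphasis",
    "high_gray_run_emphasis",
    "short_run_low_gray_emphasis",
    "short_run_high_gray_emphasis",
    "long_run_low_gray_emphasis",
    "long_run_high_gray_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
]


def _scan_lines(h: int, w: int, angle: int):
    """Pixel index sequences of every scan line for one orientation."""
    if angle == 0:  # along rows, left to right
        for r in range(h):
            yield [(r, c) for c in range(w)]
    elif angle == 90:  # along columns
        for c in range(w):
            yield [(r, c) for r in range(h)]
    elif angle == 45:  # up-right anti-diagonals (r+c constant, r descending)
        for d in range(h + w - 1):
            yield [(r, d - r) for r in range(h - 1, -1, -1) if 0 <= d - r < w]
    elif angle == 135:  # down-right diagonals
        for d in range(-(h - 1), w):
            yield [(r, r + d) for r in range(h) if 0 <= r + d < w]
    else:
        raise ValueError(f"unsupported orientation {angle}")


def extract_runs(quantized: np.ndarray, mask: np.ndarray, angle: int) -> list[tuple[int, int]]:
    """All maximal (level, length) runs inside the mask for one orientation."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    runs: list[tuple[int, int]] = []
    for line in _scan_lines(h, w, angle):
        level = None
        length = 0
        for r, c in line:
            if mask[r, c]:
                v = int(quantized[r, c])
                if v == level:
                    length += 1
                else:
                    if level is not None:
                        runs.append((level, length))
                    level, length = v, 1
            else:
                if level is not None:
                    runs.append((level, length))
                level, length = None, 0
        if level is not None:
            runs.append((level, length))
    return runs


def run_length_matrix(
    quantized: np.ndarray, mask: np.ndarray, angle: int, levels: int = NG
) -> np.ndarray:
    """Counts g(i, j) of runs of level i (1..levels) and length j (1..R)."""
    runs = extract_runs(quantized, mask, angle)
    if not runs:
        return np.zeros((levels, 1))
    max_len = max(length for _, length in runs)
    g = np.zeros((levels, max_len))
    for level, length in runs:
        g[level - 1, length - 1] += 1
    return g


def glrlm_statistics(g: np.ndarray, n_pixels: int) -> np.ndarray:
    """The 11 run-length statistics of one run-length count matrix."""
    n_r = float(g.sum())
    if n_r == 0:
        return np.zeros(len(GLRLM_STAT_NAMES))
    i = np.arange(1, g.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, g.shape[1] + 1, dtype=float)[None, :]
    return np.array(
        [
            float(np.sum(g / j**2)) / n_r,
            float(np.sum(g * j**2)) / n_r,
            float(np.sum(g / i**2)) / n_r,
            float(np.sum(g * i**2)) / n_r,
            float(np.sum(g / (i**2 * j**2))) / n_r,
            float(np.sum(g * i**2 / j**2)) / n_r,
            float(np.sum(g * j**2 / i**2)) / n_r,
            float(np.sum(g * i**2 * j**2)) / n_r,
            float(np.sum(g.sum(axis=1) ** 2)) / n_r,
            float(np.sum(g.sum(axis=0) ** 2)) / n_r,
            n_r / float(n_pixels),
        ]
    )
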