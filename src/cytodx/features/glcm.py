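"""Gray-level cooccurrence matrix (GLCM) texture statistics (F70-F157).

The gray channel is quantized to NG=8 uniform levels over [0, 255]; for
each of the four orientations (0, 45, 90, 135 degrees, offset distance
d=1) pairs are counted only when both pixels lie inside the nucleus
mask, accumulated symmetrically and normalized to a probability matrix.
Twenty-two statistics are derived per orientation.  Levels are 1-based
(i, j = 1..8) in every formula, matching the classical texture-analysis
convention; logarithms are natural and 0 log 0 = 0.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GLCM_STAT_NAMES",
    "GLCM_OFFSETS",
    "quantize_gray",
    "cooccurrence_matrix",
    "glcm_statistics",
]

NG = 8

#: (drow, dcol) offsets; angles measured counterclockwise with the image
#: row axis pointing down, as is conventional for texture orientations.
GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_STAT_NAMES = [
    "autocorrelation",
    "contrast",
    "correlation_i",
    "correlation_ii",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity_i",
    "homogeneity_ii",
    "maximum_probability",
    "sum_of_square",
    "sum_average",
    "sum_energy",
    "sum_variance",
    "difference_variance",
    "difference_entropy",
    "imc_i",
    "imc_ii",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
]


def quantize_gray(gray: np.ndarray, levels: int = NG) -> np.ndarray:
    """Uniform quantization of [0, 255] intensities to 1..levels."""
    g = np.clip(np.rint(np.asarray(gray, dtype=float)), 0, 255)
    return np.minimum((g * levels / 256.0).astype(int), levels - 1) + 1


def cooccurrence_matrix(
    quantized: np.ndarray, mask: np.ndarray, angle: int, levels: int = NG
) -> np.ndarray:
    """Symmetric normalized cooccurrence matrix for one orientation.

    Raises ``ValueError`` when the mask admits no valid pixel pair at the
    orientation's offset.
    """
    dr, dc = GLCM_OFFSETS[angle]
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    counts = np.zeros((levels, levels), dtype=float)
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a_mask = mask[r0s:r0e, c0s:c0e]
    b_mask = mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    valid = a_mask & b_mask
    if not valid.any():
        raise ValueError(f"no in-mask pixel pair at orientation {angle}")
    a = quantized[r0s:r0e, c0s:c0e][valid] - 1
    b = quantized[r0s + dr : r0e + dr, c0s + dc : c0e + dc][valid] - 1
    np.add.at(counts, (a, b), 1.0)
    np.add.at(counts, (b, a), 1.0)
    return counts / counts.sum()


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def glcm_statistics(p: np.ndarray) -> np.ndarray:
    """The 22 cooccurrence statistics of one normalized GLCM."""
    levels = p.shape[0]
    i = np.arange(1, levels + 1, dtype=float)[:, None]
    j = np.arange(1, levels + 1, dtype=float)[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    lv = np.arange(1, levels + 1, dtype=float)
    mu_x = float(np.sum(lv * px))
    mu_y = float(np.sum(lv * py))
    sd_x = float(np.sqrt(np.sum((lv - mu_x) ** 2 * px)))
    sd_y = float(np.sqrt(np.sum((lv - mu_y) ** 2 * py)))

    # p_{x+y}(k), k = 2..2L and p_{x-y}(k), k = 0..L-1
    ksum = np.arange(2, 2 * levels + 1, dtype=float)
    p_sum = np.zeros(2 * levels - 1)
    kdiff = np.arange(0, levels, dtype=float)
    p_diff = np.zeros(levels)
    ii, jj = np.meshgrid(np.arange(1, levels + 1), np.arange(1, levels + 1), indexing="ij")
    np.add.at(p_sum, (ii + jj - 2).ravel(), p.ravel())
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())

    autocorr = float(np.sum(i * j * p))
    contrast = float(np.sum((i - j) ** 2 * p))
    if sd_x > 0 and sd_y > 0:
        corr_i = float(np.sum((i - mu_x) * (j - mu_y) * p)) / (sd_x * sd_y)
        corr_ii = (autocorr - mu_x * mu_y) / (sd_x * sd_y)
    else:
        corr_i = corr_ii = 0.0
    cluster_prom = float(np.sum((i + j - mu_x - mu_y) ** 4 * p))
    cluster_shade = float(np.sum((i + j - mu_x - mu_y) ** 3 * p))
    dissim = float(np.sum(np.abs(i - j) * p))
    energy = float(np.sum(p**2))
    entropy = -float(np.sum(_xlogx(p)))
    homog_i = float(np.sum(p / (1.0 + np.abs(i - j))))
    homog_ii = float(np.sum(p / (1.0 + (i - j) ** 2)))
    max_prob = float(p.max())
    sum_of_square = float(np.sum((i - mu_x) ** 2 * p))
    sum_average = float(np.sum(ksum * p_sum))
    sum_energy = -float(np.sum(_xlogx(p_sum)))  # entropy of p_{x+y}, as tabulated
    sum_variance = float(np.sum((ksum - sum_energy) ** 2 * p_sum))
    diff_variance = float(np.sum(kdiff**2 * p_diff))
    diff_entropy = -float(np.sum(_xlogx(p_diff)))

    hxy = entropy
    pxpy = px[:, None] * py[None, :]
    lg = np.zeros_like(pxpy)
    nz = pxpy > 0
    lg[nz] = np.log(pxpy[nz])
    hxy1 = -float(np.sum(p * lg))
    hxy2 = -float(np.sum(_xlogx(pxpy)))
    hx = -float(np.sum(_xlogx(px)))
    hy = -float(np.sum(_xlogx(py)))
    denom = max(hx, hy)
    imc_i = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc_ii = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    idn = float(np.sum(p / (1.0 + np.abs(i - j) / levels)))
    idmn = float(np.sum(p / (1.0 + (i - j) ** 2 / levels**2)))

    return np.array(
        [
            autocorr, contrast, corr_i, corr_ii, cluster_prom, cluster_shade,
            dissim, energy, entropy, homog_i, homog_ii, max_prob,
            sum_of_square, sum_average, sum_energy, sum_variance,
            diff_variance, diff_entropy, imc_i, imc_ii, idn, idmn,
        ]
    )
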