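"""Morphometric features F1-F14: nucleus size, shape irregularity, intensity.

The perimeter is the classical chain-code length of the 8-connected
boundary: axial steps count 1, diagonal steps sqrt(2).  Axis lengths come
from the image-moments best-fit ellipse.
"""

from __future__ import annotations

import math

import numpy as np
from skimage.measure import regionprops

__all__ = ["chain_code_perimeter", "morphometric_features", "MORPHOMETRIC_NAMES"]

MORPHOMETRIC_NAMES = [
    "area",
    "perimeter",
    "roundness",
    "solidity",
    "equivalent_diameter",
    "compactness",
    "eccentricity",
    "diameter",
    "major_axis_length",
    "minor_axis_length",
    "elongation",
    "max_intensity",
    "min_intensity",
    "mean_intensity",
]

# clockwise Moore neighbourhood starting north
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Moore-neighbour boundary trace of the (single) foreground blob."""
    padded = np.pad(np.asarray(mask, dtype=bool), 1)
    rs, cs = np.nonzero(padded)
    start = (int(rs[0]), int(cs[0]))  # topmost-then-leftmost
    path = [start]
    prev = (start[0], start[1] - 1)  # came from the west (background)
    cur = start
    limit = 4 * padded.sum() + 8
    for _ in range(int(limit)):
        di = _MOORE.index((prev[0] - cur[0], prev[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            idx = (di + k) % 8
            cand = (cur[0] + _MOORE[idx][0], cur[1] + _MOORE[idx][1])
            if padded[cand]:
                nxt = cand
                prev = (cur[0] + _MOORE[(di + k - 1) % 8][0], cur[1] + _MOORE[(di + k - 1) % 8][1])
                break
        if nxt is None:  # isolated pixel
            return path
        cur = nxt
        if cur == start:
            return path
        path.append(cur)
    return path


def chain_code_perimeter(mask: np.ndarray) -> float:
    """Boundary length: unit axial steps plus sqrt(2) diagonal steps.

    Single-pixel (or single-line) regions whose traced length would be 0
    return 1.0 so that ratio features downstream stay finite.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region")
    path = _trace_boundary(mask)
    if len(path) < 2:
        return 1.0
    closed = path + [path[0]]
    p = 0.0
    for (r0, c0), (r1, c1) in zip(closed[:-1], closed[1:]):
        p += math.sqrt(2.0) if (r0 != r1 and c0 != c1) else 1.0
    return p


def morphometric_features(mask: np.ndarray, gray: np.ndarray) -> np.ndarray:
    """The 14 morphometric features of one nucleus.

    ``gray`` is the luma image over the same crop as ``mask``; intensity
    features use only the masked pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region")
    props = regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perim = chain_code_perimeter(mask)
    vals = np.asarray(gray, dtype=float)[mask]
    ma = float(props.axis_major_length)
    mi = float(props.axis_minor_length)
    return np.array(
        [
            area,
            perim,
            4.0 * math.pi * area / perim**2,
            float(props.solidity),
            math.sqrt(4.0 * area / math.pi),
            area / perim**2,
            float(props.eccentricity),
            perim / math.pi,
            ma,
            mi,
            ma / perim,
            float(vals.max()),
            float(vals.min()),
            float(vals.mean()),
        ]
    )
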