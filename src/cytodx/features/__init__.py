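"""The 201-dimensional per-nucleus feature vector, coded F1-F201.

Layout:

==========  =====  ==================================================
codes       count  content
==========  =====  ==================================================
F1-F14      14     morphometric (size, shape irregularity, intensity)
F15-F20     6      colorimetric: mean R, G, B, H, S, V
F21-F69     49     first-order statistics, component-major
                   (R, G, B, H, S, V, gray) x (mean, std, smoothness,
                   variance, skewness, kurtosis, energy)
F70-F157    88     GLCM, orientation-major (0, 45, 90, 135 deg) x 22
F158-F201   44     GLRLM, orientation-major x 11
==========  =====  ==================================================

All color components are expressed on the 0-255 scale (H, S, V rescaled
from [0, 1]); the gray channel is ITU-R 601 luma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import rgb2hsv

from .firstorder import FOS_STAT_NAMES, fos_statistics, histogram_256
from .glcm import GLCM_STAT_NAMES, cooccurrence_matrix, glcm_statistics, quantize_gray
from .glrlm import GLRLM_STAT_NAMES, glrlm_statistics, run_length_matrix
from .morphometric import MORPHOMETRIC_NAMES, chain_code_perimeter, morphometric_features

__all__ = [
    "NucleusRegion",
    "FEATURE_CODES",
    "FEATURE_NAMES",
    "ANGLES",
    "COMPONENTS",
    "colorimetric_features",
    "ccfos_features",
    "glcm_features",
    "glrlm_features",
    "assemble_feature_vector",
    "extract_table",
    "regions_from_labels",
    "chain_code_perimeter",
    "morphometric_features",
]

ANGLES = (0, 45, 90, 135)
COMPONENTS = ("R", "G", "B", "H", "S", "V", "gray")


def _build_names() -> list[str]:
    names = list(MORPHOMETRIC_NAMES)
    names += [f"mean_{c}" for c in ("R", "G", "B", "H", "S", "V")]
    for comp in COMPONENTS:
        names += [f"{stat}_{comp}" for stat in FOS_STAT_NAMES]
    for ang in ANGLES:
        names += [f"glcm{ang}_{stat}" for stat in GLCM_STAT_NAMES]
    for ang in ANGLES:
        names += [f"glrlm{ang}_{stat}" for stat in GLRLM_STAT_NAMES]
    assert len(names) == 201
    return names


FEATURE_NAMES: list[str] = _build_names()
FEATURE_CODES: list[str] = [f"F{i}" for i in range(1, 202)]


@dataclass
class NucleusRegion:
    """One delineated nucleus: cropped mask + color pixels.

    ``rgb`` and ``mask`` share the crop; derived channels are computed
    lazily and cached on first use.
    """

    id: int
    mask: np.ndarray  # bool, cropped
    rgb: np.ndarray  # uint8, same crop, HxWx3
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("empty nucleus region")
        if self.rgb.shape[:2] != self.mask.shape:
            raise ValueError("rgb and mask crops disagree")
        self._channels: dict[str, np.ndarray] | None = None

    def channels(self) -> dict[str, np.ndarray]:
        """Full-crop R, G, B, H, S, V, gray planes on the 0-255 scale."""
        if self._channels is None:
            rgb = self.rgb.astype(float)
            hsv = rgb2hsv(self.rgb) * 255.0
            gray = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
            self._channels = {
                "R": rgb[..., 0],
                "G": rgb[..., 1],
                "B": rgb[..., 2],
                "H": hsv[..., 0],
                "S": hsv[..., 1],
                "V": hsv[..., 2],
                "gray": gray,
            }
        return self._channels

    def masked(self, component: str) -> np.ndarray:
        return self.channels()[component][self.mask]


def colorimetric_features(region: NucleusRegion) -> np.ndarray:
    """F15-F20: componentwise means of R, G, B, H, S, V over the mask."""
    return np.array([region.masked(c).mean() for c in ("R", "G", "B", "H", "S", "V")])


def ccfos_features(region: NucleusRegion) -> np.ndarray:
    """F21-F69: seven histogram statistics per color component."""
    out = []
    for comp in COMPONENTS:
        out.append(fos_statistics(histogram_256(region.masked(comp))))
    return np.concatenate(out)


def glcm_features(region: NucleusRegion) -> np.ndarray:
    """F70-F157: 22 cooccurrence statistics at each of four orientations."""
    q = quantize_gray(region.channels()["gray"])
    out = []
    for ang in ANGLES:
        p = cooccurrence_matrix(q, region.mask, ang)
        out.append(glcm_statistics(p))
    return np.concatenate(out)


def glrlm_features(region: NucleusRegion) -> np.ndarray:
    """F158-F201: 11 run-length statistics at each of four orientations."""
    q = quantize_gray(region.channels()["gray"])
    n_pixels = int(region.mask.sum())
    out = []
    for ang in ANGLES:
        g = run_length_matrix(q, region.mask, ang)
        out.append(glrlm_statistics(g, n_pixels))
    return np.concatenate(out)


def assemble_feature_vector(region: NucleusRegion) -> np.ndarray:
    """Concatenate all groups in code order F1..F201 (all values finite)."""
    vec = np.concatenate(
        [
            morphometric_features(region.mask, region.channels()["gray"]),
            colorimetric_features(region),
            ccfos_features(region),
            glcm_features(region),
            glrlm_features(region),
        ]
    )
    if not np.isfinite(vec).all():
        bad = [FEATURE_CODES[k] for k in np.flatnonzero(~np.isfinite(vec))]
        raise ValueError(f"non-finite features {bad} for nucleus {region.id}")
    return vec


def regions_from_labels(
    img: np.ndarray, label_mask: np.ndarray, labels: dict[int, str] | None = None, pad: int = 2
) -> list[NucleusRegion]:
    """Crop one :class:`NucleusRegion` per positive id of an instance mask."""
    label_mask = np.asarray(label_mask)
    regions = []
    for sl, i in zip(ndi.find_objects(label_mask), range(1, int(label_mask.max()) + 1)):
        if sl is None:
            continue
        r0 = max(0, sl[0].start - pad)
        r1 = min(label_mask.shape[0], sl[0].stop + pad)
        c0 = max(0, sl[1].start - pad)
        c1 = min(label_mask.shape[1], sl[1].stop + pad)
        crop = (slice(r0, r1), slice(c0, c1))
        regions.append(
            NucleusRegion(
                id=i,
                mask=label_mask[crop] == i,
                rgb=np.asarray(img)[crop],
                label=(labels or {}).get(i, "unlabeled"),
            )
        )
    return regions


def extract_table(
    img: np.ndarray,
    label_mask: np.ndarray,
    image_id: str = "image",
    labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Feature table with columns image_id, nucleus_id, F1..F201, label."""
    rows = []
    for region in regions_from_labels(img, label_mask, labels):
        vec = assemble_feature_vector(region)
        row = {"image_id": image_id, "nucleus_id": region.id}
        row.update(dict(zip(FEATURE_CODES, vec)))
        row["label"] = region.label
        rows.append(row)
    return pd.DataFrame(rows, columns=["image_id", "nucleus_id", *FEATURE_CODES, "label"])
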