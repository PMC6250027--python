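"""Shared fixtures: small rendered scenes and the cached gate SVM."""

from __future__ import annotations

import numpy as np
import pytest

from cytodx import overlap
from cytodx.fixtures import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 512x512 scene with known ground truth (no overlaps)."""
    spec = SceneSpec(width=512, height=512, n_nuclei=8, overlap_fraction=0.0,
                     malignant_fraction=0.25, seed=11)
    img, gt = generate_scene(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def overlap_scene():
    """A 512x512 scene dominated by touching pairs."""
    spec = SceneSpec(width=512, height=512, n_nuclei=8, overlap_fraction=0.75,
                     malignant_fraction=0.0, seed=23)
    img, gt = generate_scene(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def gate_svm():
    """The single/overlapped shape SVM (trained once per session)."""
    return overlap.default_overlap_svm(seed=0)


def two_disks(r: float = 20.0, d: float = 30.0, angle: float = 0.0) -> tuple[np.ndarray, tuple, tuple]:
    """Binary clump of two fused disks; returns (mask, center1, center2) in (x, y)."""
    size = int(2 * r + d + 12)
    yy, xx = np.mgrid[0:size, 0:size]
    mid = size / 2
    c1 = (mid - d / 2 * np.cos(angle), mid - d / 2 * np.sin(angle))
    c2 = (mid + d / 2 * np.cos(angle), mid + d / 2 * np.sin(angle))
    m1 = (xx - c1[0]) ** 2 + (yy - c1[1]) ** 2 <= r**2
    m2 = (xx - c2[0]) ** 2 + (yy - c2[1]) ** 2 <= r**2
    return m1 | m2, c1, c2
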