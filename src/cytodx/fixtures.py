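"""Synthetic pleural-effusion-like scenes and feature tables with ground truth.

Real cytological pleural effusion (CPE) image sets with per-nucleus
annotation are scarce, so this module renders controllable stand-ins:
dark, roughly elliptical nuclei on a pale Pap-stain-like background, with
a tunable fraction of touching nucleus pairs, a benign/malignant contrast
in size, darkness and chromatin texture, and impulse plus Gaussian sensor
noise.  Every scene comes with an exact instance mask and a per-nucleus
record, so each downstream stage can be scored against a known answer.

All geometry and noise are drawn from a single ``numpy`` generator seeded
from the spec, so an identical spec reproduces a byte-identical scene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import zoom as _ndzoom

__all__ = [
    "SceneSpec",
    "Nucleus",
    "GroundTruth",
    "generate_scene",
    "generate_feature_table",
    "write_scene",
    "FEATURE_EFFECT_SIZE",
]

#: Per-column class mean shift of :func:`generate_feature_table`'s
#: informative columns, in units of the column SD.  0.6 makes each column
#: individually weak (any strict subset of the panel still misclassifies
#: ~10% of samples) while the full panel is cleanly separable — the
#: complementary-marker regime feature selection exists for.
FEATURE_EFFECT_SIZE = 0.6

# Pap-stained background: pale pink-grey.  Nuclei: dark blue-purple tint.
_BG_RGB = np.array([235.0, 222.0, 228.0])
_NUCLEUS_TINT = np.array([0.72, 0.58, 0.88])


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic CPE-like scene.

    Defaults approximate a 40x field at the 1024x1024 working resolution:
    a few tens of nuclei, mostly benign, with malignant nuclei larger
    (nuclear enlargement), darker (hyperchromasia) and coarser in
    chromatin texture than benign ones.
    """

    width: int = 1024
    height: int = 1024
    n_nuclei: int = 30
    overlap_fraction: float = 0.2
    malignant_fraction: float = 0.15
    radius_range_benign: tuple[float, float] = (14.0, 22.0)
    radius_range_malignant: tuple[float, float] = (24.0, 38.0)
    darkness_contrast: float = 40.0
    chromatin_noise_sigma: tuple[float, float] = (6.0, 14.0)
    impulse_noise_density: float = 0.02
    gaussian_noise_sigma: float = 4.0
    benign_mean_intensity: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("scene must be at least 8x8 pixels")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        for name in ("overlap_fraction", "malignant_fraction", "impulse_noise_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("radius_range_benign", "radius_range_malignant"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must be a positive non-degenerate interval")
        if self.gaussian_noise_sigma < 0:
            raise ValueError("gaussian_noise_sigma must be non-negative")


@dataclass(frozen=True)
class Nucleus:
    """Ground-truth record for one rendered nucleus (semi-axes, radians)."""

    id: int
    label: Literal["benign", "malignant"]
    overlap_flag: Literal["single", "overlapped"]
    center: tuple[float, float]  # (cx, cy) in x/y pixel coords
    axes: tuple[float, float]  # (a, b) semi-axes, a >= b
    angle: float


@dataclass
class GroundTruth:
    """Instance mask (0 = background) plus one record per positive label."""

    instance_mask: np.ndarray
    nuclei: list[Nucleus] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = set(np.unique(self.instance_mask)) - {0}
        rec_ids = {n.id for n in self.nuclei}
        if ids != rec_ids:
            raise ValueError(f"mask labels {ids} do not match records {rec_ids}")

    def binary_mask(self) -> np.ndarray:
        return self.instance_mask > 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": n.id,
                "class": n.label,
                "overlap_flag": n.overlap_flag,
                "cx": n.center[0],
                "cy": n.center[1],
                "a": n.axes[0],
                "b": n.axes[1],
                "angle": n.angle,
            }
            for n in self.nuclei
        ]
        return pd.DataFrame(rows)


def _ellipse_ndist(h: int, w: int, cx: float, cy: float, a: float, b: float, theta: float) -> np.ndarray:
    """Normalized ellipse distance field: <= 1 inside the ellipse."""
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2


def _sample_ellipse(rng: np.random.Generator, radius_range: tuple[float, float]) -> tuple[float, float, float]:
    """Draw (a, b, angle) with equivalent radius uniform in radius_range."""
    r = rng.uniform(*radius_range)
    q = rng.uniform(0.6, 0.95)  # b/a aspect; keeps area ~ pi r^2
    a = r / math.sqrt(q)
    b = r * math.sqrt(q)
    return a, b, rng.uniform(0.0, math.pi)


def _low_freq_field(rng: np.random.Generator, h: int, w: int, amp: float = 0.15) -> np.ndarray:
    """Multiplicative chromatin-clump field: coarse noise upsampled smoothly."""
    coarse = rng.normal(0.0, 1.0, size=(max(2, h // 12), max(2, w // 12)))
    f = _ndzoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)
    f = f[:h, :w]
    s = f.std()
    if s > 0:
        f = f / s
    return 1.0 + amp * f


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene and its ground truth.

    Nuclei are filled ellipses darker than the pale background.  A
    fraction ``overlap_fraction`` of them is placed in touching pairs
    (center distance uniform in [0.7, 1.1] x the summed mean radii,
    resampled until the two ellipses actually share pixels), which
    guarantees the concave neck the splitting stage looks for.  Malignant
    nuclei draw from the larger radius range, are ``darkness_contrast``
    grey levels darker, and carry stronger chromatin noise.

    Returns the 8-bit RGB image and a :class:`GroundTruth` whose instance
    mask assigns contested pixels (inside two ellipses) to the nucleus
    with the smaller normalized ellipse distance.

    Raises ``RuntimeError`` when rejection sampling cannot place the
    requested number of nuclei on the canvas.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    n_pairs = int(round(spec.n_nuclei * spec.overlap_fraction / 2.0))
    n_single = spec.n_nuclei - 2 * n_pairs

    # class labels first: pair geometry must use each member's true radius
    n_mal = int(round(spec.n_nuclei * spec.malignant_fraction))
    labels = np.array(["benign"] * spec.n_nuclei, dtype=object)
    if n_mal and spec.n_nuclei:
        labels[rng.choice(spec.n_nuclei, size=n_mal, replace=False)] = "malignant"

    def radius_range(idx: int) -> tuple[float, float]:
        return spec.radius_range_malignant if labels[idx] == "malignant" else spec.radius_range_benign

    placed: list[dict] = []  # geometry dicts, one per nucleus

    def collides(cx, cy, r, ignore_from: int | None = None) -> bool:
        margin = 6.0
        for j, p in enumerate(placed):
            if ignore_from is not None and j >= ignore_from:
                continue
            if math.hypot(cx - p["cx"], cy - p["cy"]) < r + p["r"] + margin:
                return True
        return False

    def in_canvas(cx, cy, r) -> bool:
        pad = r + 3
        return pad <= cx <= w - pad and pad <= cy <= h - pad

    max_attempts = 300

    # Touching pairs first (they need the most room).
    for _ in range(n_pairs):
        for attempt in range(max_attempts):
            a1, b1, t1 = _sample_ellipse(rng, radius_range(len(placed)))
            a2, b2, t2 = _sample_ellipse(rng, radius_range(len(placed) + 1))
            r1, r2 = (a1 + b1) / 2, (a2 + b2) / 2
            d = rng.uniform(0.7, 1.1) * (r1 + r2)
            phi = rng.uniform(0.0, 2 * math.pi)
            cx1 = rng.uniform(0, w)
            cy1 = rng.uniform(0, h)
            cx2 = cx1 + d * math.cos(phi)
            cy2 = cy1 + d * math.sin(phi)
            rmax = max(r1, r2)
            if not (in_canvas(cx1, cy1, max(a1, b1)) and in_canvas(cx2, cy2, max(a2, b2))):
                continue
            if collides(cx1, cy1, max(a1, b1)) or collides(cx2, cy2, max(a2, b2)):
                continue
            # require true pixel overlap so the clump has a neck
            lo_x = int(max(0, min(cx1, cx2) - 2 * rmax))
            hi_x = int(min(w, max(cx1, cx2) + 2 * rmax))
            lo_y = int(max(0, min(cy1, cy2) - 2 * rmax))
            hi_y = int(min(h, max(cy1, cy2) + 2 * rmax))
            sub_h, sub_w = hi_y - lo_y, hi_x - lo_x
            m1 = _ellipse_ndist(sub_h, sub_w, cx1 - lo_x, cy1 - lo_y, a1, b1, t1) <= 1
            m2 = _ellipse_ndist(sub_h, sub_w, cx2 - lo_x, cy2 - lo_y, a2, b2, t2) <= 1
            if not (m1 & m2).any():
                continue
            placed.append(dict(cx=cx1, cy=cy1, a=a1, b=b1, t=t1, r=r1, flag="overlapped"))
            placed.append(dict(cx=cx2, cy=cy2, a=a2, b=b2, t=t2, r=r2, flag="overlapped"))
            break
        else:
            raise RuntimeError(
                f"could not place overlap pair {len(placed) // 2 + 1} after {max_attempts} attempts"
            )

    for _ in range(n_single):
        for attempt in range(max_attempts):
            a, b, t = _sample_ellipse(rng, radius_range(len(placed)))
            cx = rng.uniform(0, w)
            cy = rng.uniform(0, h)
            if in_canvas(cx, cy, max(a, b)) and not collides(cx, cy, max(a, b)):
                placed.append(dict(cx=cx, cy=cy, a=a, b=b, t=t, r=(a + b) / 2, flag="single"))
                break
        else:
            raise RuntimeError(f"could not place nucleus {len(placed) + 1} after {max_attempts} attempts")

    # Rasterize: normalized distance per nucleus, ownership = arg min.
    dist = np.full((h, w), np.inf)
    owner = np.zeros((h, w), dtype=np.int32)
    for i, p in enumerate(placed, start=1):
        nd = _ellipse_ndist(h, w, p["cx"], p["cy"], p["a"], p["b"], p["t"])
        inside = nd <= 1.0
        take = inside & (nd < dist)
        dist[take] = nd[take]
        owner[take] = i

    # Background: pale with a mild diagonal illumination gradient.
    yy, xx = np.mgrid[0:h, 0:w]
    grad = 1.0 - 0.06 * ((xx / max(w - 1, 1)) + (yy / max(h - 1, 1))) / 2.0
    img = _BG_RGB[None, None, :] * grad[:, :, None]

    sigma_b, sigma_m = spec.chromatin_noise_sigma
    for i, p in enumerate(placed, start=1):
        mask = owner == i
        if not mask.any():
            continue
        is_mal = labels[i - 1] == "malignant"
        base = spec.benign_mean_intensity - (spec.darkness_contrast if is_mal else 0.0)
        ys, xs = np.nonzero(mask)
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        tex = _low_freq_field(rng, y1 - y0, x1 - x0)
        sigma = sigma_m if is_mal else sigma_b
        chroma = rng.normal(0.0, sigma, size=(y1 - y0, x1 - x0))
        val = base * tex + chroma
        sub = mask[y0:y1, x0:x1]
        for c in range(3):
            ch = img[y0:y1, x0:x1, c]
            ch[sub] = val[sub] * _NUCLEUS_TINT[c]

    # Sensor noise: additive Gaussian, then salt-and-pepper impulses.
    img = img + rng.normal(0.0, spec.gaussian_noise_sigma, size=img.shape)
    if spec.impulse_noise_density > 0:
        flips = rng.random((h, w)) < spec.impulse_noise_density
        salt = rng.random((h, w)) < 0.5
        img[flips & salt] = 255.0
        img[flips & ~salt] = 0.0
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    nuclei = [
        Nucleus(
            id=i,
            label=labels[i - 1],
            overlap_flag=p["flag"],
            center=(p["cx"], p["cy"]),
            axes=(max(p["a"], p["b"]), min(p["a"], p["b"])),
            angle=p["t"],
        )
        for i, p in enumerate(placed, start=1)
        if (owner == i).any()
    ]
    keep_ids = {n.id for n in nuclei}
    if len(keep_ids) != len(placed):  # a nucleus fully occluded by a neighbour
        relabel = {old: new for new, old in enumerate(sorted(keep_ids), start=1)}
        owner = np.vectorize(lambda v: relabel.get(v, 0))(owner).astype(np.int32)
        nuclei = [
            Nucleus(relabel[n.id], n.label, n.overlap_flag, n.center, n.axes, n.angle)
            for n in nuclei
        ]
    return img, GroundTruth(instance_mask=owner, nuclei=nuclei)


def generate_feature_table(
    n_samples: int,
    n_informative: int = 20,
    imbalance: float = 0.5,
    seed: int = 0,
    effect_size: float = FEATURE_EFFECT_SIZE,
) -> pd.DataFrame:
    """Synthetic 201-column nucleus feature table for selector/classifier tests.

    Exactly ``n_informative`` columns (chosen by the seeded generator and
    recorded in ``df.attrs['informative_codes']``) carry a class signal: a
    mean shift of ``effect_size`` column SDs between benign and malignant
    rows.  The informative columns form a complementary panel: their
    within-class fluctuations share latent factors that cancel only when
    the whole panel is combined, so each marker alone is weak, any strict
    subset leaves residual error, and the full panel is cleanly separable
    — the situation that makes wrapper selection worth running.  The
    remaining columns are independent standard-normal noise.
    Positive-class (malignant) prevalence is ``imbalance``.

    Raises ``ValueError`` when either class ends up empty.
    """
    if not 0 <= n_informative <= 201:
        raise ValueError("n_informative must lie in [0, 201]")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(seed)
    y = rng.random(n_samples) < imbalance
    if y.all() or not y.any():
        raise ValueError(
            f"imbalance={imbalance} produced a single-class table of {n_samples} rows"
        )
    codes = [f"F{i}" for i in range(1, 202)]
    x = rng.normal(0.0, 1.0, size=(n_samples, 201))
    informative = sorted(rng.choice(201, size=n_informative, replace=False))
    k = n_informative
    if k >= 2:
        # shared within-class factors, centred so they cancel over the panel
        z = rng.normal(0.0, 1.0, size=(n_samples, k))
        e = z - z.mean(axis=1, keepdims=True) + 0.15 * rng.normal(0.0, 1.0, size=(n_samples, k))
        col_sd = np.sqrt(1.0 - 1.0 / k + 0.15**2)
        for idx, j in enumerate(informative):
            x[:, j] = effect_size * col_sd * y + e[:, idx]
    elif k == 1:
        x[y, informative[0]] += effect_size
    df = pd.DataFrame(x, columns=codes)
    df["label"] = np.where(y, "malignant", "benign")
    df.attrs["informative_codes"] = [codes[j] for j in informative]
    return df


def write_scene(outdir: str | Path, stem: str, img: np.ndarray, gt: GroundTruth) -> dict[str, Path]:
    """Write scene PNG, 16-bit instance-mask PNG and per-nucleus CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": outdir / f"{stem}.png",
        "mask": outdir / f"{stem}_mask.png",
        "nuclei": outdir / f"{stem}_nuclei.csv",
    }
    iio.imwrite(paths["image"], img)
    iio.imwrite(paths["mask"], gt.instance_mask.astype(np.uint16))
    gt.to_frame().to_csv(paths["nuclei"], index=False)
    return paths
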