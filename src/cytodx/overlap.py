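"""Identification and splitting of overlapped nucleus clumps.

Touching nuclei merge into one connected component after segmentation and
would otherwise be measured as a single giant "nucleus".  Splitting every
component is wasteful and oversplits lone nuclei, so a two-stage scheme
is used: (i) a gate — an SVM over five shape features (solidity,
eccentricity, equivalent diameter, major/minor axis) flags components as
single or overlapped; (ii) only flagged clumps are split by contour
concavity analysis: concave points of the Gaussian-smoothed boundary cut
the contour into segments, segments are greedily regrouped when their
joint direct least-squares ellipse fit is good, and the clump's pixels
are reassigned to the nearest fitted ellipse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.ndimage import gaussian_filter1d
from skimage.measure import EllipseModel, find_contours, regionprops
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .fixtures import SceneSpec, generate_scene

__all__ = [
    "OverlapConfig",
    "ShapeDescriptor",
    "EllipseParams",
    "shape_descriptor",
    "train_overlap_svm",
    "default_overlap_svm",
    "make_shape_samples",
    "detect_concave_points",
    "split_overlapped",
    "resolve_overlaps",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class OverlapConfig:
    smooth_sigma: float = 3.0  # contour smoothing, in boundary samples
    curvature_percentile: float = 90.0
    min_curvature: float = 0.02  # 1/px; ignores wiggles flatter than r=50 px
    min_segment_len: int = 8  # boundary samples
    residual_threshold: float = 0.05  # mean fit residual / mean semi-axis
    max_axis_ratio: float = 4.0


@dataclass(frozen=True)
class ShapeDescriptor:
    """Five shape features of one connected component."""

    solidity: float
    eccentricity: float
    equivalent_diameter: float
    major_axis: float
    minor_axis: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.solidity, self.eccentricity, self.equivalent_diameter, self.major_axis, self.minor_axis]
        )


@dataclass(frozen=True)
class EllipseParams:
    """Fitted ellipse: center in (x, y) pixel coords, semi-axes a >= b."""

    cx: float
    cy: float
    a: float
    b: float
    angle: float


def shape_descriptor(component: np.ndarray) -> ShapeDescriptor:
    """Shape features of a single connected region.

    Solidity = area / convex area; equivalent diameter = sqrt(4 area / pi);
    axes from the image-moments best-fit ellipse; eccentricity
    sqrt(1 - (b/a)^2).
    """
    component = np.asarray(component, dtype=bool)
    if not component.any():
        raise ValueError("empty region")
    props = regionprops(component.astype(np.uint8))[0]
    return ShapeDescriptor(
        solidity=float(props.solidity),
        eccentricity=float(props.eccentricity),
        equivalent_diameter=float(props.equivalent_diameter_area),
        major_axis=float(props.axis_major_length),
        minor_axis=float(props.axis_minor_length),
    )


def train_overlap_svm(samples: list[tuple[ShapeDescriptor, str]], seed: int = 0) -> Pipeline:
    """Fit the single/overlapped gate: RBF-SVM on standardized shape features."""
    labels = sorted({lab for _, lab in samples})
    if len(labels) < 2:
        raise ValueError("training data must contain both single and overlapped samples")
    x = np.stack([d.as_array() for d, _ in samples])
    y = np.array([lab for _, lab in samples])
    model = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="rbf", C=10.0, random_state=seed))]
    )
    model.fit(x, y)
    return model


def make_shape_samples(
    n_single: int = 100, n_overlapped: int = 100, seed: int = 0
) -> list[tuple[ShapeDescriptor, str]]:
    """Labelled shape descriptors from rendered lone nuclei and fused pairs.

    Uses the scene generator's ground-truth geometry so the SVM's training
    distribution matches the nuclei the pipeline later meets.
    """
    rng = np.random.default_rng(seed)
    samples: list[tuple[ShapeDescriptor, str]] = []

    def components_of(spec: SceneSpec) -> list[np.ndarray]:
        _, gt = generate_scene(spec)
        labelled, n = ndi.label(gt.binary_mask(), structure=_EIGHT)
        return [labelled == i for i in range(1, n + 1)]

    while sum(1 for _, lab in samples if lab == "single") < n_single:
        spec = SceneSpec(
            width=512, height=512, n_nuclei=8, overlap_fraction=0.0,
            malignant_fraction=0.3, seed=int(rng.integers(2**31)),
        )
        for comp in components_of(spec):
            samples.append((shape_descriptor(comp), "single"))
    while sum(1 for _, lab in samples if lab == "overlapped") < n_overlapped:
        spec = SceneSpec(
            width=512, height=512, n_nuclei=6, overlap_fraction=1.0,
            malignant_fraction=0.3, seed=int(rng.integers(2**31)),
        )
        for comp in components_of(spec):
            # a pair may render as two barely-touching blobs; label by part count
            samples.append((shape_descriptor(comp), "overlapped"))
    return samples


_svm_cache: dict[int, Pipeline] = {}


def default_overlap_svm(seed: int = 0) -> Pipeline:
    """The gate SVM trained on generated shapes (cached per seed)."""
    if seed not in _svm_cache:
        _svm_cache[seed] = train_overlap_svm(make_shape_samples(seed=seed), seed=seed)
    return _svm_cache[seed]


def _closed_contour(component: np.ndarray) -> np.ndarray:
    """Longest closed boundary of the component as (x, y) points."""
    padded = np.pad(np.asarray(component, dtype=float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        raise ValueError("component has no boundary")
    contour = max(contours, key=len)[:-1]  # drop duplicated closing point
    xy = np.column_stack([contour[:, 1], contour[:, 0]]) - 1.0  # undo pad
    # enforce positive signed area so concavity has a fixed curvature sign
    x, y = xy[:, 0], xy[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        xy = xy[::-1]
    return xy


def _smoothed_curvature(xy: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Curvature of the periodically Gaussian-smoothed contour.

    Returns (smoothed xy, signed curvature); with positive orientation,
    concave boundary points (interior angle > pi) have negative curvature.
    """
    x, y = xy[:, 0], xy[:, 1]
    xs = gaussian_filter1d(x, sigma, mode="wrap")
    ys = gaussian_filter1d(y, sigma, mode="wrap")
    dx = gaussian_filter1d(x, sigma, order=1, mode="wrap")
    dy = gaussian_filter1d(y, sigma, order=1, mode="wrap")
    ddx = gaussian_filter1d(x, sigma, order=2, mode="wrap")
    ddy = gaussian_filter1d(y, sigma, order=2, mode="wrap")
    denom = (dx**2 + dy**2) ** 1.5
    denom[denom == 0] = np.inf
    kappa = (dx * ddy - dy * ddx) / denom
    return np.column_stack([xs, ys]), kappa


def _concave_indices(kappa: np.ndarray, cfg: OverlapConfig) -> np.ndarray:
    """Indices of concave curvature extrema (one per contiguous excursion)."""
    thresh = max(np.percentile(np.abs(kappa), cfg.curvature_percentile), cfg.min_curvature)
    cand = (kappa < 0) & (np.abs(kappa) >= thresh)
    if not cand.any():
        return np.array([], dtype=int)
    idx = np.flatnonzero(cand)
    # group circularly-consecutive candidates, keep the extremum of each
    breaks = np.flatnonzero(np.diff(idx) > 1)
    groups = np.split(idx, breaks + 1)
    n = len(kappa)
    if len(groups) > 1 and groups[0][0] == 0 and groups[-1][-1] == n - 1:
        groups[0] = np.concatenate([groups[-1], groups[0]])
        groups.pop()
    return np.array(sorted(int(g[np.argmin(kappa[g])]) % n for g in groups), dtype=int)


def detect_concave_points(
    component: np.ndarray, cfg: OverlapConfig = OverlapConfig()
) -> np.ndarray:
    """Concave points of a component's boundary as an (n, 2) (x, y) array.

    A point qualifies when it is a local curvature extremum of the
    smoothed closed contour, its curvature magnitude exceeds the
    ``curvature_percentile`` of the contour, and the contour turns away
    from the region there (concave).  Convex shapes yield an empty array.
    """
    xy = _closed_contour(component)
    if len(xy) < 8:
        return np.empty((0, 2))
    _, kappa = _smoothed_curvature(xy, cfg.smooth_sigma)
    idx = _concave_indices(kappa, cfg)
    return xy[idx]


def _fit_model(points: np.ndarray) -> EllipseModel | None:
    if len(points) < 5:
        return None
    with np.errstate(all="ignore"):
        model = EllipseModel.from_estimate(points.astype(float))
    if not model:
        return None
    (xc, yc), (a, b) = model.center, model.axis_lengths
    if not (np.isfinite([xc, yc, a, b, model.theta]).all() and a > 0 and b > 0):
        return None
    return model


def _params_of(model: EllipseModel) -> EllipseParams:
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, float(model.theta)
    if a < b:
        a, b = b, a
        theta += math.pi / 2
    return EllipseParams(cx=float(xc), cy=float(yc), a=float(a), b=float(b), angle=theta % math.pi)


def _fit_ellipse(points: np.ndarray) -> EllipseParams | None:
    """Direct least-squares ellipse fit; None when unstable or degenerate."""
    model = _fit_model(points)
    return None if model is None else _params_of(model)


def _fit_score(points: np.ndarray) -> tuple[EllipseParams | None, float]:
    model = _fit_model(points)
    if model is None:
        return None, np.inf
    e = _params_of(model)
    with np.errstate(all="ignore"):
        res = np.abs(model.residuals(points.astype(float)))
    if not np.isfinite(res).all():
        return e, np.inf
    return e, float(res.mean() / ((e.a + e.b) / 2))


def split_overlapped(
    component: np.ndarray, cfg: OverlapConfig = OverlapConfig()
) -> list[EllipseParams]:
    """Contour-concavity splitting of one overlapped clump.

    The boundary is cut at its concave points; the resulting segments are
    greedily merged (any pair, not only adjacent ones — the middle nucleus
    of a chain owns two opposite arcs) whenever the pooled direct
    least-squares fit has mean normalized residual below
    ``cfg.residual_threshold`` and axis ratio below ``cfg.max_axis_ratio``.
    One ellipse is returned per final group.  When no valid grouping
    exists (e.g. a convex lone nucleus routed here), the whole contour is
    fitted as a single ellipse — the fail-safe never splits.
    """
    component = np.asarray(component, dtype=bool)
    if not component.any():
        raise ValueError("empty component")
    xy = _closed_contour(component)
    smooth_xy, kappa = _smoothed_curvature(xy, cfg.smooth_sigma)
    cut = _concave_indices(kappa, cfg)

    def whole_fit() -> list[EllipseParams]:
        e = _fit_ellipse(xy)
        if e is None:  # moments fallback for degenerate contours
            props = regionprops(component.astype(np.uint8))[0]
            cy, cx = props.centroid
            e = EllipseParams(
                cx=cx, cy=cy,
                a=max(props.axis_major_length / 2, 1.0),
                b=max(props.axis_minor_length / 2, 1.0),
                angle=float(-props.orientation % math.pi),
            )
        return [e]

    if len(cut) < 2:
        return whole_fit()

    # circular split of the (unsmoothed) contour at the concave points
    cut = np.sort(cut)
    segments = []
    for s, t in zip(cut, np.roll(cut, -1)):
        if t > s:
            seg = xy[s:t + 1]
        else:
            seg = np.vstack([xy[s:], xy[: t + 1]])
        if len(seg) >= cfg.min_segment_len:
            segments.append(seg)
    if not segments:
        return whole_fit()

    groups: list[list[np.ndarray]] = [[s] for s in segments]

    def group_points(g: list[np.ndarray]) -> np.ndarray:
        return np.vstack(g)

    while len(groups) > 1:
        best: tuple[float, int, int] | None = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                e, score = _fit_score(group_points(groups[i] + groups[j]))
                if e is None or score >= cfg.residual_threshold:
                    continue
                if e.a / e.b > cfg.max_axis_ratio:
                    continue
                if best is None or score < best[0]:
                    best = (score, i, j)
        if best is None:
            break
        _, i, j = best
        groups[i] = groups[i] + groups[j]
        groups.pop(j)

    ellipses = []
    for g in groups:
        e, score = _fit_score(group_points(g))
        if e is None or e.a / e.b > cfg.max_axis_ratio:
            continue
        ellipses.append(e)
    if not ellipses:
        return whole_fit()
    return ellipses


def _ellipse_membership(shape: tuple[int, int], ellipses: list[EllipseParams]) -> np.ndarray:
    """Per-pixel index of the nearest ellipse (normalized ellipse distance)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dists = np.empty((len(ellipses), h, w))
    for k, e in enumerate(ellipses):
        dx = xx - e.cx
        dy = yy - e.cy
        ct, st = math.cos(e.angle), math.sin(e.angle)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        dists[k] = (u / e.a) ** 2 + (v / e.b) ** 2
    return np.argmin(dists, axis=0)


def resolve_overlaps(
    mask: np.ndarray,
    svm_model: Pipeline | None = None,
    cfg: OverlapConfig = OverlapConfig(),
    svm_seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Gate every component, split only the overlapped ones.

    Returns the instance label mask (contiguous positive ids, background
    0) and a per-nucleus table (id, cx, cy, a, b, angle, was_split).
    Splitting conserves pixels: a clump's pixel set is partitioned among
    its fitted ellipses by nearest normalized ellipse distance.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=np.int32)
    records = []
    labelled, n = ndi.label(mask, structure=_EIGHT)
    if n == 0:
        return out, pd.DataFrame(columns=["id", "cx", "cy", "a", "b", "angle", "was_split"])
    if svm_model is None:
        svm_model = default_overlap_svm(seed=svm_seed)
    next_id = 1
    for sl, i in zip(ndi.find_objects(labelled), range(1, n + 1)):
        comp = labelled[sl] == i
        desc = shape_descriptor(comp)
        verdict = svm_model.predict(desc.as_array()[None, :])[0]
        ellipses = split_overlapped(comp, cfg) if verdict == "overlapped" else []
        if len(ellipses) >= 2:
            member = _ellipse_membership(comp.shape, ellipses)
            for k, e in enumerate(ellipses):
                piece = comp & (member == k)
                if not piece.any():
                    continue
                out[sl][piece] = next_id
                records.append(
                    dict(id=next_id, cx=e.cx + sl[1].start, cy=e.cy + sl[0].start,
                         a=e.a, b=e.b, angle=e.angle, was_split=True)
                )
                next_id += 1
        else:
            out[sl][comp] = next_id
            fit = _fit_ellipse(_closed_contour(comp))
            if fit is None:
                props = regionprops(comp.astype(np.uint8))[0]
                cy, cx = props.centroid
                fit = EllipseParams(cx, cy, max(props.axis_major_length / 2, 1.0),
                                    max(props.axis_minor_length / 2, 1.0),
                                    float(-props.orientation % math.pi))
            records.append(
                dict(id=next_id, cx=fit.cx + sl[1].start, cy=fit.cy + sl[0].start,
                     a=fit.a, b=fit.b, angle=fit.angle, was_split=False)
            )
            next_id += 1
    return out, pd.DataFrame(records)
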