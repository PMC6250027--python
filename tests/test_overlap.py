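"""Shape gate and concavity-based splitting of nucleus clumps."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk as skdisk, ellipse as skellipse

from cytodx import overlap
from cytodx.fixtures import SceneSpec, generate_scene
from cytodx.overlap import (
    OverlapConfig,
    detect_concave_points,
    resolve_overlaps,
    shape_descriptor,
    split_overlapped,
    train_overlap_svm,
)

from conftest import two_disks

EIGHT = np.ones((3, 3), int)


def make_disk(radius=20, pad=6):
    size = 2 * (radius + pad)
    m = np.zeros((size, size), bool)
    rr, cc = skdisk((size // 2, size // 2), radius)
    m[rr, cc] = True
    return m


class TestShapeDescriptor:
    def test_disk_is_round_and_solid(self):
        d = shape_descriptor(make_disk(20))
        assert d.solidity >= 0.95
        assert d.eccentricity <= 0.2
        assert abs(d.equivalent_diameter - 40) < 2

    def test_two_to_one_ellipse_eccentricity(self):
        m = np.zeros((120, 120), bool)
        rr, cc = skellipse(60, 60, 20, 40)
        m[rr, cc] = True
        d = shape_descriptor(m)
        assert d.eccentricity == pytest.approx(math.sqrt(1 - 0.25), abs=0.02)
        assert d.minor_axis <= d.major_axis

    def test_fused_pair_less_solid_than_disk(self):
        clump, _, _ = two_disks(r=20, d=24)
        assert shape_descriptor(clump).solidity < shape_descriptor(make_disk(20)).solidity

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            shape_descriptor(np.zeros((10, 10), bool))


class TestGateSvm:
    def test_heldout_accuracy_on_fixture_shapes(self):
        samples = overlap.make_shape_samples(60, 60, seed=1)
        train, test = samples[::2], samples[1::2]
        svm = train_overlap_svm(train, seed=0)
        x = np.stack([d.as_array() for d, _ in test])
        y = np.array([lab for _, lab in test])
        assert (svm.predict(x) == y).mean() >= 0.9

    def test_single_class_rejected(self):
        samples = [(shape_descriptor(make_disk(15)), "single")] * 5
        with pytest.raises(ValueError):
            train_overlap_svm(samples)

    def test_duplicate_rows_tolerated(self):
        d_single = shape_descriptor(make_disk(15))
        clump, _, _ = two_disks()
        d_over = shape_descriptor(clump)
        samples = [(d_single, "single")] * 10 + [(d_over, "overlapped")] * 10
        svm = train_overlap_svm(samples)
        assert svm.predict(d_single.as_array()[None, :])[0] == "single"


class TestConcavePoints:
    def test_convex_disk_has_none(self):
        assert len(detect_concave_points(make_disk(20))) == 0

    def test_fused_pair_has_two_at_the_neck(self):
        clump, c1, c2 = two_disks(r=20.0, d=30.0)
        pts = detect_concave_points(clump)
        assert len(pts) == 2
        # analytic intersection of the two circles
        mid = ((c1[0] + c2[0]) / 2, (c1[1] + c2[1]) / 2)
        h = math.sqrt(20.0**2 - 15.0**2)
        expected = {(mid[0], mid[1] - h), (mid[0], mid[1] + h)}
        for p in pts:
            err = min(math.hypot(p[0] - e[0], p[1] - e[1]) for e in expected)
            assert err <= 3.0

    def test_three_disk_chain_has_four(self):
        m = np.zeros((80, 160), bool)
        for cx in (40, 75, 110):
            rr, cc = skdisk((40, cx), 20)
            m[rr, cc] = True
        assert len(detect_concave_points(m)) == 4


class TestSplitOverlapped:
    def test_two_disks_recovered(self):
        clump, c1, c2 = two_disks(r=20.0, d=30.0)
        ellipses = split_overlapped(clump)
        assert len(ellipses) == 2
        centers = sorted([(e.cx, e.cy) for e in ellipses])
        truth = sorted([c1, c2])
        for got, want in zip(centers, truth):
            assert math.hypot(got[0] - want[0], got[1] - want[1]) <= 3.0

    def test_lone_ellipse_failsafe_no_split(self):
        m = np.zeros((100, 100), bool)
        rr, cc = skellipse(50, 50, 18, 28)
        m[rr, cc] = True
        ellipses = split_overlapped(m)
        assert len(ellipses) == 1
        assert math.hypot(ellipses[0].cx - 50, ellipses[0].cy - 50) <= 2.0

    def test_chain_of_three_gives_three(self):
        m = np.zeros((80, 160), bool)
        for cx in (40, 75, 110):
            rr, cc = skdisk((40, cx), 20)
            m[rr, cc] = True
        ellipses = split_overlapped(m)
        assert len(ellipses) == 3
        xs = sorted(e.cx for e in ellipses)
        assert np.allclose(xs, [40, 75, 110], atol=3)

    def test_empty_component_raises(self):
        with pytest.raises(ValueError):
            split_overlapped(np.zeros((10, 10), bool))


class TestResolveOverlaps:
    def test_no_overlap_scene_keeps_component_count(self, small_scene, gate_svm):
        _, _, gt = small_scene
        mask = gt.binary_mask()
        n_in = ndi.label(mask, structure=EIGHT)[1]
        labels, recs = resolve_overlaps(mask, gate_svm)
        assert labels.max() == n_in
        assert not recs["was_split"].any()

    def test_pairs_are_split_to_expected_count(self, gate_svm):
        spec = SceneSpec(width=640, height=640, n_nuclei=9, overlap_fraction=0.45,
                         malignant_fraction=0.0, seed=31)
        _, gt = generate_scene(spec)
        labels, _ = resolve_overlaps(gt.binary_mask(), gate_svm)
        assert labels.max() == len(gt.nuclei)

    def test_split_conserves_pixels(self, overlap_scene, gate_svm):
        _, _, gt = overlap_scene
        mask = gt.binary_mask()
        labels, _ = resolve_overlaps(mask, gate_svm)
        assert np.array_equal(labels > 0, mask)
        assert set(np.unique(labels)) == set(range(int(labels.max()) + 1))

    def test_empty_mask(self, gate_svm):
        labels, recs = resolve_overlaps(np.zeros((32, 32), bool), gate_svm)
        assert labels.max() == 0 and len(recs) == 0


def count_split_errors(gt, labels_fn):
    """Sum of |parts found - true parts| over connected clumps."""
    mask = gt.binary_mask()
    comp, n = ndi.label(mask, structure=EIGHT)
    errors = 0
    for sl, i in zip(ndi.find_objects(comp), range(1, n + 1)):
        sub = comp[sl] == i
        true_parts = len(set(np.unique(gt.instance_mask[sl][sub])) - {0})
        errors += abs(labels_fn(sub) - true_parts)
    return errors


def test_gating_prevents_over_and_undersplitting(gate_svm):
    """Splitting only SVM-flagged clumps errs no more than splitting everything."""
    gated = ungated = 0
    for seed in range(6):
        spec = SceneSpec(width=512, height=512, n_nuclei=8, overlap_fraction=0.5,
                         malignant_fraction=0.0, seed=60 + seed)
        _, gt = generate_scene(spec)

        def gated_parts(sub):
            verdict = gate_svm.predict(shape_descriptor(sub).as_array()[None, :])[0]
            return len(split_overlapped(sub)) if verdict == "overlapped" else 1

        gated += count_split_errors(gt, gated_parts)
        ungated += count_split_errors(gt, lambda sub: len(split_overlapped(sub)))
    assert gated <= ungated
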