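"""The 201-feature extractor, checked against independent brute-force oracles."""

import math

import numpy as np
import pytest
from skimage.draw import disk as skdisk, ellipse as skellipse

from cytodx import features
from cytodx.features import (
    FEATURE_CODES,
    FEATURE_NAMES,
    NucleusRegion,
    assemble_feature_vector,
    chain_code_perimeter,
)
from cytodx.features.firstorder import fos_statistics, histogram_256
from cytodx.features.glcm import GLCM_OFFSETS, cooccurrence_matrix, glcm_statistics, quantize_gray
from cytodx.features.glrlm import extract_runs, glrlm_statistics, run_length_matrix

# ---------------------------------------------------------------- oracles


def brute_glcm(q, mask, angle, levels=8):
    """Explicit pair enumeration, symmetric accumulation."""
    dr, dc = GLCM_OFFSETS[angle]
    h, w = mask.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[q[r, c] - 1, q[r2, c2] - 1] += 1
                counts[q[r2, c2] - 1, q[r, c] - 1] += 1
    return counts / counts.sum()


def brute_runs(q, mask, angle):
    """Explicit run enumeration by walking each scan line."""
    h, w = mask.shape
    step = {0: (0, 1), 90: (1, 0), 45: (-1, 1), 135: (1, 1)}[angle]
    if angle == 0:
        starts = [(r, 0) for r in range(h)]
    elif angle == 90:
        starts = [(0, c) for c in range(w)]
    elif angle == 45:
        starts = [(r, 0) for r in range(h)] + [(h - 1, c) for c in range(1, w)]
    else:
        starts = [(r, 0) for r in range(h - 1, -1, -1)] + [(0, c) for c in range(1, w)]
    runs = []
    for r0, c0 in starts:
        r, c = r0, c0
        cur, length = None, 0
        while 0 <= r < h and 0 <= c < w:
            if mask[r, c]:
                v = int(q[r, c])
                if v == cur:
                    length += 1
                else:
                    if cur is not None:
                        runs.append((cur, length))
                    cur, length = v, 1
            else:
                if cur is not None:
                    runs.append((cur, length))
                cur, length = None, 0
            r += step[0]
            c += step[1]
        if cur is not None:
            runs.append((cur, length))
    return sorted(runs)


def random_region(seed, size=8):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, (size, size), dtype=np.uint8)
    mask = rng.random((size, size)) < 0.7
    if not mask.any():
        mask[size // 2, size // 2] = True
    return img, mask


# ---------------------------------------------------------------- layout


def test_dimensionality_by_group():
    assert len(FEATURE_CODES) == len(FEATURE_NAMES) == 201
    morpho = [n for n in FEATURE_NAMES[:14]]
    assert len(morpho) == 14
    assert FEATURE_NAMES[14:20] == ["mean_R", "mean_G", "mean_B", "mean_H", "mean_S", "mean_V"]
    assert sum(n.startswith("glcm") for n in FEATURE_NAMES) == 88
    assert sum(n.startswith("glrlm") for n in FEATURE_NAMES) == 44
    textural = FEATURE_NAMES[20:]
    assert len(textural) == 181


@pytest.mark.parametrize(
    "code, name",
    [
        ("F19", "mean_S"),
        ("F25", "skewness_R"),
        ("F28", "mean_G"),
        ("F37", "smoothness_B"),
        ("F51", "smoothness_S"),
        ("F55", "energy_S"),
        ("F70", "glcm0_autocorrelation"),
        ("F82", "glcm0_sum_of_square"),
        ("F88", "glcm0_imc_i"),
        ("F96", "glcm45_cluster_prominence"),
        ("F146", "glcm135_homogeneity_ii"),
        ("F163", "glrlm0_short_run_high_gray_emphasis"),
        ("F168", "glrlm0_run_percentage"),
        ("F183", "glrlm90_high_gray_run_emphasis"),
        ("F187", "glrlm90_long_run_high_gray_emphasis"),
    ],
)
def test_code_layout(code, name):
    assert FEATURE_NAMES[FEATURE_CODES.index(code)] == name


# ---------------------------------------------------------------- morphometric


def disk_region(value=100, radius=15):
    size = 2 * radius + 10
    rgb = np.full((size, size, 3), value, np.uint8)
    mask = np.zeros((size, size), bool)
    rr, cc = skdisk((size // 2, size // 2), radius)
    mask[rr, cc] = True
    return NucleusRegion(1, mask, rgb)


class TestMorphometric:
    def test_disk_roundness_near_one(self):
        vec = assemble_feature_vector(disk_region(radius=30))
        roundness = vec[FEATURE_CODES.index("F3")]
        assert 0.85 <= roundness <= 1.1

    def test_compactness_is_roundness_over_4pi(self):
        vec = assemble_feature_vector(disk_region(radius=20))
        f3 = vec[FEATURE_CODES.index("F3")]
        f6 = vec[FEATURE_CODES.index("F6")]
        assert f6 == pytest.approx(f3 / (4 * math.pi), rel=1e-12)

    def test_diameter_is_perimeter_over_pi(self):
        vec = assemble_feature_vector(disk_region())
        assert vec[FEATURE_CODES.index("F8")] == pytest.approx(
            vec[FEATURE_CODES.index("F2")] / math.pi, rel=1e-12
        )

    def test_constant_intensity_extremes(self):
        vec = assemble_feature_vector(disk_region(value=100))
        for code in ("F12", "F13", "F14"):
            assert vec[FEATURE_CODES.index(code)] == pytest.approx(100.0)

    def test_chain_code_perimeter_of_square(self):
        m = np.zeros((12, 12), bool)
        m[3:8, 3:8] = True  # 5x5 square: 16 boundary steps, all axial
        assert chain_code_perimeter(m) == pytest.approx(16.0)

    def test_chain_code_perimeter_of_disk_close_to_circle(self):
        m = np.zeros((70, 70), bool)
        rr, cc = skdisk((35, 35), 30)
        m[rr, cc] = True
        assert chain_code_perimeter(m) == pytest.approx(2 * math.pi * 30, rel=0.06)


# ---------------------------------------------------------------- color / FOS


class TestColorimetric:
    def test_pure_red(self):
        rgb = np.zeros((20, 20, 3), np.uint8)
        rgb[..., 0] = 255
        region = NucleusRegion(1, np.ones((20, 20), bool), rgb)
        vec = features.colorimetric_features(region)
        assert vec[0] == 255 and vec[1] == 0 and vec[2] == 0

    def test_grayscale_has_zero_saturation(self):
        rgb = np.full((10, 10, 3), 131, np.uint8)
        region = NucleusRegion(1, np.ones((10, 10), bool), rgb)
        assert features.colorimetric_features(region)[4] == 0.0


class TestFos:
    def test_constant_region(self):
        stats = fos_statistics(histogram_256(np.full(50, 42.0)))
        mean, std, smooth, var, skew, kurt, energy = stats
        assert (mean, std, smooth, var) == (42.0, 0.0, 0.0, 0.0)
        assert skew == 0.0 and kurt == 0.0 and energy == 1.0

    def test_symmetric_two_point(self):
        vals = np.array([0.0] * 50 + [255.0] * 50)
        mean, std, smooth, var, skew, kurt, energy = fos_statistics(histogram_256(vals))
        assert mean == pytest.approx(127.5)
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert energy == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_histogram_route_matches_direct_moments(self, seed):
        """256-bin histogram statistics == closed-form moments of the pixels."""
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 256, size=500).astype(float)
        stats = fos_statistics(histogram_256(vals))
        mu = vals.mean()
        var = ((vals - mu) ** 2).mean()
        sd = math.sqrt(var)
        skew = ((vals - mu) ** 3).mean() / sd**3
        kurt = ((vals - mu) ** 4).mean() / sd**4 - 3
        _, counts = np.unique(vals, return_counts=True)
        energy = np.sum((counts / len(vals)) ** 2)
        expected = [mu, sd, 1 - 1 / (1 + var), var, skew, kurt, energy]
        assert np.allclose(stats, expected, atol=1e-6)


# ---------------------------------------------------------------- GLCM


class TestGlcm:
    def test_constant_region_degenerate_matrix(self):
        q = quantize_gray(np.full((6, 6), 90.0))
        mask = np.ones((6, 6), bool)
        for angle in (0, 45, 90, 135):
            stats = glcm_statistics(cooccurrence_matrix(q, mask, angle))
            contrast, energy, entropy = stats[1], stats[7], stats[8]
            assert (contrast, energy) == (0.0, 1.0)
            assert entropy == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_contrast(self):
        img = np.array([[0, 255], [0, 255]], float)
        q = quantize_gray(img)
        p = cooccurrence_matrix(q, np.ones((2, 2), bool), 0)
        assert glcm_statistics(p)[1] == pytest.approx(49.0)

    def test_no_valid_pair_raises(self):
        mask = np.eye(4, dtype=bool)
        q = quantize_gray(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            cooccurrence_matrix(q, mask, 0)

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_matrix_matches_brute_force_on_random_masks(self, angle):
        for seed in range(50):
            img, mask = random_region(seed)
            q = quantize_gray(img.astype(float))
            dr, dc = GLCM_OFFSETS[angle]
            # skip the rare mask with no valid pair
            try:
                got = cooccurrence_matrix(q, mask, angle)
            except ValueError:
                continue
            assert np.allclose(got, brute_glcm(q, mask, angle), atol=1e-9)


# ---------------------------------------------------------------- GLRLM


class TestGlrlm:
    def test_single_row_short_run_emphasis(self):
        q = quantize_gray(np.array([[100.0, 100.0, 200.0]]))
        mask = np.ones((1, 3), bool)
        g = run_length_matrix(q, mask, 0)
        stats = glrlm_statistics(g, n_pixels=3)
        assert g.sum() == 2  # two runs
        assert stats[0] == pytest.approx(0.625)  # (1/2)(1/4 + 1)

    def test_constant_row_run_percentage(self):
        n = 7
        q = quantize_gray(np.full((1, n), 33.0))
        g = run_length_matrix(q, np.ones((1, n), bool), 0)
        stats = glrlm_statistics(g, n_pixels=n)
        assert stats[10] == pytest.approx(1 / n)

    def test_runs_truncate_at_mask_boundary(self):
        q = quantize_gray(np.full((1, 5), 100.0))
        mask = np.array([[True, True, False, True, True]])
        runs = extract_runs(q, mask, 0)
        assert sorted(runs) == [(int(q[0, 0]), 2), (int(q[0, 0]), 2)]

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_runs_match_brute_force_on_random_masks(self, angle):
        for seed in range(50):
            img, mask = random_region(seed)
            q = quantize_gray(img.astype(float))
            assert sorted(extract_runs(q, mask, angle)) == brute_runs(q, mask, angle)

    def test_run_count_and_pixel_identities(self):
        img, mask = random_region(123)
        q = quantize_gray(img.astype(float))
        for angle in (0, 45, 90, 135):
            g = run_length_matrix(q, mask, angle)
            j = np.arange(1, g.shape[1] + 1)
            assert g.sum() == len(extract_runs(q, mask, angle))
            assert np.sum(g * j) == mask.sum()


# ---------------------------------------------------------------- assembly


class TestAssembly:
    def test_full_vector_on_textured_region(self):
        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        mask = np.zeros((40, 40), bool)
        rr, cc = skellipse(20, 20, 12, 16)
        mask[rr, cc] = True
        vec = assemble_feature_vector(NucleusRegion(1, mask, rgb))
        assert vec.shape == (201,)
        assert np.isfinite(vec).all()

    def test_identical_regions_identical_vectors(self):
        r1 = disk_region(value=80, radius=12)
        r2 = disk_region(value=80, radius=12)
        assert np.array_equal(assemble_feature_vector(r1), assemble_feature_vector(r2))

    def test_rotation_permutes_orientation_blocks(self):
        rng = np.random.default_rng(3)
        rgb = rng.integers(0, 256, (30, 30, 3), dtype=np.uint8)
        mask = np.zeros((30, 30), bool)
        rr, cc = skellipse(15, 15, 8, 12)
        mask[rr, cc] = True
        vec = assemble_feature_vector(NucleusRegion(1, mask, rgb))
        rot = assemble_feature_vector(NucleusRegion(1, np.rot90(mask), np.rot90(rgb)))

        def block(v, prefix, angle, n):
            i = FEATURE_NAMES.index(f"{prefix}{angle}_" + {
                "glcm": "autocorrelation", "glrlm": "short_run_emphasis"}[prefix])
            return v[i : i + n]

        for prefix, n in (("glcm", 22), ("glrlm", 11)):
            assert np.allclose(block(vec, prefix, 0, n), block(rot, prefix, 90, n), atol=1e-9)
            assert np.allclose(block(vec, prefix, 90, n), block(rot, prefix, 0, n), atol=1e-9)
            assert np.allclose(block(vec, prefix, 45, n), block(rot, prefix, 135, n), atol=1e-9)
            assert np.allclose(block(vec, prefix, 135, n), block(rot, prefix, 45, n), atol=1e-9)
        # rotation-invariant morphometrics unchanged
        for code in ("F1", "F3", "F4"):
            i = FEATURE_CODES.index(code)
            assert vec[i] == pytest.approx(rot[i], rel=1e-6)

    def test_extract_table_columns(self, small_scene):
        _, img, gt = small_scene
        table = features.extract_table(
            img, gt.instance_mask, image_id="s", labels={n.id: n.label for n in gt.nuclei}
        )
        assert list(table.columns) == ["image_id", "nucleus_id", *FEATURE_CODES, "label"]
        assert len(table) == len(gt.nuclei)
        assert set(table["label"]) <= {"benign", "malignant"}
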