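"""Texture-matrix features vs exhaustive brute-force enumeration, plus the
hand-computable toy cases for each family."""

import numpy as np
import pytest

import oracles
from conftest import random_roi
from octomics.features import (
    discretize,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from octomics.features.texture import glcm_matrices, glrlm_matrices

FAMILIES = {
    "glcm": (glcm_features, oracles.glcm_features_oracle),
    "glrlm": (glrlm_features, oracles.glrlm_features_oracle),
    "glszm": (glszm_features, oracles.glszm_features_oracle),
    "gldm": (gldm_features, oracles.gldm_features_oracle),
    "ngtdm": (ngtdm_features, oracles.ngtdm_features_oracle),
}


@pytest.mark.parametrize("family", FAMILIES)
def test_matches_bruteforce_on_random_rois(family):
    impl_fn, oracle_fn = FAMILIES[family]
    rng = np.random.default_rng(hash(family) % 2**31)
    for _ in range(25):
        raw, mask = random_roi(rng)
        d = discretize(raw, mask, 10.0)
        impl = impl_fn(d)
        ref = oracle_fn(d.levels, d.mask, d.ng)
        assert set(impl) == set(ref)
        for k in impl:
            assert impl[k] == pytest.approx(ref[k], rel=1e-9, abs=1e-12), (family, k)


def test_probability_matrices_normalize():
    rng = np.random.default_rng(7)
    raw, mask = random_roi(rng)
    d = discretize(raw, mask, 10.0)
    for mat in glcm_matrices(d):
        if mat.sum() > 0:
            assert (mat / mat.sum()).sum() == pytest.approx(1.0, abs=1e-9)
    for mat in glrlm_matrices(d):
        if mat.sum() > 0:
            assert (mat / mat.sum()).sum() == pytest.approx(1.0, abs=1e-9)


def test_glcm_constant_roi_degenerate_constants():
    d = discretize(np.full((6, 6), 42.0), np.ones((6, 6), bool), 25.0)
    f = glcm_features(d)
    assert f["Contrast"] == 0.0
    assert f["ClusterShade"] == 0.0
    assert f["Correlation"] == 1.0  # flagged degenerate convention


def test_glcm_checkerboard_contrast():
    # 2x2 checkerboard of levels {1,2}: all horizontal/vertical co-occurrence
    # mass is off-diagonal, so Contrast = 1 in those directions
    raw = np.array([[0.0, 30.0], [30.0, 0.0]])
    d = discretize(raw, np.ones((2, 2), bool), 25.0)
    mats = glcm_matrices(d)
    for direction in (0, 1):  # horizontal, vertical
        p = mats[direction] / mats[direction].sum()
        assert p[0, 0] == 0 and p[1, 1] == 0
        idx = np.arange(1, 3)
        contrast = sum((i - j) ** 2 * p[i - 1, j - 1] for i in idx for j in idx)
        assert contrast == pytest.approx(1.0)


def test_glrlm_single_row_run():
    # a single run [1,1,1]: LRHGLE horizontal = 1^2 * 3^2 / 1 = 9
    raw = np.zeros((1, 3))
    mask = np.ones((1, 3), bool)
    d = discretize(raw, mask, 25.0)
    mats = glrlm_matrices(d)
    horiz = mats[0]
    assert horiz.sum() == 1 and horiz[0, 2] == 1
    p = horiz / horiz.sum()
    lrhgle = sum(p[i, j] * (i + 1) ** 2 * (j + 1) ** 2
                 for i in range(p.shape[0]) for j in range(p.shape[1]))
    assert lrhgle == pytest.approx(9.0)


def test_glrlm_constant_roi_run_entropy_zero_along_rows_and_columns():
    # constant ROI: every horizontal/vertical line is one maximal run, so the
    # run matrix of those directions has a single nonzero cell -> entropy 0
    # (diagonal lines of a square have varying lengths, so their run matrix
    # legitimately has several cells)
    d = discretize(np.full((4, 4), 7.0), np.ones((4, 4), bool), 25.0)
    for direction in (0, 1):
        mat = glrlm_matrices(d)[direction]
        p = (mat / mat.sum()).ravel()
        p = p[p > 0]
        assert float(-(p * np.log2(p)).sum()) == pytest.approx(0.0)


def test_glszm_constant_3x3_lahgle():
    # one 8-connected zone of size 9 at level 1: LAHGLE = 1*81/1 = 81
    d = discretize(np.zeros((3, 3)), np.ones((3, 3), bool), 25.0)
    assert glszm_features(d)["LargeAreaHighGrayLevelEmphasis"] == pytest.approx(81.0)


def test_glszm_all_distinct_small_area_emphasis():
    raw = np.arange(9, dtype=float).reshape(3, 3) * 100
    d = discretize(raw, np.ones((3, 3), bool), 25.0)
    assert glszm_features(d)["SmallAreaEmphasis"] == pytest.approx(1.0)


def test_gldm_equal_dependence_gives_zero_variance():
    # when every ROI pixel has the same dependence size the variance is 0:
    # isolated pixels (no in-mask neighbor) all have dependence 1
    mask = np.zeros((8, 8), bool)
    mask[::2, ::2] = True  # 16 pixels, pairwise non-adjacent
    d = discretize(np.full((8, 8), 3.0), mask, 25.0)
    assert gldm_features(d)["DependenceVariance"] == pytest.approx(0.0)
    # constant fully-masked ROI: a single gray level, zero gray-level variance
    d_full = discretize(np.full((5, 5), 3.0), np.ones((5, 5), bool), 25.0)
    assert gldm_features(d_full)["GrayLevelVariance"] == pytest.approx(0.0)


def test_gldm_3x3_matches_enumeration():
    raw = np.array([[1, 1, 2], [1, 2, 2], [2, 2, 1]], dtype=float) * 30
    d = discretize(raw, np.ones((3, 3), bool), 25.0)
    ref = oracles.gldm_features_oracle(d.levels, d.mask, d.ng)
    impl = gldm_features(d)
    for k in impl:
        assert impl[k] == pytest.approx(ref[k], rel=1e-9)


def test_ngtdm_constant_roi_flagged_zeros():
    d = discretize(np.full((4, 4), 9.0), np.ones((4, 4), bool), 25.0)
    f = ngtdm_features(d)
    assert f["Contrast"] == 0.0
    assert f["Busyness"] == 0.0


def test_ngtdm_bright_center_hand_values():
    # 3x3 with one bright center pixel, two levels
    raw = np.zeros((3, 3))
    raw[1, 1] = 30.0
    d = discretize(raw, np.ones((3, 3), bool), 25.0)
    ref = oracles.ngtdm_features_oracle(d.levels, d.mask, d.ng)
    impl = ngtdm_features(d)
    # s_1: 8 border pixels each |1 - mean(neighbors)|; s_2: center |2 - 1|
    assert impl["Contrast"] == pytest.approx(ref["Contrast"], rel=1e-12)
    for k in impl:
        assert impl[k] == pytest.approx(ref[k], rel=1e-9)


def test_translation_invariance_of_texture_features():
    rng = np.random.default_rng(3)
    raw, mask = random_roi(rng, max_side=10)
    h, w = raw.shape
    big_raw = np.zeros((h + 6, w + 6))
    big_mask = np.zeros((h + 6, w + 6), bool)
    big_raw[3:3 + h, 3:3 + w] = raw
    big_mask[3:3 + h, 3:3 + w] = mask
    d0 = discretize(raw, mask, 10.0)
    d1 = discretize(big_raw, big_mask, 10.0)
    for fn in (glcm_features, glrlm_features, glszm_features, gldm_features,
               ngtdm_features):
        a, b = fn(d0), fn(d1)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12), (fn.__name__, k)


def test_constant_shift_leaves_discretized_texture_unchanged():
    # adding a constant shifts min and values alike: identical levels
    rng = np.random.default_rng(5)
    raw, mask = random_roi(rng)
    d0 = discretize(raw, mask, 10.0)
    d1 = discretize(raw + 137.0, mask, 10.0)
    assert np.array_equal(d0.levels, d1.levels)
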