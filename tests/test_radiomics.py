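"""Radiomic features: hand-computed fixtures, brute-force matrix oracles
and the 100-feature contract."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placim.radiomics import (
    ALL_NAMES,
    FAMILY_COUNTS,
    extract_all,
    family_of,
    first_order_features,
    shape_features,
)
from placim.radiomics.discretize import DiscretizedRoi, discretize, discretize_values
from placim.radiomics.texture import (
    ANGLE_OFFSETS,
    _lines_along,
    _size_distribution_features,
    glcm_features,
    glcm_features_single,
    glcm_matrix,
    gldm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngtdm_table,
    run_lengths,
)

from .oracles import brute_glcm, brute_runs, brute_zones


# ------------------------------------------------------------ discretize

def test_discretize_half_open_bins():
    assert list(discretize_values(np.array([0.0, 0.5, 1.0]), 2)) == [1, 2, 2]


def test_discretize_constant_roi():
    assert (discretize_values(np.full(5, 2.2), 4) == 1).all()


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 50), shift=st.floats(-10, 10))
def test_discretize_affine_invariance(scale, shift):
    x = np.array([0.1, 0.4, 0.43, 0.9, 1.7, 2.0])
    assert np.array_equal(discretize_values(x, 8),
                          discretize_values(scale * x + shift, 8))


def test_discretize_respects_roi(rng):
    img = rng.random((6, 6))
    m = np.zeros((6, 6), dtype=np.uint8)
    m[2:5, 1:4] = 1
    d = discretize(img, m, n_bins=4)
    assert (d.levels[d.levels > 0] >= 1).all()
    assert d.n_pixels == 9


# ------------------------------------------------------------ first order

def test_first_order_constant_roi():
    f = first_order_features(np.full(7, 3.0))
    assert f["firstorder_energy"] == 7 * 9
    assert f["firstorder_variance"] == 0
    assert f["firstorder_entropy"] == 0
    assert f["firstorder_uniformity"] == 1
    assert f["firstorder_skewness"] == 0 and f["firstorder_kurtosis"] == 0


def test_first_order_hand_values():
    f = first_order_features(np.array([1.0, 1.0, 2.0, 4.0]))
    assert f["firstorder_mean"] == 2.0
    assert f["firstorder_variance"] == 1.5          # ((1+1+0+4)/4)
    g = first_order_features(np.array([1.0, 2.0, 3.0]))
    assert g["firstorder_mean"] == 2.0
    assert abs(g["firstorder_skewness"]) < 1e-12    # symmetric


def test_first_order_order_invariance(rng):
    x = rng.random(50)
    a = first_order_features(x)
    b = first_order_features(x[::-1].copy())
    assert a == pytest.approx(b, rel=1e-10)


# ------------------------------------------------------------ shape

def test_shape_square_area():
    m = np.zeros((12, 12), dtype=np.uint8)
    m[1:11, 1:11] = 1
    assert shape_features(m)["shape_pixel_surface"] == 100


def test_shape_circle_rounder_than_square():
    yy, xx = np.mgrid[0:61, 0:61]
    disk = ((yy - 30) ** 2 + (xx - 30) ** 2 <= 400).astype(np.uint8)
    side = int(np.sqrt(disk.sum()))
    square = np.zeros((61, 61), dtype=np.uint8)
    square[3:3 + side, 3:3 + side] = 1
    assert (shape_features(disk)["shape_sphericity"]
            > shape_features(square)["shape_sphericity"])


def test_shape_disk_elongation_near_one():
    yy, xx = np.mgrid[0:41, 0:41]
    disk = ((yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2).astype(np.uint8)
    assert abs(shape_features(disk)["shape_elongation"] - 1.0) < 0.05


def test_shape_translation_invariance():
    m = np.zeros((20, 20), dtype=np.uint8)
    m[2:8, 3:10] = 1
    a = shape_features(m)
    b = shape_features(np.roll(m, (5, 4), axis=(0, 1)))
    assert a == pytest.approx(b)


def test_shape_rejects_empty_and_multicomponent():
    with pytest.raises(ValueError):
        shape_features(np.zeros((5, 5)))
    two = np.zeros((9, 9), dtype=np.uint8)
    two[0, 0] = two[5, 5] = 1
    with pytest.raises(ValueError):
        shape_features(two)


# ------------------------------------------------------------ GLCM

def test_glcm_vertical_hand_example():
    """[[1,1],[2,2]] at 90 degrees: two symmetric (1,2) pairs, contrast 1."""
    d = DiscretizedRoi(levels=np.array([[1, 1], [2, 2]]), n_levels=2)
    p = glcm_matrix(d, angles=(90,))[90]
    assert p.sum() == pytest.approx(1.0)
    assert p[0, 1] == p[1, 0] == 0.5 and p[0, 0] == p[1, 1] == 0.0
    assert glcm_features_single(p)["glcm_contrast"] == pytest.approx(1.0)


def test_glcm_constant_image_degenerate():
    d = DiscretizedRoi(levels=np.ones((4, 4), dtype=int), n_levels=1)
    f = glcm_features(d)
    assert f["glcm_contrast"] == 0
    assert f["glcm_correlation"] == 0
    assert f["glcm_joint_entropy"] == 0


def test_glcm_normalisation(rng):
    lv = rng.integers(0, 4, size=(7, 7))
    d = DiscretizedRoi(levels=lv, n_levels=max(int(lv.max()), 1))
    for p in glcm_matrix(d).values():
        assert p.sum() == pytest.approx(1.0)


# ------------------------------------------------------------ GLRLM / GLSZM

def test_glrlm_stripe_example():
    d = DiscretizedRoi(levels=np.array([[1, 1, 1, 1]]), n_levels=1)
    assert run_lengths(d.levels, 0) == [(1, 4)]
    f = _size_distribution_features(glrlm_matrix(d, 0), 4, "g", ("sre", "lre"))
    assert f["g_lre"] == 16.0                      # sum r^2 p(r)
    assert f["g_size_nonuniformity"] == 1.0


def test_glszm_checkerboard_8connected():
    """Under 8-connectivity each level of a checkerboard is ONE zone."""
    ch = np.indices((4, 4)).sum(axis=0) % 2 + 1
    d = DiscretizedRoi(levels=ch, n_levels=2)
    m = glszm_matrix(d)
    assert m.shape == (2, 8)
    assert m[0, 7] == 1 and m[1, 7] == 1 and m.sum() == 2


@pytest.mark.parametrize("trial", range(8))
def test_matrices_match_brute_force(trial):
    """GLCM pairs, GLRLM runs and GLSZM zones agree with naive
    enumeration on random 6x6 images with up to 4 gray levels."""
    rng = np.random.default_rng(100 + trial)
    lv = rng.integers(0, rng.integers(2, 5), size=(6, 6))
    if (lv > 0).sum() < 2:
        lv[2:4, 2:4] = 1
    d = DiscretizedRoi(levels=lv, n_levels=max(int(lv.max()), 1))
    mats = glcm_matrix(d)
    for ang, off in ANGLE_OFFSETS.items():
        ref = brute_glcm(lv, d.n_levels, off)
        if ref is not None:
            assert np.allclose(mats[ang], ref)
    for ang in ANGLE_OFFSETS:
        assert sorted(run_lengths(lv, ang)) == brute_runs(lv, _lines_along(lv, ang))
    m = glszm_matrix(d)
    got = sorted((g + 1, s + 1)
                 for g in range(m.shape[0]) for s in range(m.shape[1])
                 for _ in range(int(m[g, s])))
    assert got == brute_zones(lv)


# ------------------------------------------------------------ NGTDM / GLDM

def test_ngtdm_hand_example():
    """2x2 block [[1,2],[2,2]]: every pixel has all 3 others as neighbours."""
    d = DiscretizedRoi(levels=np.array([[1, 2], [2, 2]]), n_levels=2)
    n_i, p_i, s_i = ngtdm_table(d)
    assert n_i.tolist() == [1, 3]
    # level 1 pixel: neighbours {2,2,2} -> |1-2| = 1
    assert s_i[0] == pytest.approx(1.0)
    # level 2 pixels: neighbour means 5/3 each -> |2 - 5/3| = 1/3, x3
    assert s_i[1] == pytest.approx(1.0)


def test_gldm_dependence_counts():
    """Constant 3x3 block: centre depends on all 8, edges on 5, corners 3."""
    d = DiscretizedRoi(levels=np.ones((3, 3), dtype=int), n_levels=1)
    m = gldm_matrix(d, alpha=0)
    # dependence = 1 + dependent neighbours: corners 4, edges 6, centre 9
    assert m[0, 3] == 4 and m[0, 5] == 4 and m[0, 8] == 1
    assert m.sum() == 9


# ------------------------------------------------------------ contract

def test_extract_all_contract(tiny_records):
    rec = tiny_records[2]
    vec = extract_all(rec.image, rec.mask)
    assert vec.shape == (100,)
    assert np.isfinite(vec).all()
    families = [family_of(n) for n in ALL_NAMES]
    assert families.count("firstorder") == 18
    assert families.count("shape") == 9
    assert families.count("texture") == 73
    assert FAMILY_COUNTS == {"firstorder": 18, "shape": 9, "texture": 73}
    assert np.array_equal(vec, extract_all(rec.image, rec.mask))


def test_extract_all_errors_name_family():
    with pytest.raises(ValueError):
        extract_all(np.zeros((5, 5)), np.zeros((5, 5)))   # empty ROI
    two = np.zeros((9, 9), dtype=np.uint8)
    two[0, 0] = two[5, 5] = 1
    # the failing family is named in the propagated error
    with pytest.raises(ValueError, match="shape features"):
        extract_all(np.ones((9, 9)), two)
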