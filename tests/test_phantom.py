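"""Phantom generator: determinism, geometry contracts and class signal."""

import numpy as np
import pytest
from scipy import ndimage

from placim.phantom import (
    ImageRecord,
    PhantomSpec,
    generate_dataset,
    generate_phantom,
    generate_records,
    heterogeneity_features,
    load_dataset,
    record_rng,
)


@pytest.mark.parametrize("kwargs", [
    {"image_size": 16},
    {"n_per_class": 0},
    {"placenta_area_frac_range": (0.0, 0.2)},
    {"placenta_area_frac_range": (0.3, 0.2)},
    {"placenta_area_frac_range": (0.2, 1.0)},
    {"noise_sigma": -0.1},
    {"myometrium_thickness_px": 0},
])
def test_spec_validation(kwargs):
    with pytest.raises(ValueError):
        PhantomSpec(**kwargs)


def test_record_validation():
    img = np.zeros((8, 8))
    with pytest.raises(ValueError):
        ImageRecord(image=img, mask=np.zeros((4, 4)))
    with pytest.raises(ValueError):
        ImageRecord(image=img, mask=np.full((8, 8), 2))
    with pytest.raises(ValueError):
        ImageRecord(image=img, label=5)


def test_rejects_bad_class_label():
    spec = PhantomSpec(image_size=64, n_per_class=1)
    with pytest.raises(ValueError):
        generate_phantom(spec, 4)


def test_seeded_determinism():
    spec = PhantomSpec(image_size=64, n_per_class=1, seed=5)
    a = generate_phantom(spec, 2, rng=record_rng(spec, 0))
    b = generate_phantom(spec, 2, rng=record_rng(spec, 0))
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.mask, b.mask)


def test_different_seeds_differ():
    r1 = generate_records(PhantomSpec(image_size=64, n_per_class=1, seed=1))
    r2 = generate_records(PhantomSpec(image_size=64, n_per_class=1, seed=2))
    assert any(not np.array_equal(a.image, b.image) for a, b in zip(r1, r2))


def test_mask_area_fraction_bounds():
    # 0.05 * 128^2 = 819.2, 0.15 * 128^2 = 2457.6
    spec = PhantomSpec(image_size=128, n_per_class=2,
                       placenta_area_frac_range=(0.05, 0.15), seed=3)
    for rec in generate_records(spec):
        assert 819 <= rec.mask.sum() <= 2458


def test_variance_ordering_same_geometry():
    """Noise-free class-0 placenta is more homogeneous than class 2 built
    from the same geometry draws."""
    spec = PhantomSpec(image_size=96, n_per_class=1, noise_sigma=0.0, seed=11)
    r0 = generate_phantom(spec, 0, rng=record_rng(spec, 0))
    r2 = generate_phantom(spec, 2, rng=record_rng(spec, 0))
    assert np.array_equal(r0.mask, r2.mask)  # same ellipse
    assert r0.image[r0.mask > 0].var() < r2.image[r2.mask > 0].var()


def test_heterogeneity_nondecreasing_in_expectation():
    means = []
    for c in range(4):
        vs = []
        for seed in range(6):
            spec = PhantomSpec(image_size=96, n_per_class=1, noise_sigma=0.0, seed=seed)
            rec = generate_phantom(spec, c, rng=record_rng(spec, 0))
            vs.append(rec.image[rec.mask > 0].var())
        means.append(np.mean(vs))
    assert all(means[i] <= means[i + 1] for i in range(3))


def test_class3_has_signal_beyond_ring():
    """The percreta bulge pushes mask tissue past where the ring sits."""
    spec = PhantomSpec(image_size=96, n_per_class=1, noise_sigma=0.0, seed=4)
    r1 = generate_phantom(spec, 1, rng=record_rng(spec, 0))
    r3 = generate_phantom(spec, 3, rng=record_rng(spec, 0))
    t = spec.myometrium_thickness_px
    dist = ndimage.distance_transform_edt(~(r1.mask > 0))
    beyond_ring = (dist > t) & (r3.mask > 0)
    assert beyond_ring.any()


def test_masks_single_4connected_component(tiny_records):
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for rec in tiny_records:
        _, n = ndimage.label(rec.mask, structure=cross)
        assert n == 1


def test_class_balance_and_planes(tiny_records):
    labels = [r.label for r in tiny_records]
    assert len(tiny_records) == 12
    assert np.bincount(labels, minlength=4).tolist() == [3, 3, 3, 3]
    assert {r.plane for r in tiny_records} <= {"transverse", "sagittal", "coronal"}


@pytest.mark.parametrize("fmt", ["png", "nifti"])
def test_dataset_roundtrip(tmp_path, fmt):
    spec = PhantomSpec(image_size=64, n_per_class=1, seed=9)
    records, manifest = generate_dataset(spec, tmp_path / fmt, fmt=fmt)
    assert len(manifest) == 4
    loaded = load_dataset(tmp_path / fmt / "manifest.csv")
    for orig, back in zip(records, loaded):
        assert back.id == orig.id and back.label == orig.label
        assert np.array_equal(back.mask, orig.mask)
        # 16-bit PNG quantisation; NIfTI stores float32
        assert np.abs(back.image - orig.image).max() < 1e-4


def test_dataset_refuses_overwrite(tmp_path):
    spec = PhantomSpec(image_size=64, n_per_class=1, seed=9)
    generate_dataset(spec, tmp_path)
    with pytest.raises(FileExistsError):
        generate_dataset(spec, tmp_path)
    generate_dataset(spec, tmp_path, force=True)  # allowed


def test_linear_separability_floor():
    """A linear model on (variance, ring integrity) beats chance, so the
    downstream learners have signal to find."""
    from sklearn.linear_model import LogisticRegression

    recs = generate_records(PhantomSpec(image_size=96, n_per_class=12,
                                        noise_sigma=0.0, seed=42))
    x = np.array([heterogeneity_features(r) for r in recs])
    y = np.array([r.label for r in recs])
    pred = LogisticRegression(max_iter=2000).fit(x, y).predict(x)
    macro_sens = np.mean([(pred[y == c] == c).mean() for c in range(4)])
    assert macro_sens > 0.25
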