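"""Fusion MLP: softmax semantics, architecture contracts, parameter
recovery on separable blobs and leakage-safety of standardisation."""

import numpy as np
import pytest

from placim.classifier import (
    ClfTrainConfig,
    FusedFeatures,
    InvasionMlp,
    build_mlp,
    load_classifier,
    predict,
    predict_proba,
    save_classifier,
    softmax4,
    train_classifier,
)


def test_softmax4_equal_logits():
    assert np.allclose(softmax4([0, 0, 0, 0]), 0.25)


def test_softmax4_closed_form():
    s = softmax4([1, 0, 0, 0])
    assert s[0] == pytest.approx(np.e / (np.e + 3), abs=1e-12)
    assert s[0] == pytest.approx(0.47536, abs=1e-5)


def test_softmax4_shift_invariance_and_stability():
    a = softmax4([5.0, 3.0, 2.0, 1.0])
    b = softmax4([105.0, 103.0, 102.0, 101.0])
    assert np.allclose(a, b)
    s = softmax4([800.0, 0.0, 0.0, 0.0])
    assert np.isfinite(s).all() and abs(s.sum() - 1) < 1e-9


def test_softmax4_rejects_bad_logits():
    with pytest.raises(ValueError):
        softmax4([np.inf, 0, 0, 0])
    with pytest.raises(ValueError):
        softmax4([0, 0, 0])


def test_build_contracts():
    a, b = build_mlp(seed=5), build_mlp(seed=5)
    assert all(np.array_equal(p.data, q.data) for p, q in zip(a.params(), b.params()))
    shapes = [p.data.shape for p in a.params()]
    assert (100, 200) in shapes and (20, 100) in shapes and (4, 20) in shapes
    probs = predict_proba(a, np.zeros((3, 200)))
    assert probs.shape == (3, 4)
    assert np.allclose(probs.sum(axis=1), 1.0)
    with pytest.raises(ValueError, match="200"):
        predict(a, np.zeros(150))


def test_fused_features_contract(rng):
    f = FusedFeatures(radiomic=rng.random((5, 100)), deep=rng.random((5, 100)))
    assert f.concatenated.shape == (5, 200)
    with pytest.raises(ValueError):
        FusedFeatures(radiomic=rng.random((5, 99)), deep=rng.random((5, 100)))
    with pytest.raises(ValueError):
        FusedFeatures(radiomic=rng.random((4, 100)), deep=rng.random((5, 100)))


def _blobs(rng, n_per_class=20, sigma=0.05):
    centers = rng.normal(size=(4, 200))
    x = np.vstack([centers[c] + sigma * rng.normal(size=(n_per_class, 200))
                   for c in range(4)])
    y = np.repeat(np.arange(4), n_per_class)
    return x, y


def test_blob_recovery(rng):
    """Well-separated Gaussian blobs are fit to high training macro
    sensitivity at the default training settings."""
    x, y = _blobs(rng)
    model, hist = train_classifier(x, y, ClfTrainConfig(epochs=120, seed=1))
    assert hist[-1] <= hist[0]
    pred = np.argmax(predict_proba(model, x), axis=1)
    macro_sens = np.mean([(pred[y == c] == c).mean() for c in range(4)])
    assert macro_sens >= 0.95


def test_permuted_labels_near_chance(rng):
    """Negative control: nothing real is learnable from shuffled labels."""
    x, y = _blobs(rng, n_per_class=25)
    yp = rng.permutation(y)
    model, _ = train_classifier(x[:80], yp[:80], ClfTrainConfig(epochs=100, seed=2))
    pred = np.argmax(predict_proba(model, x[80:]), axis=1)
    assert (pred == y[80:]).mean() <= 0.5


def test_training_input_validation(rng):
    x = rng.random((6, 200))
    with pytest.raises(ValueError):
        train_classifier(x, [0] * 6)                 # single class
    with pytest.raises(ValueError):
        train_classifier(x, [0, 1, 2, 3, 4, 0])      # out of range
    with pytest.raises(ValueError):
        train_classifier(x, [0, 1, 2])               # length mismatch


def test_tie_breaks_toward_lowest_class():
    model = build_mlp(seed=0)
    for p in model.params():
        p.data[...] = 0.0                            # all logits equal
    out = predict(model, np.ones(200))
    assert np.allclose(out.probabilities, 0.25)
    assert out.predicted_type == 0


def test_standardisation_fitted_on_train_only(rng):
    x, y = _blobs(rng, n_per_class=10)
    model, _ = train_classifier(x, y, ClfTrainConfig(epochs=5, seed=0))
    mean, scale = model.feat_mean.copy(), model.feat_scale.copy()
    # prediction on wildly different data must not refit the scaler
    predict_proba(model, 100.0 * rng.random((7, 200)))
    predict(model, 50.0 * np.ones(200))
    assert np.array_equal(model.feat_mean, mean)
    assert np.array_equal(model.feat_scale, scale)
    assert not hasattr(model, "fit_standardization")


def test_agrees_with_sklearn_reference(rng):
    """Independent cross-check: sklearn's MLP with the same topology also
    separates the blobs — two routes, one conclusion."""
    from sklearn.neural_network import MLPClassifier

    x, y = _blobs(rng, n_per_class=15)
    ours, _ = train_classifier(x, y, ClfTrainConfig(epochs=120, seed=3))
    ours_acc = (np.argmax(predict_proba(ours, x), axis=1) == y).mean()
    ref = MLPClassifier(hidden_layer_sizes=(100, 20), activation="relu",
                        random_state=0, max_iter=500).fit(x, y)
    ref_acc = ref.score(x, y)
    assert ours_acc >= 0.95 and ref_acc >= 0.95


def test_checkpoint_roundtrip(tmp_path, rng):
    x, y = _blobs(rng, n_per_class=8)
    model, _ = train_classifier(x, y, ClfTrainConfig(epochs=10, seed=1))
    save_classifier(tmp_path / "c.ckpt", model)
    back = load_classifier(tmp_path / "c.ckpt")
    assert np.array_equal(predict_proba(model, x), predict_proba(back, x))
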