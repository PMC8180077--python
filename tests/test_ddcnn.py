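"""Dynamic convolution (attention weights, kernel superposition) and the
codec: structural contracts, training descent, frozen-encoder features."""

import numpy as np
import pytest

from placim.ddcnn import (
    DdcnnSpec,
    DdcnnTrainConfig,
    DynamicConvSpec,
    attention_weights,
    build_ddcnn,
    deep_features,
    dynamic_conv,
    load_ddcnn,
    make_dynamic_conv,
    reconstruction_mse,
    save_ddcnn,
    train_autoencoder,
)

RNG = np.random.default_rng(7)


# ---------------------------------------------------- attention (weights)

def test_attention_weights_normalised():
    layer = make_dynamic_conv(DynamicConvSpec(n_kernels=4, in_channels=3), seed=1)
    x = RNG.normal(size=(5, 3, 6, 6)).astype(np.float32)
    w = attention_weights(layer, x)
    assert w.shape == (5, 4)
    assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)
    assert (w >= 0).all()


def test_single_kernel_weight_is_one():
    layer = make_dynamic_conv(DynamicConvSpec(n_kernels=1, in_channels=2), seed=0)
    w = attention_weights(layer, RNG.normal(size=(3, 2, 4, 4)).astype(np.float32))
    assert np.allclose(w, 1.0)


def test_zero_input_gives_uniform_weights():
    layer = make_dynamic_conv(DynamicConvSpec(n_kernels=4, in_channels=3), seed=2)
    w = attention_weights(layer, np.zeros((2, 3, 4, 4), np.float32))
    assert np.allclose(w, 0.25)


def test_dynamic_conv_spec_validation():
    with pytest.raises(ValueError):
        DynamicConvSpec(n_kernels=0)
    with pytest.raises(ValueError):
        DynamicConvSpec(kernel_size=4)
    with pytest.raises(ValueError):
        DynamicConvSpec(softmax_temperature=0)


# ---------------------------------------------------- kernel aggregation

def test_linearity_identity():
    """Convolving with sum(w_i k_i) equals the weighted sum of per-kernel
    convolutions (computed both ways)."""
    k = RNG.normal(size=(3, 2, 1, 3, 3))
    b = RNG.normal(size=(3, 2))
    w = np.array([0.2, 0.5, 0.3])
    x = RNG.normal(size=(1, 1, 5, 5)).astype(np.float32)
    y_agg = dynamic_conv(x, k, w, b)
    y_sum = sum(w[i] * dynamic_conv(x, k[i:i + 1], np.ones(1), b[i:i + 1])
                for i in range(3))
    assert np.abs(y_agg - y_sum).max() < 1e-5


def test_one_hot_weights_select_kernel():
    k = RNG.normal(size=(4, 2, 1, 3, 3))
    b = RNG.normal(size=(4, 2))
    x = RNG.normal(size=(1, 1, 6, 6)).astype(np.float32)
    sel = dynamic_conv(x, k, np.array([0.0, 0.0, 1.0, 0.0]), b)
    direct = dynamic_conv(x, k[2:3], np.ones(1), b[2:3])
    assert np.allclose(sel, direct, atol=1e-6)


def test_identical_kernels_reduce_to_plain_conv():
    k = np.repeat(RNG.normal(size=(1, 2, 1, 3, 3)), 3, axis=0)
    b = np.repeat(RNG.normal(size=(1, 2)), 3, axis=0)
    x = RNG.normal(size=(1, 1, 5, 5)).astype(np.float32)
    for w in ([1, 0, 0], [0.3, 0.3, 0.4]):
        assert np.allclose(dynamic_conv(x, k, np.array(w, float), b),
                           dynamic_conv(x, k[:1], np.ones(1), b[:1]), atol=1e-5)


def test_mismatched_weights_rejected():
    with pytest.raises(ValueError):
        dynamic_conv(np.zeros((1, 1, 4, 4), np.float32),
                     RNG.normal(size=(3, 1, 1, 3, 3)), np.array([0.5, 0.5]))


# ---------------------------------------------------- codec structure

def test_codec_shapes():
    spec = DdcnnSpec(stages=2, base_channels=4, input_size=32)
    model = build_ddcnn(spec, seed=0)
    x = RNG.random((3, 1, 32, 32)).astype(np.float32)
    z = model.encode(x)
    assert z.shape == (3, 100)
    recon = model.forward(x)
    assert recon.shape == x.shape
    assert recon.min() >= 0 and recon.max() <= 1      # bounded output


def test_spatial_halving_arithmetic():
    # 5 stages halve 128 -> 4; the bottleneck is always 100-dim
    spec = DdcnnSpec(stages=5, base_channels=2, max_channels=8, input_size=128)
    model = build_ddcnn(spec, seed=0)
    assert model._latent_hw == 4
    assert model.fc_enc.weight.data.shape[0] == 100


def test_indivisible_input_size_rejected():
    with pytest.raises(ValueError, match="divisible"):
        DdcnnSpec(stages=2, input_size=30)


def test_wrong_crop_size_rejected():
    model = build_ddcnn(DdcnnSpec(stages=2, base_channels=2, input_size=32), seed=0)
    with pytest.raises(ValueError, match="32x32"):
        deep_features(model, np.zeros((16, 16)))


# ---------------------------------------------------- training

def _crops(n=8, size=32):
    rng = np.random.default_rng(5)
    return [rng.random((size, size)) for _ in range(n)]


def test_autoencoder_descends_and_is_deterministic():
    spec = DdcnnSpec(stages=2, base_channels=4, input_size=32)
    cfg = DdcnnTrainConfig(batch_size=4, learning_rate=0.1, epochs=4,
                           momentum=0.9, seed=0)
    m1, h1 = train_autoencoder(build_ddcnn(spec, seed=0), _crops(), cfg)
    assert len(h1) == 4 and h1[-1] <= h1[0]
    m2, h2 = train_autoencoder(build_ddcnn(spec, seed=0), _crops(), cfg)
    assert h1 == h2


def test_autoencoder_fits_constant_crops():
    """On constant images the reconstruction error approaches zero."""
    spec = DdcnnSpec(stages=1, base_channels=4, input_size=16)
    crops = [np.full((16, 16), 0.4) for _ in range(4)]
    cfg = DdcnnTrainConfig(batch_size=4, learning_rate=0.5, epochs=40,
                           momentum=0.9, seed=0)
    model, hist = train_autoencoder(build_ddcnn(spec, seed=0), crops, cfg)
    assert reconstruction_mse(model, crops) < 1e-3


def test_autoencoder_needs_crops():
    with pytest.raises(ValueError):
        train_autoencoder(build_ddcnn(DdcnnSpec(stages=1, input_size=16), seed=0),
                          [np.zeros((16, 16))], DdcnnTrainConfig())


# ---------------------------------------------------- features

def test_deep_features_contract():
    model = build_ddcnn(DdcnnSpec(stages=2, base_channels=4, input_size=32), seed=0)
    crop = RNG.random((32, 32))
    before = [p.data.copy() for p in model.params()]
    f1 = deep_features(model, crop)
    f2 = deep_features(model, crop)
    assert f1.shape == (100,)
    assert np.array_equal(f1, f2)
    # the encoder is frozen: extraction never changes parameters
    assert all(np.array_equal(a, p.data) for a, p in zip(before, model.params()))
    other = deep_features(model, RNG.random((32, 32)))
    assert not np.array_equal(f1, other)


def test_checkpoint_roundtrip(tmp_path):
    spec = DdcnnSpec(stages=2, base_channels=4, input_size=32)
    cfg = DdcnnTrainConfig(batch_size=4, learning_rate=0.1, epochs=2, seed=0)
    model, _ = train_autoencoder(build_ddcnn(spec, seed=0), _crops(), cfg)
    save_ddcnn(tmp_path / "d.ckpt", model)
    back = load_ddcnn(tmp_path / "d.ckpt")
    crop = _crops(1)[0]
    assert np.array_equal(deep_features(model, crop), deep_features(back, crop))
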