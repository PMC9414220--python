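"""The classifier zoo: layer transcription, shape propagation, transfer."""

import numpy as np
import pytest

import mirepr as m
from mirepr.models import LayerSpec

CANONICAL_INPUT = {
    "cnn2d-1": (3, 32, 32), "cnn2d-2": (3, 32, 32), "cnn2d-3": (3, 32, 32),
    "tl-1": (3, 256, 256), "tl-3": (3, 256, 256),
    "cnn1d-1": (1, 640), "cnn1d-2": (1, 640), "cnn1d-3": (1, 640),
    "cnn1d-4": (1, 640), "cnn1d-5": (1, 640),
}


def shape_oracle(layers, shape, n_classes=3):
    """Independent per-layer arithmetic: floor((L + 2p - k)/s) + 1."""
    def conv_len(L, k, s, p):
        out = (L + 2 * p - k) // s + 1
        assert out >= 1
        return out

    for ls in layers:
        if ls.kind in ("conv1d", "conv2d"):
            spatial = [conv_len(d, ls.kernel, ls.stride, ls.padding)
                       for d in shape[1:]]
            shape = (ls.filters, *spatial)
        elif ls.kind in ("maxpool1d", "maxpool2d"):
            shape = (shape[0], *[conv_len(d, ls.kernel, ls.stride, 0)
                                 for d in shape[1:]])
        elif ls.kind == "flatten":
            shape = (int(np.prod(shape)),)
        elif ls.kind == "linear":
            shape = (n_classes,)
    return shape


def test_zoo_has_ten_models():
    zoo = m.model_zoo()
    assert len(zoo) == 10
    assert set(zoo) == set(m.MODEL_IDS)


def test_published_layer_hyperparameters():
    zoo = m.model_zoo()
    assert zoo["cnn2d-1"].layers[0] == LayerSpec("conv2d", 64, 3, 1, 1)
    assert zoo["cnn2d-2"].layers[0] == LayerSpec("conv2d", 64, 5, 1, 1)
    assert zoo["cnn2d-2"].layers[3] == LayerSpec("conv2d", 128, 1, 1, 1)
    assert zoo["cnn1d-1"].layers[0] == LayerSpec("conv1d", 128, 5, 2, 0)
    assert zoo["cnn1d-1"].layers[3] == \
        LayerSpec("maxpool1d", kernel=3, stride=2)
    assert zoo["cnn1d-5"].layers[0] == LayerSpec("conv1d", 32, 5, 2, 1)
    # transfer models reuse the 1- and 3-layer heads on a residual backbone
    assert zoo["tl-1"].backbone == "resnet18"
    assert zoo["tl-1"].layers == zoo["cnn2d-1"].layers
    assert zoo["tl-3"].layers == zoo["cnn2d-3"].layers
    for spec in zoo.values():
        assert spec.layers[-1].kind == "linear"
        assert spec.n_classes == 3


@pytest.mark.parametrize("model_id", m.MODEL_IDS)
def test_shape_propagation_matches_oracle(model_id):
    zoo = m.model_zoo()
    spec = zoo[model_id]
    shape = CANONICAL_INPUT[model_id]
    model = m.build_model(spec, shape, seed=0)
    if spec.backbone is not None:
        head_in = model.backbone.output_shape(shape)
        assert head_in == (512, 8, 8)   # 256/32 residual downsampling
        shape = head_in
    assert shape_oracle(spec.layers, shape) == (3,)
    assert model.head.output_shape(shape) == (3,)
    # flatten width of the final linear layer matches the oracle
    pre_linear = shape_oracle(spec.layers[:-1], shape)
    assert model.head.layers[-1].nin == pre_linear[0]


def test_derived_shapes_cnn1d_1():
    zoo = m.model_zoo()
    model = m.build_model(zoo["cnn1d-1"], (1, 640))
    conv = model.head.layers[0]
    assert conv.output_shape((1, 640)) == (128, 318)
    pool = model.head.layers[3]
    assert pool.output_shape((128, 318)) == (128, 158)
    assert model.head.layers[-1].nin == 128 * 158


def test_derived_shapes_cnn2d_1():
    zoo = m.model_zoo()
    model = m.build_model(zoo["cnn2d-1"], (3, 32, 32))
    assert model.head.layers[0].output_shape((3, 32, 32)) == (64, 32, 32)
    assert model.head.layers[2].output_shape((64, 32, 32)) == (64, 31, 31)


@pytest.mark.parametrize("model_id", [i for i in m.MODEL_IDS
                                      if not i.startswith("tl")])
def test_forward_logits_and_connectivity(model_id):
    """Finite 3-logit output; loss gradient reaches every trainable layer."""
    import mirepr.nn as nn

    zoo = m.model_zoo()
    shape = CANONICAL_INPUT[model_id]
    model = m.build_model(zoo[model_id], shape, seed=1)
    rng = np.random.default_rng(0)
    x = rng.standard_normal((4, *shape)).astype(np.float32)
    logits = model.forward(x, training=True)
    assert logits.shape == (4, 3)
    assert np.isfinite(logits).all()
    loss, grad = nn.cross_entropy(logits, rng.integers(0, 3, 4))
    for p in model.params():
        p.grad[...] = 0
    model.backward(grad)
    for layer in model.head.layers:
        for p in layer.params():
            assert np.abs(p.grad).max() > 0, f"dead layer in {model_id}"


def test_volume_input_maps_depth_to_planes():
    zoo = m.model_zoo()
    model = m.build_model(zoo["cnn2d-1"], (7, 3, 640), seed=0)
    x = np.random.default_rng(1).standard_normal((2, 7, 3, 640))
    assert model.forward(x.astype(np.float32)).shape == (2, 3)
    # the two-layer net's 5x5 first kernel cannot fit the 3-row volume;
    # faithful layer transcription makes that a named shape error
    with pytest.raises(m.ShapeError, match="maxpool2d"):
        m.build_model(zoo["cnn2d-2"], (7, 3, 640), seed=0)


def test_incompatible_shape_names_layer():
    zoo = m.model_zoo()
    with pytest.raises(m.ShapeError, match="maxpool2d"):
        # 1x1 spatial extent survives the conv but not the 2x2 pool
        m.build_model(zoo["cnn2d-1"], (3, 1, 1))
    with pytest.raises(m.ShapeError, match="conv1d"):
        m.build_model(zoo["cnn1d-1"], (1, 2))


def test_transfer_requires_256_input():
    zoo = m.model_zoo()
    with pytest.raises(m.ShapeError):
        m.build_model(zoo["tl-1"], (3, 32, 32))


def test_transfer_stage_controller():
    zoo = m.model_zoo()
    model = m.build_model(zoo["tl-1"], (3, 256, 256), seed=0)
    stages = m.transfer_stages(model)
    all_params = model.params()
    head_set = {id(p) for p in model.head_params()}
    stages.freeze_backbone()
    trainable = {id(p) for p in model.params() if p.trainable}
    assert trainable == head_set
    stages.freeze_backbone()        # idempotent
    assert {id(p) for p in model.params() if p.trainable} == head_set
    stages.unfreeze_all()
    assert all(p.trainable for p in all_params)
    with pytest.raises(m.TransferStateError):
        m.transfer_stages(m.build_model(zoo["cnn2d-1"], (3, 32, 32)))


def test_transfer_forward_and_frozen_gradients():
    import mirepr.nn as nn

    zoo = m.model_zoo()
    model = m.build_model(zoo["tl-3"], (3, 256, 256), seed=0)
    m.transfer_stages(model).freeze_backbone()
    x = np.random.default_rng(2).standard_normal((1, 3, 256, 256))
    logits = model.forward(x.astype(np.float32), training=True)
    assert logits.shape == (1, 3) and np.isfinite(logits).all()
    loss, grad = nn.cross_entropy(logits, np.array([1]))
    for p in model.params():
        p.grad[...] = 0
    model.backward(grad, through_backbone=False)
    for layer in model.head.layers:
        for p in layer.params():
            assert np.abs(p.grad).max() > 0


def test_spec_json_round_trip():
    zoo = m.model_zoo()
    for spec in zoo.values():
        back = m.ModelSpec.from_json(spec.to_json())
        assert back == spec


def test_checkpoint_round_trip(tmp_path):
    zoo = m.model_zoo()
    model = m.build_model(zoo["cnn1d-2"], (1, 640), seed=5)
    x = np.random.default_rng(0).standard_normal((3, 1, 640)).astype(np.float32)
    want = model.forward(x)
    path = tmp_path / "ckpt.npz"
    model.save(path)
    back = m.Model.load(path)
    assert np.array_equal(back.forward(x), want)
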