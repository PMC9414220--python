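"""The ten-network classifier zoo, specified declaratively.

Three plain 2D CNNs consume the image representations (and, with depth
mapped to input planes, the 2D matrices and 3D volumes); two transfer
compositions bolt the single- and three-layer 2D CNNs as heads onto a
headless 18-layer residual backbone; five 1D CNNs consume the length-640
single-channel vectors.  Every architecture ends in a fully connected
3-logit output.

Each network is a :class:`ModelSpec` — an ordered list of
:class:`LayerSpec` entries transcribing the published layer
hyperparameters — and :func:`build_model` instantiates it against a
concrete input shape, computing the flatten dimension of the final linear
layer at build time.  Two kernel sizes the source description leaves
unstated (the three-layer 2D CNN's middle convolution and the two-layer 1D
CNN's first convolution) default to each family's first-layer style (3x3
and 5) and are overridable in :func:`model_zoo`.

The residual backbone is randomly initialized: pretrained weights are an
optional extra, and none of the structural or training machinery depends
on them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn

__all__ = [
    "LayerSpec", "ModelSpec", "Model", "ShapeError", "TransferStateError",
    "model_zoo", "build_model", "transfer_stages", "TransferStages",
    "MODEL_IDS",
]

MODEL_IDS: Tuple[str, ...] = (
    "cnn2d-1", "cnn2d-2", "cnn2d-3", "tl-1", "tl-3",
    "cnn1d-1", "cnn1d-2", "cnn1d-3", "cnn1d-4", "cnn1d-5",
)


class ShapeError(ValueError):
    """An input shape is incompatible with a layer of the architecture."""


class TransferStateError(RuntimeError):
    """Transfer-stage control requested on a model without a backbone."""


@dataclass(frozen=True)
class LayerSpec:
    kind: str                      # conv1d|conv2d|batchnorm|relu|maxpool1d|
    #                                maxpool2d|dropout|flatten|linear
    filters: Optional[int] = None
    kernel: Optional[int] = None
    stride: Optional[int] = None
    padding: Optional[int] = None
    rate: Optional[float] = None   # dropout only

    def __post_init__(self):
        meaningful = {
            "conv1d": ("filters", "kernel", "stride", "padding"),
            "conv2d": ("filters", "kernel", "stride", "padding"),
            "maxpool1d": ("kernel", "stride"),
            "maxpool2d": ("kernel", "stride"),
            "dropout": ("rate",),
            "batchnorm": (), "relu": (), "flatten": (), "linear": (),
        }
        if self.kind not in meaningful:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        for name in ("filters", "kernel", "stride", "padding", "rate"):
            val = getattr(self, name)
            if name in meaningful[self.kind]:
                if val is None and name != "rate":
                    raise ValueError(f"{self.kind} layer requires {name}")
            elif val is not None:
                raise ValueError(f"{name} is meaningless for {self.kind}")


@dataclass(frozen=True)
class ModelSpec:
    id: str
    layers: Tuple[LayerSpec, ...]
    n_classes: int = 3
    backbone: Optional[str] = None    # 'resnet18' for the transfer models

    def to_json(self) -> str:
        return json.dumps({
            "id": self.id,
            "n_classes": self.n_classes,
            "backbone": self.backbone,
            "layers": [asdict(l) for l in self.layers],
        })

    @classmethod
    def from_json(cls, payload: str) -> "ModelSpec":
        d = json.loads(payload)
        return cls(id=d["id"],
                   layers=tuple(LayerSpec(**l) for l in d["layers"]),
                   n_classes=d["n_classes"], backbone=d["backbone"])


def _conv_block_2d(filters, kernel, stride, padding):
    return LayerSpec("conv2d", filters, kernel, stride, padding)


def model_zoo(cnn2d3_mid_kernel: int = 3,
              cnn1d2_first_kernel: int = 5,
              dropout_rate: float = 0.5) -> Dict[str, ModelSpec]:
    """The ten frozen architectures, keyed by id."""
    L = LayerSpec
    cnn2d_1 = (
        L("conv2d", 64, 3, 1, 1), L("relu"), L("maxpool2d", kernel=2, stride=1),
        L("flatten"), L("linear"),
    )
    cnn2d_2 = (
        L("conv2d", 64, 5, 1, 1), L("relu"), L("maxpool2d", kernel=2, stride=1),
        L("conv2d", 128, 1, 1, 1), L("relu"),
        L("flatten"), L("linear"),
    )
    cnn2d_3 = (
        L("conv2d", 64, 3, 1, 1), L("relu"), L("maxpool2d", kernel=2, stride=1),
        L("conv2d", 128, cnn2d3_mid_kernel, 1, 1), L("relu"),
        L("conv2d", 256, 3, 1, 1), L("relu"), L("maxpool2d", kernel=2, stride=1),
        L("flatten"), L("linear"),
    )
    cnn1d_1 = (
        L("conv1d", 128, 5, 2, 0), L("batchnorm"), L("relu"),
        L("maxpool1d", kernel=3, stride=2),
        L("flatten"), L("linear"),
    )
    cnn1d_2 = (
        L("conv1d", 64, cnn1d2_first_kernel, 1, 0),
        L("dropout", rate=dropout_rate), L("relu"),
        L("maxpool1d", kernel=2, stride=1),
        L("conv1d", 128, 1, 1, 0), L("relu"),
        L("flatten"), L("linear"),
    )
    cnn1d_3 = (
        L("conv1d", 64, 5, 1, 1), L("batchnorm"), L("relu"),
        L("conv1d", 128, 3, 1, 0), L("batchnorm"),
        L("dropout", rate=dropout_rate), L("relu"),
        L("conv1d", 256, 3, 1, 1), L("batchnorm"),
        L("dropout", rate=dropout_rate), L("relu"),
        L("flatten"), L("linear"),
    )
    cnn1d_4 = (
        L("conv1d", 64, 5, 1, 1), L("batchnorm"), L("relu"),
        L("maxpool1d", kernel=2, stride=1),
        L("conv1d", 128, 3, 1, 0), L("batchnorm"),
        L("dropout", rate=dropout_rate), L("relu"),
        L("conv1d", 256, 3, 1, 1), L("batchnorm"),
        L("dropout", rate=dropout_rate), L("relu"),
        L("maxpool1d", kernel=2, stride=2),
        L("conv1d", 256, 1, 1, 1), L("batchnorm"), L("relu"),
        L("flatten"), L("linear"),
    )
    cnn1d_5 = (
        L("conv1d", 32, 5, 2, 1), L("batchnorm"), L("relu"),
        L("maxpool1d", kernel=2, stride=1),
        L("conv1d", 64, 3, 2, 4), L("batchnorm"),
        L("dropout", rate=dropout_rate), L("relu"),
        L("maxpool1d", kernel=2, stride=1),
        L("conv1d", 128, 1, 1, 0), L("batchnorm"), L("relu"),
        L("conv1d", 256, 3, 1, 4), L("batchnorm"), L("relu"),
        L("conv1d", 128, 5, 1, 4), L("batchnorm"), L("relu"),
        L("dropout", rate=dropout_rate),
        L("flatten"), L("linear"),
    )
    zoo = {
        "cnn2d-1": ModelSpec("cnn2d-1", cnn2d_1),
        "cnn2d-2": ModelSpec("cnn2d-2", cnn2d_2),
        "cnn2d-3": ModelSpec("cnn2d-3", cnn2d_3),
        "tl-1": ModelSpec("tl-1", cnn2d_1, backbone="resnet18"),
        "tl-3": ModelSpec("tl-3", cnn2d_3, backbone="resnet18"),
        "cnn1d-1": ModelSpec("cnn1d-1", cnn1d_1),
        "cnn1d-2": ModelSpec("cnn1d-2", cnn1d_2),
        "cnn1d-3": ModelSpec("cnn1d-3", cnn1d_3),
        "cnn1d-4": ModelSpec("cnn1d-4", cnn1d_4),
        "cnn1d-5": ModelSpec("cnn1d-5", cnn1d_5),
    }
    return zoo


# ---------------------------------------------------------------------------
# instantiation

def _build_resnet18(in_channels: int, rng: np.random.Generator
                    ) -> nn.Sequential:
    """Headless 18-layer residual backbone (stem + 4 stages of 2 blocks).

    Output is the final 512-plane feature map; the classification head
    (global pool + fc) is deliberately absent — the zoo's own CNN heads
    replace it.
    """
    layers: List[nn.Layer] = [
        nn.Conv2d(in_channels, 64, 7, 2, 3, rng),
        nn.BatchNorm(64), nn.ReLU(),
        nn.MaxPool2d(3, 2, padding=1),
    ]
    channels = 64
    for stage, out_ch in enumerate((64, 128, 256, 512)):
        stride = 1 if stage == 0 else 2
        layers.append(nn.BasicBlock2d(channels, out_ch, stride, rng))
        layers.append(nn.BasicBlock2d(out_ch, out_ch, 1, rng))
        channels = out_ch
    return nn.Sequential(layers)


def _instantiate(spec: ModelSpec, input_shape: Tuple[int, ...],
                 rng: np.random.Generator,
                 dropout_rng: np.random.Generator) -> nn.Sequential:
    layers: List[nn.Layer] = []
    shape = tuple(input_shape)
    for i, ls in enumerate(spec.layers):
        where = f"layer {i} ({ls.kind})"
        try:
            if ls.kind == "conv1d":
                if len(shape) != 2:
                    raise ValueError(f"expects (channels, length), got {shape}")
                layer = nn.Conv1d(shape[0], ls.filters, ls.kernel,
                                  ls.stride, ls.padding, rng)
            elif ls.kind == "conv2d":
                if len(shape) != 3:
                    raise ValueError(f"expects (planes, H, W), got {shape}")
                layer = nn.Conv2d(shape[0], ls.filters, ls.kernel,
                                  ls.stride, ls.padding, rng)
            elif ls.kind == "batchnorm":
                layer = nn.BatchNorm(shape[0])
            elif ls.kind == "relu":
                layer = nn.ReLU()
            elif ls.kind == "maxpool1d":
                layer = nn.MaxPool1d(ls.kernel, ls.stride)
            elif ls.kind == "maxpool2d":
                layer = nn.MaxPool2d(ls.kernel, ls.stride)
            elif ls.kind == "dropout":
                layer = nn.Dropout(ls.rate if ls.rate is not None else 0.5,
                                   dropout_rng)
            elif ls.kind == "flatten":
                layer = nn.Flatten()
            elif ls.kind == "linear":
                layer = nn.Linear(shape[0], spec.n_classes, rng)
            else:  # pragma: no cover - guarded by LayerSpec
                raise ValueError(f"unknown kind {ls.kind}")
            shape = layer.output_shape(shape)
        except ValueError as err:
            raise ShapeError(f"{spec.id}: {where}: {err}") from None
        layers.append(layer)
    if shape != (spec.n_classes,):
        raise ShapeError(
            f"{spec.id}: architecture does not end in {spec.n_classes} "
            f"logits (got {shape})")
    return nn.Sequential(layers)


class Model:
    """An instantiated network: callable batch -> [batch x 3] logits."""

    def __init__(self, spec: ModelSpec, input_shape: Tuple[int, ...],
                 seed: int = 0):
        self.spec = spec
        self.input_shape = tuple(int(s) for s in input_shape)
        self.seed = seed
        rng = np.random.default_rng([abs(int(seed)), 71])
        self._dropout_rng = np.random.default_rng([abs(int(seed)), 72])
        if spec.backbone is not None:
            if self.input_shape != (3, 256, 256):
                raise ShapeError(
                    f"{spec.id}: transfer models require 3x256x256 input, "
                    f"got {self.input_shape}")
            self.backbone: Optional[nn.Sequential] = _build_resnet18(3, rng)
            head_in = self.backbone.output_shape(self.input_shape)
        else:
            self.backbone = None
            head_in = self.input_shape
        self.head = _instantiate(spec, head_in, rng, self._dropout_rng)

    # -- forward/backward --------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.shape[1:] != self.input_shape:
            raise ShapeError(
                f"{self.spec.id}: batch shape {x.shape[1:]} does not match "
                f"model input {self.input_shape}")
        if self.backbone is not None:
            x = self.backbone.forward(x, training)
        return self.head.forward(x, training)

    __call__ = forward

    def backward(self, grad: np.ndarray,
                 through_backbone: bool = True) -> np.ndarray:
        grad = self.head.backward(grad)
        if self.backbone is not None and through_backbone:
            grad = self.backbone.backward(grad)
        return grad

    # -- parameters --------------------------------------------------------
    def params(self) -> List[nn.Param]:
        out = self.backbone.params() if self.backbone is not None else []
        return out + self.head.params()

    def head_params(self) -> List[nn.Param]:
        return self.head.params()

    def trainable_params(self) -> List[nn.Param]:
        return [p for p in self.params() if p.trainable]

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class indices for a batch of inputs (evaluation mode)."""
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i:i + batch_size]).argmax(axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)

    # -- checkpointing -----------------------------------------------------
    def state_arrays(self) -> List[np.ndarray]:
        arrays = [p.data for p in self.params()]
        stacks = [self.backbone, self.head] if self.backbone is not None \
            else [self.head]
        for seq in stacks:
            for layer in seq.layers:
                arrays.extend(_layer_buffers(layer))
        return arrays

    def save(self, path) -> None:
        header = json.dumps({
            "spec": json.loads(self.spec.to_json()),
            "input_shape": list(self.input_shape),
            "seed": self.seed,
        })
        arrays = {f"a{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, header=np.array(header), **arrays)

    @classmethod
    def load(cls, path) -> "Model":
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            spec = ModelSpec.from_json(json.dumps(header["spec"]))
            model = cls(spec, tuple(header["input_shape"]),
                        seed=header["seed"])
            for i, a in enumerate(model.state_arrays()):
                a[...] = z[f"a{i}"]
        return model


def _layer_buffers(layer: nn.Layer) -> List[np.ndarray]:
    out = list(layer.buffers())
    for attr in ("conv1", "bn1", "conv2", "bn2", "down"):
        sub = getattr(layer, attr, None)
        if isinstance(sub, nn.Layer):
            out.extend(_layer_buffers(sub) if isinstance(sub, (
                nn.Sequential, nn.BasicBlock2d)) else sub.buffers())
    if isinstance(layer, nn.Sequential):
        for sub in layer.layers:
            out.extend(_layer_buffers(sub))
    return out


def build_model(spec: ModelSpec, input_shape: Tuple[int, ...],
                seed: int = 0) -> Model:
    """Instantiate a spec for a concrete input shape.

    1D specs take (1, 640) single-channel series; 2D specs take
    (planes, H, W) — RGB images as (3, H, W), raw matrices as
    (1, n_channels, 640), volumes with depth mapped to planes as
    (D, C, 640).  Raises :class:`ShapeError` naming the first layer an
    incompatible shape fails at.
    """
    return Model(spec, input_shape, seed=seed)


class TransferStages:
    """Freeze/unfreeze controller for the transfer-learning models.

    ``freeze_backbone`` marks every backbone parameter non-trainable so
    only the head learns; ``unfreeze_all`` restores full trainability for
    fine-tuning at a small learning rate.  Both are idempotent.
    """

    def __init__(self, model: Model):
        if model.backbone is None:
            raise TransferStateError(
                f"{model.spec.id} has no pretrained backbone to stage")
        self.model = model

    def freeze_backbone(self) -> None:
        for p in self.model.backbone.params():
            p.trainable = False

    def unfreeze_all(self) -> None:
        for p in self.model.params():
            p.trainable = True


def transfer_stages(model: Model) -> TransferStages:
    return TransferStages(model)
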