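"""Lightweight multitask bladder network: shared encoder, QSE segmentation
decoder and a global-pooled classification head.

The encoder is a single-channel MobileNetV2 truncated right after the last
stride-16 bottleneck stage with 96 output channels, so a 192 x 192 input
yields a 12 x 12 x 96 feature map.  The segmentation path runs two parallel
branches over that map — a *quantizable squeeze-and-excitation* (QSE)
branch injecting global channel context, and a 3 x 3 convolution branch
keeping local detail — concatenates them to 512 channels, merges with a
depthwise-separable (DWC) block down to 256, reduces to the two pixel
classes and upscales bilinearly back to the input size.  The
classification path is global average pooling plus a dense layer.

The QSE block replaces the classic squeeze-and-excitation gating
(a sigmoid-weighted elementwise *product* of activations, which 8-bit
fixed-point pipelines handle poorly) by concatenating the tiled squeeze
vector with the feature map and mixing with a 1 x 1 convolution: channel
context enters through convolution weights only, and the whole graph is
free of activation-activation multiplications.

The entire default model must stay under one million trainable parameters;
:func:`build_model` enforces the budget with an exact per-layer account.
The 3 x 3 convolution branch is realized with depthwise-separable
convolutions: full dense 3 x 3 kernels at 256 channels alone would exceed
the parameter budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .exceptions import BudgetViolationError, InvalidArgumentError
from .nn import Network
from .nn.layers import (
    Add,
    BatchNorm,
    BilinearUpsample,
    Concat,
    Conv2D,
    Dense,
    DepthwiseConv2D,
    Flatten,
    GlobalAvgPool,
    Multiply,
    ReLU6,
    Softmax,
    TileToSpatial,
)

#: MobileNetV2 inverted-residual plan truncated at the 96-channel
#: stride-16 stage: (expansion t, out channels c, repeats n, first stride s)
BACKBONE_PLAN = [(1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2), (6, 96, 3, 1)]
STEM_CHANNELS = 32
ENCODER_CHANNELS = 96
PARAMETER_BUDGET = 1_000_000


@dataclass
class ModelConfig:
    input_size: int = 192
    num_classes_seg: int = 2
    num_classes_clf: int = 2
    qse_blocks: int = 2
    conv_branch_layers: int = 2
    branch_channels: int = 256
    merge_channels: int = 256
    seed: int = 0
    budget: int = PARAMETER_BUDGET


# ----------------------------------------------------------------- descriptors

def _count_formula(layer) -> int:
    """Closed-form trainable-parameter count per layer kind."""
    kind = layer.kind
    if kind == "conv":
        n = layer.k * layer.k * layer.c_in * layer.c_out
        return n + (layer.c_out if layer.use_bias else 0)
    if kind == "depthwise_conv":
        n = layer.k * layer.k * layer.c_in
        return n + (layer.c_in if layer.use_bias else 0)
    if kind == "dense":
        return layer.c_in * layer.c_out + (layer.c_out if layer.use_bias else 0)
    if kind == "batch_norm":
        return 2 * layer.c
    return 0


@dataclass
class LayerDescriptor:
    name: str
    kind: str
    inputs: list[str]
    group: str
    shape: dict
    parameter_count: int


def describe(network: Network) -> list[LayerDescriptor]:
    out = []
    for node in network.nodes:
        lay = node.layer
        expected = _count_formula(lay)
        actual = lay.param_count()
        if expected != actual:  # descriptor invariant
            raise RuntimeError(f"parameter accounting mismatch at {node.name}")
        shape = {
            k: getattr(lay, k)
            for k in ("c_in", "c_out", "k", "stride", "c", "factor")
            if hasattr(lay, k)
        }
        out.append(LayerDescriptor(node.name, lay.kind, list(node.inputs), node.group, shape, actual))
    return out


# ------------------------------------------------------------- graph builders

def _conv_bn_relu(net, inp, c_in, c_out, prefix, rng, group, kernel=1, stride=1, act=True):
    x = net.add(f"{prefix}_conv", Conv2D(c_in, c_out, kernel, stride, rng=rng), [inp], group)
    x = net.add(f"{prefix}_bn", BatchNorm(c_out), [x], group)
    if act:
        x = net.add(f"{prefix}_relu", ReLU6(), [x], group)
    return x


def _inverted_residual(net, inp, c_in, c_out, stride, expansion, prefix, rng, group):
    c_mid = c_in * expansion
    x = inp
    if expansion != 1:
        x = _conv_bn_relu(net, x, c_in, c_mid, f"{prefix}_expand", rng, group)
    x = net.add(f"{prefix}_dw", DepthwiseConv2D(c_mid, 3, stride, rng=rng), [x], group)
    x = net.add(f"{prefix}_dw_bn", BatchNorm(c_mid), [x], group)
    x = net.add(f"{prefix}_dw_relu", ReLU6(), [x], group)
    x = net.add(f"{prefix}_proj", Conv2D(c_mid, c_out, 1, rng=rng), [x], group)
    x = net.add(f"{prefix}_proj_bn", BatchNorm(c_out), [x], group)
    if stride == 1 and c_in == c_out:
        x = net.add(f"{prefix}_add", Add(), [inp, x], group)
    return x


def add_backbone(net: Network, inp: str, rng, group="backbone") -> str:
    x = net.add("stem_conv", Conv2D(1, STEM_CHANNELS, 3, 2, rng=rng), [inp], group)
    x = net.add("stem_bn", BatchNorm(STEM_CHANNELS), [x], group)
    x = net.add("stem_relu", ReLU6(), [x], group)
    c_in = STEM_CHANNELS
    for si, (t, c, n, s) in enumerate(BACKBONE_PLAN):
        for bi in range(n):
            stride = s if bi == 0 else 1
            x = _inverted_residual(net, x, c_in, c, stride, t, f"bb{si}_{bi}", rng, group)
            c_in = c
    return x


def build_backbone(input_size: int = 192, rng=None) -> Network:
    """Stand-alone feature extractor; output head name is ``features``."""
    if input_size % 16 != 0:
        raise InvalidArgumentError("input size must be divisible by 16")
    rng = rng or np.random.default_rng(0)
    net = Network(outputs={})
    out = add_backbone(net, "input", rng)
    net.outputs["features"] = out
    return net


def add_qse_block(net, inp, c_in, c_out, prefix, rng, group, use_bias=False, norm=True):
    """Squeeze -> tile -> concat -> 1x1 conv: channel context without products."""
    sq = net.add(f"{prefix}_squeeze", GlobalAvgPool(), [inp], group)
    tile = net.add(f"{prefix}_tile", TileToSpatial(), [sq, inp], group)
    cat = net.add(f"{prefix}_concat", Concat(), [inp, tile], group)
    x = net.add(f"{prefix}_conv", Conv2D(2 * c_in, c_out, 1, use_bias=use_bias, rng=rng), [cat], group)
    if norm:
        x = net.add(f"{prefix}_bn", BatchNorm(c_out), [x], group)
    x = net.add(f"{prefix}_relu", ReLU6(), [x], group)
    return x


def add_dwc_block(net, inp, c_in, c_out, prefix, rng, group, norm=True, act=True):
    x = net.add(f"{prefix}_dw", DepthwiseConv2D(c_in, 3, rng=rng), [inp], group)
    if norm:
        x = net.add(f"{prefix}_dw_bn", BatchNorm(c_in), [x], group)
    if act:
        x = net.add(f"{prefix}_dw_relu", ReLU6(), [x], group)
    x = net.add(f"{prefix}_pw", Conv2D(c_in, c_out, 1, rng=rng), [x], group)
    if norm:
        x = net.add(f"{prefix}_pw_bn", BatchNorm(c_out), [x], group)
    if act:
        x = net.add(f"{prefix}_pw_relu", ReLU6(), [x], group)
    return x


class _MiniBlock:
    """A block wrapped in its own one-output graph, runnable on raw arrays."""

    def __init__(self, net: Network):
        self.network = net

    def __call__(self, feature: np.ndarray, training=False) -> np.ndarray:
        x = np.asarray(feature, np.float32)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        y = self.network.forward(x, training=training)["out"]
        return y[0] if squeeze else y

    def param_count(self) -> int:
        return self.network.param_count()


def qse_block(c_in: int, c_out: int, use_bias=False, norm=True, rng=None) -> _MiniBlock:
    rng = rng or np.random.default_rng(0)
    net = Network(outputs={})
    net.outputs["out"] = add_qse_block(net, "input", c_in, c_out, "qse", rng, "seg",
                                       use_bias=use_bias, norm=norm)
    return _MiniBlock(net)


def dwc_block(c_in: int, c_out: int, norm=True, act=True, rng=None) -> _MiniBlock:
    rng = rng or np.random.default_rng(0)
    net = Network(outputs={})
    net.outputs["out"] = add_dwc_block(net, "input", c_in, c_out, "dwc", rng, "seg",
                                       norm=norm, act=act)
    return _MiniBlock(net)


def se_block(c_in: int, rng=None) -> _MiniBlock:
    """Classic squeeze-and-excitation with elementwise gating.

    Not used by the shipped model (its activation product is hostile to
    8-bit fixed-point); kept as the reference the quantization audit must
    reject.
    """
    rng = rng or np.random.default_rng(0)
    net = Network(outputs={})
    sq = net.add("se_squeeze", GlobalAvgPool(), ["input"], "seg")
    fc = net.add("se_fc", Conv2D(c_in, c_in, 1, use_bias=True, rng=rng), [sq], "seg")
    gate = net.add("se_gate", ReLU6(), [fc], "seg")
    net.outputs["out"] = net.add("se_scale", Multiply(), ["input", gate], "seg")
    return _MiniBlock(net)


# ------------------------------------------------------------------ full model

class MultitaskModel:
    """The assembled two-headed network plus its accounting and audits."""

    def __init__(self, network: Network, config: ModelConfig):
        self.network = network
        self.config = config

    # -- running ---------------------------------------------------------
    def forward(self, images: np.ndarray, training=False) -> dict[str, np.ndarray]:
        """images: (N, S, S) or (N, S, S, 1) float in [0, 1]."""
        x = np.asarray(images, np.float32)
        if x.ndim == 3:
            x = x[..., None]
        return self.network.forward(x, training=training)

    def predict(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Single preprocessed image -> (seg probabilities, clf probabilities)."""
        out = self.forward(image[None])
        return out["seg"][0], out["clf"][0]

    # -- accounting ------------------------------------------------------
    def count_parameters(self) -> int:
        return self.network.param_count()

    def parameter_breakdown(self) -> dict[str, int]:
        groups: dict[str, int] = {}
        for node in self.network.nodes:
            groups[node.group] = groups.get(node.group, 0) + node.layer.param_count()
        return groups

    def shape_audit(self) -> dict[str, tuple]:
        x = np.zeros((1, self.config.input_size, self.config.input_size, 1), np.float32)
        self.network.forward(x)
        return {k: tuple(v.shape[1:]) for k, v in self.network.activations().items()}

    def is_quantization_friendly(self) -> bool:
        return not self.network.has_activation_multiply()

    def descriptors(self) -> list[LayerDescriptor]:
        return describe(self.network)

    def save_architecture(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([d.__dict__ for d in self.descriptors()], fh, indent=1)

    # -- persistence -----------------------------------------------------
    def save_weights(self, path) -> None:
        np.savez(path, __input_size__=self.config.input_size,
                 **self.network.state_dict())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            state = {k: v for k, v in data.items() if not k.startswith("__")}
        self.network.load_state_dict(state)


def build_model(config: ModelConfig | None = None) -> MultitaskModel:
    cfg = config or ModelConfig()
    if cfg.input_size % 16 != 0:
        raise InvalidArgumentError("input size must be divisible by 16")
    rng = np.random.default_rng(cfg.seed)
    net = Network(outputs={})
    bb = add_backbone(net, "input", rng)

    # segmentation path: QSE branch || separable 3x3 branch -> concat -> merge
    x, c = bb, ENCODER_CHANNELS
    for i in range(cfg.qse_blocks):
        x = add_qse_block(net, x, c, cfg.branch_channels, f"qse{i}", rng, "seg")
        c = cfg.branch_channels
    qse_out = x
    x, c = bb, ENCODER_CHANNELS
    for i in range(cfg.conv_branch_layers):
        x = add_dwc_block(net, x, c, cfg.branch_channels, f"convbr{i}", rng, "seg")
        c = cfg.branch_channels
    cat = net.add("seg_concat", Concat(), [qse_out, x], "seg")
    merged = add_dwc_block(net, cat, 2 * cfg.branch_channels, cfg.merge_channels,
                           "seg_merge", rng, "seg")
    logits = net.add(
        "seg_reduce",
        Conv2D(cfg.merge_channels, cfg.num_classes_seg, 1, use_bias=True, rng=rng),
        [merged], "seg",
    )
    up = net.add("seg_upsample", BilinearUpsample(16), [logits], "seg")
    net.outputs["seg"] = net.add("seg_softmax", Softmax(), [up], "seg")

    # classification path
    gp = net.add("clf_pool", GlobalAvgPool(), [bb], "clf")
    fl = net.add("clf_flatten", Flatten(), [gp], "clf")
    de = net.add("clf_dense", Dense(ENCODER_CHANNELS, cfg.num_classes_clf, rng=rng), [fl], "clf")
    net.outputs["clf"] = net.add("clf_softmax", Softmax(), [de], "clf")

    model = MultitaskModel(net, cfg)
    total = model.count_parameters()
    if total >= cfg.budget:
        raise BudgetViolationError(
            f"{total} trainable parameters exceed the {cfg.budget} budget: "
            f"{model.parameter_breakdown()}"
        )
    return model


def load_model(path) -> MultitaskModel:
    """Load a float checkpoint written by :meth:`MultitaskModel.save_weights`."""
    with np.load(path) as data:
        size = int(data["__input_size__"])
        state = {k: v for k, v in data.items() if not k.startswith("__")}
    model = build_model(ModelConfig(input_size=size))
    model.network.load_state_dict(state)
    return model


def resize_model(model: MultitaskModel, input_size: int) -> MultitaskModel:
    """Rebuild the graph for a different input size, carrying the weights.

    Every layer is convolutional or global-pooled, so the same weights run
    at any /16 input size; training at a reduced size and deploying at the
    full 192 grid (where the segmentation logit grid is finest) is the
    intended use.
    """
    import dataclasses as _dc

    new = build_model(_dc.replace(model.config, input_size=input_size))
    new.network.load_state_dict(model.network.state_dict())
    return new


def count_parameters(model: MultitaskModel | _MiniBlock | Network) -> int:
    if isinstance(model, Network):
        return model.param_count()
    return model.count_parameters() if isinstance(model, MultitaskModel) else model.param_count()


# ------------------------------------------------------------ pre/postprocess

def preprocess(image: np.ndarray, target: int = 192) -> np.ndarray:
    """Native-grid uint8/float image -> (target, target) float32 in [0, 1]."""
    img = np.asarray(image)
    if img.size == 0:
        raise InvalidArgumentError("empty image")
    out = resize(img.astype(np.float32) / 255.0, (target, target), order=1,
                 mode="edge", anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def postprocess(seg: np.ndarray, native_shape: tuple[int, int]) -> np.ndarray:
    """(S, S, 2) class probabilities -> native-grid boolean bladder mask."""
    labels = np.argmax(seg, axis=-1).astype(np.uint8)
    back = resize(labels, native_shape, order=0, mode="edge",
                  anti_aliasing=False, preserve_range=True)
    return back.astype(bool)
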