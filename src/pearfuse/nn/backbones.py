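"""Scale-reducible convolutional backbones with named tap points.

Six classic families are re-implemented from their published block
patterns: VGG16/19 (plain conv blocks), ResNet50/101 (bottleneck residual
stages), Xception (depthwise-separable conv flows with residual
shortcuts) and DenseNet201 (densely connected blocks with transitions).
Each backbone exposes an ordered set of *tap points* — named intermediate
positions whose activations can be extracted as image features — plus a
small classification head (global average pool, dense layer, two-class
softmax).

Two knobs make desk-scale training feasible without changing the shape
pattern: ``width_scale`` multiplies every channel count, and
``block_repeats`` / ``middle_flow_repeats`` reduce stage depth.  At
``width_scale=1.0`` and 224 px input the ResNet stages reproduce the
canonical spatial ladder 112/56/28/14/7 and the Xception exit flow pools
to a 2048-long vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    AvgPool2d, BatchNorm2d, Conv2d, Dense, DepthwiseConv2d, GlobalAvgPool,
    MaxPool2d, Module, ReLU, Sequential, softmax,
)

__all__ = ["BackboneSpec", "Backbone", "build_backbone", "FAMILIES",
           "TAP_POINTS", "desk_spec", "paper_spec"]

FAMILIES = ("vgg16", "vgg19", "resnet50", "resnet101", "xception", "densenet201")

TAP_POINTS = {
    "vgg16": ("block1", "block2", "block3", "block4", "block5"),
    "vgg19": ("block1", "block2", "block3", "block4", "block5"),
    "resnet50": ("layer1", "layer2", "layer3", "layer4", "layer5"),
    "resnet101": ("layer1", "layer2", "layer3", "layer4", "layer5"),
    "xception": ("entry_flow", "middle_flow", "exit_flow"),
    "densenet201": ("block1", "block2", "block3", "block4"),
}

_DEFAULT_REPEATS = {
    "vgg16": (2, 2, 3, 3, 3),
    "vgg19": (2, 2, 4, 4, 4),
    "resnet50": (3, 4, 6, 3),
    "resnet101": (3, 4, 23, 3),
    "densenet201": (6, 12, 48, 32),
    "xception": (),  # depth controlled by middle_flow_repeats
}

_DESK_REPEATS = {
    "vgg16": (1, 1, 2, 2, 2),
    "vgg19": (1, 1, 2, 2, 2),
    "resnet50": (2, 2, 2, 2),
    "resnet101": (2, 2, 2, 2),
    "densenet201": (2, 2, 4, 2),
    "xception": (),
}


@dataclass(frozen=True)
class BackboneSpec:
    """Declarative description of a backbone family, scale and tap points."""

    family: str
    width_scale: float = 1.0
    input_size_px: int = 224
    middle_flow_repeats: int = 8
    block_repeats: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown backbone family {self.family!r}; "
                             f"choose from {FAMILIES}")
        if not 0.0 < self.width_scale <= 1.0:
            raise ValueError("width_scale must be in (0, 1]")
        if self.input_size_px < 32:
            raise ValueError("input_size_px must be >= 32")
        if self.middle_flow_repeats < 1:
            raise ValueError("middle_flow_repeats must be >= 1")

    @property
    def tap_points(self) -> tuple:
        return TAP_POINTS[self.family]

    @property
    def repeats(self) -> tuple:
        return self.block_repeats or _DEFAULT_REPEATS[self.family]

    def ch(self, c: int) -> int:
        return max(1, int(round(c * self.width_scale)))


def desk_spec(family: str, seed: int = 0, input_size_px: int = 64) -> BackboneSpec:
    """Reduced-scale preset that preserves each family's shape pattern."""
    return BackboneSpec(
        family=family, width_scale=0.25, input_size_px=input_size_px,
        middle_flow_repeats=2, block_repeats=_DESK_REPEATS[family], seed=seed,
    )


def paper_spec(family: str, seed: int = 0) -> BackboneSpec:
    """Full-width, full-depth configuration (224 px input)."""
    return BackboneSpec(family=family, seed=seed)


class Residual(Module):
    """main(x) + shortcut(x), optional post-addition ReLU."""

    def __init__(self, main: Module, shortcut: Module | None = None,
                 relu_after: bool = True):
        super().__init__()
        self.main, self.shortcut = main, shortcut
        self.relu = ReLU() if relu_after else None

    def children(self):
        out = [self.main]
        if self.shortcut is not None:
            out.append(self.shortcut)
        if self.relu is not None:
            out.append(self.relu)
        return out

    def forward(self, x):
        y = self.main.forward(x)
        y = y + (self.shortcut.forward(x) if self.shortcut is not None else x)
        return self.relu.forward(y) if self.relu is not None else y

    def backward(self, grad):
        if self.relu is not None:
            grad = self.relu.backward(grad)
        gm = self.main.backward(grad)
        gs = self.shortcut.backward(grad) if self.shortcut is not None else grad
        return gm + gs


def _bottleneck(c_in, c_mid, c_out, stride, rng):
    main = Sequential(
        Conv2d(c_in, c_mid, 1, bias=False, rng=rng), BatchNorm2d(c_mid), ReLU(),
        Conv2d(c_mid, c_mid, 3, stride=stride, bias=False, rng=rng),
        BatchNorm2d(c_mid), ReLU(),
        Conv2d(c_mid, c_out, 1, bias=False, rng=rng), BatchNorm2d(c_out),
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = Sequential(
            Conv2d(c_in, c_out, 1, stride=stride, bias=False, rng=rng),
            BatchNorm2d(c_out),
        )
    return Residual(main, shortcut, relu_after=True)


def _sepconv(c_in, c_out, rng, stride=1):
    return Sequential(
        DepthwiseConv2d(c_in, 3, stride=stride, rng=rng),
        Conv2d(c_in, c_out, 1, bias=False, rng=rng),
        BatchNorm2d(c_out),
    )


def _xception_block(c_in, c_out, reps, stride, rng, start_with_relu=True):
    layers = []
    c = c_in
    for i in range(reps):
        if i > 0 or start_with_relu:
            layers.append(ReLU())
        layers.append(_sepconv(c, c_out, rng))
        c = c_out
    if stride != 1:
        layers.append(MaxPool2d(3, stride=stride, pad=1))
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = Sequential(
            Conv2d(c_in, c_out, 1, stride=stride, bias=False, rng=rng),
            BatchNorm2d(c_out),
        )
    return Residual(Sequential(*layers), shortcut, relu_after=False)


class DenseLayer(Module):
    """BN-ReLU-Conv1x1(4g)-BN-ReLU-Conv3x3(g), producing g new channels."""

    def __init__(self, c_in, growth, rng):
        super().__init__()
        self.seq = Sequential(
            BatchNorm2d(c_in), ReLU(),
            Conv2d(c_in, 4 * growth, 1, bias=False, rng=rng),
            BatchNorm2d(4 * growth), ReLU(),
            Conv2d(4 * growth, growth, 3, bias=False, rng=rng),
        )

    def children(self):
        return [self.seq]

    def forward(self, x):
        return self.seq.forward(x)

    def backward(self, grad):
        return self.seq.backward(grad)


class DenseBlock(Module):
    """Densely connected block: each layer sees all previous feature maps."""

    def __init__(self, c_in, growth, reps, rng):
        super().__init__()
        self.c_in, self.growth = c_in, growth
        self.layers = [DenseLayer(c_in + i * growth, growth, rng)
                       for i in range(reps)]
        self.c_out = c_in + reps * growth

    def children(self):
        return self.layers

    def forward(self, x):
        feats = x
        for layer in self.layers:
            y = layer.forward(feats)
            feats = np.concatenate([feats, y], axis=1)
        return feats

    def backward(self, grad):
        g = grad
        for i in reversed(range(len(self.layers))):
            n_in = self.c_in + i * self.growth
            g = g[:, :n_in] + self.layers[i].backward(g[:, n_in:])
        return g


class Backbone(Module):
    """An ordered stack of stages with tap recording plus a 2-class head."""

    def __init__(self, spec: BackboneSpec, stages, head_channels: int, rng):
        super().__init__()
        self.spec = spec
        self.stages = stages  # list of (tap_name | None, Module)
        self.head_channels = head_channels
        self.gap = GlobalAvgPool()
        self.fc = Dense(head_channels, 2, rng=rng)

    def children(self):
        return [m for _, m in self.stages] + [self.gap, self.fc]

    def forward(self, x, record: dict | None = None):
        for tap, module in self.stages:
            x = module.forward(x)
            if record is not None and tap is not None:
                record[tap] = x
        pooled = self.gap.forward(x)
        if record is not None:
            record["_pooled"] = pooled
        return self.fc.forward(pooled)

    def backward(self, dlogits):
        g = self.fc.backward(dlogits)
        g = self.gap.backward(g)
        for _, module in reversed(self.stages):
            g = module.backward(g)
        return g

    def forward_features(self, x, taps=None):
        """Evaluation-mode activations at the requested taps.

        Returns ``(record, logits)`` where ``record`` maps each tap name
        to its NCHW activation and ``"_pooled"`` to the (N, C) vector the
        head consumes.
        """
        taps = tuple(taps) if taps is not None else self.spec.tap_points
        unknown = set(taps) - set(self.spec.tap_points)
        if unknown:
            raise ValueError(f"unknown tap(s) {sorted(unknown)} for family "
                             f"{self.spec.family!r}; valid: {self.spec.tap_points}")
        was_training = self.training
        self.set_training(False)
        record: dict = {}
        logits = self.forward(x, record=record)
        self.set_training(was_training)
        keep = {t: record[t] for t in taps}
        keep["_pooled"] = record["_pooled"]
        return keep, logits

    def predict_proba(self, x) -> np.ndarray:
        was_training = self.training
        self.set_training(False)
        logits = self.forward(x)
        self.set_training(was_training)
        return softmax(logits)


def _build_vgg(spec: BackboneSpec, rng) -> Backbone:
    channels = [64, 128, 256, 512, 512]
    stages = []
    c_prev = 3
    for i, (c, reps) in enumerate(zip(channels, spec.repeats)):
        c = spec.ch(c)
        layers = []
        for _ in range(reps):
            layers += [Conv2d(c_prev, c, 3, rng=rng), ReLU()]
            c_prev = c
        layers.append(MaxPool2d(2))
        stages.append((f"block{i + 1}", Sequential(*layers)))
    return Backbone(spec, stages, c_prev, rng)


def _build_resnet(spec: BackboneSpec, rng) -> Backbone:
    stages = [("layer1", Sequential(
        Conv2d(3, spec.ch(64), 7, stride=2, pad=3, bias=False, rng=rng),
        BatchNorm2d(spec.ch(64)), ReLU(),
    ))]
    c_prev = spec.ch(64)
    mids = [64, 128, 256, 512]
    for i, (mid, reps) in enumerate(zip(mids, spec.repeats)):
        c_mid, c_out = spec.ch(mid), spec.ch(mid * 4)
        blocks = []
        if i == 0:
            blocks.append(MaxPool2d(3, stride=2, pad=1))
        stride = 1 if i == 0 else 2
        for j in range(reps):
            blocks.append(_bottleneck(c_prev, c_mid, c_out,
                                      stride if j == 0 else 1, rng))
            c_prev = c_out
        stages.append((f"layer{i + 2}", Sequential(*blocks)))
    return Backbone(spec, stages, c_prev, rng)


def _build_xception(spec: BackboneSpec, rng) -> Backbone:
    ch = spec.ch
    entry = Sequential(
        Conv2d(3, ch(32), 3, stride=2, bias=False, rng=rng),
        BatchNorm2d(ch(32)), ReLU(),
        Conv2d(ch(32), ch(64), 3, bias=False, rng=rng),
        BatchNorm2d(ch(64)), ReLU(),
        _xception_block(ch(64), ch(128), 2, 2, rng, start_with_relu=False),
        _xception_block(ch(128), ch(256), 2, 2, rng),
        _xception_block(ch(256), ch(728), 2, 2, rng),
    )
    middle = Sequential(*[
        _xception_block(ch(728), ch(728), 3, 1, rng)
        for _ in range(spec.middle_flow_repeats)
    ])
    exit_flow = Sequential(
        _xception_block(ch(728), ch(1024), 2, 2, rng),
        _sepconv(ch(1024), ch(1536), rng), ReLU(),
        _sepconv(ch(1536), ch(2048), rng), ReLU(),
    )
    stages = [("entry_flow", entry), ("middle_flow", middle),
              ("exit_flow", exit_flow)]
    return Backbone(spec, stages, ch(2048), rng)


def _build_densenet(spec: BackboneSpec, rng) -> Backbone:
    growth = spec.ch(32)
    c = spec.ch(64)
    stem = Sequential(
        Conv2d(3, c, 7, stride=2, pad=3, bias=False, rng=rng),
        BatchNorm2d(c), ReLU(), MaxPool2d(3, stride=2, pad=1),
    )
    stages = [(None, stem)]
    reps = spec.repeats
    for i, r in enumerate(reps):
        block = DenseBlock(c, growth, r, rng)
        c = block.c_out
        # tap sits on the dense block output, before downsampling
        stages.append((f"block{i + 1}", block))
        if i < len(reps) - 1:
            trans_out = max(1, c // 2)
            stages.append((None, Sequential(
                BatchNorm2d(c), ReLU(),
                Conv2d(c, trans_out, 1, bias=False, rng=rng), AvgPool2d(2),
            )))
            c = trans_out
        else:
            stages.append((None, Sequential(BatchNorm2d(c), ReLU())))
    return Backbone(spec, stages, c, rng)


def build_backbone(spec: BackboneSpec) -> Backbone:
    """Construct a seeded backbone with its classification head."""
    rng = np.random.default_rng(spec.seed)
    if spec.family in ("vgg16", "vgg19"):
        model = _build_vgg(spec, rng)
    elif spec.family in ("resnet50", "resnet101"):
        model = _build_resnet(spec, rng)
    elif spec.family == "xception":
        model = _build_xception(spec, rng)
    else:
        model = _build_densenet(spec, rng)
    return model
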