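"""Image branch: backbone training, tap feature extraction, flattening.

The image side of the fusion pipeline trains a convolutional backbone
from scratch as a two-class fruit classifier, then reads activations off
any named tap point as image features.  A Height x Width x Channel tap
activation is flattened height-major into a 1-D vector of length
H*W*C before fusion with the spectral features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .nn.backbones import (
    FAMILIES, TAP_POINTS, Backbone, BackboneSpec, build_backbone, desk_spec,
    paper_spec,
)
from .nn.layers import Adam, softmax_cross_entropy

__all__ = [
    "FAMILIES", "TAP_POINTS", "BackboneSpec", "Backbone", "build_backbone",
    "desk_spec", "paper_spec", "FeatureMap", "ImageTrainConfig",
    "prepare_images", "train_image_classifier", "predict_labels",
    "extract_features_at_tap", "flatten", "feature_matrix",
]


@dataclass
class FeatureMap:
    """One tap activation in Height x Width x Channel layout."""

    values: np.ndarray
    tap_name: str

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(
                f"feature map must be 3-D (H, W, C) with positive dims, "
                f"got shape {self.values.shape}"
            )

    @property
    def shape(self):
        return self.values.shape


def flatten(fmap: FeatureMap | np.ndarray) -> np.ndarray:
    """Flatten (H, W, C) -> 1-D of length H*W*C, height-major.

    The element at (h, w, c) lands at index ``(h * W + w) * C + c``.  The
    order is a fixed convention: the fused head is order-agnostic, but a
    fixed order keeps features reproducible across runs.
    """
    values = fmap.values if isinstance(fmap, FeatureMap) else np.asarray(fmap)
    if values.ndim != 3:
        raise ValueError(f"expected (H, W, C), got shape {values.shape}")
    return np.ascontiguousarray(values).reshape(-1)


@dataclass(frozen=True)
class ImageTrainConfig:
    epochs: int = 20
    batch_size: int = 16
    lr: float = 1e-3
    seed: int = 0


def prepare_images(images: np.ndarray, input_size_px: int) -> np.ndarray:
    """uint8 (N, H, W, 3) -> float32 NCHW in [-0.5, 0.5], resized bilinearly."""
    out = np.empty((len(images), 3, input_size_px, input_size_px), dtype=np.float32)
    for i, img in enumerate(images):
        if img.shape[0] != input_size_px or img.shape[1] != input_size_px:
            img = np.asarray(
                Image.fromarray(img).resize(
                    (input_size_px, input_size_px), Image.BILINEAR
                )
            )
        out[i] = (img.astype(np.float32) / 255.0 - 0.5).transpose(2, 0, 1)
    return out


def train_image_classifier(
    backbone: Backbone, images: np.ndarray, y: np.ndarray,
    config: ImageTrainConfig = ImageTrainConfig(),
):
    """Train a backbone from scratch on uint8 images with integer labels.

    Seeded epoch shuffling plus deterministic NumPy kernels make the run
    reproducible bit-for-bit for a fixed (backbone seed, config, data)
    triple.  Returns the per-epoch loss history; the backbone is left in
    evaluation mode, ready for feature extraction.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    x = prepare_images(images, backbone.spec.input_size_px)
    rng = np.random.default_rng(config.seed)
    opt = Adam(backbone.params(), lr=config.lr)
    backbone.set_training(True)
    history = []
    n = len(x)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = backbone.forward(x[idx])
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            backbone.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    backbone.set_training(False)
    return history


def predict_labels(backbone: Backbone, images: np.ndarray,
                   batch_size: int = 32) -> np.ndarray:
    """Argmax class indices for uint8 images."""
    x = prepare_images(images, backbone.spec.input_size_px)
    preds = []
    for start in range(0, len(x), batch_size):
        preds.append(backbone.predict_proba(x[start:start + batch_size]).argmax(axis=1))
    return np.concatenate(preds)


def extract_features_at_tap(
    backbone: Backbone, images: np.ndarray, tap_name: str,
    batch_size: int = 32,
) -> list[FeatureMap]:
    """Evaluation-mode activations at ``tap_name``, one FeatureMap per image."""
    if tap_name not in backbone.spec.tap_points:
        raise ValueError(
            f"unknown tap {tap_name!r} for family {backbone.spec.family!r}; "
            f"valid: {backbone.spec.tap_points}"
        )
    x = prepare_images(images, backbone.spec.input_size_px)
    maps: list[FeatureMap] = []
    for start in range(0, len(x), batch_size):
        record, _ = backbone.forward_features(x[start:start + batch_size],
                                              taps=(tap_name,))
        for act in record[tap_name]:  # (C, H, W) per sample
            maps.append(FeatureMap(values=act.transpose(1, 2, 0), tap_name=tap_name))
    return maps


def feature_matrix(maps: list[FeatureMap]) -> np.ndarray:
    """Stack flattened feature maps into an (N, H*W*C) design matrix."""
    return np.stack([flatten(m) for m in maps])
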