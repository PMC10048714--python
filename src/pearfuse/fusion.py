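"""Feature-level fusion: concatenate branch features, train the head.

Fusion is an exact append: the flattened image feature vector F_a comes
first, the spectral hidden-layer vector F_b is stitched after it, with
no scaling or re-weighting (an optional standardisation flag exists
because scale mismatch between branches is a known hazard, but it is off
by default to match the reference procedure).  Both branch models stay
frozen; only the prediction head — a single dense layer to two class
scores with an argmax decision — is trained on the fused vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import compute_metrics, confusion_from_predictions
from .nn.layers import Adam, Dense, softmax, softmax_cross_entropy

__all__ = [
    "FusedFeatureVector", "HeadConfig", "FusionHead", "fuse_features",
    "fuse_matrices", "train_fusion_head", "evaluate_head",
    "run_fusion_grid", "run_layer_ablation",
]


@dataclass
class FusedFeatureVector:
    """Concatenated feature vector with its branch segment lengths."""

    values: np.ndarray
    image_len: int
    spectral_len: int

    def __post_init__(self) -> None:
        if len(self.values) != self.image_len + self.spectral_len:
            raise ValueError(
                f"fused length {len(self.values)} != image_len "
                f"{self.image_len} + spectral_len {self.spectral_len}"
            )

    @property
    def image_part(self) -> np.ndarray:
        return self.values[: self.image_len]

    @property
    def spectral_part(self) -> np.ndarray:
        return self.values[self.image_len:]


def fuse_features(Fa: np.ndarray, Fb: np.ndarray) -> FusedFeatureVector:
    """Append the spectral vector F_b after the image vector F_a."""
    Fa = np.asarray(Fa).reshape(-1)
    Fb = np.asarray(Fb).reshape(-1)
    if Fa.size == 0 and Fb.size == 0:
        raise ValueError("cannot fuse two empty feature vectors")
    if not (np.all(np.isfinite(Fa)) and np.all(np.isfinite(Fb))):
        raise ValueError("feature vectors must be finite")
    return FusedFeatureVector(
        values=np.concatenate([Fa, Fb]),
        image_len=Fa.size, spectral_len=Fb.size,
    )


def fuse_matrices(Fa: np.ndarray, Fb: np.ndarray) -> np.ndarray:
    """Row-wise fusion of two aligned (N, d) feature matrices."""
    Fa, Fb = np.asarray(Fa), np.asarray(Fb)
    if Fa.shape[0] != Fb.shape[0]:
        raise ValueError(
            f"unpaired samples: {Fa.shape[0]} image rows vs {Fb.shape[0]} spectral rows"
        )
    return np.concatenate([Fa, Fb], axis=1)


@dataclass(frozen=True)
class HeadConfig:
    """Training settings for the dense prediction head."""

    epochs: int = 150
    batch_size: int = 32
    lr: float = 1e-3
    weight_decay: float = 1e-4
    standardize: bool = False
    seed: int = 0


class FusionHead:
    """Single dense layer to two class scores over frozen fused features."""

    def __init__(self, n_features: int, config: HeadConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.dense = Dense(n_features, 2, rng=rng)
        self._mu = np.zeros(n_features, dtype=np.float32)
        self._sd = np.ones(n_features, dtype=np.float32)

    def _transform(self, F: np.ndarray) -> np.ndarray:
        F = np.asarray(F, dtype=np.float32)
        return (F - self._mu) / self._sd if self.config.standardize else F

    def fit(self, F: np.ndarray, y: np.ndarray) -> "FusionHead":
        F = np.asarray(F, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        if self.config.standardize:
            self._mu = F.mean(axis=0)
            self._sd = F.std(axis=0) + 1e-8
        F = self._transform(F)
        rng = np.random.default_rng(self.config.seed + 1)
        opt = Adam([*self.dense.params()], lr=self.config.lr,
                   weight_decay=self.config.weight_decay)
        n = len(F)
        self.dense.set_training(True)
        for _ in range(self.config.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.config.batch_size):
                idx = order[start:start + self.config.batch_size]
                logits = self.dense.forward(F[idx])
                _, dlogits = softmax_cross_entropy(logits, y[idx])
                opt.zero_grad()
                self.dense.backward(dlogits)
                opt.step()
        self.dense.set_training(False)
        return self

    def predict_proba(self, F: np.ndarray) -> np.ndarray:
        return softmax(self.dense.forward(self._transform(F)))

    def predict(self, F: np.ndarray) -> np.ndarray:
        return self.predict_proba(F).argmax(axis=1)


def train_fusion_head(
    Fa_train: np.ndarray, Fb_train: np.ndarray, y_train: np.ndarray,
    config: HeadConfig = HeadConfig(),
) -> FusionHead:
    """Fuse the training feature matrices and fit the prediction head.

    Branch models are not touched: the head sees cached, frozen features
    (deterministic branches make re-extraction and caching equivalent).
    """
    F = fuse_matrices(Fa_train, Fb_train)
    return FusionHead(F.shape[1], config).fit(F, y_train)


def evaluate_head(head: FusionHead, Fa, Fb, y) -> dict:
    """Score a fitted head on fused validation features (macro metrics)."""
    F = fuse_matrices(Fa, Fb)
    pred = head.predict(F)
    rep = compute_metrics(confusion_from_predictions(np.asarray(y, int), pred, 1))
    c = rep.confusion
    return {**rep.rounded(3), "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}


def run_fusion_grid(
    spectral_features: dict, image_features: dict, y_train, y_val,
    head_config: HeadConfig = HeadConfig(),
) -> pd.DataFrame:
    """One fused model per (spectral variant, backbone) pair.

    ``spectral_features`` maps ``n_hidden -> (Fb_train, Fb_val)``;
    ``image_features`` maps ``backbone name -> (Fa_train, Fa_val)``.  The
    best pair (highest validation accuracy, ties to the smaller hidden
    width) is flagged.
    """
    if not spectral_features or not image_features:
        raise ValueError("both grids must be non-empty")
    rows = []
    for n_hidden in sorted(spectral_features):
        Fb_tr, Fb_va = spectral_features[n_hidden]
        for backbone in image_features:
            Fa_tr, Fa_va = image_features[backbone]
            head = train_fusion_head(Fa_tr, Fb_tr, y_train, head_config)
            row = evaluate_head(head, Fa_va, Fb_va, y_val)
            rows.append({
                "model": f"MLP_{n_hidden}_{backbone}",
                "n_hidden": n_hidden, "backbone": backbone, **row,
            })
    df = pd.DataFrame(rows)
    best = df.sort_values(["accuracy", "n_hidden"],
                          ascending=[False, True]).index[0]
    df["best"] = False
    df.loc[best, "best"] = True
    return df


def run_layer_ablation(
    tap_features: dict, Fb_train, Fb_val, y_train, y_val,
    model_prefix: str = "fused",
    head_config: HeadConfig = HeadConfig(),
) -> pd.DataFrame:
    """One fused model per tap, branches held fixed (only the tap varies).

    ``tap_features`` maps ``tap name -> (Fa_train, Fa_val)`` extracted
    from one trained backbone.
    """
    if not tap_features:
        raise ValueError("tap list must be non-empty")
    rows = []
    for tap, (Fa_tr, Fa_va) in tap_features.items():
        head = train_fusion_head(Fa_tr, Fb_train, y_train, head_config)
        row = evaluate_head(head, Fa_va, Fb_val, y_val)
        rows.append({"model": f"{model_prefix}_{tap}", "tap": tap, **row})
    return pd.DataFrame(rows)
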