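"""End-to-end experiment harness.

Reproduces the study's experiment sequence on synthetic data: generate
the paired dataset, make one stratified 7:3 split shared by every model,
sweep the spectral hidden width, train the convolutional backbones,
fuse each backbone's deepest features with the chosen spectral variant,
ablate the tap depth for one backbone, and reconstruct the published
worked examples.  Every stage derives its own seed from one master seed
by a counter scheme, so stages can be rerun independently and the whole
run is deterministic.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acquisition import split_indices
from .fusion import HeadConfig, evaluate_head, run_fusion_grid, run_layer_ablation, train_fusion_head
from .image_branch import (
    BackboneSpec, ImageTrainConfig, build_backbone, desk_spec,
    extract_features_at_tap, feature_matrix, predict_labels,
)
from .metrics import compute_metrics, confusion_from_predictions, reconstruct_worked_examples
from .report import render_report
from .spectral_branch import (
    BASELINE_PRESETS, MLPConfig, extract_spectral_features, run_node_sweep,
    train_baseline, train_spectral_mlp,
)
from .synthetic_data import PairedDataset, SyntheticConfig, generate_paired_dataset

__all__ = [
    "ExperimentConfig", "derive_seed", "run_branches_and_fusion", "run_all",
    "accuracy_of",
]

log = logging.getLogger("pearfuse")

# stage name -> fixed counter used in seed fan-out
_STAGE_COUNTERS = {
    "simulate": 0, "split": 1, "spectral": 2, "baselines": 3,
    "image": 4, "fusion": 5, "ablation": 6,
}


def derive_seed(master_seed: int, stage: str, k: int = 0) -> int:
    """Counter-based fan-out of the master seed, stable across runs."""
    counter = _STAGE_COUNTERS.get(stage, hash(stage) % 97)
    ss = np.random.SeedSequence(master_seed, spawn_key=(counter, k))
    return int(ss.generate_state(1)[0] % (2**31))


def accuracy_of(y_true, y_pred) -> float:
    return float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))


@dataclass(frozen=True)
class ExperimentConfig:
    """Desk-scale defaults for a full synthetic run."""

    synthetic: SyntheticConfig = field(
        default_factory=lambda: SyntheticConfig(n_per_class=100))
    train_fraction: float = 0.7
    mlp: MLPConfig = field(default_factory=MLPConfig)
    fusion_n_hidden: int = 30
    families: tuple = ("vgg16", "vgg19", "resnet50", "resnet101",
                       "xception", "densenet201")
    ablation_family: str = "resnet101"
    image_input_px: int = 64
    image_train: ImageTrainConfig = field(default_factory=ImageTrainConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    sweep_grid: tuple = tuple(range(10, 101, 10))
    master_seed: int = 0


def run_branches_and_fusion(
    dataset: PairedDataset, train_idx, val_idx, *,
    n_hidden: int = 30, family: str = "resnet101", taps=None,
    mlp_config: MLPConfig | None = None,
    image_config: ImageTrainConfig | None = None,
    head_config: HeadConfig | None = None,
    input_px: int = 64, seed: int = 0,
) -> dict:
    """Train both branches once, fuse at the requested taps, score all.

    Returns branch validation accuracies, per-tap fused accuracies and
    the extracted feature matrices — the workhorse behind the fusion
    grid, the depth ablation and the null/dominance property checks.
    """
    tr, va = dataset.subset(train_idx), dataset.subset(val_idx)
    mlp_config = replace(mlp_config or MLPConfig(), n_hidden=n_hidden,
                         seed=derive_seed(seed, "spectral"))
    image_config = image_config or ImageTrainConfig(
        seed=derive_seed(seed, "image"))
    head_config = head_config or HeadConfig(seed=derive_seed(seed, "fusion"))

    mlp = train_spectral_mlp((tr.spectra, tr.y), mlp_config)
    spectral_acc = accuracy_of(va.y, mlp.predict(va.spectra))
    Fb_tr = extract_spectral_features(mlp, tr.spectra)
    Fb_va = extract_spectral_features(mlp, va.spectra)

    spec = desk_spec(family, seed=derive_seed(seed, "image", 1),
                     input_size_px=input_px)
    backbone = build_backbone(spec)
    train_image_history = _train_backbone(backbone, tr, image_config)
    image_acc = accuracy_of(va.y, predict_labels(backbone, va.images))

    taps = tuple(taps) if taps is not None else (spec.tap_points[-1],)
    fused = {}
    for tap in taps:
        Fa_tr = feature_matrix(extract_features_at_tap(backbone, tr.images, tap))
        Fa_va = feature_matrix(extract_features_at_tap(backbone, va.images, tap))
        head = train_fusion_head(Fa_tr, Fb_tr, tr.y, head_config)
        fused[tap] = evaluate_head(head, Fa_va, Fb_va, va.y)
    return {
        "spectral_acc": spectral_acc,
        "image_acc": image_acc,
        "fused": fused,
        "fused_acc": max(r["accuracy"] for r in fused.values()),
        "mlp": mlp, "backbone": backbone,
        "Fb": (Fb_tr, Fb_va),
        "history": train_image_history,
    }


def _train_backbone(backbone, train_ds, image_config):
    from .image_branch import train_image_classifier

    return train_image_classifier(backbone, train_ds.images, train_ds.y,
                                  image_config)


def _timed(name, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception:
        log.exception("stage %s failed", name)
        raise RuntimeError(f"pipeline stage {name!r} failed") from None
    log.info("stage %-12s %.1fs", name, time.perf_counter() - t0)
    return out


def run_all(config: ExperimentConfig, out_dir=None, stages=None) -> dict:
    """Execute the full experiment sequence; optionally render reports.

    ``stages`` may restrict execution (e.g. ``{"reconstruct"}``); the
    reconstruction stage needs no data and always works standalone.
    """
    stages = set(stages) if stages else {
        "simulate", "spectral", "baselines", "image", "fusion",
        "ablation", "reconstruct",
    }
    results: dict = {}
    tables: dict[str, pd.DataFrame] = {}

    if "reconstruct" in stages:
        tables["worked_examples"] = _timed(
            "reconstruct", reconstruct_worked_examples)
        results["worked_examples"] = tables["worked_examples"]
    need_data = stages - {"reconstruct"}

    if need_data:
        synth = replace(config.synthetic,
                        seed=derive_seed(config.master_seed, "simulate"))
        ds = _timed("simulate", generate_paired_dataset, synth)
        train_idx, val_idx = _timed(
            "split", split_indices, ds.labels, config.train_fraction,
            derive_seed(config.master_seed, "split"))
        tr, va = ds.subset(train_idx), ds.subset(val_idx)
        results["split"] = {"n_train": len(train_idx), "n_val": len(val_idx)}

        if "spectral" in stages:
            tables["spectral_sweep"] = _timed(
                "spectral", run_node_sweep, (tr.spectra, tr.y),
                (va.spectra, va.y), config.sweep_grid,
                replace(config.mlp, seed=derive_seed(config.master_seed, "spectral")))

        if "baselines" in stages:
            rows = []
            for name in BASELINE_PRESETS:
                model = train_baseline((tr.spectra, tr.y), name,
                                       seed=derive_seed(config.master_seed, "baselines"))
                pred = model.predict(va.spectra)
                rep = compute_metrics(confusion_from_predictions(va.y, pred, 1))
                rows.append({"model": name, **rep.rounded(3)})
            tables["spectral_baselines"] = _timed(
                "baselines", lambda r: pd.DataFrame(r), rows)

        if {"image", "fusion", "ablation"} & stages:
            mlp_cfg = replace(config.mlp, n_hidden=config.fusion_n_hidden,
                              seed=derive_seed(config.master_seed, "spectral", 1))
            mlp = train_spectral_mlp((tr.spectra, tr.y), mlp_cfg)
            Fb_tr = extract_spectral_features(mlp, tr.spectra)
            Fb_va = extract_spectral_features(mlp, va.spectra)

            image_rows, image_features, backbones = [], {}, {}
            for i, family in enumerate(config.families):
                spec = desk_spec(family,
                                 seed=derive_seed(config.master_seed, "image", i),
                                 input_size_px=config.image_input_px)
                backbone = build_backbone(spec)
                _timed(f"image:{family}", _train_backbone, backbone, tr,
                       replace(config.image_train,
                               seed=derive_seed(config.master_seed, "image", 100 + i)))
                pred = predict_labels(backbone, va.images)
                rep = compute_metrics(confusion_from_predictions(va.y, pred, 1))
                image_rows.append({"model": family, **rep.rounded(3)})
                backbones[family] = backbone
                last_tap = spec.tap_points[-1]
                image_features[family] = (
                    feature_matrix(extract_features_at_tap(backbone, tr.images, last_tap)),
                    feature_matrix(extract_features_at_tap(backbone, va.images, last_tap)),
                )
            tables["image_models"] = pd.DataFrame(image_rows)

            if "fusion" in stages:
                tables["fusion_models"] = _timed(
                    "fusion", run_fusion_grid,
                    {config.fusion_n_hidden: (Fb_tr, Fb_va)},
                    image_features, tr.y, va.y,
                    replace(config.head, seed=derive_seed(config.master_seed, "fusion")))

            if "ablation" in stages:
                backbone = backbones[config.ablation_family]
                tap_features = {
                    tap: (
                        feature_matrix(extract_features_at_tap(backbone, tr.images, tap)),
                        feature_matrix(extract_features_at_tap(backbone, va.images, tap)),
                    )
                    for tap in backbone.spec.tap_points
                }
                tables["layer_ablation"] = _timed(
                    "ablation", run_layer_ablation, tap_features,
                    Fb_tr, Fb_va, tr.y, va.y,
                    f"MLP_{config.fusion_n_hidden}_{config.ablation_family}",
                    replace(config.head, seed=derive_seed(config.master_seed, "ablation")))

    results["tables"] = tables
    if out_dir is not None and tables:
        results["files"] = render_report(tables, out_dir)
    return results
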