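"""Raw-scan calibration, scan averaging and dataset splitting.

A handheld NIR spectrometer reports per-band luminance.  Each sample
region is scanned five times; every scan is calibrated against a white
reference ``W`` (light on, against a white board) and a dark reference
``B`` (light off) via ``R = (I - B) / (W - B)``, and the five calibrated
scans are averaged into the single modelling spectrum for that sample.
Reflectance is stored as a dimensionless fraction (nominally 0-1);
percentages are a display concern only, which keeps both modelling
branches on one scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralDataset",
    "compute_reflectance",
    "average_scans",
    "split_indices",
    "split_dataset",
]


@dataclass
class Spectrum:
    """One calibrated reflectance spectrum on a fixed wavelength grid."""

    reflectance: np.ndarray
    wavelengths: np.ndarray
    sample_id: str
    label: str | None = None

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.shape != self.wavelengths.shape:
            raise ValueError(
                f"reflectance ({self.reflectance.shape}) and wavelengths "
                f"({self.wavelengths.shape}) must align"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError(f"non-finite reflectance in sample {self.sample_id!r}")


@dataclass
class SpectralDataset:
    """A collection of spectra sharing one wavelength grid."""

    spectra: list[Spectrum]
    label_encoding: dict = field(default_factory=lambda: {"healthy": 0, "diseased": 1})

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in dataset")
        if self.spectra:
            grid = self.spectra[0].wavelengths
            for s in self.spectra[1:]:
                if not np.array_equal(s.wavelengths, grid):
                    raise ValueError(f"wavelength grid mismatch at {s.sample_id!r}")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def X(self) -> np.ndarray:
        return np.stack([s.reflectance for s in self.spectra])

    @property
    def y(self) -> np.ndarray:
        return np.array([self.label_encoding[s.label] for s in self.spectra])

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.spectra])


def compute_reflectance(I: np.ndarray, W: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Calibrate raw luminance to reflectance, ``(I - B) / (W - B)``.

    No clipping is applied: a sample brighter than the white reference
    legitimately yields reflectance > 1.
    """
    I, W, B = (np.asarray(v, dtype=float) for v in (I, W, B))
    if not (I.shape == W.shape == B.shape):
        raise ValueError(f"shape mismatch: I{I.shape} W{W.shape} B{B.shape}")
    degenerate = np.nonzero(W == B)[0]
    if degenerate.size:
        raise ValueError(
            f"calibration degenerate (W == B) at band index {int(degenerate[0])}"
        )
    return (I - B) / (W - B)


def average_scans(scans) -> np.ndarray:
    """Elementwise arithmetic mean of repeated scans of one region."""
    scans = list(scans)
    if not scans:
        raise ValueError("cannot average an empty list of scans")
    lengths = {len(s) for s in scans}
    if len(lengths) != 1:
        raise ValueError(f"ragged scan lengths {sorted(lengths)}")
    return np.mean(np.asarray(scans, dtype=float), axis=0)


def split_indices(labels, train_fraction: float, seed: int):
    """Stratified train/validation index split with a seeded shuffle.

    Each class contributes ``round(train_fraction * n_class)`` training
    samples, so a balanced 480-sample set at 0.7 splits 336/144 with both
    sides class-balanced.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    labels = np.asarray(labels)
    if labels.size < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    train_parts, val_parts = [], []
    # singleton classes cannot be stratified; alternate them across sides
    # so the partition stays exact and both sides stay non-empty
    n_singletons_seen = 0
    for cls in sorted(map(str, np.unique(labels))):
        idx = np.nonzero(labels.astype(str) == cls)[0]
        if idx.size == 1:
            (train_parts if n_singletons_seen % 2 == 0 else val_parts).append(idx)
            n_singletons_seen += 1
            continue
        perm = rng.permutation(idx)
        n_train = int(np.floor(train_fraction * idx.size + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)  # keep both sides non-empty
        train_parts.append(perm[:n_train])
        val_parts.append(perm[n_train:])
    if not train_parts or not val_parts:
        raise ValueError("split left one side empty; provide more samples per class")
    train = np.sort(np.concatenate(train_parts))
    val = np.sort(np.concatenate(val_parts))
    return train, val


def split_dataset(dataset, train_fraction: float, seed: int):
    """Split any indexable dataset object (or label array) stratified by label.

    Accepts a :class:`SpectralDataset`, a paired dataset exposing
    ``labels`` and ``subset``, or a bare label sequence (returning index
    arrays in that case).
    """
    if isinstance(dataset, SpectralDataset):
        tr, va = split_indices(dataset.labels, train_fraction, seed)
        pick = lambda idx: SpectralDataset(
            [dataset.spectra[i] for i in idx], dict(dataset.label_encoding)
        )
        return pick(tr), pick(va)
    if hasattr(dataset, "labels") and hasattr(dataset, "subset"):
        tr, va = split_indices(np.asarray(dataset.labels), train_fraction, seed)
        return dataset.subset(tr), dataset.subset(va)
    return split_indices(np.asarray(dataset), train_fraction, seed)


def write_split_manifests(manifest: pd.DataFrame, train_idx, val_idx, out_dir):
    """Persist a split as two manifest CSVs next to the dataset manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, idx in (("train", train_idx), ("validation", val_idx)):
        p = out / f"{name}_manifest.csv"
        manifest.iloc[np.asarray(idx)].to_csv(p, index=False)
        paths[name] = p
    return paths
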