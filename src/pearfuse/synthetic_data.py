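"""Seeded synthetic paired spectra+image datasets.

The study this package mirrors collected, for each of 480 pears (240
healthy, 240 with the woolliness response disorder), five NIR reflectance
scans per region averaged into one 228-band spectrum over 900-1700 nm,
plus one RGB photograph of the fruit on a light background.  That dataset
is not public, so this module generates a statistical stand-in with the
same structure and controllable class separation, letting every
downstream stage (calibration, branch training, fusion, evaluation) run
offline and deterministically.

Spectra are a fixed smooth baseline minus Gaussian absorption dips; the
disorder (tissue water loss, boron/calcium deficiency) is emulated as
deeper absorption at the water-related bands near 1200 and 1450 nm.
Images are an elliptical fruit on a white background; the disorder shifts
the skin colour toward a darker yellow and adds darker blotches
concentrated near the fruit rim.  Per-sample multiplicative scatter,
per-dip depth variability, pixel noise and variable blotch counts keep
either modality individually imperfect, so fusing them can help — the
qualitative regime of the original study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .acquisition import average_scans, compute_reflectance

__all__ = [
    "SyntheticConfig",
    "RawScanSet",
    "PairedDataset",
    "generate_spectrum",
    "generate_raw_scan_set",
    "generate_image",
    "generate_paired_dataset",
]

LABELS = ("healthy", "diseased")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study.

    Effect sizes are dimensionless: ``spectral_effect_size`` is the extra
    absorption-dip depth (reflectance units) of the diseased class, and
    ``image_effect_size`` the fractional colour shift of diseased skin
    toward a darker yellow.  Noise terms are chosen so that at defaults
    neither modality alone is perfectly separable.
    """

    n_per_class: int = 240
    n_bands: int = 228
    wavelength_start_nm: float = 900.0
    wavelength_end_nm: float = 1700.0
    image_size_px: int = 128
    spectral_effect_size: float = 0.08
    image_effect_size: float = 0.25
    spectral_noise_sd: float = 0.01
    scatter_sd: float = 0.04
    dip_scatter_sd: float = 0.35
    scans_per_region: int = 5
    blotches: bool = True
    image_noise_sd: float = 10.0
    seed: int = 0
    # Gaussian absorption dips: (center nm, width nm, healthy depth);
    # diseased depth = healthy depth + spectral_effect_size.
    dip_centers_nm: tuple = ((1200.0, 30.0, 0.10), (1450.0, 45.0, 0.16))

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        if self.wavelength_end_nm <= self.wavelength_start_nm:
            raise ValueError("wavelength grid must be increasing")
        if self.image_size_px < 16:
            raise ValueError("image_size_px must be >= 16")
        if self.spectral_effect_size < 0 or self.image_effect_size < 0:
            raise ValueError("effect sizes must be non-negative")
        if self.spectral_noise_sd < 0 or self.scatter_sd < 0 or self.dip_scatter_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if self.scans_per_region < 1:
            raise ValueError("scans_per_region must be >= 1")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(
            self.wavelength_start_nm, self.wavelength_end_nm, self.n_bands
        )

    def null(self) -> "SyntheticConfig":
        """The zero-signal variant: labels carry no information."""
        return replace(
            self, spectral_effect_size=0.0, image_effect_size=0.0, blotches=False
        )


@dataclass
class RawScanSet:
    """Uncalibrated luminance scans of one region plus its references."""

    scans: list
    white_reference: np.ndarray
    dark_reference: np.ndarray
    region_id: str

    def __post_init__(self) -> None:
        if not np.all(self.white_reference > self.dark_reference):
            raise ValueError("white reference must exceed dark reference at every band")

    def calibrated_mean(self) -> np.ndarray:
        """Calibrate every scan and average — the modelling spectrum."""
        return average_scans(
            [compute_reflectance(s, self.white_reference, self.dark_reference)
             for s in self.scans]
        )


def _baseline(config: SyntheticConfig) -> np.ndarray:
    # Fixed smooth quadratic baseline, highest in the middle of the grid.
    t = (config.wavelengths - config.wavelength_start_nm) / (
        config.wavelength_end_nm - config.wavelength_start_nm
    )
    return 0.55 + 0.35 * t - 0.45 * t**2


def _sample_spectrum(config: SyntheticConfig, label: str, rng) -> np.ndarray:
    """Noise-free (band-wise) per-sample spectrum: baseline minus dips,
    with per-sample scatter and per-dip depth variability."""
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    wl = config.wavelengths
    spectrum = _baseline(config).copy()
    for center, width, depth_h in config.dip_centers_nm:
        depth = depth_h + (config.spectral_effect_size if label == "diseased" else 0.0)
        depth *= 1.0 + config.dip_scatter_sd * rng.standard_normal()
        spectrum -= depth * np.exp(-0.5 * ((wl - center) / width) ** 2)
    spectrum *= 1.0 + config.scatter_sd * rng.standard_normal()
    return spectrum


def generate_spectrum(config: SyntheticConfig, label: str, rng) -> np.ndarray:
    """One calibrated-equivalent reflectance spectrum for ``label``."""
    s = _sample_spectrum(config, label, rng)
    s = s + config.spectral_noise_sd * rng.standard_normal(config.n_bands)
    return np.clip(s, 0.0, None)


def generate_raw_scan_set(
    config: SyntheticConfig, label: str, rng, region_id: str = "r0"
) -> RawScanSet:
    """Uncalibrated scans that round-trip to :func:`generate_spectrum`.

    The white/dark references are deterministic instrument curves; each
    scan carries independent reflectance-domain noise of sd
    ``spectral_noise_sd``, so calibrating and averaging recovers the
    underlying sample spectrum with noise sd reduced by ``sqrt(n_scans)``.
    """
    target = _sample_spectrum(config, label, rng)
    t = np.linspace(0.0, 1.0, config.n_bands)
    W = 4000.0 + 400.0 * np.sin(np.pi * t)  # lamp/detector response
    B = 180.0 + 40.0 * t                    # dark current drift
    scans = []
    for _ in range(config.scans_per_region):
        r = np.clip(target + config.spectral_noise_sd * rng.standard_normal(config.n_bands), 0.0, None)
        scans.append(B + r * (W - B))
    return RawScanSet(scans=scans, white_reference=W, dark_reference=B,
                      region_id=region_id)


def generate_image(config: SyntheticConfig, label: str, rng) -> np.ndarray:
    """One uint8 RGB image (H, W, 3) of a synthetic pear.

    Healthy skin is yellow-green; diseased skin shifts toward a darker
    yellow by ``image_effect_size`` and, when ``blotches`` is enabled,
    carries a variable number of darker blotches concentrated near the
    fruit rim (the disorder spreads inward from near the skin).  Both
    classes consume the randomness stream identically, so with a zero
    effect size and blotches disabled the class-conditional image
    distributions coincide exactly.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    S = config.image_size_px
    img = np.full((S, S, 3), 243.0)  # near-white background

    cx, cy = S / 2 + 0.02 * S * rng.standard_normal(2)
    ax = S * (0.36 + 0.02 * rng.standard_normal())
    ay = S * (0.42 + 0.02 * rng.standard_normal())

    healthy_rgb = np.array([186.0, 199.0, 96.0])
    diseased_rgb = np.array([168.0, 144.0, 62.0])
    shift = 1.0 if label == "diseased" else 0.0
    base = healthy_rgb + config.image_effect_size * shift * (diseased_rgb - healthy_rgb)
    base = base + 6.0 * rng.standard_normal(3)

    yy, xx = np.mgrid[0:S, 0:S]
    r2 = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
    inside = r2 <= 1.0
    # gentle radial shading so the fruit is not a flat disc
    shade = 1.0 - 0.18 * np.clip(r2, 0.0, 1.0)
    img[inside] = (base[None, :] * shade[inside, None])

    if config.blotches:
        n_blotch = rng.poisson(2.5)
        for _ in range(n_blotch):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            rad = rng.uniform(0.55, 0.92)  # concentrated near the rim
            bx = cx + rad * ax * np.cos(theta)
            by = cy + rad * ay * np.sin(theta)
            bsz = S * rng.uniform(0.03, 0.08)
            dark = rng.uniform(25.0, 80.0)
            blob = np.exp(-0.5 * (((xx - bx) ** 2 + (yy - by) ** 2) / bsz**2))
            img -= (shift * dark) * (blob * inside)[:, :, None]

    img += config.image_noise_sd * rng.standard_normal((S, S, 3))
    return np.clip(img, 0.0, 255.0).astype(np.uint8)


@dataclass
class PairedDataset:
    """In-memory paired dataset: one averaged spectrum and one image per sample."""

    wavelengths: np.ndarray
    spectra: np.ndarray      # (n, n_bands) float
    images: np.ndarray       # (n, S, S, 3) uint8
    labels: np.ndarray       # (n,) str
    sample_ids: np.ndarray   # (n,) str
    config: SyntheticConfig | None = None

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, idx) -> "PairedDataset":
        idx = np.asarray(idx)
        return PairedDataset(
            wavelengths=self.wavelengths, spectra=self.spectra[idx],
            images=self.images[idx], labels=self.labels[idx],
            sample_ids=self.sample_ids[idx], config=self.config,
        )

    @property
    def y(self) -> np.ndarray:
        return (self.labels == "diseased").astype(int)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "label": self.labels,
            "spectrum_path": [f"spectra/{sid}.csv" for sid in self.sample_ids],
            "image_path": [f"images/{sid}.png" for sid in self.sample_ids],
        })

    def save(self, out_dir) -> Path:
        """Write manifest.csv, per-sample spectrum CSVs and PNG images."""
        out = Path(out_dir)
        (out / "spectra").mkdir(parents=True, exist_ok=True)
        (out / "images").mkdir(parents=True, exist_ok=True)
        man = self.manifest()
        man.to_csv(out / "manifest.csv", index=False)
        header = ",".join(f"{w:.6f}" for w in self.wavelengths)
        for i, sid in enumerate(self.sample_ids):
            row = ",".join(f"{v:.8f}" for v in self.spectra[i])
            (out / "spectra" / f"{sid}.csv").write_text(header + "\n" + row + "\n")
            Image.fromarray(self.images[i]).save(out / "images" / f"{sid}.png")
        return out / "manifest.csv"

    @classmethod
    def load(cls, data_dir) -> "PairedDataset":
        root = Path(data_dir)
        man = pd.read_csv(root / "manifest.csv")
        spectra, images, wavelengths = [], [], None
        for _, row in man.iterrows():
            lines = (root / row["spectrum_path"]).read_text().strip().splitlines()
            if wavelengths is None:
                wavelengths = np.array([float(v) for v in lines[0].split(",")])
            spectra.append([float(v) for v in lines[1].split(",")])
            images.append(np.asarray(Image.open(root / row["image_path"]).convert("RGB")))
        return cls(
            wavelengths=wavelengths, spectra=np.array(spectra),
            images=np.stack(images), labels=man["label"].to_numpy(dtype=object),
            sample_ids=man["sample_id"].to_numpy(dtype=object),
        )


def generate_paired_dataset(
    config: SyntheticConfig, out_dir=None
) -> PairedDataset:
    """Generate the full balanced paired dataset (and optionally persist it).

    Each sample's spectrum goes through the full acquisition pipeline:
    raw scans are generated, calibrated against the white/dark references
    and averaged.  Per-sample random streams are spawned from the config
    seed, so the dataset is bit-identical across runs for a fixed config.
    """
    n = config.n_per_class
    children = np.random.SeedSequence(config.seed).spawn(2 * n)
    spectra, images, labels, ids = [], [], [], []
    for j, label in enumerate(LABELS):
        for i in range(n):
            rng = np.random.default_rng(children[j * n + i])
            scan_set = generate_raw_scan_set(config, label, rng, region_id=f"{label}_{i:03d}")
            spectra.append(scan_set.calibrated_mean())
            images.append(generate_image(config, label, rng))
            labels.append(label)
            ids.append(f"{label}_{i:03d}")
    ds = PairedDataset(
        wavelengths=config.wavelengths, spectra=np.array(spectra),
        images=np.stack(images), labels=np.array(labels, dtype=object),
        sample_ids=np.array(ids, dtype=object), config=config,
    )
    if out_dir is not None:
        ds.save(out_dir)
    return ds
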