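"""Synthetic knee-slice fixtures.

The generator emulates the statistical structure the localization pipeline
consumes — grayscale-in-RGB JPEG slices with smooth low-frequency background,
one brighter rectangular region of interest per injured volume with a z-extent,
and contrast-free control volumes — together with the ROI metadata CSV and
lossless reference masks. It is not an MRI simulator: anatomy, sequence
physics and scanner artifacts are out of scope.

Defaults mirror the study conditions: 917 volumes of 320x320 slices with a
balanced control set and per-volume slice counts drawn so the corpus totals
roughly 15k slices.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .masks import (METADATA_COLUMNS, DatasetManifest, ROIRecord,
                    build_volume_masks, save_mask_image)


@dataclass(frozen=True)
class SynthConfig:
    n_volumes: int = 917
    slices_per_volume: tuple = (3, 30)  # inclusive range, or (k, k) for fixed
    image_size: tuple = (320, 320)
    control_fraction: float = 0.5
    roi_size_range: tuple = (60, 180)  # pixel bounds for rectangle edges
    intensity_contrast: float = 0.35   # ROI-background mean separation, [0,1] units
    noise_sd: float = 0.08
    blur_sigma: float = 3.0
    background_level: float = 0.35
    control_mask_mode: str = "empty"   # or "healthy": mark the healthy ACL box
    jpeg_quality: int = 95
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.control_fraction <= 1.0:
            raise ValueError("control_fraction must lie in [0, 1]")
        lo, hi = self.roi_size_range
        h, w = self.image_size
        if lo < 1 or hi < lo:
            raise ValueError("roi_size_range must satisfy 1 <= lo <= hi")
        if hi > min(h, w):
            raise ValueError(f"roi_size_range upper bound {hi} exceeds the "
                             f"image size {self.image_size}")
        if self.control_mask_mode not in ("empty", "healthy"):
            raise ValueError("control_mask_mode must be 'empty' or 'healthy'")

    def hard(self) -> "SynthConfig":
        """Low-contrast, high-noise preset so toy training cannot saturate."""
        return replace(self, intensity_contrast=0.12, noise_sd=0.15)

    def easy(self) -> "SynthConfig":
        """High-contrast, low-noise preset for mechanism checks."""
        return replace(self, intensity_contrast=0.5, noise_sd=0.03)


def _background(config: SynthConfig, rng) -> np.ndarray:
    """Smooth anatomy-like background: blurred low-frequency noise."""
    h, w = config.image_size
    coarse = rng.standard_normal((max(h // 16, 2), max(w // 16, 2)))
    field = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]),
                         order=3)
    field = ndimage.gaussian_filter(field, sigma=4.0)
    field *= 0.08 / max(field.std(), 1e-8)
    return config.background_level + field


def _draw_record(config: SynthConfig, rng, volume_name: str, n_slices: int,
                 control: bool) -> ROIRecord:
    h, w = config.image_size
    lo, hi = config.roi_size_range
    roi_w = int(rng.integers(lo, hi + 1))
    roi_h = int(rng.integers(lo, hi + 1))
    roi_x = int(rng.integers(0, w - roi_w + 1))
    roi_y = int(rng.integers(0, h - roi_h + 1))
    if control and config.control_mask_mode == "empty":
        depth, z = 0, 0
    else:
        depth = int(rng.integers(max(1, n_slices // 4),
                                 max(2, n_slices // 2 + 1)))
        z = int(rng.integers(0, n_slices - depth + 1))
    return ROIRecord(volume_filename=volume_name, roi_x=roi_x, roi_y=roi_y,
                     roi_z=z, roi_height=roi_h, roi_width=roi_w,
                     roi_depth=depth)


def generate_volume(config: SynthConfig, rng, volume_index: int = 0,
                    control: bool = False):
    """One synthetic volume: a list of (H, W, 3) uint8 slices plus its record.

    Injured volumes carry a brighter rectangle exactly where the record says,
    on slices within the z-extent only; control volumes have zero added
    contrast everywhere.
    """
    h, w = config.image_size
    lo, hi = config.slices_per_volume
    n_slices = int(rng.integers(lo, hi + 1))
    record = _draw_record(config, rng, f"vol{volume_index:04d}.jpeg",
                          n_slices, control)
    base = _background(config, rng)
    bump = np.zeros((h, w), dtype=np.float64)
    if not control and record.roi_width and record.roi_height:
        box = np.s_[record.roi_y:record.roi_y + record.roi_height,
                    record.roi_x:record.roi_x + record.roi_width]
        bump[box] = 1.0
        inside = bump > 0.5
        bump = ndimage.gaussian_filter(bump, sigma=config.blur_sigma)
        # rescale after edge blurring so the inside-outside mean separation
        # equals the configured contrast exactly (before noise)
        separation = bump[inside].mean() - bump[~inside].mean()
        bump *= config.intensity_contrast / max(separation, 1e-9)
    in_extent = range(record.roi_z, record.roi_z + record.roi_depth)
    slices = []
    for z in range(n_slices):
        img = base + 0.02 * rng.standard_normal()  # slice-to-slice drift
        if not control and z in in_extent:
            img = img + bump
        img = img + config.noise_sd * rng.standard_normal((h, w))
        img = np.clip(img, 0.0, 1.0)
        u8 = (img * 255.0).round().astype(np.uint8)
        slices.append(np.repeat(u8[..., None], 3, axis=2))
    return slices, record


def generate_dataset(config: SynthConfig, out_dir,
                     overwrite: bool = False) -> DatasetManifest:
    """Write images, metadata CSV and reference masks; return the manifest.

    Layout: ``images/<stem>_s<k>.jpeg``, ``masks/<stem>_s<k>.png``,
    ``metadata.csv`` (ROI schema), ``manifest.csv``. Rebuilding masks from
    the emitted metadata reproduces the emitted reference masks exactly.
    """
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    masks_dir = out_dir / "masks"
    if images_dir.exists() and any(images_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{images_dir} already contains files "
                              "(pass overwrite=True to replace)")
    images_dir.mkdir(parents=True, exist_ok=True)
    masks_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    n_control = int(round(config.control_fraction * config.n_volumes))
    controls = np.zeros(config.n_volumes, dtype=bool)
    controls[:n_control] = True
    rng.shuffle(controls)

    manifest = DatasetManifest()
    records = []
    for v in range(config.n_volumes):
        slices, record = generate_volume(config, rng, volume_index=v,
                                         control=bool(controls[v]))
        records.append(record)
        masks = build_volume_masks(record, len(slices), config.image_size)
        for z, (img, mask) in enumerate(zip(slices, masks)):
            img_path = images_dir / f"{record.stem}_s{z:03d}.jpeg"
            mask_path = masks_dir / f"{record.stem}_s{z:03d}.png"
            Image.fromarray(img, mode="RGB").save(
                img_path, quality=config.jpeg_quality)
            save_mask_image(mask, mask_path)
            manifest.entries.append((str(img_path), str(mask_path),
                                     record.stem, z))
            manifest.foreground_pixels += int(mask.sum())
            manifest.total_pixels += int(mask.size)
        manifest.n_volumes += 1
        if controls[v]:
            manifest.n_control += 1

    with open(out_dir / "metadata.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(METADATA_COLUMNS)
        for r in records:
            writer.writerow([r.volume_filename, r.roi_x, r.roi_y, r.roi_z,
                             r.roi_height, r.roi_width, r.roi_depth])
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest


def generate_arrays(config: SynthConfig, target_size=(128, 128),
                    positives_only: bool = False):
    """In-memory dataset: prepared (X, Y) arrays ready for training.

    X is (N, h, w, 3) float32 in [0, 1]; Y is (N, h, w, 1) binary float32.
    With ``positives_only`` only slices inside an ROI z-extent are kept.
    """
    from .masks import prepare_pair

    rng = np.random.default_rng(config.seed)
    n_control = int(round(config.control_fraction * config.n_volumes))
    controls = np.zeros(config.n_volumes, dtype=bool)
    controls[:n_control] = True
    rng.shuffle(controls)
    xs, ys = [], []
    for v in range(config.n_volumes):
        slices, record = generate_volume(config, rng, volume_index=v,
                                         control=bool(controls[v]))
        masks = build_volume_masks(record, len(slices), config.image_size)
        for z, (img, mask) in enumerate(zip(slices, masks)):
            if positives_only and not mask.any():
                continue
            x, y = prepare_pair(img, mask, target_size)
            xs.append(x)
            ys.append(y[..., None].astype(np.float32))
    return np.stack(xs), np.stack(ys)
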