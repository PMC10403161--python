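"""Region-of-interest mask construction and image/mask preparation.

Ground-truth masks for the ACL region are filled axis-aligned rectangles
derived from per-volume metadata (position and extent in x, y and z). The
coordinate convention is 0-based with (roi_x, roi_y) the top-left corner and
half-open intervals: the rectangle covers rows [roi_y, roi_y + roi_height)
and columns [roi_x, roi_x + roi_width), on slices
[roi_z, roi_z + roi_depth). Out-of-bounds rectangles raise rather than clip,
so the foreground-count identity (ones == width x height) always holds.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

METADATA_COLUMNS = ("volume_filename", "roi_x", "roi_y", "roi_z",
                    "roi_height", "roi_width", "roi_depth")


class MetadataError(ValueError):
    """Malformed ROI metadata (missing column, non-numeric or negative field)."""


@dataclass(frozen=True)
class ROIRecord:
    """One volume's rectangular region-of-interest metadata."""

    volume_filename: str
    roi_x: int
    roi_y: int
    roi_z: int
    roi_height: int
    roi_width: int
    roi_depth: int

    def __post_init__(self):
        for name in ("roi_x", "roi_y", "roi_z", "roi_height", "roi_width",
                     "roi_depth"):
            if getattr(self, name) < 0:
                raise MetadataError(
                    f"{self.volume_filename}: {name} must be >= 0, "
                    f"got {getattr(self, name)}")

    @property
    def stem(self) -> str:
        return os.path.splitext(self.volume_filename)[0]

    def validate_against(self, image_shape):
        h, w = image_shape[:2]
        if self.roi_x + self.roi_width > w or self.roi_y + self.roi_height > h:
            raise MetadataError(
                f"{self.volume_filename}: ROI rectangle "
                f"({self.roi_x},{self.roi_y})+({self.roi_width}x"
                f"{self.roi_height}) exceeds image bounds {h}x{w}")


def parse_metadata(csv_source) -> list[ROIRecord]:
    """Read ROI metadata rows (path, file-like or DataFrame) into records."""
    if isinstance(csv_source, pd.DataFrame):
        df = csv_source
    else:
        df = pd.read_csv(csv_source)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata is missing column(s): {missing}")
    records = []
    for idx, row in df.iterrows():
        fields = {"volume_filename": str(row["volume_filename"])}
        for name in METADATA_COLUMNS[1:]:
            value = row[name]
            try:
                as_float = float(value)
                as_int = int(as_float)
                if as_int != as_float:
                    raise ValueError
            except (TypeError, ValueError):
                raise MetadataError(
                    f"row {idx}: field {name!r} is not an integer "
                    f"({value!r})") from None
            fields[name] = as_int
        records.append(ROIRecord(**fields))
    return records


def build_roi_mask(record: ROIRecord, image_shape) -> np.ndarray:
    """Filled-rectangle binary mask on the given (H, W) grid."""
    h, w = image_shape[:2]
    record.validate_against((h, w))
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[record.roi_y:record.roi_y + record.roi_height,
         record.roi_x:record.roi_x + record.roi_width] = 1
    return mask


def build_volume_masks(record: ROIRecord, n_slices: int,
                       image_shape) -> list[np.ndarray]:
    """Per-slice masks: the rectangle on slices within the z-extent, else empty."""
    if record.roi_z + record.roi_depth > n_slices:
        raise MetadataError(
            f"{record.volume_filename}: z-extent [{record.roi_z}, "
            f"{record.roi_z + record.roi_depth}) exceeds {n_slices} slices")
    rect = build_roi_mask(record, image_shape)
    empty = np.zeros_like(rect)
    return [rect if record.roi_z <= z < record.roi_z + record.roi_depth
            else empty for z in range(n_slices)]


def prepare_pair(image: np.ndarray, mask: np.ndarray,
                 target_size=(128, 128)):
    """Resize and normalize an image/mask pair for the network.

    The image is resized with bilinear interpolation, keeps its 3 channels,
    and is scaled to [0, 1] by dividing by 255; the mask is resized with
    nearest-neighbor so it stays strictly binary.
    """
    th, tw = target_size
    if th <= 0 or tw <= 0:
        raise ValueError(f"target size must be positive, got {target_size}")
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got {image.shape}")
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask must share a spatial grid")
    img = Image.fromarray(image.astype(np.uint8), mode="RGB")
    img = img.resize((tw, th), resample=Image.BILINEAR)
    out_image = np.asarray(img, dtype=np.float32) / 255.0
    msk = Image.fromarray((mask > 0).astype(np.uint8) * 255, mode="L")
    msk = msk.resize((tw, th), resample=Image.NEAREST)
    out_mask = (np.asarray(msk) > 127).astype(np.uint8)
    return out_image, out_mask


def save_mask_image(mask: np.ndarray, path, jpeg_quality: int | None = None):
    """Write a binary mask; PNG is lossless, JPEG compatibility needs q >= 95."""
    path = Path(path)
    img = Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255,
                          mode="L")
    if path.suffix.lower() in (".jpg", ".jpeg"):
        quality = 95 if jpeg_quality is None else jpeg_quality
        if quality < 95:
            raise ValueError("JPEG mask writing requires quality >= 95 so "
                             "midpoint binarization can undo ringing")
        img.save(path, quality=quality)
    else:
        img.save(path)


def load_mask_image(path) -> np.ndarray:
    """Load a mask image, binarizing gray values at the 127.5 midpoint."""
    try:
        img = Image.open(path).convert("L")
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read mask image {path}: {exc}") from exc
    return (np.asarray(img) > 127).astype(np.uint8)


def load_slice_image(path) -> np.ndarray:
    """Load an RGB slice image as (H, W, 3) uint8."""
    try:
        img = Image.open(path).convert("RGB")
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return np.asarray(img)


@dataclass
class DatasetManifest:
    """Ordered (image, mask, volume, slice) entries plus dataset tallies."""

    entries: list = field(default_factory=list)  # (image, mask, volume, slice)
    n_volumes: int = 0
    n_control: int = 0
    foreground_pixels: int = 0
    total_pixels: int = 0

    def __len__(self):
        return len(self.entries)

    @property
    def foreground_prevalence(self) -> float:
        return self.foreground_pixels / self.total_pixels if self.total_pixels else 0.0

    def to_csv(self, path):
        pd.DataFrame(self.entries,
                     columns=["image", "mask", "volume", "slice"]).to_csv(
                         path, index=False)

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        entries = [tuple(row) for row in
                   df[["image", "mask", "volume", "slice"]].itertuples(index=False)]
        volumes = {e[2] for e in entries}
        return cls(entries=entries, n_volumes=len(volumes))

    def validate(self):
        images = [e[0] for e in self.entries]
        if len(set(images)) != len(images):
            raise ValueError("manifest image paths are not unique")
        for e in self.entries:
            if not e[1]:
                raise ValueError(f"manifest entry {e[0]} has no mask")


def write_volume_masks(records, images_dir, out_dir, compat_jpeg=False,
                       target_size=None):
    """Materialize per-slice masks for every metadata record.

    Slice images are expected as ``<stem>_s<k>.jpeg`` under ``images_dir``
    (a single ``<volume_filename>`` file is also accepted for flat, one-image
    volumes). Masks are written as PNG, or JPEG at quality 95 when
    ``compat_jpeg`` is set.
    """
    images_dir, out_dir = Path(images_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".jpeg" if compat_jpeg else ".png"
    manifest = DatasetManifest()
    for record in records:
        slice_paths = sorted(images_dir.glob(f"{record.stem}_s*.jpeg")) or \
            sorted(images_dir.glob(f"{record.stem}_s*.jpg"))
        if not slice_paths:
            flat = images_dir / record.volume_filename
            if not flat.exists():
                raise FileNotFoundError(
                    f"no slice images found for {record.volume_filename!r} "
                    f"in {images_dir}")
            slice_paths = [flat]
        shape = load_slice_image(slice_paths[0]).shape[:2]
        masks = build_volume_masks(record, len(slice_paths), shape)
        for z, (img_path, mask) in enumerate(zip(slice_paths, masks)):
            if target_size is not None:
                _, mask = prepare_pair(
                    np.zeros(shape + (3,), dtype=np.uint8), mask, target_size)
            mask_path = out_dir / (img_path.stem + ext)
            save_mask_image(mask, mask_path)
            manifest.entries.append((str(img_path), str(mask_path),
                                     record.stem, z))
            manifest.foreground_pixels += int(mask.sum())
            manifest.total_pixels += int(mask.size)
        manifest.n_volumes += 1
        if record.roi_depth == 0:
            manifest.n_control += 1
    return manifest
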