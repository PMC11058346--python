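"""Image / ROI I/O, preparation, augmentation, patching and dataset splits.

Images live in memory as 2-D float64 arrays in [0, 1]; bit depth is purely a
file concern (8- or 16-bit PNG/TIFF are read and written losslessly at
their own precision).  ROI boxes are 0-based half-open {row, col, height,
width} rectangles carried in JSON sidecar files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize
import tifffile

from .metrics import ROI, ROIPair

__all__ = [
    "ImageRecord", "NoisyCleanPair", "DatasetSplit", "PatchGrid",
    "read_image", "write_image", "read_rois", "write_rois",
    "resize", "augment", "extract_patches", "reassemble_patches",
    "split_dataset", "write_manifest", "load_manifest",
]

logger = logging.getLogger(__name__)


@dataclass
class ImageRecord:
    """A single-channel image with values in [0, 1]."""
    id: str
    pixels: np.ndarray
    source_path: Path | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"{self.id}: expected 2-D grayscale, "
                             f"got shape {self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise ValueError(f"{self.id}: non-finite pixel values")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError(f"{self.id}: pixel values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class NoisyCleanPair:
    """Aligned noisy and clean B-scans plus their ROI boxes — the unit of
    training and evaluation.  ``rois`` may be None when an augmentation
    cropped the boxes away."""
    noisy: ImageRecord
    clean: ImageRecord
    rois: ROIPair | None = None

    def __post_init__(self):
        if self.noisy.shape != self.clean.shape:
            raise ValueError(
                f"noisy {self.noisy.shape} and clean {self.clean.shape} "
                "shapes differ")
        if self.rois is not None:
            self.rois.signal.check_inside(self.noisy.shape)
            self.rois.background.check_inside(self.noisy.shape)


@dataclass
class DatasetSplit:
    train: list[NoisyCleanPair]
    val: list[NoisyCleanPair]
    test: list[NoisyCleanPair]


@dataclass
class PatchGrid:
    """Row-major flattened P x P patches of one (possibly padded) image."""
    patches: np.ndarray            # (N, P*P)
    grid_shape: tuple[int, int]    # (rows, cols)
    patch: int
    pad: tuple[int, int] = (0, 0)  # rows/cols of edge padding added

    def __post_init__(self):
        n = self.grid_shape[0] * self.grid_shape[1]
        if self.patches.shape != (n, self.patch * self.patch):
            raise ValueError(
                f"patch matrix {self.patches.shape} inconsistent with grid "
                f"{self.grid_shape} and patch size {self.patch}")

    @property
    def n_patches(self) -> int:
        return self.patches.shape[0]


# -- file I/O ---------------------------------------------------------------


def read_image(path: str | Path, id: str | None = None) -> ImageRecord:
    """Read an 8/16-bit grayscale PNG or TIFF into [0, 1] floats."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        raise ValueError(f"{path}: expected single-channel image")
    if arr.dtype == np.uint8:
        pixels = arr / 255.0
    elif arr.dtype in (np.uint16, np.int32):
        pixels = np.asarray(arr, dtype=np.float64) / 65535.0
    else:
        pixels = np.asarray(arr, dtype=np.float64)
    return ImageRecord(id=id or path.stem, pixels=np.clip(pixels, 0.0, 1.0),
                       source_path=path)


def write_image(pixels: np.ndarray, path: str | Path,
                bit_depth: int = 16) -> None:
    """Write [0, 1] floats as 8/16-bit grayscale PNG or TIFF."""
    path = Path(path)
    pixels = np.asarray(pixels, dtype=np.float64)
    if bit_depth == 16:
        arr = np.round(np.clip(pixels, 0, 1) * 65535.0).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.round(np.clip(pixels, 0, 1) * 255.0).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_rois(path: str | Path) -> ROIPair:
    return ROIPair.from_dict(json.loads(Path(path).read_text()))


def write_rois(rois: ROIPair, path: str | Path) -> None:
    Path(path).write_text(json.dumps(rois.to_dict(), indent=2))


# -- preparation ------------------------------------------------------------


def resize(image: ImageRecord, target_h: int, target_w: int) -> ImageRecord:
    """Bilinear resize to (target_h, target_w), clipped back to [0, 1]."""
    if target_h < 2 or target_w < 2:
        raise ValueError("target dimensions must be at least 2 pixels")
    if image.shape == (target_h, target_w):
        return ImageRecord(id=image.id, pixels=image.pixels.copy(),
                           source_path=image.source_path)
    out = _sk_resize(image.pixels, (target_h, target_w), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return ImageRecord(id=image.id, pixels=np.clip(out, 0.0, 1.0),
                       source_path=image.source_path)


def _transform_roi(roi: ROI, name: str, h: int, w: int,
                   zoom: float) -> ROI | None:
    """Transport a box through the named pixel transform of an (h, w) image."""
    r, c, bh, bw = roi.row, roi.col, roi.height, roi.width
    if name == "identity":
        return roi
    if name == "rot90":       # numpy rot90: (r, c) -> (w - 1 - c, r)
        return ROI(w - c - bw, r, bw, bh)
    if name == "rot180":
        return ROI(h - r - bh, w - c - bw, bh, bw)
    if name == "rot270":
        return ROI(c, h - r - bh, bw, bh)
    if name == "hflip":       # flip columns
        return ROI(r, w - c - bw, bh, bw)
    if name == "vflip":       # flip rows
        return ROI(h - r - bh, c, bh, bw)
    if name == "zoom":
        sh, sw = round(h * zoom), round(w * zoom)
        top, left = (sh - h) // 2, (sw - w) // 2
        nr = round(r * zoom) - top
        nc = round(c * zoom) - left
        nh, nw = round(bh * zoom), round(bw * zoom)
        if nr < 0 or nc < 0 or nr + nh > h or nc + nw > w:
            return None
        return ROI(nr, nc, nh, nw)
    raise ValueError(f"unknown transform {name!r}")


def _transform_pixels(px: np.ndarray, name: str, zoom: float) -> np.ndarray:
    if name == "identity":
        return px.copy()
    if name == "rot90":
        return np.rot90(px, 1).copy()
    if name == "rot180":
        return np.rot90(px, 2).copy()
    if name == "rot270":
        return np.rot90(px, 3).copy()
    if name == "hflip":
        return px[:, ::-1].copy()
    if name == "vflip":
        return px[::-1, :].copy()
    if name == "zoom":
        h, w = px.shape
        sh, sw = round(h * zoom), round(w * zoom)
        big = _sk_resize(px, (sh, sw), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
        top, left = (sh - h) // 2, (sw - w) // 2
        return np.clip(big[top:top + h, left:left + w], 0.0, 1.0)
    raise ValueError(f"unknown transform {name!r}")


AUGMENTATIONS = ("identity", "rot90", "rot180", "rot270",
                 "hflip", "vflip", "zoom")


def augment(pair: NoisyCleanPair, zoom: float = 1.25) -> list[NoisyCleanPair]:
    """The fixed 7-member augmentation family: identity, the three rotations,
    both flips, and a central zoom-crop.  The same transform is applied to
    the noisy image, the clean image, and the ROI boxes.  A ROI that the
    zoom-crop pushes outside the frame is dropped with a warning."""
    h, w = pair.noisy.shape
    out: list[NoisyCleanPair] = []
    for name in AUGMENTATIONS:
        rois = None
        if pair.rois is not None:
            sig = _transform_roi(pair.rois.signal, name, h, w, zoom)
            bg = _transform_roi(pair.rois.background, name, h, w, zoom)
            if sig is None or bg is None:
                logger.warning("augment %s on %s: ROI left the frame; "
                               "dropping ROIs", name, pair.clean.id)
            else:
                rois = ROIPair(signal=sig, background=bg)
        out.append(NoisyCleanPair(
            noisy=ImageRecord(id=f"{pair.noisy.id}_{name}",
                              pixels=_transform_pixels(pair.noisy.pixels,
                                                       name, zoom)),
            clean=ImageRecord(id=f"{pair.clean.id}_{name}",
                              pixels=_transform_pixels(pair.clean.pixels,
                                                       name, zoom)),
            rois=rois))
    return out


# -- patching ---------------------------------------------------------------


def extract_patches(image: ImageRecord | np.ndarray,
                    patch: int = 32) -> PatchGrid:
    """Tile an image into non-overlapping P x P patches (row-major order),
    edge-padding to the next multiple of P when needed."""
    px = image.pixels if isinstance(image, ImageRecord) else np.asarray(image)
    h, w = px.shape
    if patch > min(h, w):
        raise ValueError(f"patch size {patch} exceeds image {px.shape}")
    pad_r = (-h) % patch
    pad_c = (-w) % patch
    if pad_r or pad_c:
        px = np.pad(px, ((0, pad_r), (0, pad_c)), mode="edge")
    rows, cols = px.shape[0] // patch, px.shape[1] // patch
    tiles = px.reshape(rows, patch, cols, patch).transpose(0, 2, 1, 3)
    return PatchGrid(patches=tiles.reshape(rows * cols, patch * patch),
                     grid_shape=(rows, cols), patch=patch,
                     pad=(pad_r, pad_c))


def reassemble_patches(grid: PatchGrid, unpad: bool = True) -> np.ndarray:
    """Invert :func:`extract_patches` (drops any recorded padding)."""
    rows, cols = grid.grid_shape
    p = grid.patch
    img = (grid.patches.reshape(rows, cols, p, p)
           .transpose(0, 2, 1, 3).reshape(rows * p, cols * p))
    if unpad and (grid.pad[0] or grid.pad[1]):
        img = img[:rows * p - grid.pad[0], :cols * p - grid.pad[1]]
    return img


# -- splitting --------------------------------------------------------------


def split_dataset(pairs: Sequence[NoisyCleanPair],
                  ratios: tuple[float, float, float] = (0.60, 0.10, 0.30),
                  seed: int = 0) -> DatasetSplit:
    """Seeded random 60:10:30 split.  Train and validation sizes are
    floored; the test split receives the remainder."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs to split")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n_train = int(len(pairs) * ratios[0])
    n_val = int(len(pairs) * ratios[1])
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    return DatasetSplit(train=[pairs[i] for i in idx_train],
                        val=[pairs[i] for i in idx_val],
                        test=[pairs[i] for i in idx_test])


# -- manifests --------------------------------------------------------------


def write_manifest(split: DatasetSplit, root: str | Path,
                   path: str | Path) -> pd.DataFrame:
    """Write the (id, noisy_path, clean_path, roi_path, split) CSV manifest,
    saving every image/ROI under ``root``."""
    from .phantom import write_pair

    root = Path(root)
    records = []
    for split_name, items in (("train", split.train), ("val", split.val),
                              ("test", split.test)):
        for pair in items:
            stem = pair.clean.id.rsplit("_", 1)[0]
            write_pair(pair, root)
            records.append({
                "id": stem,
                "noisy_path": str(root / f"{stem}_noisy.png"),
                "clean_path": str(root / f"{stem}_clean.png"),
                "roi_path": str(root / f"{stem}_roi.json")
                if pair.rois is not None else "",
                "split": split_name,
            })
    df = pd.DataFrame.from_records(records)
    df.to_csv(path, index=False)
    return df


def load_manifest(path: str | Path) -> DatasetSplit:
    df = pd.read_csv(path, keep_default_na=False)
    buckets: dict[str, list[NoisyCleanPair]] = {"train": [], "val": [],
                                                "test": []}
    for rec in df.itertuples():
        rois = read_rois(rec.roi_path) if rec.roi_path else None
        buckets[rec.split].append(NoisyCleanPair(
            noisy=read_image(rec.noisy_path, id=f"{rec.id}_noisy"),
            clean=read_image(rec.clean_path, id=f"{rec.id}_clean"),
            rois=rois))
    return DatasetSplit(**buckets)
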