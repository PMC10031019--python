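"""Data processing (crop, resize, split) and shared I/O.

Scanner frames carry burned-in text outside the imaging sector; a
user-supplied :class:`CropBox` removes it, after which images are resized
to the working resolution (bilinear for images, nearest-neighbor for
masks so they stay binary).  Intensities are [0,1] floats everywhere in
memory and 8-bit grayscale PNG on disk; masks use {0,255} on disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize as _sk_resize

from .phantom import DomainDataset, ImageSample

__all__ = [
    "CropBox",
    "crop_to_content",
    "resize_image",
    "resize_mask",
    "split_train_test",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "save_dataset",
    "load_dataset",
    "load_config",
    "save_config",
    "write_metrics_table",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class CropBox:
    top: int
    left: int
    height: int
    width: int

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError(f"crop box must have positive size, got {self.height}x{self.width}")
        if self.top < 0 or self.left < 0:
            raise ValueError(f"crop box origin must be nonnegative, got ({self.top},{self.left})")


def crop_to_content(image: np.ndarray, box: CropBox) -> np.ndarray:
    """Exact sub-image; apply the same box to the mask to keep alignment."""
    h, w = image.shape[:2]
    if box.top + box.height > h or box.left + box.width > w:
        raise ValueError(
            f"crop box (top={box.top}, left={box.left}, height={box.height}, "
            f"width={box.width}) exceeds image bounds {h}x{w}"
        )
    return image[box.top : box.top + box.height, box.left : box.left + box.width].copy()


def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize to size x size, clipped to [0,1]."""
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    out = _sk_resize(np.asarray(image, dtype=np.float64), (size, size), order=1,
                     anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbor resize; stays binary."""
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    out = _sk_resize(np.asarray(mask, dtype=np.float64), (size, size), order=0,
                     anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def split_train_test(dataset: DomainDataset, test_count_or_fraction: Union[int, float],
                     seed: int = 0) -> DomainDataset:
    """Re-assign the train/test split by a seeded uniform draw."""
    n = len(dataset.samples)
    if isinstance(test_count_or_fraction, float) and 0.0 < test_count_or_fraction < 1.0:
        n_test = int(round(n * test_count_or_fraction))
    else:
        n_test = int(test_count_or_fraction)
    if not (0 < n_test < n):
        raise ValueError(f"test size {n_test} must be in (0, {n})")
    rng = np.random.default_rng(seed)
    test_idx = set(rng.permutation(n)[:n_test].tolist())
    split = ["test" if i in test_idx else "train" for i in range(n)]
    return DomainDataset(samples=dataset.samples, split=split, domain=dataset.domain)


# ---------------------------------------------------------------------------
# PNG round trips


def write_image(path: PathLike, image: np.ndarray) -> None:
    arr = np.asarray(image, dtype=np.float64)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"image values outside [0,1] cannot be written to {path}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), np.round(arr * 255.0).astype(np.uint8))


def read_image(path: PathLike) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr.astype(np.float32) / 255.0).astype(np.float32)


def write_mask(path: PathLike, mask: np.ndarray) -> None:
    m = np.asarray(mask)
    if not np.all(np.isin(np.unique(m), (0, 1))):
        raise ValueError(f"mask must be binary to be written to {path}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), (m.astype(np.uint8) * 255))


def read_mask(path: PathLike) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr >= 128).astype(np.uint8)


# ---------------------------------------------------------------------------
# dataset trees: <root>/<domain>/<split>/{images,masks}/<id>.png + manifest.csv


def save_dataset(root: PathLike, dataset: DomainDataset, seed: Optional[int] = None) -> None:
    root = Path(root)
    rows = []
    for sample, split in zip(dataset.samples, dataset.split):
        base = root / dataset.domain / split
        write_image(base / "images" / f"{sample.id}.png", sample.image)
        if sample.mask is not None:
            write_mask(base / "masks" / f"{sample.id}.png", sample.mask)
        rows.append({"id": sample.id, "domain": dataset.domain, "split": split,
                     "seed": "" if seed is None else seed})
    manifest = root / "manifest.csv"
    df = pd.DataFrame(rows, columns=["id", "domain", "split", "seed"])
    if manifest.exists():
        prev = pd.read_csv(manifest, dtype=str, keep_default_na=False)
        prev = prev[prev["domain"] != dataset.domain]
        df = pd.concat([prev, df.astype(str)], ignore_index=True)
    df.to_csv(manifest, index=False)


def load_dataset(root: PathLike, domain: str) -> DomainDataset:
    root = Path(root)
    manifest = root / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv under {root}")
    df = pd.read_csv(manifest, dtype=str, keep_default_na=False)
    df = df[df["domain"] == domain]
    if df.empty:
        raise ValueError(f"manifest has no rows for domain {domain!r}")
    samples, split = [], []
    for _, row in df.iterrows():
        base = root / domain / row["split"]
        img_path = base / "images" / f"{row['id']}.png"
        if not img_path.exists():
            raise FileNotFoundError(f"manifest names {img_path} but it does not exist")
        image = read_image(img_path)
        mask_path = base / "masks" / f"{row['id']}.png"
        mask = read_mask(mask_path) if mask_path.exists() else None
        if mask is not None and mask.shape != image.shape:
            raise ValueError(f"mask/image shape mismatch for {row['id']}")
        samples.append(ImageSample(image=image, mask=mask, domain=domain, id=row["id"]))
        split.append(row["split"])
    return DomainDataset(samples=samples, split=split, domain=domain)


# ---------------------------------------------------------------------------
# configs and tables


def load_config(path: PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def save_config(path: PathLike, config: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def write_metrics_table(path: PathLike, table: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.6f")
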