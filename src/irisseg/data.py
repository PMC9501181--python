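"""Dataset discovery, preprocessing and the seeded 7:1:2 split.

Images (PNG/JPEG/BMP) live in ``<data_dir>/images`` with a same-stem PNG
mask in ``<data_dir>/masks``.  Loading resizes images bilinearly to the
network input size, scales to [0, 1] and replicates grayscale to three
channels; masks are resized by nearest neighbour and binarized at >127.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .nn import DimensionError

__all__ = ["SamplePair", "DatasetSplits", "discover_pairs", "load_image",
           "load_mask", "split_indices", "load_dataset"]

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".bmp")


@dataclass(frozen=True)
class SamplePair:
    image_path: Path
    mask_path: Path


@dataclass
class DatasetSplits:
    """Preprocessed train/val/test arrays (images NCHW, masks NHW)."""

    train_images: np.ndarray
    train_masks: np.ndarray
    val_images: np.ndarray
    val_masks: np.ndarray
    test_images: np.ndarray
    test_masks: np.ndarray
    test_pairs: list


def discover_pairs(data_dir) -> list:
    """List image/mask pairs; missing masks raise with the files named."""
    root = Path(data_dir)
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no images directory under {root}")
    images = sorted(p for p in img_dir.iterdir()
                    if p.suffix.lower() in IMAGE_EXTENSIONS)
    if not images:
        raise FileNotFoundError(f"no images found in {img_dir}")
    pairs, missing = [], []
    for img in images:
        mask = mask_dir / (img.stem + ".png")
        if mask.exists():
            pairs.append(SamplePair(img, mask))
        else:
            missing.append(str(img))
    if missing:
        raise FileNotFoundError(
            "images without a same-stem mask: " + ", ".join(missing))
    return pairs


def load_image(path, input_size: int) -> np.ndarray:
    """(3, S, S) float32 in [0, 1]; grayscale replicated to 3 channels."""
    with Image.open(path) as im:
        gray = im.mode in ("L", "I", "I;16", "1")
        im = im.convert("L" if gray else "RGB")
        im = im.resize((input_size, input_size), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float32) / 255.0
    if arr.ndim == 2:
        arr = np.repeat(arr[None], 3, axis=0)
    else:
        arr = arr.transpose(2, 0, 1)
    return arr


def load_mask(path, input_size: int) -> np.ndarray:
    """(S, S) uint8 {0, 1}, nearest-neighbour resized, binarized at >127."""
    with Image.open(path) as im:
        im = im.convert("L").resize((input_size, input_size), Image.NEAREST)
        return (np.asarray(im) > 127).astype(np.uint8)


def split_indices(n: int, fractions=(0.7, 0.1, 0.2), seed: int = 0):
    """Seeded shuffle split; floor for train and val, remainder to test."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    return (perm[:n_train], perm[n_train:n_train + n_val],
            perm[n_train + n_val:])


def load_dataset(data_dir, input_size: int = 224, fractions=(0.7, 0.1, 0.2),
                 seed: int = 0) -> DatasetSplits:
    pairs = discover_pairs(data_dir)
    images = np.stack([load_image(p.image_path, input_size) for p in pairs])
    masks = np.stack([load_mask(p.mask_path, input_size) for p in pairs])
    tr, va, te = split_indices(len(pairs), fractions, seed)
    return DatasetSplits(
        train_images=images[tr], train_masks=masks[tr],
        val_images=images[va], val_masks=masks[va],
        test_images=images[te], test_masks=masks[te],
        test_pairs=[pairs[i] for i in te])
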