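"""Image and color-mask I/O, tiling, and dataset splitting.

Masks are color-coded PNGs — red (255,0,0) for crop, green (0,255,0) for
vacancy, black (0,0,0) for background — and converted to/from class-index
arrays with the fixed convention 0=background, 1=crop, 2=vacancy, which the
loss-weight ordering also follows.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image

#: class index -> reference mask color, in class order (background, crop, vacancy)
CLASS_COLORS = np.array([[0, 0, 0], [255, 0, 0], [0, 255, 0]], dtype=np.uint8)
CLASS_NAMES = ("background", "crop", "vacancy")
NUM_CLASSES = 3


class MaskColorError(ValueError):
    """A mask pixel is not close to any of the three reference colors."""


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG as an H×W×3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(arr: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(arr, dtype=np.uint8)).save(path)


def load_mask(path, tolerance: int = 0) -> np.ndarray:
    return decode_color_mask(load_image(path), tolerance=tolerance)


def save_mask(mask: np.ndarray, path) -> None:
    save_image(encode_color_mask(mask), path)


def decode_color_mask(img: np.ndarray, tolerance: int = 0) -> np.ndarray:
    """Map a color-coded mask image to class indices {0,1,2}.

    A pixel is assigned the class whose reference color it matches within
    `tolerance` (Chebyshev distance per channel).  Any pixel matching no
    reference color raises :class:`MaskColorError` naming the first
    offending coordinate in row-major order.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 image, got shape {img.shape}")
    # Chebyshev distance to each reference color: (H, W, 3 classes)
    dist = np.abs(img[:, :, None, :].astype(np.int16)
                  - CLASS_COLORS[None, None, :, :].astype(np.int16)).max(axis=3)
    nearest = dist.argmin(axis=2)
    ok = np.take_along_axis(dist, nearest[:, :, None], axis=2)[:, :, 0] <= tolerance
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise MaskColorError(
            f"pixel at (row={r}, col={c}) has color {tuple(img[r, c])}, not within "
            f"tolerance {tolerance} of the reference colors (black/red/green)")
    return nearest.astype(np.uint8)


def encode_color_mask(mask: np.ndarray) -> np.ndarray:
    """Inverse of :func:`decode_color_mask` at tolerance 0."""
    mask = np.asarray(mask)
    if mask.min(initial=0) < 0 or mask.max(initial=0) > 2:
        bad = mask[(mask < 0) | (mask > 2)].flat[0]
        raise ValueError(f"mask contains label {bad} outside {{0,1,2}}")
    return CLASS_COLORS[mask.astype(np.intp)]


def tile_quarters(img: np.ndarray) -> list[np.ndarray]:
    """Split an even-sized image (or mask) into its four quadrants, row-major."""
    img = np.asarray(img)
    h, w = img.shape[:2]
    if h % 2 or w % 2:
        raise ValueError(f"tile_quarters needs even dimensions, got {h}×{w}")
    hh, hw = h // 2, w // 2
    return [img[:hh, :hw], img[:hh, hw:], img[hh:, :hw], img[hh:, hw:]]


def mosaic_quarters(tiles) -> np.ndarray:
    """Reassemble the four quadrants produced by :func:`tile_quarters`."""
    tl, tr, bl, br = (np.asarray(t) for t in tiles)
    return np.concatenate([np.concatenate([tl, tr], axis=1),
                           np.concatenate([bl, br], axis=1)], axis=0)


@dataclass(frozen=True)
class ManifestEntry:
    image: str
    mask: str
    split: str  # train | val | test


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry]
    split_seed: int

    def paths(self, split: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == split]

    def save(self, path) -> None:
        payload = {"split_seed": self.split_seed,
                   "entries": [asdict(e) for e in self.entries]}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        payload = json.loads(Path(path).read_text())
        return cls(entries=[ManifestEntry(**e) for e in payload["entries"]],
                   split_seed=payload["split_seed"])


def apportion(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n items by the given ratios."""
    total = float(sum(ratios))
    quotas = [n * r / total for r in ratios]
    sizes = [int(q) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    for i in sorted(range(len(ratios)), key=lambda i: -remainders[i])[: n - sum(sizes)]:
        sizes[i] += 1
    return sizes


def split_dataset(items, ratios=(8, 1, 2), seed: int = 0) -> DatasetManifest:
    """Shuffle (image, mask) pairs and partition them into train/val/test.

    Partition sizes follow largest-remainder apportionment of the ratio, so
    110 items at 8:1:2 give exactly 80/10/20.  Deterministic given `seed`.
    """
    items = list(items)
    if not items:
        raise ValueError("cannot split an empty item list")
    if any(r <= 0 for r in ratios) or len(ratios) != 3:
        raise ValueError(f"ratios must be three positive numbers, got {ratios}")
    n_train, n_val, n_test = apportion(len(items), tuple(ratios))
    order = np.random.default_rng(seed).permutation(len(items))
    tags = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    entries = [None] * len(items)
    for rank, idx in enumerate(order):
        img, msk = items[idx]
        entries[idx] = ManifestEntry(image=str(img), mask=str(msk), split=tags[rank])
    return DatasetManifest(entries=entries, split_seed=seed)
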