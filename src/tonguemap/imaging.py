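"""Image I/O, grid tiling and patch geometry.

Tongue-surface photographs are analysed tile-by-tile: a photograph is cut
into a grid of square-ish crop regions, each crop is resized to the
classifier's 96x96 input and optionally augmented by flips and a 90-degree
rotation.  Two tilings exist:

* :func:`grid_crop` — a non-overlapping partition used to build labeled
  patch datasets (e.g. 8x12 pieces of a 2592x3872 photograph give
  324x323-pixel crops);
* :func:`overlapping_grid` — a denser, partially overlapping grid
  (typically 16x24 = 384 tiles per photograph) used at inference time so
  the resulting point map samples the surface finely.

Coordinates are 0-based with half-open ``[x0, x0 + crop_w)`` pixel
intervals; regions are returned in row-major order (row varies slowest).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

PATCH_SIZE = 96
AUGMENTATION_TAGS = ("identity", "hflip", "vflip", "rot90")


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves rounded up.

    Used for crop dimensions so that e.g. 3872 / 12 = 322.67 -> 323,
    whereas floor division would give 322.
    """
    return int(math.floor(x + 0.5))


def validate_image(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB array, got shape {pixels.shape}")
    if pixels.shape[0] < 1 or pixels.shape[1] < 1:
        raise ValueError("zero-area image")
    return pixels


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a JPEG/PNG file as an HxWx3 uint8 array.

    Grayscale inputs are replicated to 3 channels; an alpha channel is
    dropped.
    """
    pixels = iio.imread(path)
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    elif pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    pixels = np.ascontiguousarray(pixels, dtype=np.uint8)
    return validate_image(pixels)


def save_image(path: str | os.PathLike, pixels: np.ndarray) -> None:
    iio.imwrite(path, validate_image(pixels).astype(np.uint8))


@dataclass(frozen=True)
class CropRegion:
    """One grid cell: 0-based (col, row) index and pixel footprint."""

    col_index: int
    row_index: int
    x0: int
    y0: int
    crop_w: int
    crop_h: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y0, self.y0 + self.crop_h),
                slice(self.x0, self.x0 + self.crop_w))

    @property
    def center(self) -> tuple[float, float]:
        """Pixel-coordinate center (x, y) of the footprint."""
        return (self.x0 + (self.crop_w - 1) / 2.0,
                self.y0 + (self.crop_h - 1) / 2.0)

    @property
    def area(self) -> int:
        return self.crop_w * self.crop_h


@dataclass(frozen=True)
class GridSpec:
    """Tiling parameters. ``crop_w``/``crop_h`` are required when overlapping."""

    n_cols: int
    n_rows: int
    overlapping: bool = False
    crop_w: int | None = None
    crop_h: int | None = None

    def __post_init__(self):
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one row and one column")

    def regions(self, image: np.ndarray) -> list[CropRegion]:
        if self.overlapping:
            return overlapping_grid(image, self)
        return grid_crop(image, self.n_cols, self.n_rows)


def default_overlap_crop_size(width: int, height: int) -> tuple[int, int]:
    """Crop size for the overlapping inference grid.

    Matches the whole-tongue training grid (12 columns x 15 rows), so
    inference tiles have the same magnification as training patches.
    """
    return round_half_up(width / 12), round_half_up(height / 15)


def grid_crop(image: np.ndarray, n_cols: int, n_rows: int) -> list[CropRegion]:
    """Partition an image into an ``n_cols`` x ``n_rows`` grid.

    Nominal crop dimensions are ``round_half_up(width / n_cols)`` by
    ``round_half_up(height / n_rows)``; the final column/row is clipped
    (shrunk or extended) to the image border so the union of regions
    covers every pixel exactly once.
    """
    image = validate_image(image)
    h, w = image.shape[:2]
    if n_cols < 1 or n_rows < 1:
        raise ValueError("n_cols and n_rows must be >= 1")
    if n_cols > w or n_rows > h:
        raise ValueError("grid finer than the image")
    crop_w = round_half_up(w / n_cols)
    crop_h = round_half_up(h / n_rows)
    regions = []
    for i in range(n_rows):
        y0 = i * crop_h
        ch = (h - y0) if i == n_rows - 1 else crop_h
        for j in range(n_cols):
            x0 = j * crop_w
            cw = (w - x0) if j == n_cols - 1 else crop_w
            regions.append(CropRegion(j, i, x0, y0, cw, ch))
    return regions


def overlapping_grid(image: np.ndarray, spec: GridSpec) -> list[CropRegion]:
    """Evenly spaced, partially overlapping grid of fixed-size crops.

    Crop origins are ``x0(j) = round(j * (width - crop_w) / (n_cols - 1))``
    (and analogously in y), so the first region sits at (0, 0) and the last
    is flush with the bottom-right corner.  Adjacent regions overlap
    whenever ``n_cols * crop_w > width``.
    """
    image = validate_image(image)
    h, w = image.shape[:2]
    crop_w, crop_h = spec.crop_w, spec.crop_h
    if crop_w is None or crop_h is None:
        crop_w, crop_h = default_overlap_crop_size(w, h)
    if crop_w > w or crop_h > h:
        raise ValueError("crop larger than the image")
    if crop_w < 1 or crop_h < 1:
        raise ValueError("crop dimensions must be positive")

    def origins(n: int, extent: int, crop: int) -> list[int]:
        if n == 1:
            return [0]
        stride = (extent - crop) / (n - 1)
        return [round_half_up(k * stride) for k in range(n)]

    xs = origins(spec.n_cols, w, crop_w)
    ys = origins(spec.n_rows, h, crop_h)
    return [CropRegion(j, i, x0, y0, crop_w, crop_h)
            for i, y0 in enumerate(ys) for j, x0 in enumerate(xs)]


def extract(image: np.ndarray, region: CropRegion) -> np.ndarray:
    """Pixel footprint of a region (a view, not a copy)."""
    return image[region.slices]


def resize_patch(pixels: np.ndarray, size: int = PATCH_SIZE) -> np.ndarray:
    """Bilinear resize to ``size`` x ``size``; identity inputs pass through bitwise."""
    pixels = validate_image(pixels)
    if pixels.shape[0] == size and pixels.shape[1] == size:
        return pixels.copy()
    out = _sk_resize(pixels.astype(np.float64), (size, size, 3), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def apply_augmentation(pixels: np.ndarray, tag: str) -> np.ndarray:
    if tag == "identity":
        return pixels.copy()
    if tag == "hflip":
        return pixels[:, ::-1].copy()
    if tag == "vflip":
        return pixels[::-1, :].copy()
    if tag == "rot90":
        return np.rot90(pixels).copy()
    raise ValueError(f"unknown augmentation tag {tag!r}")


@dataclass(frozen=True)
class Patch:
    """A 96x96 RGB tile with its source-region provenance."""

    image: np.ndarray
    region: CropRegion
    source_id: str
    augmentation_tag: str = "identity"

    def __post_init__(self):
        img = validate_image(self.image)
        if img.shape[:2] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError("patches must be 96x96 (resize before constructing)")


def make_patch(image: np.ndarray, region: CropRegion, source_id: str) -> Patch:
    """Extract a region from a photograph and resize it to the patch size."""
    return Patch(resize_patch(extract(image, region)), region, source_id)


def augment(patch: Patch) -> list[Patch]:
    """Return the four label-preserving variants of a patch.

    Horizontal flip, vertical flip and a single 90-degree rotation, plus
    the identity — the x4 multiplicity applied to training data.
    """
    return [replace(patch, image=apply_augmentation(patch.image, tag),
                    augmentation_tag=tag)
            for tag in AUGMENTATION_TAGS]


def regions_to_frame(regions: Sequence[CropRegion], source_id: str = "") -> pd.DataFrame:
    """Region list as a table (exportable to CSV)."""
    return pd.DataFrame(
        [{"source_id": source_id, "row": r.row_index, "col": r.col_index,
          "x0": r.x0, "y0": r.y0, "w": r.crop_w, "h": r.crop_h}
         for r in regions])
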