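"""Point-mapping segmentation.

Instead of pixel-dense semantic segmentation, the whole-surface photograph
is tiled with a partially overlapping grid (typically 16x24 = 384 tiles),
every tile is classified, and a class-colored dot is drawn at each tile's
center: blue for abnormal mucosa, green for normal, red for other.  The
grid of per-tile labels (with softmax confidences) is the segmentation —
a :class:`PointMap`.  A matching ground-truth point map is built from the
expert's pixel mask by giving each grid cell the plurality class of its
footprint, the same support the classifier sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ClassLabel, LabelMask, N_CLASSES, label_region
from .imaging import (CropRegion, GridSpec, extract, overlapping_grid,
                      resize_patch, validate_image)


@dataclass(frozen=True)
class PointRecord:
    """One grid point: cell index, pixel anchor, class and confidence."""

    col_index: int
    row_index: int
    center_x: float
    center_y: float
    label: ClassLabel
    probs: np.ndarray | None = None  # length-3 softmax; None for ground truth


@dataclass(frozen=True)
class PointMap:
    """A complete n_cols x n_rows grid of classified points."""

    source_id: str
    grid: GridSpec
    points: tuple[PointRecord, ...]  # row-major
    image_shape: tuple[int, int]  # (height, width)

    def __post_init__(self):
        if len(self.points) != self.grid.n_cols * self.grid.n_rows:
            raise ValueError("point map must cover the full grid")

    @property
    def labels(self) -> np.ndarray:
        """(n_rows, n_cols) array of class codes."""
        return np.array([int(p.label) for p in self.points]).reshape(
            self.grid.n_rows, self.grid.n_cols)

    @property
    def probs(self) -> np.ndarray | None:
        if self.points[0].probs is None:
            return None
        return np.stack([p.probs for p in self.points]).reshape(
            self.grid.n_rows, self.grid.n_cols, N_CLASSES)

    def class_points(self, label: ClassLabel) -> set[tuple[int, int]]:
        """Grid coordinates (row, col) predicted/labeled as ``label``."""
        return {(p.row_index, p.col_index) for p in self.points
                if p.label == label}


@dataclass(frozen=True)
class RenderSpec:
    """Dot colors and geometry for the overlay rendering."""

    colors: dict = field(default_factory=lambda: {
        ClassLabel.ABNORMAL: (0, 0, 255),   # blue
        ClassLabel.NORMAL: (0, 255, 0),     # green
        ClassLabel.OTHER: (255, 0, 0),      # red
    })
    dot_radius: int = 5
    opacity: float = 1.0

    def __post_init__(self):
        if len({tuple(c) for c in self.colors.values()}) != N_CLASSES:
            raise ValueError("the three class colors must be distinct")
        if not 0.0 <= self.opacity <= 1.0:
            raise ValueError("opacity must be in [0, 1]")


def _grid_regions(image_shape: tuple[int, int], spec: GridSpec) -> list[CropRegion]:
    dummy = np.zeros(image_shape + (3,), dtype=np.uint8)
    return overlapping_grid(dummy, spec)


def predict_pointmap(image: np.ndarray, classifier, spec: GridSpec,
                     source_id: str = "") -> PointMap:
    """Classify every tile of an overlapping grid into a :class:`PointMap`.

    ``classifier`` is either a fitted patch estimator (``predict_proba`` on
    stacked 96x96x3 patches) or a region-aware oracle exposing
    ``predict_regions``.
    """
    image = validate_image(image)
    if not spec.overlapping:
        raise ValueError("point mapping requires an overlapping GridSpec")
    regions = overlapping_grid(image, spec)
    if hasattr(classifier, "predict_regions"):
        labels, probs = classifier.predict_regions(regions)
    else:
        X = np.stack([resize_patch(extract(image, r)) for r in regions])
        probs = classifier.predict_proba(X)
        labels = np.argmax(probs, axis=1)  # first max: ABNORMAL>NORMAL>OTHER
    points = tuple(
        PointRecord(r.col_index, r.row_index, *r.center,
                    ClassLabel(int(lab)), np.asarray(p, dtype=float))
        for r, lab, p in zip(regions, labels, probs))
    return PointMap(source_id, spec, points, image.shape[:2])


def ground_truth_pointmap(mask: LabelMask, spec: GridSpec,
                          source_id: str = "") -> PointMap:
    """Point map of plurality mask classes over each grid-cell footprint."""
    if not spec.overlapping:
        raise ValueError("point mapping requires an overlapping GridSpec")
    regions = _grid_regions(mask.shape, spec)
    points = tuple(
        PointRecord(r.col_index, r.row_index, *r.center, label_region(mask, r))
        for r in regions)
    return PointMap(source_id or mask.source_id, spec, points, mask.shape)


def render_pointmap(image: np.ndarray, pmap: PointMap,
                    spec: RenderSpec | None = None) -> np.ndarray:
    """Draw one class-colored dot per grid point onto a copy of the image."""
    spec = spec or RenderSpec()
    image = validate_image(image)
    if image.shape[:2] != pmap.image_shape:
        raise ValueError("point map does not belong to this image")
    out = image.astype(np.float64).copy()
    h, w = out.shape[:2]
    rad = spec.dot_radius
    yy, xx = np.mgrid[-rad:rad + 1, -rad:rad + 1]
    disk = (xx ** 2 + yy ** 2) <= rad ** 2
    for p in pmap.points:
        cx, cy = int(round(p.center_x)), int(round(p.center_y))
        color = np.array(spec.colors[p.label], dtype=np.float64)
        y0, y1 = max(cy - rad, 0), min(cy + rad + 1, h)
        x0, x1 = max(cx - rad, 0), min(cx + rad + 1, w)
        sub = disk[y0 - (cy - rad):y1 - (cy - rad), x0 - (cx - rad):x1 - (cx - rad)]
        region = out[y0:y1, x0:x1]
        region[sub] = (1 - spec.opacity) * region[sub] + spec.opacity * color
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def pointmap_to_frame(pmap: PointMap) -> pd.DataFrame:
    rows = []
    for p in pmap.points:
        row = {"source_id": pmap.source_id, "row": p.row_index,
               "col": p.col_index, "center_x": p.center_x,
               "center_y": p.center_y, "label": p.label.name.lower()}
        if p.probs is not None:
            row.update(p_abnormal=p.probs[0], p_normal=p.probs[1],
                       p_other=p.probs[2])
        rows.append(row)
    return pd.DataFrame(rows)


def save_pointmap(pmap: PointMap, path: str | Path) -> None:
    pointmap_to_frame(pmap).to_csv(path, index=False)


def load_pointmap(path: str | Path, grid: GridSpec,
                  image_shape: tuple[int, int]) -> PointMap:
    frame = pd.read_csv(path)
    has_probs = "p_abnormal" in frame.columns
    points = []
    for r in frame.sort_values(["row", "col"]).itertuples():
        probs = (np.array([r.p_abnormal, r.p_normal, r.p_other])
                 if has_probs else None)
        points.append(PointRecord(int(r.col), int(r.row), float(r.center_x),
                                  float(r.center_y),
                                  ClassLabel[r.label.upper()], probs))
    source = str(frame["source_id"].iloc[0]) if len(frame) else ""
    return PointMap(source, grid, tuple(points), tuple(image_shape))
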