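"""Labeled patch datasets: masks, labels, splits and manifests.

Ground truth arrives as a color-painted annotation image: regions of the
photograph painted blue mark abnormal mucosa, green marks normal mucosa,
and unpainted pixels (background, teeth, lips) are "other".
:func:`mask_from_colors` converts such an annotation into a per-pixel
:class:`LabelMask`; :func:`label_region` summarizes a crop's footprint into
a single class by plurality vote.  :func:`assign_splits` produces
photograph-grouped, class-stratified train/validation/test splits so crops
from one photograph never leak across splits.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import CropRegion, Patch, save_image, validate_image


class ClassLabel(enum.IntEnum):
    """The three patch classes, in canonical tie-break / matrix order."""

    ABNORMAL = 0
    NORMAL = 1
    OTHER = 2


CLASS_NAMES = tuple(c.name.lower() for c in ClassLabel)
N_CLASSES = len(ClassLabel)

#: Annotation paint colors: blue marks abnormal mucosa, green normal mucosa.
ANNOTATION_COLORS: dict[ClassLabel, tuple[int, int, int]] = {
    ClassLabel.ABNORMAL: (0, 0, 255),
    ClassLabel.NORMAL: (0, 255, 0),
}

#: Ten recognised abnormality categories (tongue-coating through artifacts).
ABNORMALITY_TAGS = (
    "tongue_coating", "hairy_tongue", "fissures", "papillary_atrophy",
    "erosion", "ulcer", "lichenoid_change", "hyperkeratotic_change",
    "papillary_hypertrophy", "artifacts",
)

SPLITS = ("train", "valid", "test")


@dataclass(frozen=True)
class LabelMask:
    """Per-pixel 3-class ground truth for one photograph."""

    classes: np.ndarray  # HxW uint8 of ClassLabel codes
    source_id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.classes)
        if arr.ndim != 2:
            raise ValueError("mask must be a 2-D array of class codes")
        if arr.size and arr.max() >= N_CLASSES:
            raise ValueError("mask contains codes outside the 3-class vocabulary")
        object.__setattr__(self, "classes", arr.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape


def mask_from_colors(annotation: np.ndarray, tolerance: float = 60.0,
                     photo_shape: tuple[int, int] | None = None,
                     source_id: str = "") -> LabelMask:
    """Decode a painted annotation image into a :class:`LabelMask`.

    Pixels within Euclidean RGB distance ``tolerance`` of pure blue become
    ABNORMAL, of pure green NORMAL; everything else is OTHER.  The default
    tolerance absorbs JPEG compression of painted annotations.  When a pixel
    is within tolerance of both paints, the smaller distance wins (ties go
    to ABNORMAL).
    """
    annotation = validate_image(annotation)
    if photo_shape is not None and annotation.shape[:2] != tuple(photo_shape):
        raise ValueError(
            f"annotation shape {annotation.shape[:2]} does not match the "
            f"photograph {tuple(photo_shape)}")
    rgb = annotation.astype(np.float64)
    d_blue = np.linalg.norm(rgb - np.array(ANNOTATION_COLORS[ClassLabel.ABNORMAL]), axis=-1)
    d_green = np.linalg.norm(rgb - np.array(ANNOTATION_COLORS[ClassLabel.NORMAL]), axis=-1)
    classes = np.full(annotation.shape[:2], ClassLabel.OTHER, dtype=np.uint8)
    classes[(d_green <= tolerance) & (d_green < d_blue)] = ClassLabel.NORMAL
    classes[(d_blue <= tolerance) & (d_blue <= d_green)] = ClassLabel.ABNORMAL
    return LabelMask(classes, source_id=source_id)


def render_mask(mask: LabelMask) -> np.ndarray:
    """Render a mask back to the canonical paint colors (OTHER = black)."""
    out = np.zeros(mask.shape + (3,), dtype=np.uint8)
    for label, color in ANNOTATION_COLORS.items():
        out[mask.classes == label] = color
    return out


def label_region(mask: LabelMask, region: CropRegion) -> ClassLabel:
    """Plurality class over a region's pixel footprint.

    Ties break by class order ABNORMAL > NORMAL > OTHER — conservative
    toward flagging pathology.
    """
    h, w = mask.shape
    if (region.x0 < 0 or region.y0 < 0 or region.x0 + region.crop_w > w
            or region.y0 + region.crop_h > h):
        raise ValueError("region extends outside the mask")
    footprint = mask.classes[region.slices]
    if footprint.size == 0:
        raise ValueError("empty region")
    counts = np.bincount(footprint.ravel(), minlength=N_CLASSES)
    return ClassLabel(int(np.argmax(counts)))  # argmax -> first max: tie-break order


def tongue_fraction(mask: LabelMask, region: CropRegion) -> float:
    """Fraction of a region's footprint on the tongue (ABNORMAL or NORMAL)."""
    footprint = mask.classes[region.slices]
    if footprint.size == 0:
        raise ValueError("empty region")
    return float(np.mean(footprint != ClassLabel.OTHER))


@dataclass(frozen=True)
class PatchRecord:
    """A labeled patch with its split assignment."""

    patch: Patch
    label: ClassLabel
    split: str = "train"
    source_id: str = ""

    def __post_init__(self):
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}")
        if not self.source_id:
            object.__setattr__(self, "source_id", self.patch.source_id)


def is_boundary_region(mask: LabelMask, region: CropRegion,
                       min_tongue_fraction: float = 0.5) -> bool:
    """True when a crop straddles the tongue boundary (mostly off-tongue)."""
    return tongue_fraction(mask, region) < min_tongue_fraction


def apply_exclusion_filters(records: Sequence[PatchRecord],
                            masks: Mapping[str, LabelMask],
                            source_kind: Mapping[str, str] | None = None,
                            min_tongue_fraction: float = 0.5,
                            drop_boundary: bool = True) -> list[PatchRecord]:
    """Optional dataset curation filters.

    Drops tongue-boundary crops (footprint under ``min_tongue_fraction``
    tongue pixels), normal-labeled crops from patient photographs and
    abnormal-labeled crops from healthy-subject photographs.  ``source_kind``
    maps source_id to ``"patient"`` or ``"healthy"``; sources missing from
    the mapping are kept unfiltered.
    """
    kept = []
    for rec in records:
        mask = masks.get(rec.source_id)
        if drop_boundary and mask is not None and rec.label != ClassLabel.OTHER \
                and is_boundary_region(mask, rec.patch.region, min_tongue_fraction):
            continue
        kind = (source_kind or {}).get(rec.source_id)
        if kind == "patient" and rec.label == ClassLabel.NORMAL:
            continue
        if kind == "healthy" and rec.label == ClassLabel.ABNORMAL:
            continue
        kept.append(rec)
    return kept


def assign_splits(records: Sequence[PatchRecord],
                  fractions: tuple[float, float, float] = (0.688, 0.154, 0.158),
                  seed: int = 0) -> list[PatchRecord]:
    """Photograph-grouped, class-stratified split assignment.

    All patches from one source photograph land in the same split (a
    leakage guard), and within that constraint a greedy allocator keeps the
    per-class counts of each split close to the requested fractions.
    Deterministic given ``seed``.
    """
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ValueError("split fractions must sum to 1")
    if not records:
        return []
    class_totals = Counter(rec.label for rec in records)
    for label in ClassLabel:
        if class_totals[label] == 0:
            raise ValueError(f"no records of class {label.name}")

    groups: dict[str, list[int]] = {}
    for idx, rec in enumerate(records):
        groups.setdefault(rec.source_id, []).append(idx)
    group_ids = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(group_ids)

    targets = np.outer(np.asarray(fractions),
                       [class_totals[c] for c in ClassLabel])  # (split, class)
    assigned = np.zeros_like(targets)
    split_of_group: dict[str, int] = {}
    for gid in group_ids:
        gcounts = np.bincount([records[i].label for i in groups[gid]],
                              minlength=N_CLASSES)
        deficits = targets - assigned
        # fraction of this group's records that still "fit" into each split
        scores = np.minimum(np.maximum(deficits, 0.0), gcounts).sum(axis=1)
        s = int(np.argmax(scores))  # ties -> train, valid, test order
        split_of_group[gid] = s
        assigned[s] += gcounts

    return [replace(rec, split=SPLITS[split_of_group[rec.source_id]])
            for rec in records]


def dataset_summary(records: Sequence[PatchRecord]) -> pd.DataFrame:
    """Per-class, per-split count table (classes as rows, plus a Total row)."""
    table = pd.DataFrame(0, index=[c.name.lower() for c in ClassLabel] + ["total"],
                         columns=["total", *SPLITS], dtype=int)
    for rec in records:
        name = rec.label.name.lower()
        table.loc[name, "total"] += 1
        table.loc[name, rec.split] += 1
    table.loc["total"] = table.iloc[:-1].sum(axis=0)
    return table


def records_to_arrays(records: Sequence[PatchRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack records into classifier inputs: (n, 96, 96, 3) uint8 and (n,) labels."""
    X = np.stack([rec.patch.image for rec in records])
    y = np.array([int(rec.label) for rec in records], dtype=np.int64)
    return X, y


def save_patch_dataset(records: Iterable[PatchRecord], out_dir: str | Path) -> pd.DataFrame:
    """Persist patches as PNGs plus a CSV manifest; returns the manifest."""
    out_dir = Path(out_dir)
    (out_dir / "patches").mkdir(parents=True, exist_ok=True)
    rows = []
    for k, rec in enumerate(records):
        rel = f"patches/{rec.source_id}_{rec.patch.region.row_index:03d}_" \
              f"{rec.patch.region.col_index:03d}_{rec.patch.augmentation_tag}_{k}.png"
        save_image(out_dir / rel, rec.patch.image)
        rows.append({"patch_path": rel, "label": rec.label.name.lower(),
                     "split": rec.split, "source_id": rec.source_id,
                     "row": rec.patch.region.row_index,
                     "col": rec.patch.region.col_index,
                     "x0": rec.patch.region.x0, "y0": rec.patch.region.y0,
                     "w": rec.patch.region.crop_w, "h": rec.patch.region.crop_h,
                     "augmentation": rec.patch.augmentation_tag})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_patch_dataset(out_dir: str | Path) -> list[PatchRecord]:
    """Inverse of :func:`save_patch_dataset`."""
    from .imaging import load_image

    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "manifest.csv")
    records = []
    for row in manifest.itertuples():
        region = CropRegion(int(row.col), int(row.row), int(row.x0), int(row.y0),
                            int(row.w), int(row.h))
        patch = Patch(load_image(out_dir / row.patch_path), region,
                      str(row.source_id), str(row.augmentation))
        records.append(PatchRecord(patch, ClassLabel[row.label.upper()],
                                   str(row.split), str(row.source_id)))
    return records
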