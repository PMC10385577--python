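"""Procedural tongue-like test imagery with exact per-pixel masks.

No clinical photograph archive accompanies this package, so every pipeline
stage is exercised on generated scenes: a roughly elliptical "tongue"
against a dark background, normal mucosa rendered as a quasi-regular
bright-dot lattice on a pink base (a papillae surrogate), and abnormal
patches carrying one of the recognised abnormality textures — smooth
reddish atrophy, dark curvilinear fissure grooves, bright low-saturation
keratotic plaques, speckled whitish coating, and coarser surrogates for
the remaining categories.  Textures are parametric and simple on purpose:
the test surface needs controllable class separability and pixel-exact
masks, not photorealism.

All randomness flows from a single seed through per-component spawn keys,
so each sub-region of a scene is reproducible independently and
``generate_scene`` is bitwise deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (ABNORMALITY_TAGS, ClassLabel, LabelMask, PatchRecord,
                      label_region, render_mask)
from .imaging import PATCH_SIZE, CropRegion, Patch, grid_crop, save_image


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Child generator for one scene component (counter-style spawning)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass(frozen=True)
class Ellipse:
    cx: float
    cy: float
    ax: float
    ay: float

    def mask(self, height: int, width: int) -> np.ndarray:
        yy, xx = np.ogrid[:height, :width]
        return (((xx - self.cx) / self.ax) ** 2
                + ((yy - self.cy) / self.ay) ** 2) <= 1.0


@dataclass(frozen=True)
class AbnormalPatch:
    """One abnormal region: a shape plus an abnormality texture tag."""

    tag: str
    shape: str = "ellipse"  # ellipse | rect
    # ellipse: (cx, cy, ax, ay); rect: (x0, y0, x1, y1) half-open
    geometry: tuple[float, float, float, float] = (0, 0, 0, 0)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tag not in ABNORMALITY_TAGS:
            raise ValueError(f"unknown abnormality tag {self.tag!r}")
        if self.shape not in ("ellipse", "rect"):
            raise ValueError("shape must be 'ellipse' or 'rect'")

    def mask(self, height: int, width: int) -> np.ndarray:
        if self.shape == "ellipse":
            cx, cy, ax, ay = self.geometry
            return Ellipse(cx, cy, ax, ay).mask(height, width)
        x0, y0, x1, y1 = self.geometry
        out = np.zeros((height, width), dtype=bool)
        out[int(y0):int(y1), int(x0):int(x1)] = True
        return out


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene."""

    width: int = 576
    height: int = 864
    seed: int = 0
    tongue: Ellipse | None = None  # None -> default centered ellipse
    no_tongue: bool = False
    patches: tuple[AbnormalPatch, ...] = ()
    dot_spacing: float = 9.0
    dot_radius: float = 2.0

    def tongue_ellipse(self) -> Ellipse | None:
        if self.no_tongue:
            return None
        if self.tongue is not None:
            return self.tongue
        return Ellipse(self.width / 2, self.height / 2,
                       0.40 * self.width, 0.42 * self.height)


@dataclass(frozen=True)
class SyntheticSample:
    image: np.ndarray
    mask: LabelMask
    spec: SceneSpec


# texture programs ----------------------------------------------------------

def _noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    return rng.normal(0.0, sigma, size=shape)


def _paint_dots(img: np.ndarray, region: np.ndarray, rng: np.random.Generator,
                spacing: float, radius: float, color: np.ndarray) -> None:
    """Quasi-regular jittered dot lattice, clipped to ``region``."""
    h, w = region.shape
    r = int(np.ceil(radius))
    ys = np.arange(spacing / 2, h, spacing)
    xs = np.arange(spacing / 2, w, spacing)
    jitter = rng.normal(0.0, spacing / 5.0, size=(len(ys), len(xs), 2))
    disk_y, disk_x = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (disk_x ** 2 + disk_y ** 2) <= radius ** 2
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            cy = int(round(y + jitter[iy, ix, 0]))
            cx = int(round(x + jitter[iy, ix, 1]))
            y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
            x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
            if y1 <= y0 or x1 <= x0:
                continue
            sub = disk[y0 - (cy - r):y1 - (cy - r), x0 - (cx - r):x1 - (cx - r)]
            keep = sub & region[y0:y1, x0:x1]
            img[y0:y1, x0:x1][keep] = color


#: texture family per abnormality tag: smooth | grooves | plaque | coating
#: | big_dots | speckle
_TEXTURE_FAMILY = {
    "papillary_atrophy": "smooth", "erosion": "smooth", "ulcer": "smooth",
    "fissures": "grooves",
    "hyperkeratotic_change": "plaque", "lichenoid_change": "plaque",
    "tongue_coating": "coating", "hairy_tongue": "coating",
    "papillary_hypertrophy": "big_dots",
    "artifacts": "speckle",
}

_FAMILY_BASE = {
    "smooth": (185.0, 78.0, 88.0),
    "grooves": (195.0, 110.0, 120.0),
    "plaque": (226.0, 219.0, 208.0),
    "coating": (205.0, 200.0, 175.0),
    "big_dots": (200.0, 120.0, 130.0),
    "speckle": (200.0, 125.0, 135.0),
}


def _render_abnormal(img: np.ndarray, footprint: np.ndarray, patch: AbnormalPatch,
                     rng: np.random.Generator) -> None:
    h, w = footprint.shape
    family = _TEXTURE_FAMILY[patch.tag]
    base = np.array(patch.params.get("base_color", _FAMILY_BASE[family]))
    sigma = {"smooth": 2.0, "grooves": 3.0, "plaque": 3.0, "coating": 12.0,
             "big_dots": 4.0, "speckle": 4.0}[family]
    layer = base[None, None, :] + _noise(rng, (h, w), sigma)[..., None]
    if family == "grooves":
        gw = float(patch.params.get("groove_width", 3.0))
        spacing = float(patch.params.get("groove_spacing", 14.0))
        yy, xx = np.mgrid[:h, :w]
        wave = xx + 4.0 * np.sin(2 * np.pi * yy / 60.0)
        grooves = np.mod(wave, spacing) < gw
        layer[grooves] = np.array([70.0, 35.0, 40.0])
    img[footprint] = layer[footprint]
    if family == "big_dots":
        _paint_dots(img, footprint, rng, spacing=15.0, radius=4.0,
                    color=np.array([240.0, 190.0, 195.0]))
    if family == "speckle":
        speck = rng.random((h, w)) < 0.01
        img[speck & footprint] = np.array([250.0, 250.0, 250.0])


def generate_scene(spec: SceneSpec) -> SyntheticSample:
    """Render a scene and its exact class mask; bitwise deterministic."""
    h, w = spec.height, spec.width
    tongue = spec.tongue_ellipse()
    img = np.empty((h, w, 3), dtype=np.float64)

    bg_rng = _rng(spec.seed, 0)
    img[:] = np.array([45.0, 38.0, 42.0])[None, None, :]
    img += _noise(bg_rng, (h, w), 4.0)[..., None]

    classes = np.full((h, w), ClassLabel.OTHER, dtype=np.uint8)
    if tongue is not None:
        tongue_mask = tongue.mask(h, w)
        norm_rng = _rng(spec.seed, 1)
        base = np.array([205.0, 130.0, 140.0])
        layer = base[None, None, :] + _noise(norm_rng, (h, w), 5.0)[..., None]
        img[tongue_mask] = layer[tongue_mask]
        _paint_dots(img, tongue_mask, norm_rng, spec.dot_spacing,
                    spec.dot_radius, np.array([240.0, 195.0, 200.0]))
        classes[tongue_mask] = ClassLabel.NORMAL
    else:
        tongue_mask = np.zeros((h, w), dtype=bool)
        if spec.patches:
            raise ValueError("abnormal patches require a tongue")

    for k, patch in enumerate(spec.patches):
        shape_mask = patch.mask(h, w)
        footprint = shape_mask & tongue_mask
        if not footprint.any():
            raise ValueError(
                f"abnormal patch {k} ({patch.tag}) lies outside the tongue")
        _render_abnormal(img, footprint, patch, _rng(spec.seed, 2, k))
        classes[footprint] = ClassLabel.ABNORMAL

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticSample(image, LabelMask(classes, f"scene{spec.seed}"), spec)


# scene sampling ------------------------------------------------------------

#: the four texture families generated as first-class benchmark content
BENCHMARK_TAGS = ("papillary_atrophy", "fissures", "hyperkeratotic_change",
                  "tongue_coating")


def random_scene_spec(seed: int, width: int = 576, height: int = 864,
                      n_patches: int = 2,
                      tags: tuple[str, ...] = BENCHMARK_TAGS) -> SceneSpec:
    """A valid random scene: tongue ellipse plus abnormal ellipses inside it."""
    rng = _rng(seed, 9)
    tongue = Ellipse(width / 2 + rng.uniform(-20, 20),
                     height / 2 + rng.uniform(-30, 30),
                     rng.uniform(0.36, 0.42) * width,
                     rng.uniform(0.38, 0.44) * height)
    patches = []
    for k in range(n_patches):
        tag = tags[(seed + k) % len(tags)]
        # place inside the tongue: pick a center well within the ellipse
        theta = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0.0, 0.45)
        cx = tongue.cx + rho * tongue.ax * np.cos(theta)
        cy = tongue.cy + rho * tongue.ay * np.sin(theta)
        ax = rng.uniform(0.22, 0.38) * tongue.ax
        ay = rng.uniform(0.22, 0.38) * tongue.ay
        patches.append(AbnormalPatch(tag, "ellipse", (cx, cy, ax, ay)))
    return SceneSpec(width, height, seed, tongue=tongue,
                     patches=tuple(patches))


def generate_patch_benchmark(seed: int, n_per_class: int,
                             min_purity: float = 0.8) -> list[PatchRecord]:
    """Balanced, labeled 96x96 patch set sampled from generated scenes.

    Scenes are tiled with a non-overlapping 96x96 grid; each crop's label
    is the plurality mask class of its footprint.  The benchmark exists as
    a class-separability floor, so only texture-pure crops are kept: at
    least ``min_purity`` of the footprint must carry the plurality class
    (mixed boundary crops are not single-texture examples of any class).
    Scenes are generated until every class has ``n_per_class`` records.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    buckets: dict[ClassLabel, list[PatchRecord]] = {c: [] for c in ClassLabel}
    scene_seed = 0
    while any(len(b) < n_per_class for b in buckets.values()):
        spec = random_scene_spec(seed * 10_000 + scene_seed)
        sample = generate_scene(spec)
        source = f"bench{seed}_{scene_seed}"
        regions = grid_crop(sample.image, spec.width // PATCH_SIZE,
                            spec.height // PATCH_SIZE)
        for region in regions:
            if region.crop_w != PATCH_SIZE or region.crop_h != PATCH_SIZE:
                continue
            label = label_region(sample.mask, region)
            if len(buckets[label]) >= n_per_class:
                continue
            footprint = sample.mask.classes[region.slices]
            if np.mean(footprint == label) < min_purity:
                continue
            patch = Patch(sample.image[region.slices].copy(), region, source)
            buckets[label].append(PatchRecord(patch, label, "train", source))
        scene_seed += 1
        if scene_seed > 500:  # defensive: quotas should fill within a few scenes
            raise RuntimeError("benchmark generation did not converge")
    records = []
    for c in ClassLabel:
        records.extend(buckets[c][:n_per_class])
    return records


def fixture_suite(width: int = 384, height: int = 576) -> dict[str, SyntheticSample]:
    """Named degenerate scenes used by end-to-end tests."""
    tongue = Ellipse(width / 2, height / 2, 0.40 * width, 0.42 * height)
    suite: dict[str, SyntheticSample] = {}
    suite["all_normal"] = generate_scene(SceneSpec(width, height, seed=101,
                                                   tongue=tongue))
    suite["all_abnormal"] = generate_scene(SceneSpec(
        width, height, seed=102, tongue=tongue,
        patches=(AbnormalPatch("papillary_atrophy", "ellipse",
                               (tongue.cx, tongue.cy, tongue.ax, tongue.ay)),)))
    suite["half_half"] = generate_scene(SceneSpec(
        width, height, seed=103, tongue=tongue,
        patches=(AbnormalPatch("hyperkeratotic_change", "rect",
                               (0, 0, width / 2, height)),)))
    cells = []
    bx0, by0 = tongue.cx - tongue.ax, tongue.cy - tongue.ay
    step_x, step_y = tongue.ax / 2, tongue.ay / 2
    for i in range(4):
        for j in range(4):
            if (i + j) % 2 == 0:
                cell = AbnormalPatch("fissures", "rect",
                                     (bx0 + j * step_x, by0 + i * step_y,
                                      bx0 + (j + 1) * step_x,
                                      by0 + (i + 1) * step_y))
                cells.append(cell)
    suite["checkerboard"] = generate_scene(SceneSpec(
        width, height, seed=104, tongue=tongue, patches=tuple(cells)))
    suite["no_tongue"] = generate_scene(SceneSpec(width, height, seed=105,
                                                  no_tongue=True))
    return suite


# persistence ---------------------------------------------------------------

def save_sample(sample: SyntheticSample, out_dir: str | Path, name: str) -> None:
    """Emit image PNG + mask PNG (canonical colors) + JSON scene spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_image(out_dir / f"{name}.png", sample.image)
    save_image(out_dir / f"{name}_mask.png", render_mask(sample.mask))
    spec = asdict(sample.spec)
    with open(out_dir / f"{name}_spec.json", "w") as fh:
        json.dump(spec, fh, indent=2, default=lambda o: list(o))


def benchmark_manifest(records: list[PatchRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"source_id": r.source_id, "label": r.label.name.lower(),
          "row": r.patch.region.row_index, "col": r.patch.region.col_index}
         for r in records])
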