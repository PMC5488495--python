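"""From dot annotations to per-region training labels and subimage pools.

A dot marks one pixel inside each cell.  Given the candidate forest of an
image, supervision is induced per region: a region is a positive example
iff it contains exactly one dot and is the largest such region on its
root-to-leaf path (no ancestor also contains exactly one dot).  Every
other region is a negative.  This yields at most one positive per path,
mirroring the non-overlap constraint the detector must satisfy.

To emulate sparse annotation effort, training uses small subimage crops
(about 1/8 of the image area by default) sampled from a pool; each crop
is centred on a cell dot so it is guaranteed to contain annotated cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .region_tree import RegionForest

__all__ = ["LabeledRegions", "SubimagePool", "Crop",
           "induce_region_labels", "make_subimage_pool", "sample_crops"]


@dataclass
class LabeledRegions:
    """Supervised design matrix: features and binary labels of candidate regions."""

    X_s: np.ndarray  # (N_s, D)
    y_s: np.ndarray  # (N_s,) in {0, 1}
    region_ids: list[int] = field(default_factory=list)
    image_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.y_s.size)


@dataclass(frozen=True)
class Crop:
    image_id: str
    rows: tuple[int, int]  # half-open [r0, r1)
    cols: tuple[int, int]
    dots: tuple[tuple[int, int], ...]  # dots inside, in *crop* coordinates


@dataclass
class SubimagePool:
    crops: list[Crop]

    def __len__(self) -> int:
        return len(self.crops)


def induce_region_labels(forest: RegionForest, dots: list[tuple[int, int]]) -> np.ndarray:
    """Label each region 1 iff it holds exactly one dot and no ancestor does.

    Dots on a region boundary count as inside (membership is a pixel test).
    Dots covered by no candidate region produce no positive; they are the
    candidate generator's miss, not the supervision's.
    """
    H, W = forest.shape
    n = len(forest.regions)
    y = np.zeros(n, dtype=np.int8)
    if n == 0:
        return y
    flat_dots = []
    for r, c in dots:
        if not (0 <= r < H and 0 <= c < W):
            raise ValueError(f"dot ({r}, {c}) outside image of shape {forest.shape}")
        flat_dots.append(r * W + c)
    flat_dots = np.asarray(flat_dots, dtype=np.int64)
    counts = np.array(
        [np.isin(flat_dots, reg.pixels).sum() if flat_dots.size else 0
         for reg in forest.regions]
    )
    for reg in forest.regions:
        if counts[reg.id] != 1:
            continue
        anc = reg.parent
        solitary = True
        while anc is not None:
            if counts[anc] == 1:
                solitary = False
                break
            anc = forest.regions[anc].parent
        if solitary:
            y[reg.id] = 1
    return y


def make_subimage_pool(images: dict[str, np.ndarray],
                       dots: dict[str, list[tuple[int, int]]],
                       crop_fraction: float = 1.0 / 8.0,
                       seed: int = 0) -> SubimagePool:
    """One candidate crop per annotated cell, centred on its dot.

    Crop side is ``sqrt(crop_fraction) * min(H, W)`` so each crop covers
    about ``crop_fraction`` of the image; ``crop_fraction=1`` yields one
    whole-image crop per image.  Deterministic under ``seed`` (the seed
    only matters for downstream sampling; pool construction is exhaustive).
    """
    if not 0 < crop_fraction <= 1:
        raise ValueError("crop_fraction must be in (0, 1]")
    crops: list[Crop] = []
    for image_id in sorted(images):
        img = images[image_id]
        H, W = img.shape
        img_dots = dots.get(image_id, [])
        if crop_fraction == 1.0:
            inside = tuple((r, c) for r, c in img_dots)
            crops.append(Crop(image_id, (0, H), (0, W), inside))
            continue
        side = max(8, int(round(np.sqrt(crop_fraction) * min(H, W))))
        for (r, c) in img_dots:
            r0 = int(np.clip(r - side // 2, 0, H - side))
            c0 = int(np.clip(c - side // 2, 0, W - side))
            inside = tuple((rr - r0, cc - c0) for rr, cc in img_dots
                           if r0 <= rr < r0 + side and c0 <= cc < c0 + side)
            crops.append(Crop(image_id, (r0, r0 + side), (c0, c0 + side), inside))
    if not any(c.dots for c in crops):
        raise ValueError("no crop contains a dot annotation")
    return SubimagePool(crops=crops)


def sample_crops(pool: SubimagePool, k: int, rng: np.random.Generator) -> list[Crop]:
    """Draw ``k`` distinct crops (all of them if fewer exist)."""
    k = min(k, len(pool.crops))
    idx = rng.choice(len(pool.crops), size=k, replace=False)
    return [pool.crops[i] for i in sorted(idx)]
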