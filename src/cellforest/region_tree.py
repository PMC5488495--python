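"""Forests of nested extremal regions (component / max-trees).

An extremal region is a connected component of the image thresholded at
some level; across all levels the components are either nested or
disjoint, which organises them into a forest of trees — one tree per
connected blob of the image that survives the area filter.  The forest
is the candidate pool for cell detection: every node is a potential
cell, and the root-to-leaf paths are chains of mutually nested regions
of which at most one may be a cell.

The tree is built as the complete component tree of the 8-bit quantised
image (no stability pruning by default), so that all extremal regions
within the configured area bounds are retained as candidates.  An
optional MSER-style stability filter (area variation across a level
offset) can be enabled on top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.morphology import max_tree

__all__ = [
    "Region",
    "RegionForest",
    "TreeParams",
    "build_forest",
    "enumerate_paths",
    "descendants",
    "forest_to_json",
    "forest_from_json",
]


@dataclass(frozen=True)
class TreeParams:
    """Candidate-generation parameters.

    ``max_area`` may be an absolute pixel count or, when ``None``, defaults
    to ``max_area_fraction`` of the image area.  ``polarity='dark'`` inverts
    the image first so that dark-on-bright blobs become maxima.
    ``max_variation``/``stability_delta`` enable the optional stability
    pruning pass; by default the complete tree is kept.
    """

    min_area: int = 30
    max_area: int | None = None
    max_area_fraction: float = 0.01
    polarity: str = "bright"
    connectivity: int = 1
    n_levels: int = 256
    max_variation: float | None = None
    stability_delta: int = 5
    # drop a node whose area exceeds (1 - step) of its parent's: such
    # near-duplicate nested regions are indistinguishable to any
    # feature-based scorer and only pad the paths.  0 keeps the complete tree.
    min_rel_area_step: float = 0.0
    # ignore thresholds in the lowest fraction of the level range: regions
    # that exist only at background/noise levels are not cell candidates.
    # 0 keeps every level.
    min_level_frac: float = 0.0

    def resolve_max_area(self, shape: tuple[int, int]) -> int:
        if self.max_area is not None:
            return int(self.max_area)
        return max(1, int(round(self.max_area_fraction * shape[0] * shape[1])))


@dataclass
class Region:
    """One extremal region: a node of the component tree."""

    id: int
    level: int  # quantised threshold at which the component exists
    pixels: np.ndarray  # sorted flat indices into the image
    parent: int | None = None
    children: list[int] = field(default_factory=list)

    @property
    def area(self) -> int:
        return int(self.pixels.size)

    def coords(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        return np.unravel_index(self.pixels, shape)

    def centroid(self, shape: tuple[int, int]) -> tuple[float, float]:
        if self.pixels.size == 0:
            return (float("nan"), float("nan"))
        rr, cc = self.coords(shape)
        return float(rr.mean()), float(cc.mean())


@dataclass
class RegionForest:
    """All extremal regions of one image, organised as trees.

    Region ids are indices into ``regions`` and are topologically ordered:
    a parent always has a smaller id than its children.
    """

    shape: tuple[int, int]
    regions: list[Region]
    roots: list[int]
    image_id: str = ""

    def __len__(self) -> int:
        return len(self.regions)

    def leaves(self) -> list[int]:
        return [r.id for r in self.regions if not r.children]

    def label_image(self, ids: list[int] | None = None) -> np.ndarray:
        """Paint the given regions (default: all roots) as an instance label image."""
        lab = np.zeros(self.shape, dtype=np.int32)
        flat = lab.ravel()
        for k, i in enumerate(ids if ids is not None else self.roots, start=1):
            flat[self.regions[i].pixels] = k
        return lab


def _quantize(arr: np.ndarray, n_levels: int = 256) -> np.ndarray:
    """Map any 2-D intensity array monotonically onto uint8 levels 0..n_levels-1.

    Coarser quantisation merges adjacent thresholds and shortens the nested
    chains of near-identical regions, at no cost to which blobs are found.
    """
    if not 2 <= n_levels <= 256:
        raise ValueError("n_levels must be in [2, 256]")
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError("expected a 2-D array")
    lo, hi = a.min(), a.max()
    if hi <= lo:
        return np.zeros(a.shape, dtype=np.uint8)
    return np.round((a - lo) / (hi - lo) * (n_levels - 1)).astype(np.uint8)


def build_forest(arr: np.ndarray, params: TreeParams | None = None,
                 image_id: str = "") -> RegionForest:
    """Build the area-filtered component forest of an image or probability map.

    The image is quantised to 256 levels and its max-tree computed; nodes
    whose pixel count falls outside ``[min_area, max_area]`` are dropped
    (children reattach to the nearest surviving ancestor).  A constant
    image, or one whose only components exceed ``max_area``, yields an
    empty forest.
    """
    params = params or TreeParams()
    q = _quantize(arr, params.n_levels)
    if params.polarity == "dark":
        q = (params.n_levels - 1 - q).astype(np.uint8)
    elif params.polarity != "bright":
        raise ValueError("polarity must be 'bright' or 'dark'")
    max_area = params.resolve_max_area(q.shape)
    if params.min_area > max_area:
        raise ValueError("min_area exceeds max_area")

    parent_img, traverser = max_tree(q, connectivity=params.connectivity)
    parent = parent_img.ravel()
    val = q.ravel()
    n = val.size

    # canonical representative per pixel: the highest pixel of its component
    canon = np.empty(n, dtype=np.int64)
    for p in traverser:  # parents precede children
        pp = parent[p]
        canon[p] = canon[pp] if (pp != p and val[p] == val[pp]) else p

    # subtree pixel counts (= component areas at canonical pixels)
    area = np.ones(n, dtype=np.int64)
    for p in traverser[::-1]:
        pp = parent[p]
        if pp != p:
            area[pp] += area[p]

    nodes = np.unique(canon)
    node_parent: dict[int, int | None] = {}
    for nd in nodes:
        pp = parent[nd]
        node_parent[int(nd)] = int(canon[pp]) if pp != nd else None

    min_level = int(np.ceil(params.min_level_frac * (params.n_levels - 1)))
    kept = [int(nd) for nd in nodes
            if params.min_area <= area[nd] <= max_area and val[nd] >= min_level]
    if params.max_variation is not None:
        kept = [nd for nd in kept
                if _variation(nd, node_parent, area, val, params.stability_delta)
                <= params.max_variation]
    if params.min_rel_area_step > 0:
        # parents first; keep the largest representative of every run of
        # nodes with nearly identical areas
        surviving: set[int] = set()
        for nd in sorted(kept, key=lambda nd: (int(val[nd]), -int(area[nd]))):
            anc = node_parent[nd]
            while anc is not None and anc not in surviving:
                anc = node_parent[anc]
            if anc is not None and area[nd] > (1.0 - params.min_rel_area_step) * area[anc]:
                continue
            surviving.add(nd)
        kept = [nd for nd in kept if nd in surviving]
    kept_set = set(kept)

    # collect pixel sets: each pixel belongs to every kept ancestor component
    pix: dict[int, list[int]] = {nd: [] for nd in kept}
    for p in range(n):
        nd: int | None = int(canon[p])
        while nd is not None and area[nd] <= max_area:
            if nd in kept_set:
                pix[nd].append(p)
            nd = node_parent[nd]

    # order kept nodes so parents precede children: a parent's level is
    # strictly below its child's (equal-level kept nodes are disjoint)
    kept.sort(key=lambda nd: (int(val[nd]), -int(area[nd])))
    id_of = {nd: i for i, nd in enumerate(kept)}
    regions: list[Region] = []
    roots: list[int] = []
    for nd in kept:
        anc = node_parent[nd]
        while anc is not None and anc not in kept_set:
            anc = node_parent[anc]
        rid = id_of[nd]
        pid = id_of[anc] if anc is not None else None
        regions.append(Region(id=rid, level=int(val[nd]),
                              pixels=np.array(sorted(pix[nd]), dtype=np.int64),
                              parent=pid))
        if pid is None:
            roots.append(rid)
    # parents sorted before children? ensure by construction check, then fill children
    for r in regions:
        if r.parent is not None:
            if r.parent > r.id:  # pragma: no cover - ordering invariant
                raise AssertionError("region ordering violated")
            regions[r.parent].children.append(r.id)
    return RegionForest(shape=q.shape, regions=regions, roots=roots, image_id=image_id)


def _variation(nd: int, node_parent: dict[int, int | None], area: np.ndarray,
               val: np.ndarray, delta: int) -> float:
    """MSER area variation: relative growth to the ancestor >= delta levels below."""
    anc = nd
    while node_parent[anc] is not None and val[node_parent[anc]] >= val[nd] - delta:
        anc = node_parent[anc]
    up = node_parent[anc] if node_parent[anc] is not None else anc
    return float(area[up] - area[nd]) / float(area[nd])


def enumerate_paths(forest: RegionForest) -> list[list[int]]:
    """All root-to-leaf region-id chains; one path per leaf."""
    paths: list[list[int]] = []
    for root in forest.roots:
        stack: list[list[int]] = [[root]]
        while stack:
            path = stack.pop()
            kids = forest.regions[path[-1]].children
            if not kids:
                paths.append(path)
            else:
                for c in kids:
                    stack.append(path + [c])
    return paths


def descendants(forest: RegionForest, region_id: int) -> set[int]:
    """Transitive closure of the children relation."""
    if not 0 <= region_id < len(forest.regions):
        raise KeyError(f"unknown region id {region_id}")
    out: set[int] = set()
    stack = list(forest.regions[region_id].children)
    while stack:
        i = stack.pop()
        out.add(i)
        stack.extend(forest.regions[i].children)
    return out


def _rle(flat_sorted: np.ndarray) -> list[list[int]]:
    if flat_sorted.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(flat_sorted) != 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [flat_sorted.size - 1]))
    return [[int(flat_sorted[s]), int(e - s + 1)] for s, e in zip(starts, ends)]


def _unrle(runs: list[list[int]]) -> np.ndarray:
    if not runs:
        return np.empty(0, dtype=np.int64)
    return np.concatenate([np.arange(s, s + ln, dtype=np.int64) for s, ln in runs])


def forest_to_json(forest: RegionForest, path: str | Path | None = None) -> dict:
    """Serialise a forest (pixel sets run-length encoded over flat indices)."""
    doc = {
        "shape": list(forest.shape),
        "image_id": forest.image_id,
        "roots": forest.roots,
        "regions": [
            {"id": r.id, "level": r.level, "parent": r.parent,
             "pixels_rle": _rle(r.pixels)}
            for r in forest.regions
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc))
    return doc


def forest_from_json(doc: dict | str | Path) -> RegionForest:
    if not isinstance(doc, dict):
        doc = json.loads(Path(doc).read_text())
    regions = [
        Region(id=d["id"], level=d["level"], parent=d["parent"],
               pixels=_unrle(d["pixels_rle"]))
        for d in doc["regions"]
    ]
    regions.sort(key=lambda r: r.id)
    for r in regions:
        if r.parent is not None:
            regions[r.parent].children.append(r.id)
    return RegionForest(shape=tuple(doc["shape"]), regions=regions,
                        roots=list(doc["roots"]), image_id=doc.get("image_id", ""))
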