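"""Selecting a non-overlapping set of detected regions from per-region scores.

Given scores ``f_i`` on the nodes of a candidate forest, detection
minimises

    sum_i [ -y_i log f_i - (1 - y_i) log(1 - f_i) ]

over binary labels ``y`` subject to: if a node is selected, every one of
its descendants (hence every nested region) is not.  Two solvers are
provided:

* a greedy pass that takes each path's highest-scoring node, resolving
  cross-path conflicts in descending order of path maxima; and
* the exact bottom-up/top-down dynamic program.  Bottom-up, each node
  accumulates the cost of being selected (its own ``-log f`` plus
  ``-log(1 - f)`` for every descendant) and of not being selected (its
  own ``-log(1 - f)`` plus the cheaper option summed over children);
  top-down, a node is selected wherever its selected energy is strictly
  lower, which zeroes its subtree, and otherwise the walk recurses.

Ties (equal energies) resolve to "not selected", preferring descent into
finer regions; outputs are therefore deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .region_tree import RegionForest, enumerate_paths, descendants

__all__ = ["NodeEnergies", "Detections", "greedy_infer",
           "bottom_up_energies", "top_down_labels", "labeling_energy"]

_CLIP = 1e-6


@dataclass
class NodeEnergies:
    """Per-node selected / not-selected energies of the dynamic program."""

    E_s: np.ndarray
    E_ns: np.ndarray


@dataclass
class Detections:
    """A valid labeling: selected region ids are pairwise non-nested."""

    y: np.ndarray  # (n_regions,) int8
    selected: list[int] = field(default_factory=list)
    centroids: np.ndarray | None = None  # (k, 2) float, (row, col)

    @property
    def n(self) -> int:
        return len(self.selected)


def _clip_scores(scores: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(scores, dtype=float), _CLIP, 1.0 - _CLIP)


def _finish(forest: RegionForest, y: np.ndarray) -> Detections:
    selected = [int(i) for i in np.flatnonzero(y)]
    cents = np.array([forest.regions[i].centroid(forest.shape) for i in selected],
                     dtype=float).reshape(len(selected), 2)
    return Detections(y=y, selected=selected, centroids=cents)


def greedy_infer(forest: RegionForest, scores: np.ndarray) -> Detections:
    """Per-path argmax selection with deterministic conflict resolution.

    Paths are processed in descending order of their best score; a path
    whose nodes are all blocked by earlier picks (nested with one) simply
    selects nothing.  The output always satisfies the non-overlap
    constraint.
    """
    f = _clip_scores(scores)
    y = np.zeros(len(forest.regions), dtype=np.int8)
    paths = enumerate_paths(forest)
    order = sorted(range(len(paths)),
                   key=lambda i: (-max(f[j] for j in paths[i]), i))
    blocked = np.zeros(len(forest.regions), dtype=bool)
    for pi in order:
        path = paths[pi]
        if any(y[j] for j in path):
            continue  # an earlier pick already covers this path
        for j in sorted(path, key=lambda j: (-f[j], j)):
            if blocked[j]:
                continue
            y[j] = 1
            for d in descendants(forest, j):
                blocked[d] = True
            anc = forest.regions[j].parent
            while anc is not None:
                blocked[anc] = True
                anc = forest.regions[anc].parent
            break
    return _finish(forest, y)


def bottom_up_energies(forest: RegionForest, scores: np.ndarray) -> NodeEnergies:
    """Bottom-up accumulation of selected / not-selected energies."""
    f = _clip_scores(scores)
    n = len(forest.regions)
    log_f = -np.log(f)
    log_nf = -np.log(1.0 - f)
    E_s = np.zeros(n)
    E_ns = np.zeros(n)
    desc_nf = np.zeros(n)  # sum of -log(1-f) over descendants
    for r in reversed(forest.regions):  # children before parents (ids ordered)
        i = r.id
        desc_nf[i] = sum(desc_nf[c] + log_nf[c] for c in r.children)
        E_s[i] = log_f[i] + desc_nf[i]
        E_ns[i] = log_nf[i] + sum(min(E_s[c], E_ns[c]) for c in r.children)
    return NodeEnergies(E_s=E_s, E_ns=E_ns)


def top_down_labels(forest: RegionForest, energies: NodeEnergies) -> Detections:
    """Root-to-leaf assignment attaining the minimum-energy valid labeling."""
    y = np.zeros(len(forest.regions), dtype=np.int8)
    stack = list(forest.roots)
    while stack:
        i = stack.pop()
        if energies.E_s[i] < energies.E_ns[i]:
            y[i] = 1  # subtree stays 0
        else:
            stack.extend(forest.regions[i].children)
    return _finish(forest, y)


def dp_infer(forest: RegionForest, scores: np.ndarray) -> Detections:
    """Exact inference: bottom-up energies then top-down labels."""
    return top_down_labels(forest, bottom_up_energies(forest, scores))


def labeling_energy(forest: RegionForest, scores: np.ndarray, y: np.ndarray) -> float:
    """Objective value of a labeling (for comparing solvers)."""
    f = _clip_scores(scores)
    y = np.asarray(y, dtype=float)
    return float(-(y * np.log(f) + (1.0 - y) * np.log(1.0 - f)).sum())
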