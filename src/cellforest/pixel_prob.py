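"""Pixel-level cell probability maps learned from dot annotations.

Candidate generation works best on a map in which cells contrast cleanly
with the background.  For low-contrast images a pixel classifier supplies
that map.  Training pixels are derived from the dot annotations alone:
every dot becomes an isotropic Gaussian of unit peak, and the
superposition of the Gaussians forms a density map.  With a small
standard deviation only pixels right at cell centres carry high density
— these are the positive samples; with a large standard deviation the
density is appreciable across whole cells and their halos, so pixels
where even this wide density is near zero are safely background — the
negative samples.

The classifier itself is a random forest over a multi-scale filter bank
(Gaussian smoothing, gradient magnitude, Laplacian, Hessian eigenvalues
at scales of 1, 2 and 4 px), an open analogue of interactive
pixel-classification tools used for this role.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage as ndi
from sklearn.ensemble import RandomForestClassifier

__all__ = ["DensitySamplingParams", "PixelModel", "density_map",
           "sample_training_pixels", "train_pixel_classifier",
           "predict_probability_map", "save_pixel_model", "load_pixel_model"]


@dataclass(frozen=True)
class DensitySamplingParams:
    """Controls the dot-to-sample conversion.

    ``sigma_neg`` should be on the order of a few cell radii so that the
    wide density covers cells entirely; defaults assume cells of roughly
    5 px radius.
    """

    sigma_pos: float = 2.0
    sigma_neg: float = 15.0
    pos_threshold: float = 0.6
    neg_threshold: float = 0.05
    max_samples_per_class: int = 5000

    def __post_init__(self) -> None:
        if self.sigma_pos >= self.sigma_neg:
            raise ValueError("sigma_pos must be smaller than sigma_neg")
        for name in ("pos_threshold", "neg_threshold"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class PixelModel:
    classifier: RandomForestClassifier
    scales: tuple[float, ...]
    invert: bool = False  # dark-on-bright images are inverted before filtering


def density_map(dots: list[tuple[int, int]], shape: tuple[int, int],
                sigma: float) -> np.ndarray:
    """Superposition of unit-peak isotropic Gaussians, one per dot."""
    H, W = shape
    out = np.zeros(shape, dtype=np.float64)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    reach = int(np.ceil(4 * sigma))
    for r, c in dots:
        if not (0 <= r < H and 0 <= c < W):
            raise ValueError(f"dot ({r}, {c}) outside image of shape {shape}")
        r0, r1 = max(r - reach, 0), min(r + reach + 1, H)
        c0, c1 = max(c - reach, 0), min(c + reach + 1, W)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        out[r0:r1, c0:c1] += np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma ** 2))
    return out


def sample_training_pixels(dots: list[tuple[int, int]], shape: tuple[int, int],
                           params: DensitySamplingParams,
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Positive / negative pixel positions from the two density maps.

    Returns ``(positions, labels)`` with positions as (row, col) pairs.
    Raises ``ValueError`` if either class is empty (e.g. no dots at all).
    """
    pos_mask = density_map(dots, shape, params.sigma_pos) >= params.pos_threshold
    neg_mask = density_map(dots, shape, params.sigma_neg) <= params.neg_threshold
    pos = np.argwhere(pos_mask)
    neg = np.argwhere(neg_mask & ~pos_mask)
    if pos.size == 0:
        raise ValueError("no positive pixels: need at least one dot annotation")
    if neg.size == 0:
        raise ValueError("no negative pixels: dots cover the whole image")
    rng = np.random.default_rng(seed)
    cap = params.max_samples_per_class
    if len(pos) > cap:
        pos = pos[rng.choice(len(pos), cap, replace=False)]
    if len(neg) > cap:
        neg = neg[rng.choice(len(neg), cap, replace=False)]
    positions = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(len(pos), dtype=np.int8),
                             np.zeros(len(neg), dtype=np.int8)])
    return positions, labels


def _as_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(np.float64) / np.iinfo(img.dtype).max
    return img.astype(np.float64)


def filter_bank(image: np.ndarray, scales: tuple[float, ...] = (1.0, 2.0, 4.0),
                invert: bool = False) -> np.ndarray:
    """Per-pixel feature stack: raw value plus 5 filter responses per scale."""
    img = _as_float(image)
    if invert:
        img = 1.0 - img
    maps = [img]
    for s in scales:
        g = ndi.gaussian_filter(img, s)
        maps.append(g)
        maps.append(ndi.gaussian_gradient_magnitude(img, s))
        maps.append(ndi.gaussian_laplace(img, s))
        hrr = ndi.gaussian_filter(img, s, order=(2, 0))
        hcc = ndi.gaussian_filter(img, s, order=(0, 2))
        hrc = ndi.gaussian_filter(img, s, order=(1, 1))
        tr2 = 0.5 * (hrr + hcc)
        det = np.sqrt(np.clip(((hrr - hcc) * 0.5) ** 2 + hrc ** 2, 0, None))
        maps.append(tr2 + det)  # larger Hessian eigenvalue
        maps.append(tr2 - det)  # smaller
    return np.stack(maps, axis=-1)


def train_pixel_classifier(images: list[np.ndarray],
                           dots_per_image: list[list[tuple[int, int]]],
                           params: DensitySamplingParams | None = None,
                           scales: tuple[float, ...] = (1.0, 2.0, 4.0),
                           invert: bool = False,
                           n_estimators: int = 50,
                           seed: int = 0) -> PixelModel:
    """Fit the random forest on sampled pixels from >= 2 annotated images."""
    if len(images) < 2:
        raise ValueError("need at least two annotated images to train the "
                         "pixel classifier")
    params = params or DensitySamplingParams()
    X_rows, y_rows = [], []
    for i, (img, dots) in enumerate(zip(images, dots_per_image)):
        positions, labels = sample_training_pixels(dots, img.shape, params,
                                                   seed=seed + i)
        feats = filter_bank(img, scales, invert)
        X_rows.append(feats[positions[:, 0], positions[:, 1]])
        y_rows.append(labels)
    X = np.vstack(X_rows)
    y = np.concatenate(y_rows)
    if len(np.unique(y)) < 2:
        raise ValueError("training pixels contain a single class")
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                 n_jobs=1, min_samples_leaf=2)
    clf.fit(X, y)
    return PixelModel(classifier=clf, scales=scales, invert=invert)


def predict_probability_map(model: PixelModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel foreground probability in [0, 1], same shape as the image."""
    feats = filter_bank(image, model.scales, model.invert)
    if feats.shape[-1] != model.classifier.n_features_in_:
        raise ValueError("filter-bank width does not match the trained model")
    H, W, D = feats.shape
    prob = model.classifier.predict_proba(feats.reshape(-1, D))[:, 1]
    return prob.reshape(H, W)


def save_pixel_model(model: PixelModel, path: str | Path) -> None:
    joblib.dump(model, path)


def load_pixel_model(path: str | Path) -> PixelModel:
    return joblib.load(path)
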