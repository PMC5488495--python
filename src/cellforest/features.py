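"""Per-region feature vectors for the cell/non-cell classifier.

Each candidate region is described by four feature families — intensity,
area, shape and texture — plus a trailing bias entry fixed at 1:

* intensity: a B-bin histogram of the region's pixel values, and the
  absolute mean / L1 / L2 / absolute-entropy differences between the
  value histogram of the region's inner border and that of an outer
  dilation ring, at two dilation radii (contrast against the surround);
* area: region area normalised by image area; perimeter and boundary
  pixel count normalised by the image diagonal;
* shape: the mean boundary radius per angular sector in a
  size-normalised polar system about the centroid, a curvature summary
  (mean absolute turning angle of the outline) and the roundness ratio
  4*pi*area/perimeter^2;
* texture: means over the region of local-entropy, local-standard-
  deviation and local-range maps computed in a k x k window.

Features are standardised (z-scored) with statistics fitted on the
training regions; the bias entry is left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import (binary_dilation, binary_erosion, maximum_filter,
                           minimum_filter, uniform_filter)
from skimage.measure import find_contours, perimeter as _perimeter
from skimage.morphology import disk

from .region_tree import Region, RegionForest

__all__ = ["FeatureConfig", "FeatureExtractor", "Standardizer"]


@dataclass(frozen=True)
class FeatureConfig:
    n_bins: int = 16
    dilation_radii: tuple[int, ...] = (1, 3)
    n_polar_bins: int = 16
    texture_window: int = 5
    degenerate_area: int = 5  # below this, shape stats use defined fallbacks


def _hist(values: np.ndarray, n_bins: int) -> np.ndarray:
    h, _ = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    s = h.sum()
    return h / s if s > 0 else np.full(n_bins, 1.0 / n_bins)


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


class Standardizer:
    """Column z-scoring fitted on training regions; the bias column is exempt."""

    def __init__(self) -> None:
        self.mean: np.ndarray | None = None
        self.std: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        self.mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std < 1e-12] = 1.0
        self.std = std
        # keep the bias column at 1
        self.mean[-1] = 0.0
        self.std[-1] = 1.0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("Standardizer not fitted")
        return (X - self.mean) / self.std


class FeatureExtractor:
    """Computes raw feature matrices for the regions of a forest.

    Texture maps are computed once per image and sampled per region, so
    extracting features for a whole forest costs roughly one pass over the
    image plus one small masked computation per region.
    """

    def __init__(self, config: FeatureConfig | None = None) -> None:
        self.config = config or FeatureConfig()

    # ------------------------------------------------------------------
    def feature_names(self) -> list[str]:
        c = self.config
        names = [f"int_hist_{i}" for i in range(c.n_bins)]
        for r in c.dilation_radii:
            names += [f"border_absmean_r{r}", f"border_l1_r{r}",
                      f"border_l2_r{r}", f"border_absent_r{r}"]
        names += ["area_norm", "perimeter_norm", "boundary_norm"]
        names += [f"polar_{i}" for i in range(c.n_polar_bins)]
        names += ["curvature", "roundness"]
        names += ["tex_entropy", "tex_std", "tex_range"]
        names += ["bias"]
        return names

    @property
    def dim(self) -> int:
        return len(self.feature_names())

    # ------------------------------------------------------------------
    def image_maps(self, image: np.ndarray) -> dict[str, np.ndarray]:
        """Precompute per-image texture maps (window means are exact box filters)."""
        k = self.config.texture_window
        img = np.asarray(image, dtype=np.float64)
        m1 = uniform_filter(img, size=k, mode="nearest")
        m2 = uniform_filter(img * img, size=k, mode="nearest")
        local_std = np.sqrt(np.clip(m2 - m1 * m1, 0.0, None))
        local_range = (maximum_filter(img, size=k, mode="nearest")
                       - minimum_filter(img, size=k, mode="nearest"))
        # windowed entropy of the 8-bit quantised image
        q = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
        local_ent = _window_entropy(q, k)
        return {"entropy": local_ent, "std": local_std, "range": local_range}

    # ------------------------------------------------------------------
    def region_features(self, region: Region, image: np.ndarray,
                        maps: dict[str, np.ndarray] | None = None,
                        norm_shape: tuple[int, int] | None = None) -> np.ndarray:
        """Raw feature vector of one region.

        ``norm_shape`` sets the image size used to normalise the area and
        perimeter features; pass the source image's shape when the region
        comes from a cropped subimage, so that geometry features stay
        comparable across crops and whole images.
        """
        if region.area == 0:
            raise ValueError("empty region")
        img = np.asarray(image, dtype=np.float64)
        shape = img.shape
        if maps is None:
            maps = self.image_maps(img)
        c = self.config
        rr, cc = region.coords(shape)
        vals = img[rr, cc]

        feats: list[float] = []
        feats.extend(_hist(vals, c.n_bins))
        feats.extend(self._border_contrast(rr, cc, img))
        feats.extend(self._area_feats(rr, cc, norm_shape or shape))
        feats.extend(self._shape_feats(rr, cc))
        for key in ("entropy", "std", "range"):
            feats.append(float(maps[key][rr, cc].mean()))
        feats.append(1.0)  # bias
        x = np.asarray(feats, dtype=np.float64)
        return np.nan_to_num(x, nan=0.0, posinf=0.0, neginf=0.0)

    def forest_features(self, forest: RegionForest, image: np.ndarray,
                        norm_shape: tuple[int, int] | None = None) -> np.ndarray:
        maps = self.image_maps(image)
        if not forest.regions:
            return np.empty((0, self.dim))
        return np.stack([self.region_features(r, image, maps, norm_shape)
                         for r in forest.regions])

    # ------------------------------------------------------------------
    def _crop_mask(self, rr, cc, shape, pad):
        r0 = max(int(rr.min()) - pad, 0)
        r1 = min(int(rr.max()) + pad + 1, shape[0])
        c0 = max(int(cc.min()) - pad, 0)
        c1 = min(int(cc.max()) + pad + 1, shape[1])
        m = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        m[rr - r0, cc - c0] = True
        return m, (r0, c0)

    def _border_contrast(self, rr, cc, img) -> list[float]:
        c = self.config
        pad = max(c.dilation_radii) + 1
        mask, (r0, c0) = self._crop_mask(rr, cc, img.shape, pad)
        sub = img[r0:r0 + mask.shape[0], c0:c0 + mask.shape[1]]
        border = mask & ~binary_erosion(mask)
        bvals = sub[border]
        hb = _hist(bvals, c.n_bins)
        out: list[float] = []
        for rad in c.dilation_radii:
            ring = binary_dilation(mask, structure=disk(rad)) & ~mask
            if ring.any():
                dvals = sub[ring]
                hd = _hist(dvals, c.n_bins)
                out.append(abs(float(bvals.mean()) - float(dvals.mean())))
                out.append(float(np.abs(hb - hd).sum()))
                out.append(float(np.sqrt(((hb - hd) ** 2).sum())))
                out.append(abs(_entropy(hb) - _entropy(hd)))
            else:  # region fills the image: no surround to contrast against
                out.extend([0.0, 0.0, 0.0, 0.0])
        return out

    def _area_feats(self, rr, cc, norm_shape) -> list[float]:
        mask, _ = self._crop_mask(rr, cc, (int(rr.max()) + 2, int(cc.max()) + 2), 1)
        diag = float(np.hypot(*norm_shape))
        per = float(_perimeter(mask, neighborhood=4))
        boundary = int((mask & ~binary_erosion(mask)).sum())
        return [rr.size / (norm_shape[0] * norm_shape[1]), per / diag, boundary / diag]

    def _shape_feats(self, rr, cc) -> list[float]:
        c = self.config
        mask, _ = self._crop_mask(rr, cc, (int(rr.max()) + 2, int(cc.max()) + 2), 1)
        per = float(_perimeter(mask, neighborhood=4))
        if rr.size < c.degenerate_area or per <= 0:
            return [1.0] * c.n_polar_bins + [0.0, 1.0]
        cy, cx = rr.mean(), cc.mean()
        border = mask & ~binary_erosion(mask)
        br, bc = np.nonzero(border)
        # border coords are relative to the crop; shift centroid accordingly
        r0 = max(int(rr.min()) - 1, 0)
        c0 = max(int(cc.min()) - 1, 0)
        dy, dx = br + r0 - cy, bc + c0 - cx
        radius = np.hypot(dy, dx)
        rmax = radius.max()
        radius = radius / rmax if rmax > 0 else radius
        ang = np.mod(np.arctan2(dy, dx), 2 * np.pi)
        bins = np.minimum((ang / (2 * np.pi) * c.n_polar_bins).astype(int),
                          c.n_polar_bins - 1)
        profile = np.full(c.n_polar_bins, np.nan)
        for b in range(c.n_polar_bins):
            sel = bins == b
            if sel.any():
                profile[b] = radius[sel].mean()
        profile = np.where(np.isnan(profile), np.nanmean(profile), profile)
        curvature = _mean_turning_angle(mask)
        roundness = 4.0 * np.pi * rr.size / (per * per)
        return list(profile) + [curvature, float(min(roundness, 2.0))]


def _mean_turning_angle(mask: np.ndarray) -> float:
    """Mean absolute turning angle along the longest 0.5-level outline."""
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return 0.0
    cont = max(contours, key=len)
    if len(cont) < 5:
        return 0.0
    d = np.diff(cont, axis=0)
    ang = np.arctan2(d[:, 0], d[:, 1])
    turn = np.diff(ang)
    turn = np.mod(turn + np.pi, 2 * np.pi) - np.pi
    return float(np.abs(turn).mean())


def _window_entropy(q: np.ndarray, k: int) -> np.ndarray:
    """Local Shannon entropy (bits) of the 8-bit image in a k x k window.

    Computed from 16 coarse intensity bins with box filters, which keeps the
    cost linear in the image size.
    """
    n_bins = 16
    b = (q >> 4).astype(np.int8)
    H = np.zeros(q.shape, dtype=np.float64)
    for i in range(n_bins):
        p = uniform_filter((b == i).astype(np.float64), size=k, mode="nearest")
        nz = p > 0
        H[nz] -= p[nz] * np.log2(p[nz])
    return H
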