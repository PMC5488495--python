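"""End-to-end wiring: scenes -> candidates -> training arms -> detections.

This module holds the glue the command-line interface and the benchmark
grid share: building candidate forests and feature matrices for sets of
images, inducing supervision from dot-annotated subimage crops, training
the supervised-only / semisupervised / semisupervised-with-pixel-maps
arms, and running a trained detector on new images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import MatchResult, match_detections
from .features import FeatureConfig, FeatureExtractor, Standardizer
from .inference import Detections, dp_infer, greedy_infer
from .model import ModelState, PathBatch, TrainConfig, score_regions, train
from .pixel_prob import (DensitySamplingParams, PixelModel,
                         predict_probability_map, train_pixel_classifier)
from .region_tree import RegionForest, TreeParams, build_forest, enumerate_paths
from .supervision import induce_region_labels, make_subimage_pool, sample_crops
from .synth import SceneSpec, SceneTruth, generate_scene

__all__ = ["CandidateSet", "TrainedDetector", "build_candidates",
           "train_detector", "make_benchmark_scenes", "run_experiment",
           "evaluate_detector", "DEFAULT_TREE", "EASY_SCENE"]

# candidate-generation defaults for the bundled synthetic scenes: cells of
# 4.5-6.5 px radius on 192 x 192 images, with room for merged touching
# pairs; coarse levels plus near-duplicate merging keep nested chains
# short, and the level floor drops background/noise-level regions
DEFAULT_TREE = dict(min_area=15, max_area=500, n_levels=16,
                    min_rel_area_step=0.3, min_level_frac=0.25)

# the easy-contrast benchmark setting: well-separated, homogeneous cells
EASY_SCENE = dict(overlap_fraction=0.05)


@dataclass
class CandidateSet:
    """Forests, raw features and padded paths for a set of images."""

    forests: list[RegionForest]
    X: np.ndarray  # (N, D) raw (unstandardised) features, all images stacked
    offsets: list[int]  # region-id offset of each forest into X
    batch: PathBatch

    @property
    def n_regions(self) -> int:
        return int(self.X.shape[0])


def build_candidates(images: list[np.ndarray], tree_params: TreeParams,
                     extractor: FeatureExtractor,
                     image_ids: list[str] | None = None) -> CandidateSet:
    forests, mats, offsets, batches = [], [], [], []
    off = 0
    for i, img in enumerate(images):
        fid = image_ids[i] if image_ids else str(i)
        forest = build_forest(img, tree_params, image_id=fid)
        forests.append(forest)
        offsets.append(off)
        mats.append(extractor.forest_features(forest, img))
        batches.append(PathBatch.from_paths(enumerate_paths(forest), len(forest)))
        off += len(forest)
    X = np.vstack(mats) if mats else np.empty((0, extractor.dim))
    batch = PathBatch.concatenate(batches, offsets, off)
    return CandidateSet(forests=forests, X=X, offsets=offsets, batch=batch)


@dataclass
class TrainedDetector:
    """Everything needed to detect cells in a new image."""

    state: ModelState
    standardizer: Standardizer
    tree_params: TreeParams
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    pixel_model: PixelModel | None = None

    def score_forest(self, forest: RegionForest, image: np.ndarray) -> np.ndarray:
        extractor = FeatureExtractor(self.feature_config)
        X = self.standardizer.transform(extractor.forest_features(forest, image))
        return score_regions(self.state.params, X)

    def detect(self, image: np.ndarray, method: str = "dp"
               ) -> tuple[Detections, RegionForest]:
        """Full pipeline on one image: candidates, scores, inference."""
        cand_img = image
        if self.pixel_model is not None:
            cand_img = predict_probability_map(self.pixel_model, image)
        forest = build_forest(cand_img, self.tree_params)
        scores = self.score_forest(forest, image)
        if method == "dp":
            det = dp_infer(forest, scores)
        elif method == "greedy":
            det = greedy_infer(forest, scores)
        else:
            raise ValueError("method must be 'dp' or 'greedy'")
        return det, forest


# ----------------------------------------------------------------------
# supervision from crops
# ----------------------------------------------------------------------

def _crop_supervision(scenes: list[SceneTruth], k: int, seed: int,
                      tree_params: TreeParams, extractor: FeatureExtractor,
                      crop_fraction: float = 1.0 / 8.0):
    """Sample k dot-centred crops and induce region labels on their forests."""
    images = {str(i): s.image for i, s in enumerate(scenes)}
    dots = {str(i): s.dots for i, s in enumerate(scenes)}
    pool = make_subimage_pool(images, dots, crop_fraction=crop_fraction, seed=seed)
    rng = np.random.default_rng(seed)
    crops = sample_crops(pool, k, rng)
    X_rows, y_rows = [], []
    for crop in crops:
        full = images[crop.image_id]
        img = full[crop.rows[0]:crop.rows[1], crop.cols[0]:crop.cols[1]]
        forest = build_forest(img, tree_params)
        if not len(forest):
            continue
        y = induce_region_labels(forest, list(crop.dots))
        # geometry features normalised by the source image, not the crop,
        # so supervised and unlabeled regions live on one feature scale
        X_rows.append(extractor.forest_features(forest, img, norm_shape=full.shape))
        y_rows.append(y)
    if not X_rows:
        raise RuntimeError("no candidate regions found in any sampled crop")
    return np.vstack(X_rows), np.concatenate(y_rows).astype(float)


# ----------------------------------------------------------------------
# training arms
# ----------------------------------------------------------------------

def train_detector(scenes_train: list[SceneTruth],
                   scenes_test: list[SceneTruth] | None = None,
                   k: int = 1, arm: str = "ss", seed: int = 0,
                   transductive: bool = False,
                   tree_kwargs: dict | None = None,
                   train_kwargs: dict | None = None,
                   crop_fraction: float = 1.0 / 8.0) -> TrainedDetector:
    """Train one arm of the framework on generated (or loaded) scenes.

    Arms: ``supervised`` (warm-start phase only), ``ss`` (full
    semisupervised objective), ``ss+pixel`` (as ``ss``, with candidates
    drawn from pixel-classifier probability maps).  ``transductive``
    additionally feeds the unlabeled test images' paths into the
    unsupervised loss.
    """
    tree_params = TreeParams(**{**DEFAULT_TREE, **(tree_kwargs or {})})
    extractor = FeatureExtractor()
    tcfg_kwargs = dict(lr=0.05, iters_supervised=300, iters_joint=50)
    tcfg_kwargs.update(train_kwargs or {})

    pixel_model = None
    train_images = [s.image for s in scenes_train]
    if arm == "ss+pixel":
        mean_r = (scenes_train[0].spec.mean_radius
                  if scenes_train[0].spec is not None else 5.5)
        # a slightly relaxed background cut keeps the negative class
        # non-empty on small, densely dotted images
        params = DensitySamplingParams(sigma_pos=2.0, sigma_neg=3.0 * mean_r,
                                       neg_threshold=0.1)
        pixel_model = train_pixel_classifier(
            train_images[:2], [s.dots for s in scenes_train[:2]],
            params=params, seed=seed)
        train_images = [predict_probability_map(pixel_model, im)
                       for im in train_images]

    X_s, y_s = _crop_supervision(scenes_train, k, seed, tree_params, extractor,
                                 crop_fraction)

    unlabeled = build_candidates(train_images, tree_params, extractor)
    if transductive and scenes_test:
        test_images = [s.image for s in scenes_test]
        if pixel_model is not None:
            test_images = [predict_probability_map(pixel_model, im)
                           for im in test_images]
        extra = build_candidates(test_images, tree_params, extractor)
        X_all = np.vstack([unlabeled.X, extra.X])
        batch = PathBatch.concatenate(
            [unlabeled.batch, extra.batch], [0, unlabeled.n_regions],
            unlabeled.n_regions + extra.n_regions)
    else:
        X_all, batch = unlabeled.X, unlabeled.batch

    std = Standardizer().fit(np.vstack([X_s, unlabeled.X]))
    X_s_z = std.transform(X_s)
    X_all_z = std.transform(X_all)

    if arm == "supervised":
        cfg = TrainConfig(seed=seed, **{**tcfg_kwargs, "iters_joint": 0})
        state = train(X_s_z, y_s, None, None, cfg)
    elif arm in ("ss", "ss+pixel"):
        cfg = TrainConfig(seed=seed, **tcfg_kwargs)
        state = train(X_s_z, y_s, X_all_z, batch, cfg)
    else:
        raise ValueError(f"unknown arm {arm!r}")

    return TrainedDetector(state=state, standardizer=std,
                           tree_params=tree_params,
                           feature_config=extractor.config,
                           pixel_model=pixel_model)


# ----------------------------------------------------------------------
# benchmark experiment
# ----------------------------------------------------------------------

def make_benchmark_scenes(n_scenes: int, train_fraction: float, seed: int,
                          **scene_kwargs) -> tuple[list[SceneTruth], list[SceneTruth]]:
    """Generate the benchmark scene set and split it into train / test."""
    scenes = [generate_scene(SceneSpec(seed=seed + i, **scene_kwargs))
              for i in range(n_scenes)]
    n_train = max(1, int(round(train_fraction * n_scenes)))
    return scenes[:n_train], scenes[n_train:]


def evaluate_detector(det: TrainedDetector, scenes: list[SceneTruth],
                      method: str = "dp",
                      max_distance: float | None = None) -> dict:
    """Aggregate precision / recall / F over a scene list."""
    if max_distance is None:
        spec = scenes[0].spec
        max_distance = spec.mean_radius if spec is not None else 5.5
    tp = fp = fn = 0
    for s in scenes:
        d, forest = det.detect(s.image, method=method)
        pred_regions = [forest.regions[i].pixels for i in d.selected]
        m = match_detections(np.array(s.dots, dtype=float).reshape(-1, 2),
                             d.centroids, max_distance,
                             pred_regions=pred_regions, shape=forest.shape)
        tp += m.TP
        fp += m.FP
        fn += m.FN
    agg = MatchResult(TP=tp, FP=fp, FN=fn)
    return {"precision": agg.precision, "recall": agg.recall,
            "f_score": agg.f_score, "TP": tp, "FP": fp, "FN": fn}


def run_experiment(scenes_train: list[SceneTruth], scenes_test: list[SceneTruth],
                   k: int, arm: str, seed: int, transductive: bool = False,
                   inference: str = "dp", tree_kwargs: dict | None = None,
                   train_kwargs: dict | None = None) -> dict:
    """Train one arm and score it on the test scenes.

    ``inference='both'`` evaluates the same trained model with both the
    greedy and the dynamic-programming solver and reports the extra
    scores under ``greedy_f_score`` / ``dp_f_score``.
    """
    det = train_detector(scenes_train, scenes_test, k=k, arm=arm, seed=seed,
                         transductive=transductive, tree_kwargs=tree_kwargs,
                         train_kwargs=train_kwargs)
    if inference == "both":
        res_dp = evaluate_detector(det, scenes_test, method="dp")
        res_gr = evaluate_detector(det, scenes_test, method="greedy")
        out = dict(res_dp)
        out["dp_f_score"] = res_dp["f_score"]
        out["greedy_f_score"] = res_gr["f_score"]
        return out
    return evaluate_detector(det, scenes_test, method=inference)
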