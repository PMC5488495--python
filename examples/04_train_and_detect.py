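"""Train the semisupervised detector from ONE labeled subimage and detect.

Supervision: a single dot-annotated crop covering ~1/8 of one training
image.  All other training images contribute only their unlabeled region
trees through the path-consistency loss.  Detections are selected by the
exact bottom-up/top-down dynamic program.
"""
import numpy as np

from cellforest import SceneSpec, generate_scene, train_detector, evaluate_detector
from cellforest.pipeline import EASY_SCENE

scenes = [generate_scene(SceneSpec(seed=100 + i, **EASY_SCENE)) for i in range(20)]
train, test = scenes[:10], scenes[10:]

detector = train_detector(train, test, k=1, arm="ss", seed=0)
res = evaluate_detector(detector, test, method="dp")
print(f"semisupervised arm, 1 labeled subimage, 10 test scenes:")
print(f"  precision={res['precision']:.3f} recall={res['recall']:.3f} "
      f"F={res['f_score']:.3f}  (TP={res['TP']}, FP={res['FP']}, FN={res['FN']})")
print("Precision near 1 means almost every detection is a real cell;")
print("recall is the fraction of annotated cells recovered.")
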