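"""Build the extremal-region forest of a scene and inspect its structure.

Every node is a connected component of some threshold of the image; the
root-to-leaf paths are chains of nested candidate regions, of which a
detector may select at most one per chain.
"""
import numpy as np

from cellforest import SceneSpec, TreeParams, build_forest, enumerate_paths, generate_scene

scene = generate_scene(SceneSpec(seed=3))
params = TreeParams(min_area=15, max_area=500, n_levels=16,
                    min_rel_area_step=0.3, min_level_frac=0.25)
forest = build_forest(scene.image, params)
paths = enumerate_paths(forest)

areas = [r.area for r in forest.regions]
print(f"{len(forest)} candidate regions in {len(forest.roots)} trees "
      f"for {scene.n_cells} true cells")
print(f"{len(paths)} root-to-leaf paths, depth "
      f"{min(map(len, paths))}-{max(map(len, paths))}")
print(f"region areas: {min(areas)}-{max(areas)} px "
      f"(true cells are roughly 60-130 px)")
print("Fewer trees than cells means some neighbours merge below the level floor;")
print("the detector must then pick the right nested subregions.")
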