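import numpy as np
import pytest

from cellforest.region_tree import Region, RegionForest
from cellforest.synth import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A small, quick scene with touching cells and full ground truth."""
    return generate_scene(SceneSpec(height=96, width=96, n_cells=10, seed=42))


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, texture-free, non-touching scene for exact checks."""
    return generate_scene(SceneSpec(height=96, width=96, n_cells=6, seed=7,
                                    noise_sigma=0.0, background_texture=0.0,
                                    overlap_fraction=0.0))


def make_random_forest(rng: np.random.Generator, n_nodes: int,
                       root_prob: float = 0.15) -> RegionForest:
    """Random tree/forest topology with empty pixel sets (structure only)."""
    regions = []
    roots = []
    for i in range(n_nodes):
        parent = None
        if i > 0 and rng.random() >= root_prob:
            parent = int(rng.integers(0, i))
        regions.append(Region(id=i, level=i, pixels=np.empty(0, dtype=np.int64),
                              parent=parent))
        if parent is None:
            roots.append(i)
        else:
            regions[parent].children.append(i)
    return RegionForest(shape=(1, 1), regions=regions, roots=roots)


@pytest.fixture
def random_forest_factory():
    return make_random_forest
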