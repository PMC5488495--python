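import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from skimage.measure import label

from cellforest.region_tree import (TreeParams, build_forest, descendants,
                                    enumerate_paths, forest_from_json,
                                    forest_to_json)


def brute_force_components(q, min_area, max_area, connectivity=1):
    """All distinct connected components over every threshold, area-filtered."""
    comps = set()
    for t in np.unique(q):
        lab = label(q >= t, connectivity=connectivity)
        for i in range(1, lab.max() + 1):
            pix = np.flatnonzero((lab == i).ravel())
            if min_area <= pix.size <= max_area:
                comps.add(tuple(pix.tolist()))
    return comps


def test_two_squares_two_single_node_trees():
    img = np.zeros((32, 32), dtype=np.uint8)
    img[4:10, 4:10] = 200
    img[20:28, 18:26] = 200
    f = build_forest(img, TreeParams(min_area=5, max_area=200))
    assert len(f.roots) == 2
    assert sorted(r.area for r in f.regions) == [36, 64]
    for r in f.regions:
        rr, cc = r.coords(f.shape)
        assert (img[rr, cc] == 200).all()


def test_nested_blobs_leaf_count():
    # one connected component containing three local maxima
    img = np.zeros((64, 64))
    for (r, c) in [(20, 20), (20, 44), (44, 32)]:
        yy, xx = np.mgrid[0:64, 0:64]
        img += np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 36.0))
    q = np.round(img / img.max() * 255).astype(np.uint8)
    f = build_forest(q, TreeParams(min_area=5, max_area=4000))
    assert len(f.roots) == 1
    assert len(f.leaves()) == 3
    assert len(enumerate_paths(f)) == 3
    # cross-check against exhaustive thresholding
    mine = {tuple(r.pixels.tolist()) for r in f.regions}
    assert mine == brute_force_components(q, 5, 4000)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_equals_exhaustive_thresholding(seed):
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.random((48, 48)), 2)
    q = np.round((img - img.min()) / (img.max() - img.min()) * 255).astype(np.uint8)
    f = build_forest(q, TreeParams(min_area=10, max_area=500))
    mine = {tuple(r.pixels.tolist()) for r in f.regions}
    assert mine == brute_force_components(q, 10, 500)


def test_nestedness_invariant(small_scene):
    f = build_forest(small_scene.image, TreeParams(min_area=10, max_area=500))
    sets = [frozenset(r.pixels.tolist()) for r in f.regions]
    for r in f.regions:
        for c in r.children:
            assert sets[c] < sets[r.id]
    # any two regions: nested or disjoint
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            inter = sets[i] & sets[j]
            assert not inter or inter == sets[i] or inter == sets[j]


def test_path_cover_and_leaf_count(small_scene):
    f = build_forest(small_scene.image, TreeParams(min_area=10, max_area=500))
    paths = enumerate_paths(f)
    assert len(paths) == len(f.leaves())
    covered = {i for p in paths for i in p}
    assert covered == set(range(len(f.regions)))
    for p in paths:
        for a, b in zip(p, p[1:]):
            assert f.regions[b].parent == a


def test_descendants_against_reachability(random_forest_factory):
    rng = np.random.default_rng(3)
    for _ in range(20):
        f = random_forest_factory(rng, int(rng.integers(1, 15)))
        for i in range(len(f.regions)):
            reach = set()
            frontier = list(f.regions[i].children)
            while frontier:
                j = frontier.pop()
                reach.add(j)
                frontier.extend(f.regions[j].children)
            assert descendants(f, i) == reach
    with pytest.raises(KeyError):
        descendants(f, 10_000)


def test_constant_image_empty_forest():
    f = build_forest(np.full((32, 32), 7, dtype=np.uint8),
                     TreeParams(min_area=5, max_area=200))
    assert len(f) == 0 and f.roots == []


def test_min_area_above_max_area_rejected():
    with pytest.raises(ValueError):
        build_forest(np.zeros((8, 8), dtype=np.uint8),
                     TreeParams(min_area=50, max_area=10))


def test_dark_polarity_finds_dark_blob():
    img = np.full((32, 32), 220, dtype=np.uint8)
    img[10:20, 10:20] = 30
    f = build_forest(img, TreeParams(min_area=10, max_area=500, polarity="dark"))
    assert len(f) == 1 and f.regions[0].area == 100


def test_near_duplicate_chain_collapsed():
    yy, xx = np.mgrid[0:64, 0:64]
    img = np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 64.0))
    q = np.round(img * 255).astype(np.uint8)
    full = build_forest(q, TreeParams(min_area=10, max_area=2000))
    pruned = build_forest(q, TreeParams(min_area=10, max_area=2000,
                                        min_rel_area_step=0.3))
    assert len(pruned) < len(full)
    for r in pruned.regions:
        if r.parent is not None:
            assert r.area <= 0.7 * pruned.regions[r.parent].area + 1e-9


def test_json_roundtrip(small_scene):
    f = build_forest(small_scene.image, TreeParams(min_area=10, max_area=500))
    doc = forest_to_json(f)
    back = forest_from_json(doc)
    assert back.roots == f.roots
    for a, b in zip(f.regions, back.regions):
        assert a.parent == b.parent and a.level == b.level
        assert np.array_equal(a.pixels, b.pixels)
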