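import numpy as np
import pytest

from cellforest.features import FeatureExtractor, Standardizer
from cellforest.region_tree import Region, TreeParams, build_forest


def region_from_mask(mask):
    return Region(id=0, level=0,
                  pixels=np.flatnonzero(mask.ravel()).astype(np.int64))


@pytest.fixture(scope="module")
def fx():
    return FeatureExtractor()


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def test_dimension_and_manifest(fx):
    img = np.random.default_rng(0).random((32, 32))
    reg = region_from_mask(disk_mask((32, 32), (16, 16), 6))
    x = fx.region_features(reg, img)
    assert x.shape == (fx.dim,)
    assert len(fx.feature_names()) == fx.dim
    assert x[-1] == 1.0  # bias
    assert np.isfinite(x).all()


def test_uniform_region_histogram_and_contrast():
    img = np.zeros((32, 32))
    mask = disk_mask((32, 32), (16, 16), 6)
    img[mask] = 1.0
    x = FeatureExtractor().region_features(region_from_mask(mask), img)
    hist = x[:16]
    assert hist[-1] == pytest.approx(1.0)  # all mass in the top bin
    assert hist[:15].sum() == pytest.approx(0.0)
    # value-1 region on value-0 surround: absolute mean difference = 1
    names = FeatureExtractor().feature_names()
    assert x[names.index("border_absmean_r1")] == pytest.approx(1.0)


def test_border_histogram_distances_match_brute_force(fx):
    rng = np.random.default_rng(1)
    img = rng.random((40, 40))
    mask = disk_mask((40, 40), (20, 20), 7)
    x = fx.region_features(region_from_mask(mask), img)
    names = fx.feature_names()
    from scipy.ndimage import binary_dilation, binary_erosion
    from skimage.morphology import disk as disk_se
    border = mask & ~binary_erosion(mask)
    ring = binary_dilation(mask, structure=disk_se(1)) & ~mask
    hb, _ = np.histogram(img[border], bins=16, range=(0, 1))
    hr, _ = np.histogram(img[ring], bins=16, range=(0, 1))
    hb = hb / hb.sum()
    hr = hr / hr.sum()
    assert x[names.index("border_l1_r1")] == pytest.approx(np.abs(hb - hr).sum())
    assert x[names.index("border_l2_r1")] == pytest.approx(np.sqrt(((hb - hr) ** 2).sum()))


def test_area_normalisations(fx):
    names = fx.feature_names()
    img = np.zeros((50, 40))
    # one-pixel region
    reg = Region(id=0, level=0, pixels=np.array([50 * 40 // 2], dtype=np.int64))
    x = fx.region_features(reg, img)
    assert x[names.index("area_norm")] == pytest.approx(1.0 / (50 * 40))
    # square of side s: boundary pixel count = 4s - 4
    s = 9
    mask = np.zeros((50, 40), dtype=bool)
    mask[10:10 + s, 10:10 + s] = True
    x = fx.region_features(region_from_mask(mask), img)
    diag = np.hypot(50, 40)
    assert x[names.index("boundary_norm")] == pytest.approx((4 * s - 4) / diag)
    assert x[names.index("perimeter_norm")] * diag == pytest.approx(4 * s, rel=0.15)


def test_shape_roundness_ordering(fx):
    names = fx.feature_names()
    i_round = names.index("roundness")
    shape = (64, 64)
    img = np.zeros(shape)
    disk = fx.region_features(region_from_mask(disk_mask(shape, (32, 32), 10)), img)
    yy, xx = np.mgrid[0:64, 0:64]
    ell = (yy - 32) ** 2 / 100.0 + (xx - 32) ** 2 / 25.0 <= 1.0
    ellipse = fx.region_features(region_from_mask(ell), img)
    line = np.zeros(shape, dtype=bool)
    line[32, 8:56] = True
    line[33, 8:56] = True
    liney = fx.region_features(region_from_mask(line), img)
    assert disk[i_round] > ellipse[i_round] > liney[i_round]
    assert liney[i_round] < 0.4
    # disk: near-uniform polar profile
    polar = disk[names.index("polar_0"):names.index("polar_0") + 16]
    assert polar.std() < 0.08


def test_texture_constant_zero_and_checkerboard_range(fx):
    names = fx.feature_names()
    img = np.full((32, 32), 0.5)
    mask = disk_mask((32, 32), (16, 16), 6)
    x = fx.region_features(region_from_mask(mask), img)
    for n in ("tex_entropy", "tex_std", "tex_range"):
        assert abs(x[names.index(n)]) < 1e-9
    yy, xx = np.mgrid[0:32, 0:32]
    img = ((yy + xx) % 2).astype(float) * 0.8
    x = fx.region_features(region_from_mask(mask), img)
    assert x[names.index("tex_range")] == pytest.approx(0.8)


def test_translation_invariance(fx):
    rng = np.random.default_rng(2)
    patch = rng.random((15, 15))
    img1 = np.zeros((48, 48)); img1[5:20, 5:20] = patch
    img2 = np.zeros((48, 48)); img2[25:40, 20:35] = patch
    m1 = np.zeros((48, 48), dtype=bool); m1[8:17, 8:17] = True
    m2 = np.zeros((48, 48), dtype=bool); m2[28:37, 23:32] = True
    x1 = fx.region_features(region_from_mask(m1), img1)
    x2 = fx.region_features(region_from_mask(m2), img2)
    assert np.allclose(x1, x2, atol=1e-12)


def test_degenerate_tiny_regions_defined(fx):
    img = np.random.default_rng(3).random((16, 16))
    for n_pix in (1, 2, 4):
        reg = Region(id=0, level=0, pixels=np.arange(n_pix, dtype=np.int64) + 40)
        x = fx.region_features(reg, img)
        assert np.isfinite(x).all()
    with pytest.raises(ValueError):
        fx.region_features(Region(id=0, level=0,
                                  pixels=np.empty(0, dtype=np.int64)), img)


def test_identical_regions_identical_vectors(fx, small_scene):
    f = build_forest(small_scene.image, TreeParams(min_area=10, max_area=400))
    X1 = fx.forest_features(f, small_scene.image)
    X2 = fx.forest_features(f, small_scene.image)
    assert np.array_equal(X1, X2)


def test_standardizer_zero_mean_unit_std_bias_kept(fx, small_scene):
    f = build_forest(small_scene.image, TreeParams(min_area=10, max_area=400))
    X = fx.forest_features(f, small_scene.image)
    Z = Standardizer().fit(X).transform(X)
    informative = X.std(axis=0) > 1e-12
    assert np.allclose(Z.mean(axis=0)[informative], 0.0, atol=1e-9)
    assert np.allclose(Z.std(axis=0)[informative], 1.0, atol=1e-9)
    assert np.allclose(Z[:, -1], 1.0)
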