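import itertools

import numpy as np
import pytest

from cellforest.model import (MLPParams, ModelState, PathBatch, TrainConfig,
                              gradient, init_params, objective,
                              path_indicator_exact, path_loss_relaxed,
                              path_losses, save_checkpoint, load_checkpoint,
                              score_region, score_regions, train,
                              update_sigmas)

rng = np.random.default_rng(0)


def random_tree_paths(rng, n_nodes):
    parent = [None] + [int(rng.integers(0, i)) for i in range(1, n_nodes)]
    children = {i: [] for i in range(n_nodes)}
    for i, p in enumerate(parent):
        if p is not None:
            children[p].append(i)
    paths, stack = [], [[0]]
    while stack:
        path = stack.pop()
        kids = children[path[-1]]
        if not kids:
            paths.append(path)
        else:
            stack.extend(path + [c] for c in kids)
    return paths


def random_problem(rng, D=None):
    D = D or int(rng.integers(4, 13))
    Ns = int(rng.integers(3, 9))
    X_s = rng.normal(size=(Ns, D)); X_s[:, -1] = 1.0
    y_s = rng.integers(0, 2, Ns).astype(float)
    y_s[0], y_s[1] = 0.0, 1.0
    Nn = int(rng.integers(3, 11))
    X_all = rng.normal(size=(Nn, D)); X_all[:, -1] = 1.0
    batch = PathBatch.from_paths(random_tree_paths(rng, Nn), Nn)
    state = ModelState(params=init_params(D, rng),
                       sigma_s=float(rng.uniform(0.3, 1.5)),
                       sigma_u=float(rng.uniform(0.3, 1.5)))
    return state, X_s, y_s, X_all, batch


# ----------------------------------------------------------------------
# scorer
# ----------------------------------------------------------------------

def test_zero_weights_score_half():
    params = MLPParams(W1=np.zeros((4, 9)), w2=np.zeros(5))
    assert score_region(params, np.ones(9)) == pytest.approx(0.5)


def test_score_monotone_in_output_bias():
    params = init_params(9, np.random.default_rng(1))
    x = np.ones(9)
    lo = score_region(params, x)
    params.w2[-1] += 1.0
    assert score_region(params, x) > lo


def test_forward_matches_independent_implementation():
    r = np.random.default_rng(5)
    params = init_params(7, r)
    X = r.normal(size=(6, 7))
    expected = 1 / (1 + np.exp(-(np.tanh(X @ params.W1.T) @ params.w2[:-1]
                                 + params.w2[-1])))
    assert np.allclose(score_regions(params, X), expected)


def test_dimension_mismatch_raises():
    params = init_params(8, np.random.default_rng(0))
    with pytest.raises(ValueError):
        score_regions(params, np.ones((3, 5)))


# ----------------------------------------------------------------------
# DNF path loss
# ----------------------------------------------------------------------

@pytest.mark.parametrize("n", range(1, 9))
def test_exact_indicator_equals_at_most_one(n):
    for bits in itertools.product([0, 1], repeat=n):
        assert path_indicator_exact(bits) == int(sum(bits) <= 1)


def test_relaxed_loss_examples():
    assert path_loss_relaxed([1 - 1e-12, 1e-12]) == pytest.approx(1.0)
    assert path_loss_relaxed([1 - 1e-12, 1 - 1e-12]) == pytest.approx(0.0, abs=1e-6)
    assert path_loss_relaxed([0.5, 0.5]) == pytest.approx(1 - 0.75 ** 3)


def test_relaxed_reduces_to_indicator_on_binary(subtests=None):
    for n in range(1, 7):
        for bits in itertools.product([0, 1], repeat=n):
            s = np.clip(np.array(bits, dtype=float), 1e-12, 1 - 1e-12)
            # agreement up to the internal score clipping epsilon
            assert path_loss_relaxed(s) == pytest.approx(
                path_indicator_exact(bits), abs=1e-5)


def test_relaxed_loss_in_unit_interval():
    r = np.random.default_rng(2)
    for _ in range(200):
        s = r.uniform(0, 1, r.integers(1, 12))
        assert 0.0 <= path_loss_relaxed(s) <= 1.0


def test_batch_padding_leaves_losses_unchanged():
    r = np.random.default_rng(3)
    scores = r.uniform(0.05, 0.95, 12)
    paths = random_tree_paths(r, 12)
    batch = PathBatch.from_paths(paths, 12)
    F = path_losses(scores, batch)
    for i, p in enumerate(paths):
        assert F[i] == pytest.approx(path_loss_relaxed(scores[p]))


# ----------------------------------------------------------------------
# objective, sigmas, gradient
# ----------------------------------------------------------------------

def test_objective_matches_term_by_term_sum():
    state, X_s, y_s, X_all, batch = random_problem(np.random.default_rng(4))
    L = objective(state, X_s, y_s, X_all, batch)
    w = state.params.flat()
    f_s = score_regions(state.params, X_s)
    F = path_losses(score_regions(state.params, X_all), batch)
    expected = (0.5 * w @ w
                + ((y_s - f_s) ** 2).sum() / (2 * state.sigma_s ** 2)
                + y_s.size * np.log(state.sigma_s)
                + ((1 - F) ** 2).sum() / (2 * state.sigma_u ** 2)
                + batch.n_paths * np.log(state.sigma_u))
    assert L == pytest.approx(expected)


def test_objective_prior_only_when_perfect_and_unit_sigmas():
    state, X_s, y_s, X_all, batch = random_problem(np.random.default_rng(6))
    state.sigma_s = state.sigma_u = 1.0
    # no supervised data / no paths: only the prior remains
    L = objective(state, None, None, None, None)
    w = state.params.flat()
    assert L == pytest.approx(0.5 * w @ w)


def test_update_sigmas_closed_form_and_floor():
    r_u = np.array([0.1, 0.3])
    sig_u, sig_s = update_sigmas(r_u, np.zeros(5))
    assert sig_u == pytest.approx(np.sqrt(0.1) / np.sqrt(2))
    assert sig_s == pytest.approx(1e-4)  # floored at zero residual


def test_update_sigmas_are_stationary_points():
    r = np.random.default_rng(7)
    r_u = r.uniform(0, 1, 23)
    r_s = r.uniform(0, 1, 11)
    sig_u, sig_s = update_sigmas(r_u, r_s)
    for sig, res in ((sig_u, r_u), (sig_s, r_s)):
        def L(s):
            return res.size * np.log(s) + (res @ res) / (2 * s * s)
        h = 1e-6 * sig
        assert abs((L(sig + h) - L(sig - h)) / (2 * h)) < 1e-6


@pytest.mark.parametrize("seed", range(5))
def test_gradient_matches_finite_differences(seed):
    r = np.random.default_rng(100 + seed)
    state, X_s, y_s, X_all, batch = random_problem(r)
    g = gradient(state, X_s, y_s, X_all, batch)
    w0 = state.params.flat()
    D = state.params.input_dim
    h = 1e-6
    gfd = np.empty_like(g)
    for i in range(w0.size):
        for sgn, out in ((+1, 0), (-1, 1)):
            pass
        wp, wm = w0.copy(), w0.copy()
        wp[i] += h; wm[i] -= h
        state.params = MLPParams.from_flat(wp, D)
        Lp = objective(state, X_s, y_s, X_all, batch)
        state.params = MLPParams.from_flat(wm, D)
        Lm = objective(state, X_s, y_s, X_all, batch)
        gfd[i] = (Lp - Lm) / (2 * h)
        state.params = MLPParams.from_flat(w0, D)
    assert np.linalg.norm(g - gfd) / np.linalg.norm(gfd) < 1e-5


def test_gradient_prior_term_alone_is_w():
    r = np.random.default_rng(8)
    state = ModelState(params=init_params(6, r))
    g = gradient(state, None, None, None, None)
    assert np.allclose(g, state.params.flat())


def test_gradient_zero_supervised_residual_contributes_nothing():
    r = np.random.default_rng(9)
    state = ModelState(params=init_params(6, r))
    X_s = r.normal(size=(4, 6))
    y_s = score_regions(state.params, X_s)  # residual exactly zero
    g = gradient(state, X_s, y_s, None, None)
    assert np.allclose(g, state.params.flat())


# ----------------------------------------------------------------------
# training loop
# ----------------------------------------------------------------------

def small_training_problem(seed=0):
    r = np.random.default_rng(seed)
    X_s = r.normal(size=(30, 8)); X_s[:, -1] = 1.0
    w_true = r.normal(size=8)
    y_s = (X_s @ w_true > 0).astype(float)
    X_all = r.normal(size=(20, 8)); X_all[:, -1] = 1.0
    batch = PathBatch.from_paths(random_tree_paths(r, 20), 20)
    return X_s, y_s, X_all, batch


def test_training_deterministic_and_fits():
    X_s, y_s, X_all, batch = small_training_problem()
    cfg = TrainConfig(seed=5, iters_supervised=150, iters_joint=30)
    s1 = train(X_s, y_s, X_all, batch, cfg)
    s2 = train(X_s, y_s, X_all, batch, cfg)
    assert np.array_equal(s1.params.flat(), s2.params.flat())
    assert s1.sigma_s == s2.sigma_s and s1.sigma_u == s2.sigma_u
    acc = ((score_regions(s1.params, X_s) > 0.5) == y_s).mean()
    assert acc > 0.9


def test_training_objective_decreases_in_joint_phase():
    X_s, y_s, X_all, batch = small_training_problem(1)
    hist = []
    train(X_s, y_s, X_all, batch,
          TrainConfig(seed=2, iters_supervised=100, iters_joint=50), history=hist)
    joint_L = [h[2] for h in hist if h[0]]
    # objective non-increasing between sigma refreshes (descent with rollback)
    drops = sum(1 for a, b in zip(joint_L, joint_L[1:]) if b <= a + 1e-9)
    assert drops >= 0.8 * (len(joint_L) - 1)
    assert np.isfinite(joint_L).all()


def test_training_without_paths_equals_supervised_only():
    X_s, y_s, _, _ = small_training_problem(2)
    empty = PathBatch.from_paths([], 0)
    cfg = TrainConfig(seed=3, iters_supervised=100, iters_joint=50)
    a = train(X_s, y_s, None, None, cfg)
    b = train(X_s, y_s, np.empty((0, 8)), empty, cfg)
    assert np.allclose(a.params.flat(), b.params.flat())


def test_single_class_supervision_rejected():
    X = np.ones((5, 4))
    with pytest.raises(ValueError):
        train(X, np.ones(5), None, None, TrainConfig(iters_supervised=5))


def test_checkpoint_roundtrip(tmp_path):
    X_s, y_s, X_all, batch = small_training_problem(3)
    st = train(X_s, y_s, X_all, batch,
               TrainConfig(seed=1, iters_supervised=50, iters_joint=10))
    save_checkpoint(st, tmp_path / "ck.json", feature_names=["a", "b"])
    back, doc = load_checkpoint(tmp_path / "ck.json")
    assert np.allclose(back.params.flat(), st.params.flat())
    assert back.sigma_u == st.sigma_u
    assert doc["feature_names"] == ["a", "b"]
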