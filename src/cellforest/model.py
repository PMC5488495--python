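"""Semisupervised region classifier with a differentiable path-consistency loss.

The scorer is a one-hidden-layer perceptron: ``D`` inputs (the region
feature vector, whose last entry is a bias fixed at 1), ``D // 2`` tanh
hidden units and a logistic output mapping to (0, 1).

Detection must pick at most one region along every root-to-leaf chain of
nested candidates.  Written in disjunctive normal form over the binary
region indicators of a path with nodes ``0..n-1``, the constraint has one
disjunct per "exactly node j selected" plus one all-negated disjunct for
the empty selection.  Replacing conjunctions by products and the binary
indicator by the network probability ``f`` gives the relaxed path score

    F_i = 1 - prod_{j=0..n} (1 - b_j),
    b_j = f_j * prod_{k != j} (1 - f_k)   (j < n),   b_n = prod_k (1 - f_k),

which equals the exact indicator at binary scores and is differentiable
everywhere else.

Learning is maximum a posteriori over the network weights ``w`` and two
noise scales: the supervised residuals ``y_s - f(X_s)`` and the
unsupervised path residuals ``1 - F`` are modelled as isotropic
Gaussians with standard deviations ``sigma_s`` and ``sigma_u``, and the
weights carry a unit Gaussian prior.  The negative log posterior

    L = N_p log sigma_u + ||1 - F||^2 / (2 sigma_u^2) + ||w||^2 / 2
      + ||y_s - f(X_s)||^2 / (2 sigma_s^2) + N_s log sigma_s

is minimised by alternating gradient descent on ``w`` with the
closed-form stationary updates

    sigma_u = ||1 - F||_2 / sqrt(N_p),   sigma_s = ||y_s - f(X_s)||_2 / sqrt(N_s).

Training runs in two phases: supervised-only warm start (the unsupervised
term excluded), then joint descent on the full objective.  The unlabeled
paths may come from the training images alone or, transductively, also
from the (unlabeled) test images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "MLPParams", "ModelState", "PathBatch", "TrainConfig",
    "init_params", "score_regions", "score_region",
    "path_indicator_exact", "path_loss_relaxed", "path_losses",
    "objective", "update_sigmas", "gradient", "train",
    "save_checkpoint", "load_checkpoint",
]

_SCORE_EPS = 1e-7
SIGMA_FLOOR = 1e-4


# ----------------------------------------------------------------------
# network
# ----------------------------------------------------------------------

@dataclass
class MLPParams:
    """Weights of the one-hidden-layer scorer.

    ``W1``: (H, D) input-to-hidden; ``w2``: (H + 1,) hidden-to-output with
    trailing output bias.  Hidden width H = D // 2.
    """

    W1: np.ndarray
    w2: np.ndarray

    @property
    def input_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[0]

    def flat(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.w2])

    @classmethod
    def from_flat(cls, v: np.ndarray, input_dim: int) -> "MLPParams":
        h = input_dim // 2
        W1 = v[: h * input_dim].reshape(h, input_dim)
        return cls(W1=W1.copy(), w2=v[h * input_dim:].copy())


def init_params(input_dim: int, rng: np.random.Generator) -> MLPParams:
    """Uniform(-0.1, 0.1) initial weights."""
    h = input_dim // 2
    return MLPParams(W1=rng.uniform(-0.1, 0.1, size=(h, input_dim)),
                     w2=rng.uniform(-0.1, 0.1, size=h + 1))


def _forward(params: MLPParams, X: np.ndarray):
    """Forward pass. Returns (scores, hidden activations)."""
    if X.ndim != 2 or X.shape[1] != params.input_dim:
        raise ValueError(
            f"feature matrix has dim {X.shape}, expected (*, {params.input_dim})")
    hidden = np.tanh(X @ params.W1.T)  # (N, H)
    z = hidden @ params.w2[:-1] + params.w2[-1]
    f = 1.0 / (1.0 + np.exp(-z))
    return np.clip(f, _SCORE_EPS, 1.0 - _SCORE_EPS), hidden


def score_regions(params: MLPParams, X: np.ndarray) -> np.ndarray:
    """Probability that each region (row of X) is a cell."""
    return _forward(params, X)[0]


def score_region(params: MLPParams, x: np.ndarray) -> float:
    return float(score_regions(params, np.asarray(x, dtype=float)[None, :])[0])


def _backward(params: MLPParams, X: np.ndarray, hidden: np.ndarray,
              f: np.ndarray, dL_df: np.ndarray) -> np.ndarray:
    """Backpropagate per-region dL/df to a flat weight gradient."""
    dz = dL_df * f * (1.0 - f)  # (N,)
    grad_w2 = np.concatenate([hidden.T @ dz, [dz.sum()]])
    dh = np.outer(dz, params.w2[:-1]) * (1.0 - hidden * hidden)  # (N, H)
    grad_W1 = dh.T @ X
    return np.concatenate([grad_W1.ravel(), grad_w2])


# ----------------------------------------------------------------------
# path loss (differentiable DNF relaxation)
# ----------------------------------------------------------------------

def path_indicator_exact(f_binary) -> int:
    """Exact DNF constraint value at binary scores: 1 iff at most one node selected.

    Evaluates the disjunction of the n "exactly node j" conjunctions plus
    the all-negated empty-selection disjunct.
    """
    f = [int(v) for v in f_binary]
    n = len(f)
    for j in range(n + 1):
        ok = all((f[k] if j == k else 1 - f[k]) for k in range(n))
        if ok:
            return 1
    return 0


@dataclass
class PathBatch:
    """All root-to-leaf paths of one or more forests, padded for vectorisation.

    ``idx`` holds indices into the global region score vector, with
    ``n_regions`` used as the padding index (a virtual region whose score
    is fixed at 0, which leaves every padded path's loss unchanged).
    """

    idx: np.ndarray  # (N_p, L) int64
    mask: np.ndarray  # (N_p, L) bool, True at real nodes
    n_regions: int

    @property
    def n_paths(self) -> int:
        return int(self.idx.shape[0])

    @classmethod
    def from_paths(cls, paths: list[list[int]], n_regions: int,
                   offsets: list[int] | None = None) -> "PathBatch":
        if not paths:
            return cls(idx=np.empty((0, 1), dtype=np.int64),
                       mask=np.empty((0, 1), dtype=bool), n_regions=n_regions)
        L = max(len(p) for p in paths)
        idx = np.full((len(paths), L), n_regions, dtype=np.int64)
        mask = np.zeros((len(paths), L), dtype=bool)
        for i, p in enumerate(paths):
            idx[i, : len(p)] = p
            mask[i, : len(p)] = True
        return cls(idx=idx, mask=mask, n_regions=n_regions)

    @classmethod
    def concatenate(cls, batches: list["PathBatch"], region_offsets: list[int],
                    n_regions: int) -> "PathBatch":
        """Merge per-image batches whose region ids are offset into one score vector."""
        rows_i, rows_m = [], []
        L = max((b.idx.shape[1] for b in batches if b.n_paths), default=1)
        for b, off in zip(batches, region_offsets):
            if b.n_paths == 0:
                continue
            idx = np.full((b.n_paths, L), n_regions, dtype=np.int64)
            m = np.zeros((b.n_paths, L), dtype=bool)
            idx[:, : b.idx.shape[1]][b.mask] = b.idx[b.mask] + off
            m[:, : b.idx.shape[1]] = b.mask
            rows_i.append(idx)
            rows_m.append(m)
        if not rows_i:
            return cls(idx=np.empty((0, 1), dtype=np.int64),
                       mask=np.empty((0, 1), dtype=bool), n_regions=n_regions)
        return cls(idx=np.vstack(rows_i), mask=np.vstack(rows_m), n_regions=n_regions)


def _padded_scores(scores: np.ndarray, batch: PathBatch) -> np.ndarray:
    s = np.append(np.clip(scores, _SCORE_EPS, 1.0 - _SCORE_EPS), 0.0)
    return s[batch.idx]  # (N_p, L)


def path_losses(scores: np.ndarray, batch: PathBatch) -> np.ndarray:
    """Relaxed path score F_i in [0, 1] for every path, vectorised."""
    if batch.n_paths == 0:
        return np.empty(0)
    f = _padded_scores(scores, batch)
    u = 1.0 - f
    Q = u.prod(axis=1)  # empty-selection disjunct
    b = f * (Q / u.T).T  # b_j = f_j * prod_{k!=j}(1 - f_k); 0 at padding
    G = (1.0 - b).prod(axis=1)
    return 1.0 - G * (1.0 - Q)


def path_loss_relaxed(scores_on_path) -> float:
    """Single-path convenience wrapper around :func:`path_losses`."""
    s = np.asarray(scores_on_path, dtype=float)
    batch = PathBatch.from_paths([list(range(s.size))], s.size)
    return float(path_losses(s, batch)[0])


def _path_grad_scores(scores: np.ndarray, batch: PathBatch):
    """Returns (F, dF/df per path node) with padding masked to zero."""
    f = _padded_scores(scores, batch)
    u = 1.0 - f
    Q = u.prod(axis=1)
    b = f * (Q[:, None] / u)
    B = 1.0 - b  # >= 1 - f >= eps
    G = B.prod(axis=1)
    A = G * (1.0 - Q)
    F = 1.0 - A
    c = (A[:, None] / B) * (f / u)
    S = c.sum(axis=1)
    dF = (Q[:, None] / u) * (A[:, None] / B + c - S[:, None] - G[:, None])
    dF[~batch.mask] = 0.0
    return F, dF


# ----------------------------------------------------------------------
# MAP objective
# ----------------------------------------------------------------------

@dataclass
class ModelState:
    params: MLPParams
    sigma_s: float = 1.0
    sigma_u: float = 1.0
    n_iter_supervised: int = 0
    n_iter_joint: int = 0
    seed: int = 0


def objective(state: ModelState, X_s: np.ndarray | None, y_s: np.ndarray | None,
              X_all: np.ndarray | None, batch: PathBatch | None) -> float:
    """Negative log posterior L(w, sigma_s, sigma_u)."""
    w = state.params.flat()
    L = 0.5 * float(w @ w)
    if X_s is not None and y_s is not None and y_s.size:
        f_s = score_regions(state.params, X_s)
        r = y_s - f_s
        L += float(r @ r) / (2.0 * state.sigma_s ** 2) + y_s.size * np.log(state.sigma_s)
    if batch is not None and batch.n_paths and X_all is not None:
        F = path_losses(score_regions(state.params, X_all), batch)
        r = 1.0 - F
        L += float(r @ r) / (2.0 * state.sigma_u ** 2) + batch.n_paths * np.log(state.sigma_u)
    return L


def update_sigmas(path_residuals: np.ndarray | None,
                  supervised_residuals: np.ndarray | None,
                  floor: float = SIGMA_FLOOR) -> tuple[float | None, float | None]:
    """Closed-form stationary noise scales; floored to keep L finite.

    sigma_u = ||1 - F||_2 / sqrt(N_p), sigma_s = ||y_s - f(X_s)||_2 / sqrt(N_s).
    """
    sig_u = sig_s = None
    if path_residuals is not None and path_residuals.size:
        sig_u = max(float(np.linalg.norm(path_residuals))
                    / np.sqrt(path_residuals.size), floor)
    if supervised_residuals is not None and supervised_residuals.size:
        sig_s = max(float(np.linalg.norm(supervised_residuals))
                    / np.sqrt(supervised_residuals.size), floor)
    return sig_u, sig_s


def gradient(state: ModelState, X_s: np.ndarray | None, y_s: np.ndarray | None,
             X_all: np.ndarray | None, batch: PathBatch | None) -> np.ndarray:
    """Analytic dL/dw: prior + supervised + unsupervised chain terms."""
    g = state.params.flat().copy()
    if X_s is not None and y_s is not None and y_s.size:
        f_s, hid = _forward(state.params, X_s)
        dL_df = -(y_s - f_s) / state.sigma_s ** 2
        g += _backward(state.params, X_s, hid, f_s, dL_df)
    if batch is not None and batch.n_paths and X_all is not None:
        f_all, hid = _forward(state.params, X_all)
        F, dF = _path_grad_scores(f_all, batch)
        upstream = -(1.0 - F)[:, None] * dF / state.sigma_u ** 2  # (N_p, L)
        per_region = np.zeros(batch.n_regions + 1)
        np.add.at(per_region, batch.idx, upstream)
        g += _backward(state.params, X_all, hid, f_all, per_region[:-1])
    return g


# ----------------------------------------------------------------------
# training loop
# ----------------------------------------------------------------------

@dataclass
class TrainConfig:
    lr: float = 0.05
    iters_supervised: int = 300
    iters_joint: int = 50
    sigma_update_every: int = 10
    seed: int = 0
    min_lr: float = 1e-6
    log: bool = False


def train(X_s: np.ndarray, y_s: np.ndarray, X_all: np.ndarray | None = None,
          batch: PathBatch | None = None, config: TrainConfig | None = None,
          history: list | None = None) -> ModelState:
    """Two-phase alternating MAP training.

    Phase 1 descends the supervised + prior terms from random weights with
    ``sigma_s`` re-estimated every few steps; phase 2 continues on the full
    objective, alternating weight steps with both sigma updates.  A step
    that raises the objective is rolled back and the learning rate halved.
    With no unsupervised paths, phase 2 reduces to continued supervised
    descent.

    Raises ``RuntimeError`` if the objective turns non-finite (divergence).
    """
    config = config or TrainConfig()
    y_s = np.asarray(y_s, dtype=float)
    if not ((y_s == 1).any() and (y_s == 0).any()):
        raise ValueError("supervised set must contain at least one positive "
                         "and one negative region")
    rng = np.random.default_rng(config.seed)
    state = ModelState(params=init_params(X_s.shape[1], rng), seed=config.seed)

    def run_phase(n_iters: int, joint: bool) -> int:
        lr = config.lr
        Xa = X_all if joint else None
        ba = batch if joint else None
        L = objective(state, X_s, y_s, Xa, ba)
        for it in range(n_iters):
            if not np.isfinite(L):
                raise RuntimeError(f"objective diverged at iteration {it}")
            g = gradient(state, X_s, y_s, Xa, ba)
            w_old = state.params.flat()
            state.params = MLPParams.from_flat(w_old - lr * g, X_s.shape[1])
            L_new = objective(state, X_s, y_s, Xa, ba)
            if L_new > L:
                state.params = MLPParams.from_flat(w_old, X_s.shape[1])
                lr *= 0.5
                if lr < config.min_lr:
                    return it
            else:
                L = L_new
            if (it + 1) % config.sigma_update_every == 0:
                r_s = y_s - score_regions(state.params, X_s)
                r_u = None
                if joint and ba is not None and ba.n_paths:
                    F = path_losses(score_regions(state.params, Xa), ba)
                    r_u = 1.0 - F
                sig_u, sig_s = update_sigmas(r_u, r_s)
                if sig_s is not None:
                    state.sigma_s = sig_s
                if sig_u is not None:
                    state.sigma_u = sig_u
                L = objective(state, X_s, y_s, Xa, ba)
            if history is not None:
                history.append((joint, it, L, state.sigma_s, state.sigma_u))
        return n_iters

    state.n_iter_supervised = run_phase(config.iters_supervised, joint=False)
    state.n_iter_joint = run_phase(config.iters_joint, joint=True)
    return state


# ----------------------------------------------------------------------
# persistence
# ----------------------------------------------------------------------

def save_checkpoint(state: ModelState, path: str | Path,
                    feature_names: list[str] | None = None,
                    extra: dict | None = None) -> None:
    """JSON checkpoint: weights, noise scales, feature manifest hash, config."""
    doc = {
        "W1": state.params.W1.tolist(),
        "w2": state.params.w2.tolist(),
        "sigma_s": state.sigma_s,
        "sigma_u": state.sigma_u,
        "seed": state.seed,
        "n_iter_supervised": state.n_iter_supervised,
        "n_iter_joint": state.n_iter_joint,
        "feature_names": feature_names,
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(doc))


def load_checkpoint(path: str | Path) -> tuple[ModelState, dict]:
    doc = json.loads(Path(path).read_text())
    state = ModelState(
        params=MLPParams(W1=np.asarray(doc["W1"]), w2=np.asarray(doc["w2"])),
        sigma_s=doc["sigma_s"], sigma_u=doc["sigma_u"], seed=doc.get("seed", 0),
        n_iter_supervised=doc.get("n_iter_supervised", 0),
        n_iter_joint=doc.get("n_iter_joint", 0),
    )
    return state, doc
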