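"""Gradient-boosted regression trees for the local soft-sensor models.

The second-order boosting algebra — optimal leaf weight
``w* = -G/(lambda + H)`` and the pruned-tree objective
``Obj* = gamma*T - 1/2 sum_j G_j^2/(lambda + H_j)`` — is implemented and
tested directly.  Full-scale training delegates to the xgboost library
behind a fixed contract (exact greedy splits, squared-error loss,
per-sample similarity weights, deterministic under a seed); the engine's
engineering internals are deliberately out of scope here.

``ReferenceTree`` is a small exhaustive-split single-tree builder using
exactly this algebra; it exists to cross-check the engine's split
decisions on tiny fixtures and is limited to depth <= 3 and a few hundred
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xgboost as xgb


@dataclass(frozen=True)
class BoosterParams:
    learning_rate: float = 0.1
    max_depth: int = 4
    n_rounds: int = 100
    reg_gamma: float = 0.0      # per-leaf complexity penalty
    reg_lambda: float = 1.0     # L2 penalty on leaf weights
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.max_depth < 1 or self.n_rounds < 1:
            raise ValueError("max_depth and n_rounds must be >= 1")
        if self.reg_gamma < 0 or self.reg_lambda < 0:
            raise ValueError("regularization terms must be >= 0")


@dataclass
class LeafStats:
    """Per-leaf gradient sums G_j, Hessian sums H_j and the leaf count T."""

    G: np.ndarray
    H: np.ndarray

    def __post_init__(self):
        self.G = np.atleast_1d(np.asarray(self.G, float))
        self.H = np.atleast_1d(np.asarray(self.H, float))
        if self.G.shape != self.H.shape:
            raise ValueError("G and H must have one entry per leaf")

    @property
    def T(self) -> int:
        return len(self.G)


def optimal_leaf_weight(G: float, H: float, reg_lambda: float) -> float:
    """Minimizer of w*G + 1/2 w^2 (lambda + H): w* = -G/(lambda + H)."""
    denom = reg_lambda + H
    if denom <= 0:
        raise ValueError("lambda + H must be > 0")
    return -G / denom


def tree_objective(stats: LeafStats, reg_gamma: float, reg_lambda: float) -> float:
    """Obj* = gamma*T - 1/2 sum_j G_j^2 / (lambda + H_j) at optimal weights."""
    if np.any(reg_lambda + stats.H <= 0):
        raise ValueError("lambda + H_j must be > 0 for every leaf")
    return float(reg_gamma * stats.T
                 - 0.5 * np.sum(stats.G ** 2 / (reg_lambda + stats.H)))


@dataclass
class BoostedModel:
    """A trained booster bound to a named feature signature."""

    booster: xgb.Booster
    feature_names: list
    params: BoosterParams
    base_score: float

    def predict(self, X) -> np.ndarray:
        return predict_boosted(self, X)

    def dump_trees(self) -> list:
        """Raw JSON tree dumps (one string per round) for audits."""
        return self.booster.get_dump(dump_format="json")


def _as_matrix(X, feature_names):
    """Coerce input to an ndarray in the training column order."""
    if hasattr(X, "columns"):
        missing = [f for f in feature_names if f not in X.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        return X[feature_names].to_numpy(float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != len(feature_names):
        raise ValueError(
            f"expected {len(feature_names)} features, got {X.shape[1]}")
    return X


def fit_boosted_model(train_X, train_y, weights=None,
                      params: BoosterParams = BoosterParams(),
                      feature_names=None, min_child_weight: float = 1.0,
                      ) -> BoostedModel:
    """Fit a weighted squared-error booster; deterministic under the seed.

    ``weights`` are the similarity weights of the neighbor set, entering
    as per-sample loss weights so that nearer samples dominate the fit
    (their scale is irrelevant: the optimal leaf weights are invariant to
    a common factor up to the lambda term, and weights are normalized to
    mean 1 here to pin that down).
    """
    if feature_names is None and hasattr(train_X, "columns"):
        feature_names = list(train_X.columns)
    X = np.atleast_2d(np.asarray(
        train_X[feature_names] if hasattr(train_X, "columns") else train_X,
        float))
    y = np.asarray(train_y, float).ravel()
    if len(X) == 0:
        raise ValueError("empty training set")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    if weights is None:
        w = np.ones(len(y))
    else:
        w = np.asarray(weights, float).ravel()
        w = w / w.mean()
    base = float(np.average(y, weights=w))
    dtrain = xgb.DMatrix(X, label=y, weight=w, feature_names=list(feature_names))
    booster = xgb.train(
        {
            "objective": "reg:squarederror",
            "eta": params.learning_rate,
            "max_depth": params.max_depth,
            "lambda": params.reg_lambda,
            "gamma": params.reg_gamma,
            "min_child_weight": min_child_weight,
            "base_score": base,
            "tree_method": "exact",
            "seed": params.seed,
            "nthread": 1,
        },
        dtrain,
        num_boost_round=params.n_rounds,
    )
    return BoostedModel(booster=booster, feature_names=list(feature_names),
                        params=params, base_score=base)


def predict_boosted(model: BoostedModel, X) -> np.ndarray:
    """Predict with name-based column binding; errors on missing features."""
    mat = _as_matrix(X, model.feature_names)
    dm = xgb.DMatrix(mat, feature_names=model.feature_names)
    pred = model.booster.predict(dm)
    if not np.all(np.isfinite(pred)):
        raise ValueError("non-finite prediction")
    return pred


# ---------------------------------------------------------------------------
# Reference exhaustive-split tree (oracle for the engine's split decisions)

@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: "_Node" = None
    right: "_Node" = None
    weight: float = 0.0          # leaf value (only for leaves)
    gain: float = 0.0            # raw structure gain of this split
    G: float = 0.0
    H: float = 0.0

    @property
    def is_leaf(self):
        return self.left is None


class ReferenceTree:
    """Single regression tree grown by exhaustive split search.

    Uses squared-error gradients (g_i = pred - y_i, h_i = 1, optionally
    sample-weighted) and mirrors the engine's grow-then-prune semantics:
    splits are taken greedily by the structure gain
        G_L^2/(H_L+lambda) + G_R^2/(H_R+lambda) - G^2/(H+lambda)
    (the engine thresholds gamma against this unhalved quantity, although
    the objective derivation carries a 1/2), then bottom-up pruning
    collapses any split of two leaves whose gain falls below gamma.
    Pre-pruning with gain - gamma > 0 is not equivalent: a weak split
    survives when a deeper strong split hangs below it.  Meant for tiny
    fixtures only.
    """

    def __init__(self, max_depth: int = 3, reg_lambda: float = 1.0,
                 reg_gamma: float = 0.0, min_child_weight: float = 0.0):
        if max_depth > 3:
            raise ValueError("reference tree is limited to depth <= 3")
        self.max_depth = max_depth
        self.reg_lambda = reg_lambda
        self.reg_gamma = reg_gamma
        self.min_child_weight = min_child_weight
        self.root = None

    def fit(self, X, g, h):
        X = np.atleast_2d(np.asarray(X, float))
        if len(X) > 200:
            raise ValueError("reference tree is limited to <= 200 samples")
        g = np.asarray(g, float)
        h = np.asarray(h, float)
        self.root = self._grow(X, g, h, depth=0)
        self._prune(self.root)
        return self

    def _leaf(self, G, H):
        return _Node(weight=optimal_leaf_weight(G, H, self.reg_lambda),
                     G=G, H=H)

    def _grow(self, X, g, h, depth):
        G, H = g.sum(), h.sum()
        if depth >= self.max_depth or len(X) < 2:
            return self._leaf(G, H)
        parent_score = G ** 2 / (H + self.reg_lambda)
        best = (1e-6, None, None)           # engine epsilon on the raw gain
        for j in range(X.shape[1]):
            order = np.argsort(X[:, j], kind="stable")
            xs, gs, hs = X[order, j], g[order], h[order]
            Gl = np.cumsum(gs)[:-1]
            Hl = np.cumsum(hs)[:-1]
            valid = xs[1:] != xs[:-1]
            for i in np.flatnonzero(valid):
                if (Hl[i] < self.min_child_weight
                        or H - Hl[i] < self.min_child_weight):
                    continue
                gain = (Gl[i] ** 2 / (Hl[i] + self.reg_lambda)
                        + (G - Gl[i]) ** 2 / (H - Hl[i] + self.reg_lambda)
                        - parent_score)
                if gain > best[0]:
                    best = (gain, j, 0.5 * (xs[i] + xs[i + 1]))
        if best[1] is None:
            return self._leaf(G, H)
        gain, j, thr = best
        mask = X[:, j] < thr
        node = _Node(feature=j, threshold=thr, gain=gain, G=G, H=H)
        node.left = self._grow(X[mask], g[mask], h[mask], depth + 1)
        node.right = self._grow(X[~mask], g[~mask], h[~mask], depth + 1)
        return node

    def _prune(self, node):
        """Bottom-up: collapse leaf-pair splits with gain < gamma."""
        if node.is_leaf:
            return
        self._prune(node.left)
        self._prune(node.right)
        if (node.left.is_leaf and node.right.is_leaf
                and node.gain < self.reg_gamma):
            node.left = node.right = None
            node.weight = optimal_leaf_weight(node.G, node.H, self.reg_lambda)

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        out = np.empty(len(X))
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] < node.threshold else node.right
            out[i] = node.weight
        return out
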