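"""Stacked fusion of the three similarity-specific base learners.

For one query, each similarity metric (ED / CWD / ANGLE) contributes a
ranked neighbor set.  Instead of k-fold cross-validation, each set is
*pre-separated* along its similarity ranking: every stride-th record (a
deterministic uniform sample over the ranks) is held out for the
meta-learner and the remainder trains that metric's boosted-tree base
model, tuned by the sparrow-search optimizer.  The meta-learner is a
deliberately weakly fitted multilayer perceptron (small hidden layer,
capped epochs) mapping the three base predictions to the final output —
weak on purpose, so the fusion cannot overfit the small holdout.

Held-out meta rows are pooled across the three metrics (deduplicated by
record id) and removed from every base training set, so no meta-training
row is ever seen by any base learner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPRegressor

from .boosting import BoosterParams, BoostedModel, fit_boosted_model, predict_boosted
from .ssa import SSAConfig, optimize

#: ISSA search space over the booster hyperparameters.
PARAM_BOUNDS = {
    "learning_rate": (0.01, 0.3),
    "max_depth": (2, 8),          # integer, rounded at evaluation
    "n_rounds": (20, 300),        # integer, rounded at evaluation
    "reg_lambda": (0.0, 5.0),
    "reg_gamma": (0.0, 2.0),
}
INTEGER_PARAMS = ("max_depth", "n_rounds")


@dataclass
class MLPConfig:
    hidden_layers: tuple = (8,)
    max_epochs: int = 200
    learning_rate: float = 1e-2
    solver: str = "adam"        # "lbfgs" converges far better on tiny holdouts
    alpha: float = 1e-4         # L2 weight decay; tames the directions the
                                # tiny collinear meta set leaves unconstrained
    seed: int = 0

    def __post_init__(self):
        if len(self.hidden_layers) < 1:
            raise ValueError("need at least one hidden layer")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class StackedModel:
    domain_id: int
    variable_set: list
    base_models: dict                      # metric -> BoostedModel
    meta: MLPRegressor
    # the MLP trains in standardized coordinates; raw units are restored here
    z_center: np.ndarray = None
    z_scale: np.ndarray = None
    y_center: float = 0.0
    y_scale: float = 1.0
    training_report: dict = field(default_factory=dict)


def pre_separate(n_records: int, fraction: float, method: str = "stride",
                 seed: int = 0):
    """Split rank positions 0..n-1 into (base_idx, meta_idx).

    method="stride" (default) holds out every floor(1/fraction)-th rank
    starting at the most similar record — a deterministic uniform sample
    over the similarity ranking.  method="random" draws the same number
    of ranks uniformly without replacement from a seeded RNG.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    stride = int(np.floor(1.0 / fraction))
    if stride < 2:
        raise ValueError("fraction too large: base training set would be empty")
    ranks = np.arange(n_records)
    if method == "stride":
        meta = ranks[::stride]
    elif method == "random":
        rng = np.random.default_rng(seed)
        meta = np.sort(rng.choice(n_records, size=len(ranks[::stride]),
                                  replace=False))
    else:
        raise ValueError("method must be 'stride' or 'random'")
    if meta.size == 0:
        raise ValueError("fraction yields an empty meta-training set")
    base = np.setdiff1d(ranks, meta)
    if base.size == 0:
        raise ValueError("fraction too large: base training set would be empty")
    return base, meta


def _vector_to_params(x, seed: int) -> BoosterParams:
    vals = dict(zip(PARAM_BOUNDS, x))
    for p in INTEGER_PARAMS:
        vals[p] = int(round(vals[p]))
    return BoosterParams(seed=seed, **vals)


def tune_booster(X, y, weights, issa_cfg: SSAConfig, val_fraction: float = 0.2):
    """ISSA-tune BoosterParams against validation RMSE on a tail split."""
    n = len(y)
    n_val = max(1, int(round(val_fraction * n)))
    if n_val >= n:
        raise ValueError("not enough samples to hold out a validation split")
    tr = slice(0, n - n_val)
    va = slice(n - n_val, n)
    cfg = SSAConfig(**{**issa_cfg.__dict__,
                       "bounds": tuple(PARAM_BOUNDS.values())})

    def fitness(vec):
        params = _vector_to_params(vec, seed=issa_cfg.seed)
        model = fit_boosted_model(X[tr], y[tr], weights[tr], params)
        pred = predict_boosted(model, X[va])
        return float(np.sqrt(np.mean((pred - y[va]) ** 2)))

    best_vec, history = optimize(fitness, cfg)
    return _vector_to_params(best_vec, seed=issa_cfg.seed), history


def fit_stacked_model(similar_sets: dict, records_X, records_y,
                      issa_cfg: SSAConfig, mlp_cfg: MLPConfig,
                      fraction: float = 0.2, domain_id: int = 0,
                      variable_set=None, tune: bool = True,
                      use_similarity_weights: bool = True) -> StackedModel:
    """Train the three tuned base learners and the MLP meta-learner.

    ``similar_sets`` maps metric name -> SimilaritySet over one
    sub-database whose (already feature-restricted) design matrix is
    ``records_X`` with target ``records_y``.  ``tune=False`` skips the
    ISSA search and uses default BoosterParams (useful for fixtures).
    """
    if len(similar_sets) != 3:
        raise ValueError(f"expected 3 similarity sets, got {len(similar_sets)}")
    records_X = np.atleast_2d(np.asarray(records_X, float))
    records_y = np.asarray(records_y, float).ravel()

    splits = {}
    meta_pool = []
    for metric, sset in similar_sets.items():
        if len(sset) == 0:
            raise ValueError(f"empty similarity set for metric {metric}")
        base_r, meta_r = pre_separate(len(sset), fraction)
        splits[metric] = (sset.indices[base_r], sset.weights[base_r])
        meta_pool.append(sset.indices[meta_r])
    meta_ids = np.unique(np.concatenate(meta_pool))

    base_models = {}
    report = {"base": {}, "tuning": {}}
    for metric, (idx, w) in splits.items():
        keep = ~np.isin(idx, meta_ids)      # leakage guard: drop pooled meta rows
        idx, w = idx[keep], w[keep]
        if idx.size == 0:
            raise ValueError(f"base training set empty for metric {metric}")
        if not use_similarity_weights:      # subset-only mode: plain fit on
            w = np.ones(idx.size)           # the selected neighbors
        Xb, yb = records_X[idx], records_y[idx]
        if tune:
            params, hist = tune_booster(Xb, yb, w, issa_cfg)
            report["tuning"][metric] = float(hist[-1])
        else:
            params = BoosterParams(seed=issa_cfg.seed)
        model = fit_boosted_model(Xb, yb, w, params,
                                  feature_names=variable_set)
        base_models[metric] = model
        report["base"][metric] = float(np.sqrt(np.mean(
            (predict_boosted(model, Xb) - yb) ** 2)))
        assert not np.isin(meta_ids, idx).any(), "meta rows leaked into base set"

    Z = np.column_stack([predict_boosted(base_models[m], records_X[meta_ids])
                         for m in similar_sets])
    y_meta = records_y[meta_ids]
    # standardize the meta problem so the capped-epoch MLP trains on O(1)
    # numbers regardless of the target's physical units
    z_center, z_scale = Z.mean(axis=0), Z.std(axis=0)
    z_scale[z_scale == 0] = 1.0
    y_center = float(y_meta.mean())
    y_scale = float(y_meta.std()) or 1.0
    meta = MLPRegressor(hidden_layer_sizes=tuple(mlp_cfg.hidden_layers),
                        max_iter=mlp_cfg.max_epochs,
                        solver=mlp_cfg.solver,
                        alpha=mlp_cfg.alpha,
                        learning_rate_init=mlp_cfg.learning_rate,
                        random_state=mlp_cfg.seed)
    import warnings as _warnings
    from sklearn.exceptions import ConvergenceWarning
    with _warnings.catch_warnings():
        # the meta-learner is weakly fitted by design: capped epochs
        _warnings.simplefilter("ignore", ConvergenceWarning)
        meta.fit((Z - z_center) / z_scale, (y_meta - y_center) / y_scale)
    model = StackedModel(domain_id=domain_id,
                         variable_set=list(variable_set) if variable_set else None,
                         base_models=base_models, meta=meta,
                         z_center=z_center, z_scale=z_scale,
                         y_center=y_center, y_scale=y_scale,
                         training_report=report)
    fitted = np.array([_meta_predict(model, Z[i]) for i in range(len(Z))])
    report["meta"] = float(np.sqrt(np.mean((fitted - y_meta) ** 2)))
    return model


def _meta_predict(model: StackedModel, z_row) -> float:
    z = (np.atleast_2d(z_row) - model.z_center) / model.z_scale
    return float(model.meta.predict(z)[0]) * model.y_scale + model.y_center


def predict_stacked(model: StackedModel, query) -> float:
    """meta(base_ED(q), base_CWD(q), base_ANGLE(q)) for one query vector."""
    if len(model.base_models) != 3:
        raise ValueError("stacked model requires exactly 3 base models")
    q = np.atleast_2d(np.asarray(query, float))
    z = np.column_stack([predict_boosted(m, q)
                         for m in model.base_models.values()])
    out = _meta_predict(model, z)
    if not np.isfinite(out):
        raise ValueError("non-finite stacked prediction")
    return out


def predict_bases(model: StackedModel, query) -> dict:
    """Per-metric base predictions (for ablation reporting)."""
    q = np.atleast_2d(np.asarray(query, float))
    return {m: float(predict_boosted(b, q)[0])
            for m, b in model.base_models.items()}
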