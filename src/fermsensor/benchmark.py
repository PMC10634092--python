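"""Seeded end-to-end benchmark on the synthetic fermentation dataset.

Runs the full offline + online soft-sensor flow on a freshly simulated
multi-batch dataset and reports, per dominant variable, the stacked
model's test metrics, each single-similarity base learner's metrics, and
a tuned global (non-JITL) boosted-tree baseline trained once on the whole
training table — the ablation the method's design claims to beat.
"""

from __future__ import annotations

import copy

import numpy as np

from .simulate import SimulatorConfig, build_dataset, AUX_NAMES, DOMINANT_NAMES
from .pipeline import PipelineConfig, offline_build, online_predict, evaluate
from .stacking import tune_booster
from .boosting import fit_boosted_model, predict_boosted


def global_model_metrics(train, test, target, issa_cfg, tune=True):
    """One tuned booster on the full training table (non-JITL baseline)."""
    X = train[AUX_NAMES].to_numpy(float)
    y = train[target].to_numpy(float)
    w = np.ones(len(y))
    if tune:
        params, _ = tune_booster(X, y, w, issa_cfg)
    else:
        from .boosting import BoosterParams
        params = BoosterParams(seed=issa_cfg.seed)
    model = fit_boosted_model(train[AUX_NAMES], y, w, params)
    pred = predict_boosted(model, test[AUX_NAMES])
    return evaluate(test[target].to_numpy(float), pred)


def run_benchmark(seed: int = 0, n_batches: int = 10, max_queries: int = None,
                  config: PipelineConfig = None, targets=None) -> dict:
    """Full pipeline + ablations; returns a plain-JSON-serializable dict."""
    sim_cfg = SimulatorConfig(seed=seed)
    train, test = build_dataset(n_batches, sim_cfg)
    config = config or PipelineConfig.fast(seed=seed)
    state = offline_build(train, config)
    queries = test
    if max_queries is not None and len(test) > max_queries:
        rows = np.linspace(0, len(test) - 1, max_queries).round().astype(int)
        queries = test.iloc[rows].reset_index(drop=True)

    result = {"seed": seed, "n_train": len(train), "n_test": len(queries),
              "k": state.k, "targets": {}}
    for target in (targets or DOMINANT_NAMES):
        # fresh copy per target: the online loop mutates the sub-databases
        preds, details = online_predict(copy.deepcopy(state), queries, target,
                                        config, return_details=True)
        y = queries[target].to_numpy(float)
        entry = {"stacked": evaluate(y, preds), "base": {}}
        for metric in ("ED", "CWD", "ANGLE"):
            if metric in details.columns:
                entry["base"][metric] = evaluate(
                    y, details[metric].to_numpy(float))
        entry["global"] = global_model_metrics(train, queries, target,
                                               config.issa, tune=config.tune)
        best_base = min(v["rmse"] for v in entry["base"].values())
        entry["stacked_vs_best_base"] = entry["stacked"]["rmse"] / best_base
        result["targets"][target] = entry
    return result
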