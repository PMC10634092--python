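"""End-to-end offline/online orchestration of the JITL soft sensor.

Offline stage
    standardize the training table -> SSE(k) curve -> elbow k ->
    Mahalanobis-ranked FCM initialization -> FCM fit -> partition into
    sub-databases -> per-domain, per-target mutual-information variable
    screening.  The result (scaler, sub-databases, variable signatures)
    persists as a directory of CSV + JSON.

Online stage, per query
    route to a sub-database (KL / Mahalanobis) -> build the three
    similarity neighbor sets over that domain restricted to its variable
    signature -> pre-separate, ISSA-tune and fit three boosted-tree base
    learners -> fit the weak MLP meta-learner -> predict -> store the
    (query, prediction) pair for the domain's next prune -> bump the
    neighbors' similarity query labels -> prune if triggered -> discard
    the model.  A failed query yields NaN; the stream never halts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import domains as dom
from . import similarity as sim
from .mi import build_mi_table
from .simulate import AUX_NAMES, DOMINANT_NAMES
from .ssa import SSAConfig
from .stacking import (MLPConfig, fit_stacked_model, predict_stacked,
                       predict_bases)

log = logging.getLogger("fermsensor")


@dataclass
class PipelineConfig:
    """Everything tunable about the offline build and the online loop."""

    k_range: tuple = (2, 3, 4, 5, 6, 7, 8)
    k_override: int = None          # skip elbow selection when set
    eta_min: int = 0
    eta_max: int = 500
    n_top_variables: int = 6
    mi_max_samples: int = 600
    similarity: sim.SimilarityConfig = field(default_factory=sim.SimilarityConfig)
    issa: SSAConfig = field(default_factory=lambda: SSAConfig(n=10, T=10))
    mlp: MLPConfig = field(default_factory=MLPConfig)
    meta_fraction: float = 0.2
    tune: bool = True
    seed: int = 0

    @classmethod
    def fast(cls, seed: int = 0) -> "PipelineConfig":
        """Desk-scale configuration: tiny ISSA budget, small meta-learner.

        With only ~60 neighbors per query the meta regression sees few,
        nearly collinear base predictions; the fast profile therefore uses
        an alternating-rank pre-separation (stride 2), a 4-unit hidden
        layer trained by L-BFGS and a strong weight decay so the fusion's
        variance stays below the base learners'.
        """
        return cls(
            k_range=(2, 3, 4, 5, 6),
            similarity=sim.SimilarityConfig(n_select=60),
            issa=SSAConfig(n=4, T=2, seed=seed),
            mlp=MLPConfig(hidden_layers=(4,), max_epochs=300,
                          solver="lbfgs", alpha=3.0, seed=seed),
            meta_fraction=0.5,
            mi_max_samples=400,
            seed=seed,
        )


@dataclass
class OfflineState:
    scaler: dom.ScalerStats
    subdatabases: list
    variable_sets: dict            # (domain_id, target) -> ordered names
    k: int
    sse: np.ndarray
    k_range: tuple
    config: PipelineConfig = field(repr=False, default=None)


def offline_build(train: pd.DataFrame, config: PipelineConfig = None) -> OfflineState:
    """Build sub-databases and per-domain variable signatures from history."""
    config = config or PipelineConfig()
    for col in AUX_NAMES + DOMINANT_NAMES:
        if col not in train.columns:
            raise ValueError(f"[offline] training table lacks column {col!r}")
    if len(train) < max(config.k_range) + 1:
        raise ValueError("[offline] too few training rows for the k range")

    scaler = dom.ScalerStats.fit(train, AUX_NAMES)
    z = scaler.transform(train)
    if config.k_override is not None:
        k = max(2, config.k_override)
        sse = np.array([])
    else:
        sse = dom.sse_curve(z, config.k_range)
        k = max(2, dom.elbow_select_k(sse, config.k_range))  # k >= 2 floor
    log.info("offline: elbow selected k=%d", k)
    init = dom.ifcm_initial_centers(z, k)
    fit = dom.fcm_fit(z, init)
    subdbs = dom.partition_into_subdatabases(
        train, fit, scaler, AUX_NAMES,
        eta_min=config.eta_min, eta_max=config.eta_max)

    variable_sets = {}
    for sdb in subdbs:
        for target in DOMINANT_NAMES:
            table = build_mi_table(sdb.records, target, domain_id=sdb.domain_id,
                                   m=config.n_top_variables,
                                   max_samples=config.mi_max_samples,
                                   seed=config.seed)
            variable_sets[(sdb.domain_id, target)] = table.selected
            log.info("offline: domain %d target %s -> %s",
                     sdb.domain_id, target, table.selected)
    return OfflineState(scaler=scaler, subdatabases=subdbs,
                        variable_sets=variable_sets, k=k, sse=sse,
                        k_range=tuple(config.k_range), config=config)


def _predict_one(state, query_row, target, config, window):
    """One JITL cycle; returns (prediction, per-base predictions, domain)."""
    zq_full = state.scaler.transform(
        query_row[AUX_NAMES].to_frame().T, AUX_NAMES)[0]
    window.append(zq_full)
    if len(window) > config.similarity.window:
        window.pop(0)
    d_id = sim.assign_subdatabase(np.array(window), state.subdatabases)
    sdb = state.subdatabases[d_id]
    names = state.variable_sets[(d_id, target)]

    Z = sdb.standardized(names)
    y = sdb.records[target].to_numpy(float)
    zq = state.scaler.transform(query_row[AUX_NAMES].to_frame().T, names)[0]

    sc = config.similarity
    sets = {}
    w_ed = sim.ed_similarity(zq, Z, sc.phi1)
    sets["ED"] = sim.select_similar_set(w_ed, sc.n_select, "ED")
    try:
        w_cwd = sim.cwd_similarity(zq, Z, y, sc.phi1)
        sets["CWD"] = sim.select_similar_set(w_cwd, sc.n_select, "CWD")
    except ValueError:                      # X^T y = 0: fall back to ED
        sets["CWD"] = sim.select_similar_set(w_ed, sc.n_select, "CWD")
    try:
        w_ang = sim.angle_distance_similarity(
            zq, Z, sc.phi2, sc.lambda_mix,
            center=sdb.center[[AUX_NAMES.index(n) for n in names]]
            if sc.center_angle else None)
        sets["ANGLE"] = sim.select_similar_set(w_ang, sc.n_select, "ANGLE")
    except ValueError:                      # all candidates excluded
        sets["ANGLE"] = sim.select_similar_set(w_ed, sc.n_select, "ANGLE")

    model = fit_stacked_model(sets, Z, y, config.issa, config.mlp,
                              fraction=config.meta_fraction, domain_id=d_id,
                              tune=config.tune)
    pred = predict_stacked(model, zq)
    bases = predict_bases(model, zq)
    del model                               # JITL contract: model discarded

    for s in sets.values():
        dom.record_similarity_hit(sdb, s.indices)
    pending = dict(query_row[AUX_NAMES])
    pending[target] = pred
    other = [t for t in DOMINANT_NAMES if t != target][0]
    # keep the table rectangular: carry the domain's mean for the other target
    pending[other] = float(sdb.records[other].mean())
    sdb.pending_store.append(pending)
    dom.prune_subdatabase(sdb)
    log.debug("query -> domain %d, %d/%d/%d neighbors, pred %.4g",
              d_id, *(len(sets[m]) for m in ("ED", "CWD", "ANGLE")), pred)
    return pred, bases, d_id


def online_predict(state: OfflineState, queries: pd.DataFrame, target: str,
                   config: PipelineConfig = None, return_details: bool = False):
    """Predict a stream of queries just-in-time; NaN for failed queries."""
    config = config or state.config or PipelineConfig()
    if target not in DOMINANT_NAMES:
        raise ValueError(f"target must be one of {DOMINANT_NAMES}")
    missing = [c for c in AUX_NAMES if c not in queries.columns]
    if missing:
        raise ValueError(f"queries lack auxiliary columns {missing}")
    preds = np.full(len(queries), np.nan)
    detail_rows = []
    window: list = []
    for i, (_, row) in enumerate(queries.iterrows()):
        try:
            pred, bases, d_id = _predict_one(state, row, target, config, window)
            preds[i] = pred
        except Exception as exc:  # an online sensor must not halt
            warnings.warn(f"query {i} failed: {exc}", stacklevel=2)
            bases, d_id = {}, -1
        if return_details:
            detail_rows.append({"query": i, "domain": d_id,
                                "stacked": preds[i], **bases})
    if return_details:
        return preds, pd.DataFrame(detail_rows)
    return preds


def evaluate(y, yhat) -> dict:
    """RMSE, R2, mean relative error, max absolute error (+ mean abs error).

    The relative error skips near-zero truths; R2 is None for a constant
    truth vector.  "Max absolute error" is the worst-case residual, not
    the mean.
    """
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if len(y) != len(yhat) or len(y) < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")
    ok = np.isfinite(yhat)
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} missing predictions excluded", stacklevel=2)
        y, yhat = y[ok], yhat[ok]
    err = y - yhat
    rmse = float(np.sqrt(np.mean(err ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if ss_tot == 0 else float(1.0 - np.sum(err ** 2) / ss_tot)
    nz = np.abs(y) > np.finfo(float).eps
    mre = float(np.mean(np.abs(err[nz]) / np.abs(y[nz]))) if nz.any() else None
    return {"rmse": rmse, "r2": r2, "mre": mre,
            "mae_max": float(np.max(np.abs(err))),
            "mean_ae": float(np.mean(np.abs(err)))}


# ---------------------------------------------------------------------------
# Persistence: directory of CSV (records) + JSON (everything else)

def save_state(state: OfflineState, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "k": state.k,
        "k_range": list(state.k_range),
        "sse": list(map(float, state.sse)),
        "scaler": {"names": state.scaler.names,
                   "mean": state.scaler.mean.tolist(),
                   "sd": state.scaler.sd.tolist()},
        "variable_sets": {f"{d}:{t}": v
                          for (d, t), v in state.variable_sets.items()},
        "domains": [],
    }
    for sdb in state.subdatabases:
        sdb.records.to_csv(path / f"domain_{sdb.domain_id}.csv", index=False)
        manifest["domains"].append({
            "domain_id": sdb.domain_id,
            "gamma": sdb.gamma.tolist(),
            "eta_min": sdb.eta_min, "eta_max": sdb.eta_max,
            "center": sdb.center.tolist(), "cov": sdb.cov.tolist(),
            "feature_names": sdb.feature_names,
            "pending_store": [{k: float(v) for k, v in p.items()}
                              for p in sdb.pending_store],
        })
    (path / "state.json").write_text(json.dumps(manifest, indent=1))


def load_state(path) -> OfflineState:
    path = Path(path)
    manifest = json.loads((path / "state.json").read_text())
    scaler = dom.ScalerStats(names=manifest["scaler"]["names"],
                             mean=np.array(manifest["scaler"]["mean"]),
                             sd=np.array(manifest["scaler"]["sd"]))
    subdbs = []
    for meta in manifest["domains"]:
        records = pd.read_csv(path / f"domain_{meta['domain_id']}.csv")
        subdbs.append(dom.SubDatabase(
            domain_id=meta["domain_id"], records=records,
            gamma=np.array(meta["gamma"], dtype=int),
            eta_min=meta["eta_min"], eta_max=meta["eta_max"],
            center=np.array(meta["center"]), cov=np.array(meta["cov"]),
            feature_names=meta["feature_names"], scaler=scaler,
            pending_store=list(meta.get("pending_store", []))))
    variable_sets = {}
    for key, v in manifest["variable_sets"].items():
        d, t = key.split(":")
        variable_sets[(int(d), t)] = v
    return OfflineState(scaler=scaler, subdatabases=subdbs,
                        variable_sets=variable_sets, k=manifest["k"],
                        sse=np.array(manifest["sse"]),
                        k_range=tuple(manifest["k_range"]))
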