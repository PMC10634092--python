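"""Offline local query domains: improved fuzzy C-means and adaptive pruning.

The offline stage of a just-in-time-learning soft sensor splits the
historical sample table into a small number of *sub-databases* (local
query domains) so that online neighbor searches scan only one cluster.
The clustering engine is fuzzy C-means (FCM) with two refinements:

* the number of clusters is picked by the elbow of the SSE(k) curve,
  where SSE(k) is the converged FCM objective J_m at that k;
* initial centers are chosen deterministically by ranking samples by
  Mahalanobis distance to the (standardized) data origin, splitting the
  ranked sequence into k contiguous equal subsets and taking the middle
  sample of each — no random initialization anywhere.

Each sub-database carries a per-record *similarity query label* gamma
counting how often the record was selected as a JITL neighbor.  When any
gamma reaches eta_max the domain prunes rarely-used records
(gamma <= eta_min), merges the predictions accumulated since the last
prune as new records, and resets all labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ScalerStats:
    """Per-variable mean/sd from training data (z-score standardization)."""

    names: list
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, table: pd.DataFrame, names: list) -> "ScalerStats":
        x = table[names].to_numpy(float)
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        bad = [n for n, s in zip(names, sd) if not s > 0]
        if bad:
            raise ValueError(f"zero-variance variables cannot be standardized: {bad}")
        return cls(names=list(names), mean=mean, sd=sd)

    def transform(self, table, names=None) -> np.ndarray:
        names = self.names if names is None else list(names)
        idx = [self.names.index(n) for n in names]
        if isinstance(table, pd.DataFrame):
            x = table[names].to_numpy(float)
        else:
            x = np.atleast_2d(np.asarray(table, float))
        return (x - self.mean[idx]) / self.sd[idx]


@dataclass
class FCMResult:
    centers: np.ndarray             # c x d
    membership: np.ndarray          # n x c, rows sum to 1
    m: float
    objective_history: np.ndarray   # J_m per iteration, non-increasing
    n_iter: int


@dataclass
class SubDatabase:
    """One local query domain: records, usage labels and pruning thresholds."""

    domain_id: int
    records: pd.DataFrame
    gamma: np.ndarray
    eta_min: int
    eta_max: int
    center: np.ndarray
    cov: np.ndarray
    feature_names: list
    scaler: ScalerStats
    pending_store: list = field(default_factory=list)

    def __post_init__(self):
        if not self.eta_min < self.eta_max:
            raise ValueError("eta_min must be < eta_max")

    def standardized(self, names=None) -> np.ndarray:
        return self.scaler.transform(self.records, names or self.feature_names)

    def __len__(self):
        return len(self.records)


def regularized_cov(x: np.ndarray, eps_scale: float = 1e-6) -> np.ndarray:
    """Sample covariance with a trace-scaled ridge for invertibility."""
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] < 2:
        return np.eye(x.shape[1])
    cov = np.atleast_2d(np.cov(x, rowvar=False))
    d = cov.shape[0]
    tr = np.trace(cov)
    ridge = eps_scale * (tr / d if tr > 0 else 1.0)
    return cov + ridge * np.eye(d)


def mahalanobis_distance(x, y, cov) -> float:
    """sqrt((x-y)^T Sigma^-1 (x-y)); Sigma must be symmetric PD."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    cov = np.atleast_2d(np.asarray(cov, float))
    diff = x - y
    try:
        sol = np.linalg.solve(cov, diff)
    except np.linalg.LinAlgError:
        deficient = [i for i, v in enumerate(np.diag(cov)) if v <= 0]
        raise ValueError(
            f"singular covariance matrix; deficient dimensions {deficient}"
        ) from None
    d2 = float(diff @ sol)
    return float(np.sqrt(max(d2, 0.0)))


def ifcm_initial_centers(data: np.ndarray, k: int) -> np.ndarray:
    """Deterministic FCM initialization by Mahalanobis ranking.

    Rank all (standardized) samples by Mahalanobis distance to the origin,
    split the ranked sequence into k contiguous subsets of near-equal size
    (remainder spread over the first subsets), and return the middle sample
    (index ceil(size/2), 1-based) of each subset.  Row order of the input
    does not matter: ties in distance are broken lexicographically by
    coordinates.
    """
    data = np.asarray(data, float)
    n, d = data.shape
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples n={n}")
    cov = regularized_cov(data) if n > 1 else np.eye(d)
    inv = np.linalg.inv(cov)
    d2 = np.einsum("ij,jk,ik->i", data, inv, data)
    order = np.lexsort(tuple(data[:, j] for j in reversed(range(d))) + (d2,))
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    centers = []
    start = 0
    for s in sizes:
        mid = start + int(np.ceil(s / 2)) - 1
        centers.append(data[order[mid]])
        start += s
    return np.array(centers)


def _memberships(data, centers, m):
    """FCM membership update with coincident-point singularity handling."""
    # squared Euclidean distances n x c
    d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 1e-300
    u = np.empty_like(d2)
    power = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-power)
    inv[zero] = 0.0
    row_zero = zero.any(axis=1)
    u[~row_zero] = inv[~row_zero] / inv[~row_zero].sum(axis=1, keepdims=True)
    if row_zero.any():
        u[row_zero] = zero[row_zero] / zero[row_zero].sum(axis=1, keepdims=True)
    return u, d2


def fcm_fit(data, init_centers, m: float = 2.0, tol: float = 1e-6,
            max_iter: int = 300) -> FCMResult:
    """Alternating-optimization fuzzy C-means from the given initial centers.

    Minimizes J_m = sum_i sum_j u_ij^m ||x_i - v_j||^2 with Euclidean
    distances; stops when |delta J_m| < tol or max_iter.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    data = np.asarray(data, float)
    centers = np.array(init_centers, float, copy=True)
    history = []
    u = None
    for it in range(max_iter):
        u, d2 = _memberships(data, centers, m)
        um = u ** m
        centers = (um.T @ data) / um.sum(axis=0)[:, None]
        _, d2 = _memberships(data, centers, m)
        J = float((um * d2).sum())
        history.append(J)
        if it > 0 and abs(history[-2] - history[-1]) < tol:
            break
    u, _ = _memberships(data, centers, m)
    return FCMResult(centers=centers, membership=u, m=m,
                     objective_history=np.array(history), n_iter=len(history))


def sse_curve(data, k_range, m: float = 2.0, tol: float = 1e-6,
              max_iter: int = 300) -> np.ndarray:
    """Converged J_m for each candidate cluster count (elbow-method input)."""
    data = np.asarray(data, float)
    n = len(data)
    sse = []
    for k in k_range:
        if k >= n:
            raise ValueError(f"k={k} must be < n={n}")
        if k == 1:
            center = data.mean(axis=0, keepdims=True)
            sse.append(float(((data - center) ** 2).sum()))
            continue
        init = ifcm_initial_centers(data, k)
        fit = fcm_fit(data, init, m=m, tol=tol, max_iter=max_iter)
        sse.append(float(fit.objective_history[-1]))
    return np.array(sse)


def elbow_select_k(sse, k_range) -> int:
    """Pick k at the sharpest bend: max discrete second difference of SSE.

    Interior candidates only; ties resolve to the smallest k.
    """
    sse = np.asarray(sse, float)
    k_range = list(k_range)
    if len(sse) != len(k_range):
        raise ValueError("sse and k_range lengths differ")
    if len(sse) < 3:
        raise ValueError("elbow selection needs at least 3 candidate k values")
    second = sse[:-2] - 2.0 * sse[1:-1] + sse[2:]
    best = int(np.argmax(second))          # argmax takes first (= smallest k) on ties
    return k_range[1 + best]


def partition_into_subdatabases(
    table: pd.DataFrame,
    fcm: FCMResult,
    scaler: ScalerStats,
    feature_names: list,
    eta_min: int = 0,
    eta_max: int = 500,
) -> list[SubDatabase]:
    """Assign each record to its max-membership cluster (ties -> lowest id)."""
    u = fcm.membership
    if len(u) != len(table):
        raise ValueError("membership rows do not match table rows")
    assign = u.argmax(axis=1)
    subdbs = []
    for j in range(u.shape[1]):
        mask = assign == j
        if not mask.any():
            raise ValueError(
                f"cluster {j} received no records; reduce the number of clusters"
            )
        records = table.loc[mask].reset_index(drop=True)
        z = scaler.transform(records, feature_names)
        subdbs.append(SubDatabase(
            domain_id=j, records=records, gamma=np.zeros(mask.sum(), dtype=int),
            eta_min=eta_min, eta_max=eta_max,
            center=z.mean(axis=0), cov=regularized_cov(z),
            feature_names=list(feature_names), scaler=scaler,
        ))
    return subdbs


def record_similarity_hit(subdb: SubDatabase, indices) -> SubDatabase:
    """Increment the similarity query label of each selected record."""
    idx = np.asarray(list(indices), dtype=int)
    if idx.size:
        np.add.at(subdb.gamma, idx, 1)
    return subdb


def prune_subdatabase(subdb: SubDatabase) -> SubDatabase:
    """Adaptive pruning: fire when any gamma reaches eta_max.

    On trigger, records with gamma <= eta_min are deleted, the pending
    (query, prediction) pairs accumulated since the last prune are merged
    as new records (flagged ``merged_prediction``), every gamma is reset to
    zero and the domain's center/covariance are recomputed.  If deletion
    would empty the domain, the heavily-used records are kept and a warning
    is issued.
    """
    if subdb.gamma.size == 0 or subdb.gamma.max() < subdb.eta_max:
        return subdb
    keep = subdb.gamma > subdb.eta_min
    if not keep.any():
        keep = subdb.gamma == subdb.gamma.max()
        warnings.warn(
            f"domain {subdb.domain_id}: prune would empty the sub-database; "
            "keeping the most-queried records", stacklevel=2)
    records = subdb.records.loc[keep].reset_index(drop=True)
    if "merged_prediction" not in records.columns:
        records = records.assign(merged_prediction=False)
    if subdb.pending_store:
        merged = pd.DataFrame([dict(q, merged_prediction=True)
                               for q in subdb.pending_store])
        records = pd.concat([records, merged], ignore_index=True)
    subdb.records = records
    subdb.gamma = np.zeros(len(records), dtype=int)
    subdb.pending_store = []
    z = subdb.standardized()
    subdb.center = z.mean(axis=0)
    subdb.cov = regularized_cov(z)
    return subdb
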