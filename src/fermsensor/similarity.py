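"""Online query handling: domain assignment and multi-metric neighbor sets.

An incoming query is first routed to a sub-database by the Kullback-
Leibler divergence between a Gaussian fitted to a sliding window of recent
queries and each domain's Gaussian (falling back to Mahalanobis distance
to the domain centers while the window is shorter than d+2).  Within the
assigned domain, three deliberately different similarity metrics each pick
their own weighted neighbor set for the query:

* ED   — Euclidean distance with the exponential locality kernel
         w_i = exp(-d_i^2 / (phi1 * sigma_d));
* CWD  — covariance-weighted distance through the rank-1 projector
         H = (X^T y)(X^T y)^T / ||X^T y||^2, i.e. distance along the
         direction in input space most aligned with the output;
* ANGLE — a blend of the distance kernel and the cosine of the angle
         between (centered) sample vectors,
         w_i = lambda * sqrt(exp(-d_i^2/(phi2 sigma_d))) + (1-lambda) cos(theta_i),
         with candidates at cos(theta_i) < 0 excluded outright.

sigma_d is always the standard deviation of the current query's distance
vector, so locality adapts to how crowded the neighborhood is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .domains import SubDatabase, mahalanobis_distance, regularized_cov

METRICS = ("ED", "CWD", "ANGLE")


@dataclass
class SimilarityConfig:
    phi1: float = 1.0           # locality adjustment, ED / CWD kernel
    phi2: float = 1.0           # locality adjustment, ANGLE kernel
    lambda_mix: float = 0.5     # distance/angle blend in [0, 1]
    n_select: int = 60          # neighbors retained per metric
    window: int = 8             # recent-query window for KL assignment
    center_angle: bool = True   # mean-center vectors before the cosine

    def __post_init__(self):
        if self.phi1 <= 0 or self.phi2 <= 0:
            raise ValueError("phi1 and phi2 must be > 0")
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ValueError("lambda_mix must lie in [0, 1]")
        if self.n_select < 2:
            raise ValueError("n_select must be >= 2")


@dataclass
class SimilaritySet:
    metric: str
    indices: np.ndarray          # ranked positions into the sub-database
    weights: np.ndarray          # descending, aligned with indices

    def __len__(self):
        return len(self.indices)


def _exp_kernel(d: np.ndarray, phi: float) -> np.ndarray:
    sigma = d.std()
    if sigma == 0:
        warnings.warn("all candidates equidistant from the query; "
                      "uniform weights", stacklevel=3)
        return np.ones_like(d)
    return np.exp(-(d ** 2) / (phi * sigma))


def ed_similarity(query, candidates, phi1: float = 1.0) -> np.ndarray:
    """Euclidean-distance weights w_i = exp(-d_i^2/(phi1 sigma_d))."""
    query = np.asarray(query, float).ravel()
    candidates = np.atleast_2d(np.asarray(candidates, float))
    d = np.linalg.norm(candidates - query, axis=1)
    return _exp_kernel(d, phi1)


def cwd_similarity(query, X, y, phi1: float = 1.0) -> np.ndarray:
    """Covariance-weighted distance converted through the same kernel.

    X and y are the sub-database's standardized inputs and target; the
    weighting matrix is the rank-1 projector onto X^T y, so the distance
    only measures separation along the input direction correlated with
    the output.
    """
    query = np.asarray(query, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    v = X.T @ y
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("X^T y is zero; CWD undefined, fall back to ED")
    u = v / norm
    d = np.abs((X - query) @ u)
    return _exp_kernel(d, phi1)


def cwd_weight_matrix(X, y) -> np.ndarray:
    """The explicit rank-1 projector H (trace 1, idempotent)."""
    v = np.atleast_2d(np.asarray(X, float)).T @ np.asarray(y, float).ravel()
    n2 = float(v @ v)
    if n2 == 0:
        raise ValueError("X^T y is zero; CWD undefined")
    return np.outer(v, v) / n2


def angle_distance_similarity(query, candidates, phi2: float = 1.0,
                              lambda_mix: float = 0.5,
                              center=None) -> np.ndarray:
    """Blended distance/angle weights; cos(theta) < 0 candidates are NaN.

    Returns an array aligned with the candidates; excluded candidates
    (negative cosine, or zero-norm vectors after centering) carry NaN so
    callers can mask them.
    """
    query = np.asarray(query, float).ravel()
    candidates = np.atleast_2d(np.asarray(candidates, float))
    d = np.linalg.norm(candidates - query, axis=1)
    kern = np.sqrt(_exp_kernel(d, phi2))
    qc = query - center if center is not None else query
    cc = candidates - center if center is not None else candidates
    qn = np.linalg.norm(qc)
    cn = np.linalg.norm(cc, axis=1)
    cos = np.full(len(candidates), np.nan)
    valid = (cn > 0) & (qn > 0)
    exact = d == 0
    cos[valid] = (cc[valid] @ qc) / (cn[valid] * qn)
    cos[exact] = 1.0                      # identical sample: angle 0 by definition
    if (~valid & ~exact).any():
        warnings.warn("zero-norm vectors excluded from the angle metric",
                      stacklevel=2)
    w = lambda_mix * kern + (1.0 - lambda_mix) * cos
    w[np.isnan(cos) | (cos < 0)] = np.nan
    return w


def select_similar_set(weights, n_select: int, metric: str = "ED") -> SimilaritySet:
    """Top-n_select candidates by weight; ties keep the lower index."""
    w = np.asarray(weights, float)
    admissible = np.flatnonzero(np.isfinite(w))
    if admissible.size == 0:
        raise ValueError("no admissible candidates for this metric")
    # stable sort on (-weight) preserves index order among ties
    order = admissible[np.argsort(-w[admissible], kind="stable")]
    top = order[:n_select]
    return SimilaritySet(metric=metric, indices=top, weights=w[top])


def gaussian_kl(mean_p, cov_p, mean_q, cov_q) -> float:
    """Closed-form KL(N_p || N_q) between multivariate Gaussians."""
    mean_p = np.asarray(mean_p, float)
    mean_q = np.asarray(mean_q, float)
    d = len(mean_p)
    sol_cov = np.linalg.solve(cov_q, cov_p)
    diff = mean_q - mean_p
    maha = float(diff @ np.linalg.solve(cov_q, diff))
    _, logdet_q = np.linalg.slogdet(cov_q)
    _, logdet_p = np.linalg.slogdet(cov_p)
    return 0.5 * (np.trace(sol_cov) + maha - d + logdet_q - logdet_p)


def assign_subdatabase(query_window, subdbs: list[SubDatabase]) -> int:
    """Route a query to the sub-database with minimal Gaussian KL divergence.

    ``query_window`` holds the recent queries (rows, standardized feature
    space), the current query last.  With fewer than d+2 rows a Gaussian
    fit is ill-posed, so the current query's Mahalanobis distance to each
    domain center decides instead.  Ties go to the lowest domain id.
    """
    if not subdbs:
        raise ValueError("no sub-databases")
    qw = np.atleast_2d(np.asarray(query_window, float))
    d = qw.shape[1]
    scores = []
    if len(qw) >= d + 2:
        mean_q = qw.mean(axis=0)
        cov_q = regularized_cov(qw)
        for sdb in subdbs:
            scores.append(gaussian_kl(mean_q, cov_q, sdb.center, sdb.cov))
    else:
        q = qw[-1]
        for sdb in subdbs:
            scores.append(mahalanobis_distance(q, sdb.center, sdb.cov))
    scores = np.asarray(scores)
    if not np.all(np.isfinite(scores)):
        raise ValueError("domain covariances singular; cannot assign query")
    return int(np.argmin(scores))        # argmin takes the lowest id on ties
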