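"""Per-domain auxiliary-variable screening by k-NN mutual information.

Implements the Kraskov–Stögbauer–Grassberger (KSG) estimator, variant 2:

    I(x, y) = psi(k) - 1/k - < psi(n_x) + psi(n_y) > + psi(N)

For each point the k-th nearest neighbor is found in the joint space under
the max-norm; eps_x and eps_y are the marginal projections of the k
nearest joint neighbors, and n_x, n_y count the marginal neighbors inside
those per-point radii (the boundary neighbor included, as the variant-2
counting requires).  Values are in nats and may be slightly negative by
estimation noise; they are returned as-is.

Each query domain ranks its auxiliary channels by MI against the dominant
variable being predicted and keeps the top m (default 6) as that domain's
soft-sensor signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma as _digamma

from .simulate import AUX_NAMES


def digamma(x):
    """Digamma psi(x) for x > 0 (library-backed, validated domain)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("digamma requires x > 0")
    out = _digamma(x)
    return float(out) if out.ndim == 0 else out


def kmi_estimate(x, y, k: int = 4, jitter: float = 1e-10, seed: int = 0) -> float:
    """KSG variant-2 mutual information between two scalar series, in nats.

    A tiny seeded jitter (relative to each variable's spread) breaks the
    exact duplicates that interpolation onto a shared grid produces, which
    would otherwise defeat neighbor counting.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n <= k:
        raise ValueError(f"need more than k={k} samples, got {n}")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant vector has zero marginal spread")
    if jitter > 0:
        rng = np.random.default_rng(seed)
        x = x + jitter * sx * rng.standard_normal(n)
        y = y + jitter * sy * rng.standard_normal(n)

    joint = np.column_stack([x, y])
    tree = cKDTree(joint)
    # k+1 because the query point itself is returned at distance 0
    _, idx = tree.query(joint, k=k + 1, p=np.inf)
    neigh = idx[:, 1:]
    eps_x = np.abs(x[neigh] - x[:, None]).max(axis=1)
    eps_y = np.abs(y[neigh] - y[:, None]).max(axis=1)

    xs = np.sort(x)
    ys = np.sort(y)
    # count points within the closed marginal radius, excluding the point itself
    n_x = (np.searchsorted(xs, x + eps_x, side="right")
           - np.searchsorted(xs, x - eps_x, side="left")) - 1
    n_y = (np.searchsorted(ys, y + eps_y, side="right")
           - np.searchsorted(ys, y - eps_y, side="left")) - 1
    n_x = np.maximum(n_x, 1)
    n_y = np.maximum(n_y, 1)
    return float(digamma(k) - 1.0 / k
                 - np.mean(digamma(n_x) + digamma(n_y)) + digamma(n))


@dataclass
class MITable:
    """Ranked mutual information of auxiliary channels for one domain/target."""

    domain_id: int
    target: str
    mi: dict                 # variable name -> MI (nats)
    selected: list           # top-m names, descending MI

    def ranking(self) -> list:
        return rank_variables(self.mi)


def rank_variables(mi: dict, order=None) -> list:
    """Names sorted by descending MI; ties broken by the canonical order."""
    order = list(order) if order is not None else AUX_NAMES
    pos = {n: i for i, n in enumerate(order)}
    return sorted(mi, key=lambda n: (-mi[n], pos.get(n, len(pos))))


def select_auxiliary_variables(mi: dict, m: int = 6, order=None) -> list:
    """Top-m variables by descending MI (the domain's model signature)."""
    if m > len(mi):
        raise ValueError(f"cannot select m={m} of {len(mi)} variables")
    return rank_variables(mi, order=order)[:m]


def build_mi_table(records, target: str, domain_id: int = 0, m: int = 6,
                   variables=None, k: int = 4, max_samples: int = 600,
                   seed: int = 0) -> MITable:
    """Estimate MI of every auxiliary channel against one dominant variable.

    Large domains are subsampled (evenly over rows) to bound the k-NN cost;
    the subsample is deterministic for a given seed.
    """
    variables = list(variables) if variables is not None else AUX_NAMES
    y = records[target].to_numpy(float)
    n = len(y)
    if n > max_samples:
        rows = np.linspace(0, n - 1, max_samples).round().astype(int)
    else:
        rows = np.arange(n)
    mi = {}
    for v in variables:
        mi[v] = kmi_estimate(records[v].to_numpy(float)[rows], y[rows],
                             k=k, seed=seed)
    return MITable(domain_id=domain_id, target=target, mi=mi,
                   selected=select_auxiliary_variables(mi, m=m))


def build_joint_mi_table(records, targets, domain_id: int = 0, m: int = 6,
                         **kwargs) -> MITable:
    """One table per domain with MI averaged over the dominant variables.

    Alternative to the per-target tables: useful when a single variable
    signature should serve every target of a domain.
    """
    tables = [build_mi_table(records, t, domain_id=domain_id, m=m, **kwargs)
              for t in targets]
    mi = {v: float(np.mean([t.mi[v] for t in tables]))
          for v in tables[0].mi}
    return MITable(domain_id=domain_id, target="+".join(targets), mi=mi,
                   selected=select_auxiliary_variables(mi, m=m))
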