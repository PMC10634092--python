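"""Similarity metrics, neighbor selection and KL domain assignment."""

import numpy as np
import pandas as pd
import pytest

from fermsensor import similarity as sim
from fermsensor.domains import (ScalerStats, SubDatabase, fcm_fit,
                                ifcm_initial_centers,
                                partition_into_subdatabases, regularized_cov)


@pytest.fixture
def anisotropic():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(80, 4)) * np.array([3.0, 1.0, 0.3, 0.1])
    y = X @ np.array([0.1, 2.0, 0.0, 0.0]) + 0.05 * rng.normal(size=80)
    return X, y


# --- ED ---------------------------------------------------------------------

def test_ed_identity_and_monotonicity():
    cands = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
    w = sim.ed_similarity([0.0, 0.0], cands, phi1=1.0)
    assert w[0] == pytest.approx(1.0)
    assert np.all(np.diff(w) < 0)
    assert np.all((w > 0) & (w <= 1))


def test_ed_kernel_matches_direct_evaluation():
    """Weights equal exp(-d_i^2/(phi1 sigma_d)) with sigma_d from this
    query's own distance vector; a candidate sitting at d^2 = phi1*sigma_d
    gets weight exactly 1/e."""
    rng = np.random.default_rng(2)
    cands = rng.normal(size=(25, 3))
    q = rng.normal(size=3)
    phi1 = 2.0
    d = np.linalg.norm(cands - q, axis=1)
    expected = np.exp(-(d ** 2) / (phi1 * d.std()))
    got = sim.ed_similarity(q, cands, phi1=phi1)
    assert np.allclose(got, expected)
    at_scale = np.abs(d ** 2 - phi1 * d.std()).argmin()
    assert np.isclose(got[at_scale], np.exp(-1.0), atol=0.2)


def test_ed_degenerate_all_identical_warns():
    with pytest.warns(UserWarning, match="equidistant"):
        w = sim.ed_similarity([1.0, 1.0], np.ones((3, 2)), phi1=1.0)
    assert np.all(w == 1.0)


# --- CWD --------------------------------------------------------------------

def test_cwd_projector_properties(anisotropic):
    X, y = anisotropic
    H = sim.cwd_weight_matrix(X, y)
    assert np.trace(H) == pytest.approx(1.0)
    assert np.allclose(H @ H, H, atol=1e-12)
    assert np.allclose(H, H.T)


def test_cwd_rank1_reduces_to_single_feature_distance():
    """When y correlates only with feature 1, the CWD distance is the
    absolute feature-1 difference."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 3))
    y = 2.0 * X[:, 0]                      # X^T y ~ e1 (up to noise-free algebra)
    q = np.zeros(3)
    v = X.T @ y
    u = v / np.linalg.norm(v)
    expected_d = np.abs((X - q) @ u)
    H = sim.cwd_weight_matrix(X, y)
    diffs = X - q
    d_via_H = np.sqrt(np.einsum("ij,jk,ik->i", diffs, H, diffs))
    assert np.allclose(d_via_H, expected_d, atol=1e-10)
    # weights: identity candidate gets 1
    w = sim.cwd_similarity(X[0], X, y)
    assert w[0] == pytest.approx(1.0)


def test_cwd_zero_direction_errors():
    X = np.array([[1.0, 0.0], [-1.0, 0.0]])
    y = np.array([1.0, 1.0])
    with pytest.raises(ValueError, match="fall back"):
        sim.cwd_similarity([0.0, 0.0], X, y)


# --- angle + distance -------------------------------------------------------

def test_angle_identity_candidate_weight_one():
    cands = np.array([[1.0, 1.0], [2.0, 0.5], [0.5, 2.0]])
    for lam in (0.0, 0.5, 1.0):
        w = sim.angle_distance_similarity([1.0, 1.0], cands, lambda_mix=lam)
        assert w[0] == pytest.approx(1.0)


def test_angle_opposite_candidate_excluded():
    cands = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]])
    w = sim.angle_distance_similarity([1.0, 0.0], cands, lambda_mix=0.5)
    assert np.isnan(w[1])                  # cos = -1 < 0
    assert np.isfinite(w[0]) and np.isfinite(w[2])


def test_angle_lambda_one_is_sqrt_of_ed_kernel():
    rng = np.random.default_rng(1)
    cands = rng.normal(size=(30, 3)) + 2.0
    q = np.full(3, 2.0)
    w_angle = sim.angle_distance_similarity(q, cands, phi2=1.0, lambda_mix=1.0)
    w_ed = sim.ed_similarity(q, cands, phi1=1.0)
    assert np.allclose(w_angle, np.sqrt(w_ed))
    # and the rankings coincide
    assert np.array_equal(np.argsort(-w_angle), np.argsort(-w_ed))


# --- top-k selection --------------------------------------------------------

def test_select_saturation_and_ties():
    s = sim.select_similar_set(np.array([0.9, 0.9, 0.1]), n_select=5)
    assert list(s.indices) == [0, 1, 2]
    assert np.all(np.diff(s.weights) <= 0)
    s1 = sim.select_similar_set(np.array([0.9, 0.9, 0.1]), n_select=2)
    assert list(s1.indices) == [0, 1]      # tie keeps the lower index first
    top = sim.select_similar_set(np.array([0.3, 0.8, 0.5, np.nan]), 2)
    assert list(top.indices) == [1, 2]


def test_select_with_nothing_admissible_errors():
    with pytest.raises(ValueError, match="admissible"):
        sim.select_similar_set(np.array([np.nan, np.nan]), 2)


def test_metric_diversity_on_anisotropic_data(anisotropic):
    """The three neighbor sets should not coincide on anisotropic data."""
    X, y = anisotropic
    q = X.mean(axis=0) + np.array([1.0, -0.5, 0.1, 0.0])
    sets = {
        "ED": sim.select_similar_set(sim.ed_similarity(q, X), 15),
        "CWD": sim.select_similar_set(sim.cwd_similarity(q, X, y), 15),
        "ANGLE": sim.select_similar_set(
            sim.angle_distance_similarity(q, X, center=X.mean(axis=0)), 15),
    }
    pairs = [("ED", "CWD"), ("ED", "ANGLE"), ("CWD", "ANGLE")]
    jaccards = []
    for a, b in pairs:
        ia, ib = set(sets[a].indices), set(sets[b].indices)
        jaccards.append(len(ia & ib) / len(ia | ib))
    assert min(jaccards) < 1.0


# --- KL assignment ----------------------------------------------------------

def test_gaussian_kl_identity_and_positivity():
    rng = np.random.default_rng(0)
    A = rng.normal(size=(3, 3))
    cov = A @ A.T + np.eye(3)
    mean = rng.normal(size=3)
    assert sim.gaussian_kl(mean, cov, mean, cov) == pytest.approx(0.0, abs=1e-10)
    cov2 = cov + np.diag([1.0, 0.0, 0.0])
    assert sim.gaussian_kl(mean, cov, mean + 1, cov2) > 0


def _gaussian_domains(rng, means, d=3, n=200):
    subdbs = []
    for j, mu in enumerate(means):
        z = mu + rng.normal(size=(n, d))
        subdbs.append(SubDatabase(
            domain_id=j, records=pd.DataFrame(z), gamma=np.zeros(n, dtype=int),
            eta_min=1, eta_max=10, center=z.mean(axis=0),
            cov=regularized_cov(z), feature_names=list(range(d)), scaler=None))
    return subdbs


def test_assignment_recovers_source_domain():
    """Windows drawn from one domain's own Gaussian route back to it."""
    rng = np.random.default_rng(7)
    means = [np.zeros(3), np.full(3, 4.0), np.array([4.0, -4.0, 0.0])]
    subdbs = _gaussian_domains(rng, means)
    correct = 0
    trials = 100
    for t in range(trials):
        j = t % 3
        window = means[j] + rng.normal(size=(50, 3))
        correct += sim.assign_subdatabase(window, subdbs) == j
    assert correct >= 95


def test_assignment_tie_prefers_lowest_id():
    rng = np.random.default_rng(0)
    z = rng.normal(size=(100, 3))
    subdbs = _gaussian_domains(rng, [np.zeros(3)])
    twin = _gaussian_domains(rng, [np.zeros(3)])[0]
    twin.domain_id = 1
    twin.center, twin.cov = subdbs[0].center, subdbs[0].cov
    assert sim.assign_subdatabase(z, subdbs + [twin]) == 0


def test_assignment_cold_start_uses_mahalanobis():
    rng = np.random.default_rng(3)
    means = [np.zeros(3), np.full(3, 6.0)]
    subdbs = _gaussian_domains(rng, means)
    # a single query (window << d+2) near domain 1
    assert sim.assign_subdatabase(np.full((1, 3), 6.0), subdbs) == 1
    assert sim.assign_subdatabase(np.zeros((1, 3)), subdbs) == 0


def test_config_validation():
    with pytest.raises(ValueError):
        sim.SimilarityConfig(phi1=0.0)
    with pytest.raises(ValueError):
        sim.SimilarityConfig(lambda_mix=1.5)
    with pytest.raises(ValueError):
        sim.SimilarityConfig(n_select=1)
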