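"""Subspace distances, the perturbation bound, shuffle and resampling."""

import numpy as np
import pytest

from crefkit import (
    dual_decompose,
    perturbation_bound,
    resample_spectrum,
    shuffle_stability,
    subspace_distance,
)


def _orthobasis(rng, n, k):
    Q, _ = np.linalg.qr(rng.normal(size=(n, k)))
    return Q


# ---------------------------------------------------------------------------
# Subspace distance
# ---------------------------------------------------------------------------

def test_identical_subspaces_distance_zero(rng):
    X = _orthobasis(rng, 6, 2)
    assert subspace_distance(X, X) == pytest.approx(0.0, abs=1e-10)


def test_orthogonal_planes_distance_one(rng):
    Q = _orthobasis(rng, 4, 4)
    assert subspace_distance(Q[:, :2], Q[:, 2:]) == pytest.approx(1.0, abs=1e-10)


def test_distance_matches_max_min_sampling_oracle(rng):
    """Dense sampling of the displayed max-min definition."""
    X = _orthobasis(rng, 6, 2)
    Y = _orthobasis(rng, 6, 2)
    rho = subspace_distance(X, Y)
    phis = np.linspace(0, 2 * np.pi, 20001)
    PY = Y @ Y.T
    PX = X @ X.T

    def directional(A, P):
        pts = A @ np.vstack([np.cos(phis), np.sin(phis)])  # unit vectors of span A
        residual = pts - P @ pts
        return np.linalg.norm(residual, axis=0).max()

    oracle = max(directional(X, PY), directional(Y, PX))
    assert rho == pytest.approx(oracle, abs=1e-3)


def test_distance_symmetric_and_rotation_invariant(rng):
    X = _orthobasis(rng, 8, 2)
    Y = _orthobasis(rng, 8, 2)
    t = rng.uniform(0, np.pi)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    assert subspace_distance(X, Y) == pytest.approx(subspace_distance(Y, X), abs=1e-10)
    assert subspace_distance(X @ R, Y) == pytest.approx(
        subspace_distance(X, Y), abs=1e-10
    )


def test_non_orthonormal_basis_rejected(rng):
    X = rng.normal(size=(6, 2))
    with pytest.raises(ValueError, match="orthonormal"):
        subspace_distance(X, X)


# ---------------------------------------------------------------------------
# Perturbation bound
# ---------------------------------------------------------------------------

def test_zero_perturbation_zero_bound():
    res = perturbation_bound(10, 8, 7, 5, 0.0)
    assert res.applicable and res.bound == 0.0


def test_large_perturbation_inapplicable():
    res = perturbation_bound(10, 8, 7, 5, 2.5)  # min gap = 2
    assert not res.applicable and res.bound is None


def test_ordering_violation_rejected():
    with pytest.raises(ValueError):
        perturbation_bound(8, 10, 7, 5, 0.1)


def test_bound_contains_exact_distance(rng):
    """Exact eigen-decomposition oracle over random perturbed matrices."""
    for _ in range(50):
        n = 20
        Q = _orthobasis(rng, n, n)
        lam = np.sort(rng.uniform(1, 50, n))[::-1]
        D = (Q * lam) @ Q.T
        gap = min(lam[2] - lam[3], lam[4] - lam[5])
        E = rng.normal(size=(n, n))
        E = (E + E.T) / 2
        E *= rng.uniform(0.05, 0.3) * gap / np.linalg.norm(E, 2)
        res = perturbation_bound(lam[2], lam[3], lam[4], lam[5], np.linalg.norm(E, 2))
        w, V = np.linalg.eigh(D + E)
        V = V[:, np.argsort(w)[::-1]]
        rho = subspace_distance(Q[:, 3:5], V[:, 3:5])
        if res.applicable:
            assert rho <= res.bound


def test_bound_slope_near_zero_perturbation():
    l3, l4, l5, l6 = 12.0, 9.0, 8.0, 5.0
    gap = min(l3 - l4, l5 - l6)
    for e in (1e-4, 1e-3, 1e-2):
        b = perturbation_bound(l3, l4, l5, l6, e).bound
        assert b / e <= 2.05 / gap


def test_individual_vectors_destabilize_but_plane_stays(rng):
    """As the level-4/5 gap closes, individual eigenvectors wobble more
    while the 2-D span distance stays bounded."""
    n = 30
    Q = _orthobasis(rng, n, n)
    base = np.array([100, 60, 40, 30, 0, 12, 8, 5, 3, 2] + [1] * (n - 10), float)
    individual = []
    plane = []
    for delta in (0.3, 0.1, 0.03, 0.01):
        lam = base.copy()
        lam[4] = lam[3] * (1 - delta)  # lambda5 approaches lambda4
        D = (Q * lam) @ Q.T
        ind_d, pl_d = [], []
        for s in range(20):
            rr = np.random.default_rng(1000 + s)
            E = rr.normal(size=(n, n))
            E = (E + E.T) / 2
            E *= 0.05 / np.linalg.norm(E, 2)
            w, V = np.linalg.eigh(D + E)
            V = V[:, np.argsort(w)[::-1]]
            ind_d.append(subspace_distance(Q[:, [3]], V[:, [3]]))
            pl_d.append(subspace_distance(Q[:, 3:5], V[:, 3:5]))
        individual.append(np.mean(ind_d))
        plane.append(np.mean(pl_d))
    assert all(a < b for a, b in zip(individual, individual[1:]))
    assert max(plane) <= 0.05


# ---------------------------------------------------------------------------
# Shuffle stability
# ---------------------------------------------------------------------------

def test_identity_permutation_control(separated_world):
    dec = dual_decompose(separated_world.lowrank)
    res = shuffle_stability(dec, level=4, reps=3, seed=0, _identity_permutation=True)
    assert np.allclose(res.mean_abs_pcc, 1.0, atol=1e-8)


def test_shuffling_leaves_separated_levels_intact(separated_world):
    dec = dual_decompose(separated_world.lowrank)
    res = shuffle_stability(dec, level=4, reps=20, seed=1)
    assert np.all(res.mean_abs_pcc[:3] >= 0.98)
    assert res.mean_abs_pcc[3] < 0.5  # the shuffled level itself decorrelates


def test_reps_validation(separated_world):
    dec = dual_decompose(separated_world.lowrank)
    with pytest.raises(ValueError):
        shuffle_stability(dec, level=4, reps=0)


# ---------------------------------------------------------------------------
# Resampling spectra
# ---------------------------------------------------------------------------

def test_full_fraction_zero_variance(separated_world):
    res = resample_spectrum(separated_world.lowrank, fraction=1.0, reps=5, seed=0)
    assert np.allclose(res.sd, 0.0, atol=1e-10)


def test_sd_decreases_with_fraction(separated_world):
    sds = []
    for f in (0.5, 0.7, 0.9):
        vals = [
            resample_spectrum(separated_world.lowrank, fraction=f, reps=30,
                              seed=s).sd.mean()
            for s in range(5)
        ]
        sds.append(np.mean(vals))
    assert sds[0] > sds[1] > sds[2]


def test_sqrt_f_scaling_in_spread_low_rank_regime(rng):
    g, m, r = 100, 200, 6
    U = _orthobasis(rng, g, r)
    V = _orthobasis(rng, m, r)
    s = np.array([50, 30, 20, 14, 9, 6.0])
    C = (U * s) @ V.T
    for f in (0.5, 0.9):
        res = resample_spectrum(C, fraction=f, reps=60, seed=1, n_levels=5)
        assert np.allclose(res.mean, np.sqrt(f) * s[1:6], rtol=0.05)


def test_too_few_columns_rejected(separated_world):
    with pytest.raises(ValueError):
        resample_spectrum(separated_world.lowrank, fraction=0.05, reps=2, seed=0)
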