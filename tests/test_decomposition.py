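"""Robust PCA, dual eigen-modules, polarization and spectrum statistics."""

import numpy as np
import pytest

from crefkit import (
    RobustSVD,
    align_signs,
    dual_decompose,
    polarization_degree,
    rpca_ialm,
    spectrum_stats,
)
from crefkit.synthetic import MatrixWorldSpec, gen_matrix_world


# ---------------------------------------------------------------------------
# Robust PCA
# ---------------------------------------------------------------------------

def test_zero_matrix_trivial():
    r = rpca_ialm(np.zeros((10, 5)))
    assert np.all(r.lowrank_ == 0) and np.all(r.sparse_ == 0)
    assert r.n_iter_ == 1


def test_exact_low_rank_no_outliers():
    w = gen_matrix_world(MatrixWorldSpec(200, 50, (100, 20), seed=3))
    r = rpca_ialm(w.raw)
    assert np.abs(r.sparse_).sum() / np.abs(w.raw).sum() <= 1e-6
    rel = np.linalg.norm(r.lowrank_ - w.lowrank) / np.linalg.norm(w.lowrank)
    assert rel <= 1e-6


def test_low_rank_recovery_with_outliers():
    spec = MatrixWorldSpec(150, 40, (100, 30, 18, 12, 8),
                           outlier_density=0.01, outlier_magnitude=5.0, seed=5)
    w = gen_matrix_world(spec)
    r = rpca_ialm(w.raw)
    rel = np.linalg.norm(r.lowrank_ - w.lowrank) / np.linalg.norm(w.lowrank)
    assert rel <= 1e-3


def test_sklearn_get_set_params():
    est = RobustSVD(tol=1e-6)
    assert est.get_params()["tol"] == 1e-6
    est.set_params(max_iter=50)
    assert est.max_iter == 50


# ---------------------------------------------------------------------------
# Dual decomposition
# ---------------------------------------------------------------------------

def test_baseline_exclusion_indexing(separated_world):
    dec = dual_decompose(separated_world.lowrank)
    raw = np.linalg.svd(separated_world.lowrank, compute_uv=False)
    # reported level 1 is the 2nd largest raw singular value
    assert dec.singular_value(1) == pytest.approx(raw[1], rel=1e-12)
    assert dec.level_index(4) == 4


def test_reconstruction_and_orthonormality(separated_world):
    dec = dual_decompose(separated_world.lowrank)
    C = dec.reconstruct()
    rel = np.linalg.norm(C - separated_world.lowrank) / np.linalg.norm(
        separated_world.lowrank
    )
    assert rel <= 1e-6
    for M in (dec.gene_eigenvectors_, dec.motif_eigenvectors_):
        assert np.allclose(M.T @ M, np.eye(M.shape[1]), atol=1e-8)


def test_rank_deficient_input_flags_truncation():
    w = gen_matrix_world(MatrixWorldSpec(40, 20, (50, 10, 5), seed=2))
    with pytest.warns(UserWarning, match="levels"):
        dec = dual_decompose(w.lowrank, n_levels=9)
    assert dec.truncated_
    assert dec.n_levels_ == 2


def test_recovered_eigenvectors_match_truth(separated_world):
    """With mild outliers and >=5% level gaps, reported motif-eigenvectors
    match the planted ones up to sign with |PCC| >= 0.999."""
    dec = dual_decompose(separated_world.lowrank)
    for level in range(1, 10):
        r = np.corrcoef(dec.v(level), separated_world.v(level))[0, 1]
        assert abs(r) >= 0.999


# ---------------------------------------------------------------------------
# Sign alignment
# ---------------------------------------------------------------------------

def test_align_identity_unchanged(separated_world):
    dec = dual_decompose(separated_world.lowrank)
    out = align_signs(dec, dec)
    assert np.array_equal(out.motif_eigenvectors_, dec.motif_eigenvectors_)


def test_align_flips_negated_level(separated_world):
    dec = dual_decompose(separated_world.lowrank)
    tgt = dec.copy()
    tgt.motif_eigenvectors_[:, 4] *= -1
    tgt.gene_eigenvectors_[:, 4] *= -1
    out = align_signs(tgt, dec)
    assert np.allclose(out.motif_eigenvectors_[:, 4], dec.motif_eigenvectors_[:, 4])
    assert np.allclose(out.reconstruct(), dec.reconstruct())


def test_align_all_inner_products_nonnegative():
    for seed in range(20):
        w = gen_matrix_world(MatrixWorldSpec(60, 25, (80, 20, 12, 7, 4), seed=seed))
        a = dual_decompose(w.lowrank)
        b = dual_decompose(w.lowrank + 0.01 * np.random.default_rng(seed).normal(
            size=w.lowrank.shape))
        out = align_signs(b, a)
        for j in range(min(a.rank_, out.rank_)):
            assert out.motif_eigenvectors_[:, j] @ a.motif_eigenvectors_[:, j] >= 0


def test_align_idempotent(separated_world):
    ref = dual_decompose(separated_world.lowrank)
    tgt = dual_decompose(separated_world.lowrank + 0.05)
    once = align_signs(tgt, ref)
    twice = align_signs(once, ref)
    assert np.array_equal(once.motif_eigenvectors_, twice.motif_eigenvectors_)


# ---------------------------------------------------------------------------
# Polarization degree
# ---------------------------------------------------------------------------

def paper_style_vector(n=1000, top_frac=0.1, top_energy=0.9, rng=None):
    """Positive vector whose top ``top_frac`` entries hold ``top_energy``
    of the energy, with the cumulative curve crossing the anti-diagonal
    exactly at that point."""
    k = int(top_frac * n)
    if rng is None:
        top = np.full(k, top_energy / k)
        rest = np.full(n - k, (1 - top_energy) / (n - k))
    else:
        top = rng.uniform(1.0, 2.0, k)
        top *= top_energy / top.sum()
        rest = rng.uniform(0.1, 0.9, n - k)
        rest *= (1 - top_energy) / rest.sum()
        assert top.min() > rest.max()
    return np.sqrt(np.concatenate([top, rest]))


def test_worked_example_gives_point_nine():
    assert polarization_degree(paper_style_vector()).d_plus == pytest.approx(
        0.9, abs=1e-12
    )


def test_equal_energies_give_half():
    res = polarization_degree(np.full(37, 0.3))
    assert res.d_plus == pytest.approx(0.5, abs=1e-12)
    assert res.d_minus is None


def _crossing_oracle(energies):
    """Brute-force evaluation of the interpolated crossing rule."""
    e = np.sort(np.asarray(energies, float))[::-1]
    n = e.size
    xs = np.linspace(0, 1, 200001)
    ys = np.interp(xs, np.arange(n + 1) / n, np.concatenate([[0], np.cumsum(e) / e.sum()]))
    i = np.argmin(np.abs(ys - (1 - xs)))
    return ys[i]


def test_one_hot_end_matches_discrete_crossing_oracle():
    w = np.zeros(10)
    w[0] = 1.0
    w[1:] = 1e-6
    d = polarization_degree(w).d_plus
    assert d == pytest.approx(_crossing_oracle(w**2), abs=1e-4)


def test_crossing_invariant_random_vectors(rng):
    """The top ceil((1-d) n) entries hold at least d of the pole energy."""
    for _ in range(25):
        n = int(rng.integers(5, 200))
        w = rng.normal(size=n)
        if not np.any(w > 0):
            w[0] = 1.0
        res = polarization_degree(w)
        e = np.sort(w[w > 0] ** 2)[::-1]
        d = res.d_plus
        k = int(np.ceil((1 - d) * e.size))
        assert e[:k].sum() / e.sum() >= d - 1e-12


def test_pole_energies_sum_to_one_for_unit_vector(rng):
    w = rng.normal(size=50)
    w /= np.linalg.norm(w)
    res = polarization_degree(w)
    assert res.energy_plus + res.energy_minus == pytest.approx(1.0, abs=1e-10)


def test_zero_vector_rejected():
    with pytest.raises(ValueError):
        polarization_degree(np.zeros(5))


# ---------------------------------------------------------------------------
# Spectrum statistics
# ---------------------------------------------------------------------------

def test_spectrum_shares():
    st = spectrum_stats([4, 3, 2, 1])
    assert np.allclose(st.shares, [40, 30, 20, 10])
    assert np.allclose(st.cumulative_shares, [40, 70, 90, 100])


def test_degenerate_delta_zero():
    st = spectrum_stats([10, 8, 5, 5, 3])
    assert st.deltas[2] == 0.0


def test_delta_arithmetic():
    st = spectrum_stats([100, 98.1])
    assert st.deltas[0] == pytest.approx(0.019, abs=1e-12)


def test_non_descending_rejected():
    with pytest.raises(ValueError):
        spectrum_stats([1, 2, 3])
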