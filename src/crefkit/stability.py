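"""Stability of eigen-modules: subspace distances, the perturbation bound,
shuffle-reconstruction simulations and motif-resampling spectra.

The motif-eigenvectors are eigenvectors of the Gram matrix ``D = C^T C``
with eigenvalues ``lambda_k = rho_k^2``.  The distance between two
subspaces is ``rho2(X, Y) = ||X_perp^T Y||_2`` (the sine of the largest
principal angle); for a symmetric perturbation ``E`` of ``D``, the 2-D
eigenspace of levels (4,5) moves by at most

    2 ||E||_2 / (min{l3 - l4, l5 - l6} - ||E||_2)

whenever the denominator is positive.  Monte-Carlo operations take explicit
seeds, with per-replicate streams derived by seed-sequence spawning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from ._util import spawn_rngs
from .decomposition import DualEigenDecomposition, dual_decompose


def subspace_distance(X, Y, tol: float = 1e-8) -> float:
    """``rho2`` distance between the column spans of orthonormal ``X``, ``Y``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    if Y.shape[0] == 1:
        Y = Y.T
    if X.shape[0] != Y.shape[0]:
        raise ValueError("bases must share the ambient dimension")
    for M, name in ((X, "X"), (Y, "Y")):
        if not np.allclose(M.T @ M, np.eye(M.shape[1]), atol=tol):
            raise ValueError(f"basis {name} is not orthonormal within {tol}")
    Xp = null_space(X.T)
    if Xp.shape[1] == 0:
        return 0.0
    return float(np.linalg.norm(Xp.T @ Y, 2))


@dataclass
class PerturbationBound:
    """Result of the 2-D eigenspace perturbation bound.

    ``applicable`` is False when the perturbation is not small relative to
    the spectral gaps (denominator <= 0), in which case ``bound`` is None.
    """

    bound: float | None
    applicable: bool
    min_gap: float
    e_norm: float


def perturbation_bound(l3, l4, l5, l6, e_norm) -> PerturbationBound:
    """Upper bound on ``rho2(span{v4,v5}, span{v4bar,v5bar})``.

    Requires ``l3 > l4 >= l5 > l6 >= 0`` (eigenvalues of ``C^T C`` around
    the 2-D plane of interest) and the spectral norm of the symmetric
    perturbation.
    """
    if not (l3 > l4 >= l5 > l6 >= 0):
        raise ValueError("need l3 > l4 >= l5 > l6 >= 0")
    if e_norm < 0:
        raise ValueError("perturbation norm must be nonnegative")
    gap = min(l3 - l4, l5 - l6)
    denom = gap - e_norm
    if denom <= 0:
        return PerturbationBound(None, False, gap, float(e_norm))
    return PerturbationBound(2.0 * e_norm / denom, True, gap, float(e_norm))


@dataclass
class ShuffleStabilityResult:
    """Mean effects of shuffling one eigen-module's loadings.

    Arrays are indexed by reported level (``levels``); ``mean_abs_pcc[k]``
    is the mean |PCC| between the original level-``levels[k]`` motif-
    eigenvector and the corresponding one after shuffle+re-decomposition,
    ``mean_frobenius[k]`` the mean Frobenius distance between the original
    and new level matrices ``rho_k u_k v_k^T``.
    """

    level: int
    reps: int
    levels: np.ndarray
    mean_abs_pcc: np.ndarray
    mean_frobenius: np.ndarray


def shuffle_stability(
    decomp: DualEigenDecomposition,
    level: int,
    reps: int = 50,
    seed: int = 0,
    _identity_permutation: bool = False,
) -> ShuffleStabilityResult:
    """Shuffle the level-``level`` module's loadings, rebuild and re-decompose.

    Per replicate the entries of ``u_level`` and ``v_level`` are permuted
    independently, the matrix is rebuilt from all raw components with the
    shuffled pair substituted, classically re-decomposed, and per reported
    level the |PCC| of motif-eigenvectors and the Frobenius distance of
    level matrices are recorded.  Means over ``reps`` are returned.
    ``_identity_permutation`` short-circuits the permutation draw (control
    path for testing).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    li = decomp.level_index(level)
    rngs = spawn_rngs(seed, reps)
    levels = np.array(list(decomp.levels))
    acc_pcc = np.zeros(levels.size)
    acc_fro = np.zeros(levels.size)
    U = decomp.gene_eigenvectors_
    V = decomp.motif_eigenvectors_
    s = decomp.singular_values_
    for rng in rngs:
        Us = U.copy()
        Vs = V.copy()
        if not _identity_permutation:
            Us[:, li] = U[rng.permutation(U.shape[0]), li]
            Vs[:, li] = V[rng.permutation(V.shape[0]), li]
        Cnew = (Us * s) @ Vs.T
        redec = dual_decompose(
            Cnew, n_levels=decomp.n_levels, exclude_baseline=decomp.exclude_baseline
        )
        for i, k in enumerate(levels):
            if k not in redec.levels:
                acc_pcc[i] += np.nan
                acc_fro[i] += np.nan
                continue
            vo, vn = decomp.v(k), redec.v(k)
            num = abs(float((vo - vo.mean()) @ (vn - vn.mean())))
            den = np.linalg.norm(vo - vo.mean()) * np.linalg.norm(vn - vn.mean())
            acc_pcc[i] += num / den
            Mo = decomp.singular_value(k) * np.outer(decomp.u(k), vo)
            Mn = redec.singular_value(k) * np.outer(redec.u(k), vn)
            acc_fro[i] += np.linalg.norm(Mo - Mn)
    return ShuffleStabilityResult(
        level=level,
        reps=reps,
        levels=levels,
        mean_abs_pcc=acc_pcc / reps,
        mean_frobenius=acc_fro / reps,
    )


@dataclass
class ResampleSpectrumResult:
    """Sampling distribution of reported-level singular values under
    motif (column) re-sampling without replacement."""

    fraction: float
    reps: int
    levels: np.ndarray
    samples: np.ndarray  # (reps, n_levels)
    mean: np.ndarray
    sd: np.ndarray
    q025: np.ndarray
    q975: np.ndarray


def resample_spectrum(
    C,
    fraction: float = 0.9,
    reps: int = 200,
    seed: int = 0,
    n_levels: int = 9,
    exclude_baseline: bool = True,
) -> ResampleSpectrumResult:
    """Singular-value sampling distributions by column re-sampling.

    Per replicate, ``floor(fraction * m)`` motif columns are drawn without
    replacement, the submatrix decomposed, and the reported-level singular
    values recorded.
    """
    C = np.asarray(C, dtype=float)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    m = C.shape[1]
    n_cols = int(np.floor(fraction * m))
    offset = 1 if exclude_baseline else 0
    if n_cols < n_levels + offset:
        raise ValueError("too few resampled columns for the reported levels")
    rngs = spawn_rngs(seed, reps)
    levels = np.arange(1, n_levels + 1)
    samples = np.full((reps, n_levels), np.nan)
    for i, rng in enumerate(rngs):
        cols = np.sort(rng.choice(m, size=n_cols, replace=False))
        s = np.linalg.svd(C[:, cols], compute_uv=False)
        for j, k in enumerate(levels):
            idx = k if exclude_baseline else k - 1
            if idx < s.size:
                samples[i, j] = s[idx]
    return ResampleSpectrumResult(
        fraction=fraction,
        reps=reps,
        levels=levels,
        samples=samples,
        mean=np.nanmean(samples, axis=0),
        sd=np.nanstd(samples, axis=0, ddof=1) if reps > 1 else np.zeros(n_levels),
        q025=np.nanquantile(samples, 0.025, axis=0),
        q975=np.nanquantile(samples, 0.975, axis=0),
    )
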