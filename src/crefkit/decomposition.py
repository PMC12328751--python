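"""Robust SVD of CREF matrices and polarized dual eigen-modules.

The count matrix ``C_tilde`` is split as ``C_tilde = C + S`` with ``C``
low-rank and ``S`` sparse by solving

    min ||C||_* + lam * ||S||_1   s.t.  C_tilde = C + S

with the inexact augmented Lagrange multiplier (IALM) scheme
(singular-value thresholding for ``C``, soft thresholding for ``S``).
``lam`` defaults to ``1/sqrt(g)`` for a ``g x m`` matrix.  Classical SVD of
``C`` then yields dual eigen-modules ``(rho_k, u_k, v_k)``; the leading
component acts as an adjusted average (the baseline) and is excluded from
reported levels, so reported level ``k`` is raw component ``k`` (0-based
raw index ``k``, with the baseline at raw index 0).

Both stages are scikit-learn style estimators; ``rpca_ialm`` and
``dual_decompose`` are thin functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator


class ConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# Robust PCA (IALM)
# ---------------------------------------------------------------------------

def _soft_threshold(x: np.ndarray, tau: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


class RobustSVD(BaseEstimator):
    """Low-rank + sparse decomposition by inexact ALM.

    Parameters
    ----------
    lam : float or None
        Weight of the l1 term; ``None`` means ``1/sqrt(n_rows)``.
    tol : float
        Stop when ``||X - C - S||_F / ||X||_F`` falls below this.
    max_iter : int
        Iteration cap; non-convergence emits :class:`ConvergenceWarning`
        and flags ``converged_ = False``.
    mu0, rho : float
        Initial penalty (``None`` means ``1.25 / ||X||_2``) and its growth
        factor per iteration.

    Attributes
    ----------
    lowrank_ : ndarray
        The recovered low-rank component ``C``.
    sparse_ : ndarray
        The sparse component ``S``.
    n_iter_, residual_, converged_, lam_ : fit diagnostics.
    """

    def __init__(self, lam=None, tol=1e-7, max_iter=1000, mu0=None, rho=1.5):
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter
        self.mu0 = mu0
        self.rho = rho

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("matrix contains non-finite entries")
        g, m = X.shape
        lam = self.lam if self.lam is not None else 1.0 / np.sqrt(g)
        if lam <= 0:
            raise ValueError("lam must be positive")
        normF = np.linalg.norm(X)
        if normF == 0:
            self.lowrank_ = np.zeros_like(X)
            self.sparse_ = np.zeros_like(X)
            self.n_iter_, self.residual_, self.converged_ = 1, 0.0, True
            self.lam_ = lam
            return self
        norm2 = np.linalg.norm(X, 2)
        mu = self.mu0 if self.mu0 is not None else 1.25 / norm2
        # dual variable scaled as in Lin et al.'s inexact ALM
        J = max(norm2, np.abs(X).max() / lam)
        Y = X / J
        S = np.zeros_like(X)
        C = np.zeros_like(X)
        converged = False
        for it in range(1, self.max_iter + 1):
            U, s, Vt = np.linalg.svd(X - S + Y / mu, full_matrices=False)
            s_thr = np.maximum(s - 1.0 / mu, 0.0)
            r = int(np.count_nonzero(s_thr))
            C = (U[:, :r] * s_thr[:r]) @ Vt[:r]
            S = _soft_threshold(X - C + Y / mu, lam / mu)
            resid = X - C - S
            Y = Y + mu * resid
            rel = np.linalg.norm(resid) / normF
            if rel < self.tol:
                converged = True
                break
            mu = min(mu * self.rho, mu * 1e7)
        if not converged:
            warnings.warn(
                f"IALM did not converge in {self.max_iter} iterations "
                f"(residual {rel:.3e})",
                ConvergenceWarning,
            )
        self.lowrank_ = C
        self.sparse_ = S
        self.n_iter_ = it
        self.residual_ = float(rel)
        self.converged_ = converged
        self.lam_ = float(lam)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).lowrank_


def rpca_ialm(X, lam=None, tol=1e-7, max_iter=1000):
    """Functional wrapper: returns a fitted :class:`RobustSVD`."""
    return RobustSVD(lam=lam, tol=tol, max_iter=max_iter).fit(X)


# ---------------------------------------------------------------------------
# Dual eigen-modules
# ---------------------------------------------------------------------------

class DualEigenDecomposition(BaseEstimator):
    """Classical SVD of the low-rank component into dual eigen-modules.

    With ``exclude_baseline`` (default) the leading singular triplet is kept
    internally but never reported: reported level ``k`` (1-based) maps to raw
    component index ``k`` (0-based, baseline at 0).

    Parameters
    ----------
    n_levels : int
        Number of reported levels (the paper-style default is nine).
    exclude_baseline : bool
        Whether the leading component is treated as a baseline.
    robust : bool
        When true, ``fit`` first runs :class:`RobustSVD` on the input and
        decomposes its low-rank part; otherwise the input is decomposed
        directly.

    Attributes
    ----------
    singular_values_ : ndarray, raw singular values (descending).
    gene_eigenvectors_ : ndarray (g, r), columns are u_k.
    motif_eigenvectors_ : ndarray (m, r), columns are v_k.
    rank_ : numerical rank retained.
    n_levels_ : number of levels actually reportable.
    truncated_ : True when rank_ < n_levels + baseline.
    gene_ids_, motif_ids_ : optional axis labels.
    """

    def __init__(self, n_levels=9, exclude_baseline=True, robust=False,
                 lam=None, tol=1e-7, max_iter=1000, rank_tol=1e-10):
        self.n_levels = n_levels
        self.exclude_baseline = exclude_baseline
        self.robust = robust
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter
        self.rank_tol = rank_tol

    def fit(self, X, y=None, gene_ids=None, motif_ids=None):
        try:  # accept a DataFrame and capture its labels
            import pandas as pd

            if isinstance(X, pd.DataFrame):
                gene_ids = list(X.index) if gene_ids is None else gene_ids
                motif_ids = list(X.columns) if motif_ids is None else motif_ids
                X = X.to_numpy(dtype=float)
        except ImportError:  # pragma: no cover
            pass
        X = np.asarray(X, dtype=float)
        if self.robust:
            rsvd = RobustSVD(lam=self.lam, tol=self.tol, max_iter=self.max_iter).fit(X)
            self.robust_ = rsvd
            X = rsvd.lowrank_
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        if s.size and s[0] > 0:
            rank = int(np.count_nonzero(s > self.rank_tol * s[0]))
        else:
            rank = 0
        self.singular_values_ = s[:rank]
        self.gene_eigenvectors_ = U[:, :rank]
        self.motif_eigenvectors_ = Vt[:rank].T
        self.rank_ = rank
        offset = 1 if self.exclude_baseline else 0
        self.n_levels_ = max(0, min(self.n_levels, rank - offset))
        self.truncated_ = self.n_levels_ < self.n_levels
        if self.truncated_:
            warnings.warn(
                f"rank {rank} supports only {self.n_levels_} reported levels",
                ConvergenceWarning,
            )
        self.gene_ids_ = list(gene_ids) if gene_ids is not None else None
        self.motif_ids_ = list(motif_ids) if motif_ids is not None else None
        return self

    # -- level accessors ----------------------------------------------------
    def level_index(self, level: int) -> int:
        """Raw component index of reported level ``level`` (1-based)."""
        if not 1 <= level <= self.n_levels_:
            raise ValueError(f"level {level} outside reported range 1..{self.n_levels_}")
        return level if self.exclude_baseline else level - 1

    @property
    def levels(self) -> range:
        return range(1, self.n_levels_ + 1)

    def singular_value(self, level: int) -> float:
        return float(self.singular_values_[self.level_index(level)])

    def u(self, level: int) -> np.ndarray:
        return self.gene_eigenvectors_[:, self.level_index(level)]

    def v(self, level: int) -> np.ndarray:
        return self.motif_eigenvectors_[:, self.level_index(level)]

    def reported_spectrum(self) -> np.ndarray:
        idx = [self.level_index(k) for k in self.levels]
        return self.singular_values_[idx]

    def reconstruct(self) -> np.ndarray:
        return (self.gene_eigenvectors_ * self.singular_values_) @ self.motif_eigenvectors_.T

    def copy(self) -> "DualEigenDecomposition":
        import copy as _copy

        return _copy.deepcopy(self)

    # -- sign conventions ---------------------------------------------------
    def orient_reference(self) -> "DualEigenDecomposition":
        """Deterministic self-orientation when no reference species exists.

        Each motif-eigenvector is flipped so the sum of cubes of its entries
        is nonnegative; exact zero sums fall back to making the
        largest-|loading| motif positive.  Returns a modified copy.
        """
        out = self.copy()
        V, U = out.motif_eigenvectors_, out.gene_eigenvectors_
        for j in range(out.rank_):
            cube = float(np.sum(V[:, j] ** 3))
            if cube == 0.0:
                cube = float(V[np.argmax(np.abs(V[:, j])), j])
            if cube < 0:
                V[:, j] *= -1
                U[:, j] *= -1
        return out

    def aligned_to(self, reference: "DualEigenDecomposition") -> "DualEigenDecomposition":
        return align_signs(self, reference)


def dual_decompose(C, n_levels=9, exclude_baseline=True,
                   gene_ids=None, motif_ids=None) -> DualEigenDecomposition:
    """Classical SVD of ``C`` into a fitted :class:`DualEigenDecomposition`."""
    return DualEigenDecomposition(
        n_levels=n_levels, exclude_baseline=exclude_baseline
    ).fit(C, gene_ids=gene_ids, motif_ids=motif_ids)


def align_signs(
    target: DualEigenDecomposition, reference: DualEigenDecomposition
) -> DualEigenDecomposition:
    """Flip ``(u_k, v_k)`` pairs of ``target`` so ``<v_k, v_k_ref> > 0``.

    Levels are matched by raw component index; the products
    ``rho_k u_k v_k^T`` are unchanged.  A zero inner product falls back to
    making the largest-|loading| motif of ``v_k`` positive.  Requires a
    shared motif axis.
    """
    if (
        target.motif_ids_ is not None
        and reference.motif_ids_ is not None
        and target.motif_ids_ != reference.motif_ids_
    ):
        raise ValueError("motif axes differ between target and reference")
    if target.motif_eigenvectors_.shape[0] != reference.motif_eigenvectors_.shape[0]:
        raise ValueError("motif axis lengths differ")
    out = target.copy()
    V, U = out.motif_eigenvectors_, out.gene_eigenvectors_
    n = min(out.rank_, reference.rank_)
    for j in range(n):
        ip = float(V[:, j] @ reference.motif_eigenvectors_[:, j])
        if ip == 0.0:
            ip = float(V[np.argmax(np.abs(V[:, j])), j])
        if ip < 0:
            V[:, j] *= -1
            U[:, j] *= -1
    return out


# ---------------------------------------------------------------------------
# Polarization degree
# ---------------------------------------------------------------------------

@dataclass
class PolarizationResult:
    """Concentration of eigenvector energy at the two poles.

    ``d_plus``/``d_minus`` are the crossing points of the pole's cumulative
    energy curve with the anti-diagonal (see :func:`polarization_degree`);
    ``None`` when a pole is empty.  ``d_overall`` combines the poles by
    energy weighting (implementation-defined convention, recorded here).
    """

    d_plus: float | None
    d_minus: float | None
    d_overall: float | None
    energy_plus: float
    energy_minus: float
    n_plus: int = 0
    n_minus: int = 0


def _pole_degree(energies: np.ndarray) -> float:
    """Crossing of the cumulative-energy curve with the anti-diagonal.

    ``energies`` are the (positive) energies of one pole.  Sort descending;
    the step curve through points ``(j/n, E_j/E)`` (cumulative energy of the
    top ``j`` entries) is linearly interpolated and intersected with
    ``y = 1 - x``; the degree is the ``y`` value at the crossing.  Equal
    energies give exactly 0.5; a single entry gives 1 - 1/(n+...) -> the
    crossing of its first segment.
    """
    e = np.sort(np.asarray(energies, dtype=float))[::-1]
    n = e.size
    total = e.sum()
    x = np.arange(n + 1) / n
    y = np.concatenate([[0.0], np.cumsum(e) / total])
    # g(x) = y(x) + x - 1 is strictly increasing from -1 to 1
    g = y + x - 1.0
    i = int(np.searchsorted(g, 0.0, side="left"))
    if i == 0:
        return float(y[0])
    if g[i - 1] == 0.0:
        return float(y[i - 1])
    # linear interpolation on segment (i-1, i)
    t = -g[i - 1] / (g[i] - g[i - 1])
    return float(y[i - 1] + t * (y[i] - y[i - 1]))


def polarization_degree(w) -> PolarizationResult:
    """Polarization degree of a (polarized) eigenvector.

    Entries are split by sign; each pole's entries are converted to energies
    (squared loadings) and the pole degree is the crossing point where the
    top ``1 - d`` fraction of the pole's entries first accumulates ``d`` of
    the pole's energy.  Empty poles report ``None`` rather than 0.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size == 0 or not np.any(w != 0):
        raise ValueError("expected a nonzero 1-D vector")
    pos = w[w > 0] ** 2
    neg = w[w < 0] ** 2
    d_plus = _pole_degree(pos) if pos.size else None
    d_minus = _pole_degree(neg) if neg.size else None
    ep, en = float(pos.sum()), float(neg.sum())
    if d_plus is None:
        d_overall = d_minus
    elif d_minus is None:
        d_overall = d_plus
    else:
        d_overall = (ep * d_plus + en * d_minus) / (ep + en)
    return PolarizationResult(
        d_plus=d_plus,
        d_minus=d_minus,
        d_overall=d_overall,
        energy_plus=ep,
        energy_minus=en,
        n_plus=int(pos.size),
        n_minus=int(neg.size),
    )


# ---------------------------------------------------------------------------
# Spectrum statistics
# ---------------------------------------------------------------------------

@dataclass
class SpectrumStats:
    """Singular-value shares and adjacent relative distances.

    ``shares`` are percentages of the total sum; ``deltas[k]`` is
    ``(rho_k - rho_{k+1}) / rho_k`` (denominator: the larger value; this
    convention is recorded in serialized metadata).
    """

    values: np.ndarray
    shares: np.ndarray
    cumulative_shares: np.ndarray
    deltas: np.ndarray
    remainder_share: float = 0.0

    convention: str = field(default="delta_k = (rho_k - rho_{k+1}) / rho_k", repr=False)


def spectrum_stats(rho, total=None) -> SpectrumStats:
    """Shares, cumulative shares and adjacent relative distances of a spectrum.

    ``rho`` must be positive and descending.  ``total`` (default: the sum of
    ``rho``) allows shares relative to a full spectrum when only the top
    levels are passed; the unreported remainder share is returned alongside.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.size == 0 or np.any(rho <= 0):
        raise ValueError("spectrum must be positive")
    if np.any(np.diff(rho) > 0):
        raise ValueError("spectrum must be non-increasing")
    tot = float(rho.sum()) if total is None else float(total)
    shares = 100.0 * rho / tot
    cum = np.cumsum(shares)
    deltas = (rho[:-1] - rho[1:]) / rho[:-1]
    return SpectrumStats(
        values=rho,
        shares=shares,
        cumulative_shares=cum,
        deltas=deltas,
        remainder_share=float(100.0 - cum[-1]) if total is not None else 0.0,
    )
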