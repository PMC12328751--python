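"""Cross-species comparison of dual eigen-modules.

Conservation of a level is measured by the Pearson correlation of the two
species' motif-eigenvectors; rotation within a near-degenerate eigen-plane
is measured by projecting the target species' level-(j,k) motif-eigenvectors
onto the reference 2-D eigenspace and extracting the nearest rotation
(orthogonal Procrustes on the 2x2 coordinate matrix, counterclockwise
positive).  Species relationships are summarized by Euclidean distances
between motif-eigenvectors and an average-linkage tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import pdist, squareform

from .decomposition import DualEigenDecomposition


def _check_shared_axis(a: DualEigenDecomposition, b: DualEigenDecomposition):
    if (
        a.motif_ids_ is not None
        and b.motif_ids_ is not None
        and a.motif_ids_ != b.motif_ids_
    ):
        raise ValueError("motif identifier axes differ")
    if a.motif_eigenvectors_.shape[0] != b.motif_eigenvectors_.shape[0]:
        raise ValueError("motif axis lengths differ")


def pcc(x, y, center: bool = True) -> float:
    """Pearson correlation (or raw cosine similarity with ``center=False``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if center:
        x = x - x.mean()
        y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance vector in correlation")
    return float((x @ y) / (nx * ny))


def motif_pcc(
    a: DualEigenDecomposition,
    b: DualEigenDecomposition,
    levels=None,
) -> pd.DataFrame:
    """Per-level PCC (and r^2) between two species' motif-eigenvectors."""
    _check_shared_axis(a, b)
    if levels is None:
        levels = [k for k in a.levels if k in set(b.levels)]
    rows = []
    for k in levels:
        r = pcc(a.v(k), b.v(k))
        rows.append({"level": k, "pcc": r, "r_squared": r * r})
    return pd.DataFrame(rows).set_index("level")


@dataclass
class ConservationThresholds:
    """Per-level conservation thresholds from replicate decompositions.

    ``thresholds[k]`` is the ``alpha``-quantile of |PCC| between the
    reference and replicate motif-eigenvectors at level ``k``; levels with
    no replicates are absent.
    """

    thresholds: dict[int, float]
    alpha: float
    n_replicates: int


def conservation_threshold(
    reference: DualEigenDecomposition,
    replicates,
    alpha: float = 0.05,
    levels=None,
) -> ConservationThresholds:
    """Empirical conservation thresholds from conspecific replicates.

    ``replicates`` are decompositions of noise-perturbed re-runs or of
    multiple conspecific genomes.  ``alpha=0`` returns the minimum replicate
    |PCC| per level.
    """
    replicates = list(replicates)
    if not replicates:
        raise ValueError("at least one replicate decomposition is required")
    if levels is None:
        levels = list(reference.levels)
    out = {}
    for k in levels:
        vals = []
        for rep in replicates:
            _check_shared_axis(reference, rep)
            if k in rep.levels:
                vals.append(abs(pcc(reference.v(k), rep.v(k))))
        if vals:
            out[k] = float(np.quantile(vals, alpha))
    return ConservationThresholds(out, alpha=alpha, n_replicates=len(replicates))


@dataclass
class SubspaceProjection:
    """Projection of a target eigen-pair into a reference 2-D eigenspace.

    ``coords`` columns are the target vectors expressed in the reference
    ``(v_j, v_k)`` basis; ``leakage`` is ``1 - ||projection||`` per vector.
    ``theta_deg`` is the nearest-rotation (Procrustes) angle, counter-
    clockwise positive; a reflection (swap-type jump between levels) is
    flagged instead of forced into a rotation.  When both projections are
    negligible the angle is undefined.
    """

    levels: tuple[int, int]
    coords: np.ndarray
    leakage: np.ndarray
    theta_deg: float | None
    direction: str | None
    reflection: bool
    per_vector_angles_deg: tuple[float, float] | None
    angle_between_deg: float | None
    undefined: bool = False


def project_2d(ref_vj, ref_vk, tgt_vj, tgt_vk, levels=(4, 5),
               max_leakage: float = 0.9) -> SubspaceProjection:
    """Project target level-(j,k) vectors onto the reference eigen-plane.

    The reference vectors must be orthonormal.  Returns coordinates,
    per-vector leakage, the Procrustes rotation angle and direction, the
    per-vector angles and the angle between the two projections.
    """
    B = np.column_stack([ref_vj, ref_vk])
    if not np.allclose(B.T @ B, np.eye(2), atol=1e-8):
        raise ValueError("reference vectors must be orthonormal")
    T = np.column_stack([tgt_vj, tgt_vk])
    coords = B.T @ T  # 2 x 2, columns = projected target vectors
    norms = np.linalg.norm(coords, axis=0)
    leakage = 1.0 - norms
    if np.all(leakage > max_leakage):
        return SubspaceProjection(
            levels, coords, leakage, None, None, False, None, None, undefined=True
        )
    U, _s, Vt = np.linalg.svd(coords)
    det = np.linalg.det(U @ Vt)
    reflection = det < 0
    R = U @ np.diag([1.0, np.sign(det)]) @ Vt
    theta = float(np.degrees(np.arctan2(R[1, 0], R[0, 0])))
    direction = "counterclockwise" if theta >= 0 else "clockwise"
    # per-vector angles relative to their own reference axes, ccw positive
    ang_j = float(np.degrees(np.arctan2(coords[1, 0], coords[0, 0])))
    ang_k = float(np.degrees(np.arctan2(-coords[0, 1], coords[1, 1])))
    cosang = coords[:, 0] @ coords[:, 1] / (norms[0] * norms[1]) if norms.all() else np.nan
    between = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return SubspaceProjection(
        levels=levels,
        coords=coords,
        leakage=leakage,
        theta_deg=theta,
        direction=direction,
        reflection=bool(reflection),
        per_vector_angles_deg=(ang_j, ang_k),
        angle_between_deg=between,
    )


def project_levels(
    reference: DualEigenDecomposition,
    target: DualEigenDecomposition,
    levels: tuple[int, int] = (4, 5),
) -> SubspaceProjection:
    """Convenience wrapper of :func:`project_2d` on two decompositions."""
    _check_shared_axis(reference, target)
    j, k = levels
    return project_2d(reference.v(j), reference.v(k), target.v(j), target.v(k),
                      levels=levels)


def species_tree(vectors: dict[str, np.ndarray]):
    """Average-linkage tree of species from level-k motif-eigenvectors.

    ``vectors`` maps species name -> motif-eigenvector on a shared, aligned
    motif axis.  Returns ``(newick, distances)`` where ``distances`` is the
    pairwise Euclidean distance matrix as a DataFrame.
    """
    if len(vectors) < 3:
        raise ValueError("need at least 3 species")
    names = list(vectors)
    X = np.vstack([np.asarray(vectors[n], dtype=float) for n in names])
    if np.unique([v.size for v in X]).size != 1:
        raise ValueError("motif axes differ in length")
    cond = pdist(X, metric="euclidean")
    Z = average(cond)
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, names)
    newick = str(tree).strip()
    dm = pd.DataFrame(squareform(cond), index=names, columns=names)
    return newick, dm
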