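"""Motifs present on SINE consensus sequences (MPCS) and their enrichment
among the top-ranked motifs of each eigen-module.

A motif is an MPCS when it has at least one hit (both strands) on at least
one SINE consensus sequence at the given cutoff profile.  Per level, the
top ``n`` motifs of the motif-eigenvector (by energy, i.e. squared loading,
covering both poles) are cross-tabulated against MPCS membership and tested
with a one-sided Fisher exact test (hypergeometric upper tail).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .pwm import PWM, CutoffProfile, count_hits


def read_fasta(path) -> dict[str, str]:
    """Read a (small, uncompressed) FASTA into id -> sequence."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"{path}: empty FASTA")
    return seqs


def identify_mpcs(
    pwms: list[PWM],
    cutoffs,
    consensus_seqs,
) -> set[str]:
    """Motif ids with >= 1 hit on >= 1 consensus sequence.

    ``consensus_seqs`` is a FASTA path or an id -> sequence mapping;
    ``cutoffs`` a shared :class:`CutoffProfile` or a per-motif mapping.
    """
    if not isinstance(consensus_seqs, dict):
        consensus_seqs = read_fasta(consensus_seqs)
    if not consensus_seqs:
        raise ValueError("no consensus sequences given")
    if isinstance(cutoffs, CutoffProfile):
        cutoffs = {p.id: cutoffs for p in pwms}
    hits = set()
    for pwm in pwms:
        prof = cutoffs[pwm.id]
        for seq in consensus_seqs.values():
            if count_hits(pwm, seq, prof) > 0:
                hits.add(pwm.id)
                break
    return hits


@dataclass
class MPCSLevelResult:
    """Per-level MPCS enrichment among the top-``n`` motifs."""

    level: int
    top_n: int
    n_motifs: int
    n_mpcs: int          # K: MPCS in the whole motif axis
    k_top: int           # MPCS among the top n
    table: np.ndarray    # 2x2: [top, rest] x [mpcs, other]
    odds_ratio: float
    p_value: float
    top_motifs: list[str]
    per_pole: bool = False


def top_motifs_by_energy(
    loadings: pd.Series, n: int = 100, per_pole: bool = False
) -> list[str]:
    """Top motif ids of a motif-eigenvector by energy (squared loading).

    With ``per_pole`` the top ``n`` are taken at each pole separately and
    concatenated (positive pole first).
    """
    if n >= loadings.size:
        raise ValueError("top-n must be smaller than the motif axis")
    if not per_pole:
        energy = loadings.pow(2)
        return list(energy.sort_values(ascending=False).index[:n])
    pos = loadings[loadings > 0].sort_values(ascending=False).index[:n]
    neg = loadings[loadings < 0].sort_values(ascending=True).index[:n]
    return list(pos) + list(neg)


def mpcs_fisher(
    loadings: pd.Series,
    mpcs_set,
    n: int = 100,
    level: int = 0,
    per_pole: bool = False,
) -> MPCSLevelResult:
    """One-sided Fisher test of MPCS enrichment among the top-``n`` motifs.

    The 2x2 table crosses [top-n vs rest] with [MPCS vs other]; the
    one-sided p-value is the hypergeometric upper tail
    ``P(X >= k)`` with ``X ~ Hypergeom(m, K, n_top)``.
    """
    m = loadings.size
    mpcs_set = set(mpcs_set)
    unknown = mpcs_set - set(loadings.index)
    if unknown:
        raise ValueError(f"MPCS ids not on the motif axis: {sorted(unknown)[:5]}")
    top = top_motifs_by_energy(loadings, n=n, per_pole=per_pole)
    n_top = len(top)
    K = len(mpcs_set)
    k = len(set(top) & mpcs_set)
    table = np.array([[k, n_top - k], [K - k, (m - n_top) - (K - k)]])
    a, b, c, d = table.ravel()
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    p = float(hypergeom.sf(k - 1, m, K, n_top))
    return MPCSLevelResult(
        level=level,
        top_n=n_top,
        n_motifs=m,
        n_mpcs=K,
        k_top=k,
        table=table,
        odds_ratio=float(odds),
        p_value=p,
        top_motifs=top,
        per_pole=per_pole,
    )


def relative_change(k_target: int, k_reference: int) -> float:
    """Percent change in MPCS counts from a reference species to a target."""
    if k_reference == 0:
        raise ValueError("reference count is zero; relative change undefined")
    return 100.0 * (k_target - k_reference) / k_reference


def mpcs_report(
    decomps: dict[str, "object"],
    mpcs_set,
    n: int = 100,
    levels=None,
    reference: str | None = None,
    per_pole: bool = False,
) -> pd.DataFrame:
    """MPCS counts and Fisher tests per species and level.

    ``decomps`` maps species -> fitted DualEigenDecomposition with motif
    ids.  When ``reference`` is given, per-level relative changes against it
    are included.  Overlap sets between species are obtainable from the
    ``top_motifs`` column.
    """
    rows = []
    for sp, dec in decomps.items():
        lv = levels if levels is not None else list(dec.levels)
        for k in lv:
            loadings = pd.Series(dec.v(k), index=dec.motif_ids_)
            res = mpcs_fisher(loadings, mpcs_set, n=n, level=k, per_pole=per_pole)
            rows.append(
                {
                    "species": sp,
                    "level": k,
                    "k_top": res.k_top,
                    "odds_ratio": res.odds_ratio,
                    "p_value": res.p_value,
                    "top_motifs": res.top_motifs,
                }
            )
    df = pd.DataFrame(rows)
    if reference is not None:
        ref = df[df.species == reference].set_index("level")["k_top"]
        df["relative_change_pct"] = [
            relative_change(r.k_top, int(ref[r.level]))
            if r.species != reference and ref.get(r.level, 0) > 0
            else (0.0 if r.species == reference else np.nan)
            for r in df.itertuples()
        ]
    return df
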