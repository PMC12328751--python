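"""Synthetic worlds with known ground truth for every pipeline stage.

Three generators cover the pipeline's inputs:

* :func:`gen_pwms` — random PWM libraries (Dirichlet positional
  preferences around a random consensus, sharpness set by ``concentration``).
* :func:`gen_matrix_world` — gene x motif count matrices with a controlled
  spectrum: a nonnegative baseline component plus random orthonormal
  factors, optional integer rounding (with the realized truth re-recorded
  after rounding) and planted sparse outliers.
* :func:`gen_sequence_world` — a small genome (FASTA + GFF3) whose promoter
  windows carry Poisson-planted motif instances with a low-rank rate
  structure, returning the planted count matrix as truth.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ALPHABET, revcomp
from .pwm import PWM

__all__ = [
    "PwmSpec",
    "MatrixWorldSpec",
    "MatrixWorldTruth",
    "SequenceWorldSpec",
    "SequenceWorld",
    "gen_pwms",
    "gen_matrix_world",
    "gen_rotated_species",
    "gen_sequence_world",
    "gen_gene_sets",
    "gen_consensus_library",
    "write_gmt",
    "write_truth_tsv",
]


# ---------------------------------------------------------------------------
# PWM worlds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PwmSpec:
    """Parameters of a synthetic PWM library.

    ``concentration`` sets the sharpness of positional preferences: the
    consensus letter's Dirichlet weight, so large values approach one-hot
    columns.  ``letters`` restricts the motif alphabet (used to build
    background-free worlds whose motifs cannot arise by chance from a
    disjoint background alphabet).
    """

    n_motifs: int
    length_range: tuple[int, int] = (8, 12)
    concentration: float = 8.0
    seed: int = 0
    letters: str = ALPHABET
    unique_consensus: bool = False

    def __post_init__(self):
        if self.n_motifs < 1:
            raise ValueError("n_motifs must be >= 1")
        lo, hi = self.length_range
        if lo < 4 or hi < lo:
            raise ValueError("length_range must satisfy 4 <= min <= max")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not set(self.letters) <= set(ALPHABET):
            raise ValueError("letters must be a subset of ACGT")


def gen_pwms(spec: PwmSpec) -> list[PWM]:
    """Generate ``spec.n_motifs`` random PWMs, deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    allowed = np.array([ALPHABET.index(b) for b in spec.letters])
    lo, hi = spec.length_range
    pwms: list[PWM] = []
    seen: set[str] = set()
    attempts = 0
    while len(pwms) < spec.n_motifs:
        attempts += 1
        if attempts > 200 * spec.n_motifs:
            raise RuntimeError("could not generate enough distinct consensi")
        L = int(rng.integers(lo, hi + 1))
        cons = rng.choice(allowed, size=L)
        alpha = np.full((L, 4), 1e-12)  # ~zero mass on disallowed letters
        alpha[:, allowed] = 0.5
        alpha[np.arange(L), cons] = spec.concentration
        freq = rng.gamma(alpha)
        freq /= freq.sum(axis=1, keepdims=True)
        # force the intended consensus to stay the per-position argmax
        amax = freq.argmax(axis=1)
        for i in np.nonzero(amax != cons)[0]:
            freq[i, [cons[i], amax[i]]] = freq[i, [amax[i], cons[i]]]
        pwm = PWM(f"M{len(pwms) + 1:04d}", freq)
        if spec.unique_consensus:
            # revcomp-aware uniqueness (and no palindromes): guarantees a
            # planted consensus can only ever hit its own motif, on one strand
            cons = pwm.consensus
            rc = revcomp(cons)
            if cons in seen or rc in seen or cons == rc:
                continue
            seen.add(cons)
        pwms.append(pwm)
    return pwms


# ---------------------------------------------------------------------------
# Matrix worlds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatrixWorldSpec:
    """Parameters of a direct CREF-like matrix world.

    ``spectrum`` lists the target singular values in descending order; the
    first entry is an explicit baseline component (nonnegative singular
    vectors, emulating the adjusted-average leading triplet of real count
    matrices).  ``count_mode`` rounds the low-rank part to nonnegative
    integers and re-records the realized truth.
    """

    n_genes: int
    n_motifs: int
    spectrum: tuple[float, ...]
    outlier_density: float = 0.0
    outlier_magnitude: float = 1.0
    count_mode: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.spectrum) > min(self.n_genes, self.n_motifs):
            raise ValueError("spectrum longer than min(n_genes, n_motifs)")
        if any(s <= 0 for s in self.spectrum):
            raise ValueError("spectrum must be strictly positive")
        if np.any(np.diff(self.spectrum) > 0):
            raise ValueError("spectrum must be descending")
        if not 0.0 <= self.outlier_density <= 1.0:
            raise ValueError("outlier_density must be in [0, 1]")
        if self.outlier_magnitude <= 0:
            raise ValueError("outlier_magnitude must be positive")


@dataclass
class MatrixWorldTruth:
    """A matrix world with its exact decomposition recorded.

    ``raw = lowrank + sparse`` holds exactly.  ``gene_eigenvectors`` /
    ``motif_eigenvectors`` are the orthonormal factors of ``lowrank`` and
    ``spectrum`` its singular values (re-measured after rounding in count
    mode).  Raw component 0 is the baseline; reported level ``k`` is raw
    component ``k``.
    """

    raw: np.ndarray
    lowrank: np.ndarray
    sparse: np.ndarray
    gene_eigenvectors: np.ndarray
    motif_eigenvectors: np.ndarray
    spectrum: np.ndarray
    gene_ids: list[str]
    motif_ids: list[str]
    spec: MatrixWorldSpec | None = None

    def v(self, level: int) -> np.ndarray:
        """Motif-eigenvector of reported level ``level`` (baseline excluded)."""
        return self.motif_eigenvectors[:, level]

    def u(self, level: int) -> np.ndarray:
        return self.gene_eigenvectors[:, level]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.raw, index=self.gene_ids, columns=self.motif_ids)


def _orthonormal_with_baseline(n: int, r: int, rng) -> np.ndarray:
    """Random orthonormal (n, r) basis whose first column is nonnegative."""
    base = 1.0 + np.abs(rng.normal(0.0, 0.25, size=n))
    M = np.column_stack([base, rng.normal(size=(n, r - 1))]) if r > 1 else base[:, None]
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))  # make the decomposition deterministic in sign
    return Q


def gen_matrix_world(spec: MatrixWorldSpec) -> MatrixWorldTruth:
    """Build a matrix world ``raw = lowrank + sparse`` with known truth."""
    rng = np.random.default_rng(spec.seed)
    g, m, r = spec.n_genes, spec.n_motifs, len(spec.spectrum)
    U = _orthonormal_with_baseline(g, r, rng)
    V = _orthonormal_with_baseline(m, r, rng)
    rho = np.asarray(spec.spectrum, dtype=float)
    C = (U * rho) @ V.T
    if spec.count_mode:
        C = np.rint(np.clip(C, 0.0, None))
        # the rounded matrix is the realized truth: re-record its SVD
        Ur, s, Vt = np.linalg.svd(C, full_matrices=False)
        rank = int(np.count_nonzero(s > 1e-10 * s[0])) if s[0] > 0 else 0
        U, rho, V = Ur[:, :rank], s[:rank], Vt[:rank].T
        # orient so baseline loadings are nonnegative, mirroring construction
        for j in range(min(1, rank)):
            if U[:, j].sum() < 0:
                U[:, j] *= -1
                V[:, j] *= -1
    S = np.zeros((g, m))
    if spec.outlier_density > 0:
        n_out = int(round(spec.outlier_density * g * m))
        cells = rng.choice(g * m, size=n_out, replace=False)
        vals = spec.outlier_magnitude * rng.choice([-1.0, 1.0], size=n_out)
        if spec.count_mode:
            vals = np.rint(vals)
        S.flat[cells] = vals
    raw = C + S
    if spec.count_mode:
        raw = np.clip(raw, 0.0, None)
    S = raw - C  # re-record so raw = lowrank + sparse holds exactly in floats
    return MatrixWorldTruth(
        raw=raw,
        lowrank=C,
        sparse=S,
        gene_eigenvectors=U,
        motif_eigenvectors=V,
        spectrum=rho,
        gene_ids=[f"G{i + 1:05d}" for i in range(g)],
        motif_ids=[f"M{j + 1:04d}" for j in range(m)],
        spec=spec,
    )


def truth_decomposition(truth: MatrixWorldTruth, n_levels: int = 9):
    """Wrap a world's exact factors as a fitted DualEigenDecomposition.

    Useful as a sign/orientation reference: rotation directions are only
    defined relative to a basis orientation, and the planted angles live in
    the truth basis.
    """
    from .decomposition import DualEigenDecomposition

    dec = DualEigenDecomposition(n_levels=n_levels, exclude_baseline=True)
    dec.gene_eigenvectors_ = truth.gene_eigenvectors.copy()
    dec.motif_eigenvectors_ = truth.motif_eigenvectors.copy()
    dec.singular_values_ = truth.spectrum.copy()
    dec.rank_ = truth.spectrum.size
    dec.n_levels_ = max(0, min(n_levels, dec.rank_ - 1))
    dec.truncated_ = dec.n_levels_ < n_levels
    dec.gene_ids_ = list(truth.gene_ids)
    dec.motif_ids_ = list(truth.motif_ids)
    return dec


def gen_rotated_species(
    truth: MatrixWorldTruth, theta: float, levels: tuple[int, int] = (4, 5)
) -> MatrixWorldTruth:
    """A second "species": eigen-plane ``levels`` rotated in place by ``theta``.

    ``theta`` is in degrees, counterclockwise positive in the ``(v_j, v_k)``
    plane; both the motif- and gene-eigenvector pairs rotate jointly.
    ``levels`` are reported levels (baseline excluded: raw index == level).
    The returned world is real-valued even for count-mode inputs, so the
    planted angle stays exact.
    """
    j, k = levels
    if j == k:
        raise ValueError("levels must be distinct")
    if abs(theta) > 180:
        raise ValueError("|theta| must be <= 180 degrees")
    r = truth.spectrum.size
    if not (0 <= j < r and 0 <= k < r):
        raise ValueError(f"levels {levels} outside available components 0..{r - 1}")
    t = np.deg2rad(theta)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    U = truth.gene_eigenvectors.copy()
    V = truth.motif_eigenvectors.copy()
    U[:, [j, k]] = U[:, [j, k]] @ R
    V[:, [j, k]] = V[:, [j, k]] @ R
    C = (U * truth.spectrum) @ V.T
    return MatrixWorldTruth(
        raw=C + truth.sparse,
        lowrank=C,
        sparse=truth.sparse.copy(),
        gene_eigenvectors=U,
        motif_eigenvectors=V,
        spectrum=truth.spectrum.copy(),
        gene_ids=list(truth.gene_ids),
        motif_ids=list(truth.motif_ids),
        spec=truth.spec,
    )


# ---------------------------------------------------------------------------
# Sequence worlds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceWorldSpec:
    """Parameters of a promoter sequence world.

    Motif instances are planted per promoter with Poisson counts whose
    gene x motif rate matrix has rank ``rate_rank`` and mean ``mean_rate``.
    ``background_letters`` restricts the background alphabet (e.g. ``"GT"``
    for worlds whose AC-alphabet motifs cannot occur by chance);
    ``consensus_only`` plants consensus strings instead of PWM samples.
    """

    n_genes: int
    n_chroms: int = 2
    chrom_length: int = 60000
    rate_rank: int = 2
    background_gc: float = 0.4
    seed: int = 0
    mean_rate: float = 0.5
    consensus_only: bool = False
    background_letters: str | None = None
    multi_transcript_fraction: float = 0.3

    def __post_init__(self):
        if self.rate_rank < 1:
            raise ValueError("rate_rank must be >= 1")
        per_chrom = -(-self.n_genes // self.n_chroms)  # ceil
        if self.chrom_length < 1700 * per_chrom + 1700:
            raise ValueError("chrom_length too small for all promoter windows")


@dataclass
class SequenceWorld:
    """Paths and ground truth of a generated sequence world."""

    fasta: Path
    gff3: Path
    truth: pd.DataFrame  # planted gene x motif counts
    tss: dict[str, tuple[str, str, int]]  # gene -> (chrom, strand, 1-based tss)


# promoter geometry shared with cref building: -1000..+499 around the TSS
PROMOTER_UP = 1000
PROMOTER_DOWN = 499
PROMOTER_LEN = PROMOTER_UP + PROMOTER_DOWN + 1


def _background(rng, n, gc: float, letters: str | None) -> np.ndarray:
    if letters:
        idx = np.array([ALPHABET.index(b) for b in letters])
        return idx[rng.integers(0, len(idx), size=n)]
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _sample_instance(pwm: PWM, rng, consensus_only: bool) -> str:
    if consensus_only:
        return pwm.consensus
    cum = np.cumsum(pwm.freq, axis=1)
    u = rng.random(pwm.width)
    letters = (u[:, None] > cum).sum(axis=1)
    return "".join(ALPHABET[b] for b in letters)


def gen_sequence_world(
    spec: SequenceWorldSpec,
    pwms: list[PWM],
    out_dir,
    max_tries: int = 200,
) -> SequenceWorld:
    """Write a genome FASTA + GFF3 with planted promoter motif instances.

    Gene promoters (−1000..+499 of the TSS, transcript orientation) receive
    Poisson-distributed instance counts per motif from a rank-``rate_rank``
    nonnegative rate matrix.  Instances are placed non-overlapping with at
    least one background base between them; exceeding the retry budget
    raises.  Returns paths plus the planted count matrix.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    g, m = spec.n_genes, len(pwms)

    A = rng.gamma(2.0, size=(g, spec.rate_rank))
    B = rng.gamma(2.0, size=(spec.rate_rank, m))
    rates = A @ B
    rates *= spec.mean_rate / rates.mean()
    planted = rng.poisson(rates)

    gene_ids = [f"G{i + 1:05d}" for i in range(g)]
    motif_ids = [p.id for p in pwms]
    chrom_ids = [f"chr{c + 1}" for c in range(spec.n_chroms)]
    chrom_seq = {
        c: _background(rng, spec.chrom_length, spec.background_gc, spec.background_letters)
        for c in chrom_ids
    }

    per_chrom = -(-g // spec.n_chroms)
    usable = spec.chrom_length - PROMOTER_UP - PROMOTER_DOWN - 200
    slot = usable // per_chrom

    tss_map: dict[str, tuple[str, str, int]] = {}
    gff_lines = ["##gff-version 3"]
    for i, gid in enumerate(gene_ids):
        chrom = chrom_ids[i // per_chrom]
        k = i % per_chrom
        # 1-based TSS, jittered inside its slot, full window guaranteed
        tss = PROMOTER_UP + 1 + k * slot + int(rng.integers(0, max(1, slot - 1700)))
        strand = "+" if rng.random() < 0.5 else "-"
        tss_map[gid] = (chrom, strand, tss)

        # promoter in transcript orientation
        window = np.empty(PROMOTER_LEN, dtype=np.int64)
        window[:] = _background(
            rng, PROMOTER_LEN, spec.background_gc, spec.background_letters
        )
        occupied = np.zeros(PROMOTER_LEN, dtype=bool)
        for jm, pwm in enumerate(pwms):
            for _ in range(int(planted[i, jm])):
                inst = _sample_instance(pwm, rng, spec.consensus_only)
                L = len(inst)
                placed = False
                for _try in range(max_tries):
                    off = int(rng.integers(0, PROMOTER_LEN - L + 1))
                    lo = max(0, off - 1)
                    hi = min(PROMOTER_LEN, off + L + 1)
                    if not occupied[lo:hi].any():
                        window[off : off + L] = [ALPHABET.index(b) for b in inst]
                        occupied[lo:hi] = True
                        placed = True
                        break
                if not placed:
                    raise RuntimeError(
                        f"window collisions beyond retry budget for {gid}/{pwm.id}"
                    )
        wstr = "".join(ALPHABET[b] for b in window)
        if strand == "+":
            start = tss - PROMOTER_UP  # 1-based inclusive genomic window
            chrom_seq[chrom][start - 1 : start - 1 + PROMOTER_LEN] = [
                ALPHABET.index(b) for b in wstr
            ]
            t1_start, t1_end = tss, tss + 999
        else:
            start = tss - PROMOTER_DOWN
            chrom_seq[chrom][start - 1 : start - 1 + PROMOTER_LEN] = [
                ALPHABET.index(b) for b in revcomp(wstr)
            ]
            t1_start, t1_end = tss - 999, tss
        gene_lo, gene_hi = t1_start, t1_end
        gff_lines.append(
            f"{chrom}\tcrefkit_sim\tgene\t{gene_lo}\t{gene_hi}\t.\t{strand}\t.\t"
            f"ID={gid};biotype=protein_coding"
        )
        gff_lines.append(
            f"{chrom}\tcrefkit_sim\tmRNA\t{t1_start}\t{t1_end}\t.\t{strand}\t.\t"
            f"ID={gid}.t1;Parent={gid};biotype=protein_coding"
        )
        if rng.random() < spec.multi_transcript_fraction:
            # an extra, strictly less upstream transcript: TSS rule unaffected
            if strand == "+":
                t2 = (t1_start + 200, t1_end)
            else:
                t2 = (t1_start, t1_end - 200)
            gff_lines.append(
                f"{chrom}\tcrefkit_sim\tmRNA\t{t2[0]}\t{t2[1]}\t.\t{strand}\t.\t"
                f"ID={gid}.t2;Parent={gid};biotype=protein_coding"
            )

    fasta_path = out_dir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom in chrom_ids:
            fh.write(f">{chrom}\n")
            s = "".join(ALPHABET[b] for b in chrom_seq[chrom])
            for off in range(0, len(s), 60):
                fh.write(s[off : off + 60] + "\n")
    gff_path = out_dir / "genes.gff3"
    gff_path.write_text("\n".join(gff_lines) + "\n")

    truth = pd.DataFrame(planted, index=gene_ids, columns=motif_ids)
    truth = truth.sort_index().sort_index(axis=1)
    return SequenceWorld(fasta=fasta_path, gff3=gff_path, truth=truth, tss=tss_map)


# ---------------------------------------------------------------------------
# Gene sets and SINE-like consensus libraries
# ---------------------------------------------------------------------------

def gen_gene_sets(
    gene_ids,
    n_sets: int = 20,
    size_range: tuple[int, int] = (5, 40),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random gene sets drawn without replacement from ``gene_ids``."""
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    lo, hi = size_range
    out = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, min(hi, len(gene_ids) - 1) + 1))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        out[f"SET{i + 1:04d}"] = [gene_ids[j] for j in sorted(members)]
    return out


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


def gen_consensus_library(
    planted_pwms: list[PWM],
    n_seqs: int = 6,
    length: int = 200,
    background_letters: str | None = None,
    background_gc: float = 0.4,
    seed: int = 0,
    path=None,
) -> dict[str, str]:
    """Synthetic SINE-like consensus sequences carrying the given motifs.

    Each planted PWM's consensus is embedded at least once across the
    library (round-robin, non-overlapping, one background base of flank).
    Returns id -> sequence; optionally writes a FASTA.
    """
    rng = np.random.default_rng(seed)
    seqs = {}
    arrays = []
    for i in range(n_seqs):
        arr = _background(rng, length, background_gc, background_letters)
        arrays.append(arr)
    cursor = [0] * n_seqs
    for idx, pwm in enumerate(planted_pwms):
        i = idx % n_seqs
        cons = pwm.consensus
        off = cursor[i]
        if off + len(cons) + 1 > length:
            raise ValueError("consensus length too small for planted motifs")
        arrays[i][off : off + len(cons)] = [ALPHABET.index(b) for b in cons]
        cursor[i] = off + len(cons) + 1  # one background base of flank
    for i, arr in enumerate(arrays):
        seqs[f"SINE{i + 1:02d}"] = "".join(ALPHABET[b] for b in arr)
    if path is not None:
        with open(path, "w") as fh:
            for sid, s in seqs.items():
                fh.write(f">{sid}\n")
                for off in range(0, len(s), 60):
                    fh.write(s[off : off + 60] + "\n")
    return seqs


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    """Write a truth matrix as TSV with gene rows and motif columns."""
    truth.to_csv(path, sep="\t", index_label="gene")
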