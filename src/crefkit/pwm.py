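"""Position weight matrices and MATCH-style motif scanning.

A PWM is stored as per-position nucleotide frequencies together with an
information-content weight per position.  Windows are scored with the
information-weighted similarity of the MATCH scheme: the matrix similarity
score (MSS) compares the observed information-weighted frequency sum against
the per-position minima and maxima, and the core similarity score (CSS) does
the same over the highest-information 5-bp core window.  A window is a hit
when both scores clear their calibrated cutoffs.

Cutoff profiles (minFN / minFP / minSUM) are calibrated by simulation:
windows sampled from the PWM estimate the false-negative rate, i.i.d.
background windows estimate the false-positive rate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._util import ALPHABET, encode, revcomp

DEFAULT_CORE_LENGTH = 5
#: Pseudocount mass added per position before count->frequency conversion.
PSEUDOCOUNT_FRACTION = 0.01
#: Floor applied to frequencies so information weights stay finite.
FREQUENCY_FLOOR = 1e-4


class DegeneratePWMError(ValueError):
    """Raised when max and min scores coincide (e.g. a uniform matrix)."""


class TransfacParseError(ValueError):
    """Raised on malformed TRANSFAC flat files; message names matrix and line."""


@dataclass(frozen=True)
class PWM:
    """A positional nucleotide frequency model.

    Parameters
    ----------
    id : str
        Motif identifier (TRANSFAC accession or identifier line).
    freq : ndarray, shape (L, 4)
        Per-position frequencies in A, C, G, T order; rows sum to 1.
    core_length : int
        Length of the core window (the consecutive window of maximal
        summed information weight); the full matrix when ``L`` is shorter.
    """

    id: str
    freq: np.ndarray
    core_length: int = DEFAULT_CORE_LENGTH
    info: np.ndarray = field(init=False, repr=False)
    core_start: int = field(init=False)

    def __post_init__(self):
        freq = np.asarray(self.freq, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4:
            raise ValueError(f"PWM {self.id}: frequency matrix must be L x 4")
        if not np.allclose(freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.id}: rows must sum to 1")
        object.__setattr__(self, "freq", freq)
        # information weight I(i) = sum_b f(i,b) ln(4 f(i,b)); zero-frequency
        # letters contribute 0 in the limit f->0.
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(freq > 0, freq * np.log(4.0 * freq), 0.0)
        info = terms.sum(axis=1)
        info[info < 0] = 0.0  # numerical guard; I(i) >= 0 analytically
        object.__setattr__(self, "info", info)
        L = freq.shape[0]
        clen = min(self.core_length, L)
        object.__setattr__(self, "core_length", clen)
        sums = np.convolve(info, np.ones(clen), mode="valid")
        object.__setattr__(self, "core_start", int(np.argmax(sums)))

    @property
    def width(self) -> int:
        return self.freq.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[b] for b in self.freq.argmax(axis=1))

    def score_table(self) -> np.ndarray:
        """Per-position letter scores, shape (L, 5).

        Column 4 is the score of an ambiguous letter (the positional
        minimum, the worst case).
        """
        w = self.info[:, None] * self.freq
        return np.hstack([w, w.min(axis=1, keepdims=True)])

    def reverse_complement(self) -> "PWM":
        return PWM(self.id + "_rc", self.freq[::-1, ::-1].copy(), self.core_length)


@dataclass(frozen=True)
class CutoffProfile:
    """Calibrated score cutoffs for one PWM.

    ``profile`` is one of ``minFN`` (keep >= 90% of PWM-sampled windows),
    ``minFP`` (background hit rate <= target per window) or ``minSUM``
    (minimize estimated FN rate + FP rate on a fixed grid).
    """

    profile: str
    core_cutoff: float
    matrix_cutoff: float
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, c in (("core", self.core_cutoff), ("matrix", self.matrix_cutoff)):
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"{name}_cutoff must be in [0, 1], got {c}")


# ---------------------------------------------------------------------------
# TRANSFAC flat-file reading
# ---------------------------------------------------------------------------

def _finish_matrix(mid, rows, lineno, core_length):
    if not rows:
        raise TransfacParseError(f"matrix {mid!r}: no count rows before line {lineno}")
    counts = np.array(rows, dtype=float)
    return PWM(mid, counts_to_frequencies(counts), core_length)


def counts_to_frequencies(counts: np.ndarray) -> np.ndarray:
    """Convert per-position counts to pseudocounted frequencies.

    Adds ``PSEUDOCOUNT_FRACTION`` of each position's total count, spread
    uniformly over the four letters, then floors at ``FREQUENCY_FLOOR`` and
    renormalizes.  All-zero positions become uniform.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    adj = np.where(totals > 0, counts + PSEUDOCOUNT_FRACTION * totals / 4.0, 0.25)
    freq = adj / adj.sum(axis=1, keepdims=True)
    freq = np.maximum(freq, FREQUENCY_FLOOR)
    return freq / freq.sum(axis=1, keepdims=True)


_ROW_RE = re.compile(r"^(\d\d)\s+(.*)$")


def read_transfac(path, core_length: int = DEFAULT_CORE_LENGTH) -> list[PWM]:
    """Read a TRANSFAC flat matrix file into a list of :class:`PWM`.

    Recognizes ``AC``/``ID``/``NA`` identifier lines, a ``P0`` (or ``PO``)
    header, and numbered count rows with four numeric columns (a trailing
    consensus letter is tolerated).  Counts are converted to frequencies with
    a pseudocount; the information vector and 5-bp core are derived.
    """
    pwms: list[PWM] = []
    mid = None
    rows: list[list[float]] = []
    seen_header = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("VV", "XX", "CC", "BF", "//")):
                if line.startswith("//") and mid is not None and rows:
                    pwms.append(_finish_matrix(mid, rows, lineno, core_length))
                    mid, rows, seen_header = None, [], False
                continue
            tag = line[:2]
            if tag in ("AC", "ID", "NA"):
                if rows and mid is not None:
                    pwms.append(_finish_matrix(mid, rows, lineno, core_length))
                    rows = []
                if tag == "AC" or mid is None:
                    mid = line[2:].strip()
                seen_header = False
                continue
            if tag in ("P0", "PO"):
                seen_header = True
                continue
            m = _ROW_RE.match(line)
            if m:
                fields = m.group(2).split()
                # tolerate a trailing consensus symbol
                if len(fields) == 5 and not _is_number(fields[4]):
                    fields = fields[:4]
                if len(fields) != 4:
                    raise TransfacParseError(
                        f"matrix {mid!r}: expected 4 count columns on line "
                        f"{lineno}, got {len(fields)}"
                    )
                try:
                    rows.append([float(x) for x in fields])
                except ValueError as exc:
                    raise TransfacParseError(
                        f"matrix {mid!r}: non-numeric count on line {lineno}"
                    ) from exc
                continue
            if seen_header or rows:
                raise TransfacParseError(
                    f"matrix {mid!r}: unrecognized line {lineno}: {line!r}"
                )
    if mid is not None and rows:
        pwms.append(_finish_matrix(mid, rows, lineno, core_length))
    if not pwms:
        raise TransfacParseError(f"{path}: no matrices found")
    return pwms


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def write_transfac(pwms, path, scale: int = 100) -> None:
    """Write PWMs as a TRANSFAC flat file with integer counts (``freq*scale``)."""
    with open(path, "w") as fh:
        fh.write("VV  crefkit synthetic PWM library\nXX\n")
        for pwm in pwms:
            fh.write(f"AC  {pwm.id}\nXX\nID  {pwm.id}\nXX\nP0      A      C      G      T\n")
            counts = np.rint(pwm.freq * scale).astype(int)
            for i, row in enumerate(counts, start=1):
                cons = ALPHABET[int(pwm.freq[i - 1].argmax())]
                fh.write(f"{i:02d}  {row[0]:5d}  {row[1]:5d}  {row[2]:5d}  {row[3]:5d}  {cons}\n")
            fh.write("XX\n//\n")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _norm_bounds(table: np.ndarray, start: int, length: int):
    sub = table[start : start + length, :4]
    lo = sub.min(axis=1).sum()
    hi = sub.max(axis=1).sum()
    return lo, hi


def score_window(pwm: PWM, window: str) -> tuple[float, float]:
    """Score one window of length ``pwm.width``; returns ``(mss, css)``.

    ``mss = (Current - Min) / (Max - Min)`` where ``Current`` is the
    information-weighted frequency sum of the window letters and Min/Max the
    analogous per-position extrema; ``css`` is the same restricted to the
    core window.  ``N`` scores as the positional minimum.
    """
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != PWM width {pwm.width} ({pwm.id})"
        )
    table = pwm.score_table()
    idx = encode(window)
    lo, hi = _norm_bounds(table, 0, pwm.width)
    if hi - lo <= 0:
        raise DegeneratePWMError(f"PWM {pwm.id}: Max == Min (uniform matrix)")
    cur = table[np.arange(pwm.width), idx].sum()
    mss = (cur - lo) / (hi - lo)
    cs, cl = pwm.core_start, pwm.core_length
    clo, chi = _norm_bounds(table, cs, cl)
    if chi - clo <= 0:
        raise DegeneratePWMError(f"PWM {pwm.id}: core Max == Min")
    ccur = table[np.arange(cs, cs + cl), idx[cs : cs + cl]].sum()
    css = (ccur - clo) / (chi - clo)
    return float(mss), float(css)


def window_scores(pwm: PWM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ``(mss, css)`` for every window of ``seq`` on one strand.

    Returns empty arrays when the sequence is shorter than the PWM.
    """
    L = pwm.width
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0), np.empty(0)
    table = pwm.score_table()
    lo, hi = _norm_bounds(table, 0, L)
    if hi - lo <= 0:
        raise DegeneratePWMError(f"PWM {pwm.id}: Max == Min (uniform matrix)")
    idx = encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    # per-position scores for each window, summed along the motif axis
    persite = table[np.arange(L)[None, :], windows]
    cur = persite.sum(axis=1)
    mss = (cur - lo) / (hi - lo)
    cs, cl = pwm.core_start, pwm.core_length
    clo, chi = _norm_bounds(table, cs, cl)
    ccur = persite[:, cs : cs + cl].sum(axis=1)
    css = (ccur - clo) / (chi - clo)
    return mss, css


def count_hits(
    pwm: PWM,
    seq: str,
    cutoffs: CutoffProfile,
    both_strands: bool = True,
) -> int:
    """Count motif hits in ``seq`` (and its reverse complement by default).

    A hit requires ``css >= core_cutoff`` and ``mss >= matrix_cutoff``;
    overlapping hits all count.  Sequences shorter than the PWM return 0.
    """
    total = 0
    strands = (seq, revcomp(seq)) if both_strands else (seq,)
    for s in strands:
        mss, css = window_scores(pwm, s)
        if mss.size:
            total += int(
                np.count_nonzero(
                    (css >= cutoffs.core_cutoff) & (mss >= cutoffs.matrix_cutoff)
                )
            )
    return total


# ---------------------------------------------------------------------------
# Cutoff calibration
# ---------------------------------------------------------------------------

def _sample_motif_scores(pwm: PWM, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    L = pwm.width
    cum = np.cumsum(pwm.freq, axis=1)
    u = rng.random((n, L))
    letters = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    return _score_letter_matrix(pwm, letters)


def _sample_background_scores(pwm: PWM, n: int, rng, background) -> tuple[np.ndarray, np.ndarray]:
    letters = rng.choice(4, size=(n, pwm.width), p=background)
    return _score_letter_matrix(pwm, letters)


def _score_letter_matrix(pwm: PWM, letters: np.ndarray):
    table = pwm.score_table()
    L = pwm.width
    persite = table[np.arange(L)[None, :], letters]
    lo, hi = _norm_bounds(table, 0, L)
    mss = (persite.sum(axis=1) - lo) / (hi - lo)
    cs, cl = pwm.core_start, pwm.core_length
    clo, chi = _norm_bounds(table, cs, cl)
    css = (persite[:, cs : cs + cl].sum(axis=1) - clo) / (chi - clo)
    return mss, css


def _smallest_cutoff_with_rate(scores: np.ndarray, target_rate: float) -> float:
    """Smallest cutoff whose estimated hit rate on ``scores`` is <= target."""
    allowed = int(np.floor(target_rate * scores.size))
    if allowed >= scores.size:
        return 0.0
    desc = np.sort(scores)[::-1]
    c = np.nextafter(desc[allowed], 2.0)
    return float(min(c, 1.0))


def _largest_cutoff_with_sensitivity(scores: np.ndarray, sens: float) -> float:
    """Largest cutoff accepting at least ``sens`` of ``scores``."""
    desc = np.sort(scores)[::-1]
    k = int(np.ceil(sens * scores.size))
    return float(np.clip(desc[k - 1], 0.0, 1.0))


def calibrate_cutoffs(
    pwm: PWM,
    profile: str = "minFN",
    n_samples: int = 2000,
    fn_sensitivity: float = 0.90,
    fp_target: float = 1e-4,
    grid: tuple[float, float, float] = (0.6, 1.0, 0.005),
    background=None,
    seed: int = 0,
) -> CutoffProfile:
    """Calibrate matrix and core cutoffs for one PWM by simulation.

    minFN: largest cutoffs retaining ``fn_sensitivity`` of windows sampled
    from the PWM.  minFP: smallest cutoffs with estimated background hit rate
    <= ``fp_target`` per window.  minSUM: grid search minimizing estimated
    FN rate + FP rate.  Deterministic under ``seed``.
    """
    if profile not in ("minFN", "minFP", "minSUM"):
        raise ValueError(f"unknown profile {profile!r}")
    table = pwm.score_table()
    lo, hi = _norm_bounds(table, 0, pwm.width)
    if hi - lo <= 0:
        raise DegeneratePWMError(f"PWM {pwm.id}: Max == Min (uniform matrix)")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    background = background / background.sum()
    rng = np.random.default_rng(seed)
    motif_mss, motif_css = _sample_motif_scores(pwm, n_samples, rng)
    if profile == "minFN":
        mc = _largest_cutoff_with_sensitivity(motif_mss, fn_sensitivity)
        cc = _largest_cutoff_with_sensitivity(motif_css, fn_sensitivity)
    else:
        bg_mss, bg_css = _sample_background_scores(pwm, n_samples, rng, background)
        if profile == "minFP":
            mc = _smallest_cutoff_with_rate(bg_mss, fp_target)
            cc = _smallest_cutoff_with_rate(bg_css, fp_target)
        else:  # minSUM
            start, stop, step = grid
            cuts = np.arange(start, stop + step / 2, step)
            mc = _min_sum_cutoff(cuts, motif_mss, bg_mss)
            cc = _min_sum_cutoff(cuts, motif_css, bg_css)
    return CutoffProfile(
        profile,
        core_cutoff=cc,
        matrix_cutoff=mc,
        params={
            "n_samples": n_samples,
            "fn_sensitivity": fn_sensitivity,
            "fp_target": fp_target,
            "grid": list(grid),
            "background": background.tolist(),
            "seed": seed,
        },
    )


def _min_sum_cutoff(cuts: np.ndarray, motif_scores: np.ndarray, bg_scores: np.ndarray) -> float:
    fn = (motif_scores[None, :] < cuts[:, None]).mean(axis=1)
    fp = (bg_scores[None, :] >= cuts[:, None]).mean(axis=1)
    return float(cuts[int(np.argmin(fn + fp))])
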