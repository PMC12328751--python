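"""MATCH-style scoring, TRANSFAC I/O and cutoff calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crefkit import (
    CutoffProfile,
    DegeneratePWMError,
    PWM,
    TransfacParseError,
    calibrate_cutoffs,
    count_hits,
    read_transfac,
    score_window,
    write_transfac,
)
from crefkit._util import revcomp
from crefkit.synthetic import PwmSpec, gen_pwms

ONE_HOT_ACGT = PWM(
    "acgt",
    np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]], float),
)


def one_hot_pwm(consensus: str) -> PWM:
    freq = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        freq[i, "ACGT".index(b)] = 1.0
    return PWM(consensus.lower(), freq)


# ---------------------------------------------------------------------------
# TRANSFAC reading
# ---------------------------------------------------------------------------

TRANSFAC_ONE = """\
AC  M00001
XX
ID  V$TEST_01
XX
P0      A      C      G      T
01     10      0      0      0
02      0     10      0      0
03      0      0     10      0
04      0      0      0     10
XX
//
"""


def test_read_transfac_one_hot(tmp_path):
    path = tmp_path / "m.dat"
    path.write_text(TRANSFAC_ONE)
    pwms = read_transfac(path)
    assert len(pwms) == 1
    (pwm,) = pwms
    assert pwm.width == 4
    assert pwm.consensus == "ACGT"
    assert np.allclose(pwm.freq.sum(axis=1), 1.0)


def test_read_transfac_uniform_position_zero_info(tmp_path):
    path = tmp_path / "m.dat"
    path.write_text(
        "AC  M1\nP0  A C G T\n01  2 2 2 2\n02  8 0 0 0\n//\n"
    )
    (pwm,) = read_transfac(path)
    # a uniform count row stays uniform after the uniform pseudocount,
    # hence information weight exactly 0
    assert np.allclose(pwm.freq[0], 0.25)
    assert pwm.info[0] == pytest.approx(0.0, abs=1e-12)
    assert pwm.info[1] > 1.0


def test_read_transfac_malformed_row_names_matrix_and_line(tmp_path):
    path = tmp_path / "m.dat"
    path.write_text("AC  MBAD\nP0  A C G T\n01  1 2 3\n//\n")
    with pytest.raises(TransfacParseError, match=r"MBAD.*line 3|line 3"):
        read_transfac(path)


def test_transfac_round_trip(tmp_path, pwm_library):
    path = tmp_path / "lib.dat"
    write_transfac(pwm_library, path, scale=1000)
    back = read_transfac(path)
    assert [p.id for p in back] == [p.id for p in pwm_library]
    for a, b in zip(pwm_library, back):
        # pseudocount perturbs frequencies slightly
        assert np.allclose(a.freq, b.freq, atol=0.02)
        assert a.consensus == b.consensus


# ---------------------------------------------------------------------------
# Window scoring
# ---------------------------------------------------------------------------

def test_score_consensus_is_maximal():
    mss, css = score_window(ONE_HOT_ACGT, "ACGT")
    assert mss == 1.0 and css == 1.0


def test_score_worst_letters_is_zero():
    mss, _ = score_window(ONE_HOT_ACGT, "TTTA")  # per-position worst letters
    assert mss == 0.0


def test_score_window_matches_direct_formula(rng):
    """Independent spreadsheet-style recomputation of the MATCH formula."""
    for _ in range(10):
        raw = rng.random((5, 4))
        freq = raw / raw.sum(axis=1, keepdims=True)
        pwm = PWM("r", freq)
        window = "".join(rng.choice(list("ACGT"), 5))
        info = [sum(f * np.log(4 * f) for f in freq[i]) for i in range(5)]
        cur = sum(info[i] * freq[i, "ACGT".index(window[i])] for i in range(5))
        lo = sum(info[i] * min(freq[i]) for i in range(5))
        hi = sum(info[i] * max(freq[i]) for i in range(5))
        expected = (cur - lo) / (hi - lo)
        mss, _ = score_window(pwm, window)
        assert mss == pytest.approx(expected, abs=1e-12)


def test_score_length_mismatch_raises():
    with pytest.raises(ValueError, match="length"):
        score_window(ONE_HOT_ACGT, "ACG")


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    wseed=st.integers(0, 10_000),
)
def test_scores_bounded_in_unit_interval(seed, wseed):
    pwm = gen_pwms(PwmSpec(1, (5, 9), concentration=2.0, seed=seed))[0]
    rng = np.random.default_rng(wseed)
    window = "".join(rng.choice(list("ACGTN"), pwm.width))
    mss, css = score_window(pwm, window)
    assert 0.0 <= mss <= 1.0
    assert 0.0 <= css <= 1.0


# ---------------------------------------------------------------------------
# Hit counting
# ---------------------------------------------------------------------------

STRICT = CutoffProfile("strict", 1.0, 1.0)


def test_count_hits_examples():
    pwm = one_hot_pwm("AAAC")
    assert count_hits(pwm, "AAACGAAAC", STRICT) == 2
    assert count_hits(pwm, "AAA", STRICT) == 0  # shorter than the PWM


def test_count_hits_monotone_in_cutoff(pwm_library, rng):
    pwm = pwm_library[0]
    seq = "".join(rng.choice(list("ACGT"), 500))
    counts = [
        count_hits(pwm, seq, CutoffProfile("c", 0.0, mc))
        for mc in np.linspace(0.0, 1.0, 11)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_count_hits_reverse_complement_symmetry(pwm_library, rng):
    for pwm in pwm_library[:5]:
        seq = "".join(rng.choice(list("ACGT"), 300))
        prof = CutoffProfile("c", 0.6, 0.7)
        assert count_hits(pwm, seq, prof) == count_hits(
            pwm.reverse_complement(), revcomp(seq), prof
        )


# ---------------------------------------------------------------------------
# Cutoff calibration
# ---------------------------------------------------------------------------

def test_minfn_near_one_hot_cutoff_near_one():
    pwm = gen_pwms(PwmSpec(1, (8, 8), concentration=1e6, seed=0))[0]
    prof = calibrate_cutoffs(pwm, "minFN", seed=1)
    assert prof.matrix_cutoff >= 0.999


def test_uniform_pwm_is_degenerate():
    pwm = PWM("u", np.full((6, 4), 0.25))
    with pytest.raises(DegeneratePWMError):
        calibrate_cutoffs(pwm, "minFN")


def test_minfp_is_most_stringent(pwm_library):
    """minFP cutoffs dominate both other profiles on random PWMs."""
    for pwm in pwm_library:
        fn = calibrate_cutoffs(pwm, "minFN", seed=1).matrix_cutoff
        fp = calibrate_cutoffs(pwm, "minFP", seed=1).matrix_cutoff
        ms = calibrate_cutoffs(pwm, "minSUM", seed=1).matrix_cutoff
        assert fp >= ms
        assert fp >= fn


def test_calibration_deterministic_under_seed(pwm_library):
    a = calibrate_cutoffs(pwm_library[3], "minSUM", seed=42)
    b = calibrate_cutoffs(pwm_library[3], "minSUM", seed=42)
    assert a == b
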