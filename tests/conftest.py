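"""Shared fixtures: synthetic worlds generated once per session."""

import numpy as np
import pytest

from crefkit.synthetic import (
    MatrixWorldSpec,
    PwmSpec,
    SequenceWorldSpec,
    gen_matrix_world,
    gen_pwms,
    gen_sequence_world,
)

# spectra with an explicit dominant baseline (component 0) and nine
# reportable levels; deltas >= 20% in the separated world, delta4 = 1.5%
# in the near-degenerate one
SEPARATED_SPECTRUM = (120, 60, 42, 30, 21, 15, 10.5, 7.4, 5.2, 3.6, 2.5)
DEGENERATE_SPECTRUM = (120, 60, 42, 30, 21, 20.685, 10.5, 7.4, 5.2, 3.6, 2.5)


@pytest.fixture(scope="session")
def separated_world():
    return gen_matrix_world(
        MatrixWorldSpec(200, 60, spectrum=SEPARATED_SPECTRUM, seed=11)
    )


@pytest.fixture(scope="session")
def degenerate_world():
    return gen_matrix_world(
        MatrixWorldSpec(200, 60, spectrum=DEGENERATE_SPECTRUM, seed=11)
    )


@pytest.fixture(scope="session")
def pwm_library():
    """Twenty moderately sharp random PWMs."""
    return gen_pwms(PwmSpec(20, (6, 12), concentration=3.0, seed=9))


@pytest.fixture(scope="session")
def background_free_world(tmp_path_factory):
    """Sequence world whose motifs cannot occur by chance on either strand.

    Motif alphabet {A, T} is complement-closed; the background is constant
    G (complement C), so any window touching background scores below the
    maximum; consensi are revcomp-unique, so each planted instance hits
    exactly its own motif exactly once.
    """
    pwms = gen_pwms(
        PwmSpec(8, (8, 8), concentration=1e6, seed=5, letters="AT",
                unique_consensus=True)
    )
    spec = SequenceWorldSpec(
        n_genes=40, n_chroms=2, chrom_length=60000, rate_rank=2, seed=7,
        mean_rate=0.8, consensus_only=True, background_letters="G",
    )
    out = tmp_path_factory.mktemp("seqworld")
    world = gen_sequence_world(spec, pwms, out)
    return pwms, world


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
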