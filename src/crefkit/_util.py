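"""Small shared helpers: alphabet encoding, reverse complement, seeding."""

from __future__ import annotations

import numpy as np

#: Canonical nucleotide order used throughout the package.
ALPHABET = "ACGT"

_ENCODE = np.full(256, 4, dtype=np.int8)  # 4 == ambiguous (N or anything else)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 indices (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (preserves case, N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one seed.

    Uses ``SeedSequence.spawn`` so per-replicate streams are reproducible
    regardless of execution order.
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
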