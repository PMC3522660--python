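"""Shared 2-bit DNA encoding helpers (A=0, C=1, G=2, T=3)."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_DEC = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """uint8 codes; non-ACGT characters (e.g. N) become 255."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DEC[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def random_dna(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, length, dtype=np.uint8))
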