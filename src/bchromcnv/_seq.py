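"""Nucleotide <-> integer code helpers shared by the simulator and mapper.

Codes: A=0, C=1, G=2, T=3, N(=anything else)=4. All heavy per-base work in
this package happens on uint8 code arrays; strings only appear at the I/O
boundary.
"""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string into a uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (code 4 renders as ``N``)."""
    return BASES[codes].tobytes().decode("ascii")


def gc_fraction(codes: np.ndarray) -> float:
    """GC fraction over non-N bases; 0.0 for empty/all-N input."""
    ok = codes < 4
    n = int(ok.sum())
    if n == 0:
        return 0.0
    gc = np.count_nonzero((codes == 1) | (codes == 2))
    return gc / n
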