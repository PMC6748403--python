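"""Shared symbol encoding for sequences in MSA coordinates.

Every sequence handled by the model (panel alleles, latent haplotypes,
realigned reads) is a string over ``{A, C, G, T, N, -}``.  Internally
symbols are stored as small integer codes so that probability tables can
be indexed directly.
"""

from __future__ import annotations

import numpy as np

#: Symbol order defines the integer code of each symbol.
SYMBOLS = "ACGTN-"

A, C, G, T, N, GAP = range(6)

#: Codes 0..3 are the four nucleotides.
N_BASES = 4

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate(SYMBOLS):
    _ENCODE[ord(_ch)] = _i
    _ENCODE[ord(_ch.lower())] = _i
_ENCODE[ord(".")] = GAP  # IMGT alignment files use '.' for indel gaps

_DECODE = np.frombuffer(SYMBOLS.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string into integer codes (uint8)."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _ENCODE[raw]
    if (codes == 255).any():
        bad = chr(raw[codes == 255][0])
        raise ValueError(f"invalid sequence symbol {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode integer codes back into a string over ``ACGTN-``."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode()
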