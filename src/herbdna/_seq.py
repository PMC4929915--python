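"""Base-encoding helpers shared by the simulator and the profilers.

Bases are encoded A=0, C=1, G=2, T=3 so that complementation is ``3 - code``.
Anything that is not an upper-case A/C/G/T maps to the sentinel 255 and is
skipped by the tally routines.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3
N_CODE = 255

# ASCII -> code lookup (uppercase and lowercase)
_LUT = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMP_TABLE = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to a uint8 code array."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a code array (must contain only 0..3) back to a string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse-complement a sequence string (A/C/G/T/N, case-preserving)."""
    return seq.translate(_COMP_TABLE)[::-1]


def complement_codes(codes: np.ndarray) -> np.ndarray:
    out = 3 - codes.astype(np.int16)
    out[codes == N_CODE] = N_CODE
    return out.astype(np.uint8)
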