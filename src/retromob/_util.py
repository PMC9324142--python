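"""Low-level sequence utilities shared across modules.

Sequences are plain upper-case ``str`` at module boundaries; hot loops
work on ``uint8`` numpy arrays produced by :func:`encode`.
All coordinates are 0-based half-open; conversion to 1-based inclusive
happens only in the GFF3 writers.
"""

from __future__ import annotations

import numpy as np

_COMP = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

# base -> 2-bit code; anything else -> 255 (treated as unmatched everywhere)
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lower case

_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)

#: transition partner per 2-bit code (A<->G, C<->T)
TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)
#: the two transversion partners per 2-bit code
TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)
#: purine/pyrimidine class per code (A,G -> 0; C,T -> 1)
BASE_CLASS = np.array([0, 1, 0, 1], dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 array of 2-bit codes (255 = other)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode("ascii")


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """I.i.d. background sequence at the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=n, p=p).astype(np.uint8))


def kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling polynomial hash (base 4, wrap-around uint64) of every k-mer.

    Positions whose window contains a non-ACGT code hash to values that
    callers must verify by direct comparison anyway; hash equality is
    always confirmed against the underlying sequence.
    """
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    h = np.zeros(n - k + 1, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            h = h * np.uint64(1099511628211) + codes[j : n - k + 1 + j]
    return h


def xdrop_extend(
    match: np.ndarray,
    lo: int,
    hi: int,
    mismatch_penalty: int = 3,
    xdrop: int = 18,
) -> tuple[int, int]:
    """Extend the seed interval ``[lo, hi)`` over a boolean match array.

    Scores +1 per match, ``-mismatch_penalty`` per mismatch, stopping a
    direction once the running score falls ``xdrop`` below its maximum.
    Returns the half-open interval whose ends sit at the score maxima.
    """
    best = lo
    score, top = 0, 0
    for i in range(lo - 1, -1, -1):
        score += 1 if match[i] else -mismatch_penalty
        if score > top:
            top, best = score, i
        elif top - score > xdrop:
            break
    left = best
    best = hi
    score, top = 0, 0
    for i in range(hi, match.size):
        score += 1 if match[i] else -mismatch_penalty
        if score > top:
            top, best = score, i + 1
        elif top - score > xdrop:
            break
    return left, best


def child_rng(rng: np.random.Generator) -> np.random.Generator:
    """Split an independent child stream off an existing generator."""
    return np.random.default_rng(rng.integers(0, 2**31 - 1))
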