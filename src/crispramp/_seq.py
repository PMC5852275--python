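"""Low-level DNA sequence primitives shared by all pipeline stages.

Sequences are plain uppercase strings over {A,C,G,T,N}; hot loops work on
``numpy`` uint8 encodings (A=0, C=1, G=2, T=3, N=4).  ``N`` never matches
anything, including another ``N``.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 array (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return bytes(_DECODE[arr]).decode("ascii")


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between two equal-length encoded sequences."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return int(np.count_nonzero(a != b))


def overlap_match_counts(a: np.ndarray, b: np.ndarray):
    """Match counts for every ungapped end-gap-free placement of ``b`` on ``a``.

    For shift ``s``, ``b[j]`` is aligned to ``a[j + s]``; ``s`` runs from
    ``-(len(b) - 1)`` to ``len(a) - 1`` so every placement with at least one
    aligned column is scored.

    Returns
    -------
    shifts, matches, overlaps : ``numpy`` int arrays of length n + m - 1.
    """
    n, m = len(a), len(b)
    counts = np.zeros(n + m - 1, dtype=np.float64)
    for code in range(4):  # code 4 (N) matches nothing
        counts += np.correlate(
            (a == code).astype(np.float64), (b == code).astype(np.float64), mode="full"
        )
    matches = np.rint(counts).astype(np.int64)
    shifts = np.arange(-(m - 1), n)
    overlaps = np.minimum(n, shifts + m) - np.maximum(shifts, 0)
    return shifts, matches, overlaps


def best_overlap(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """Best ungapped end-gap-free alignment of ``b`` against ``a``.

    "Best" maximizes the number of matching columns; ties prefer the smaller
    overlap (hence the higher identity), then the smaller shift, which makes
    the result deterministic.

    Returns ``(matches, overlap, shift)``.
    """
    shifts, matches, overlaps = overlap_match_counts(a, b)
    cand = np.flatnonzero(matches == matches.max())
    cand = cand[overlaps[cand] == overlaps[cand].min()]
    i = int(cand[0])  # shifts ascend, so first candidate has the smallest shift
    return int(matches[i]), int(overlaps[i]), int(shifts[i])
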