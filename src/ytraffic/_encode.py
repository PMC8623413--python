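"""2-bit nucleotide encoding and integer k-mer codes.

Shared by the k-mer classifier, the simulators and the read placer.  A k-mer
over ACGT is packed into an int64 (2 bits per base, A=0 C=1 G=2 T=3, leftmost
base in the highest bits), which keeps k <= 31 exact.  Windows containing any
non-ACGT symbol are excluded by the validity mask.
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lowercase

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (255 marks ambiguous symbols)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def revcomp_str(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Int64 codes of every valid k-window of `arr`, with window start positions.

    Valid means the window contains only ACGT.  Returns (codes, starts).
    """
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    for j in range(k):
        codes |= np.where(arr[j : j + m] < 4, arr[j : j + m], 0).astype(np.int64) << (
            2 * (k - 1 - j)
        )
    ok = np.cumsum(np.concatenate(([0], (arr < 4).astype(np.int64))))
    valid = (ok[k:] - ok[:-k]) == k
    starts = np.nonzero(valid)[0]
    return codes[starts], starts


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    rc = np.zeros_like(codes)
    for j in range(k):
        base = (codes >> (2 * j)) & 3
        rc |= (3 ^ base) << (2 * (k - 1 - j))
    return rc


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Strand-collapsed representation: min(code, revcomp(code))."""
    return np.minimum(codes, revcomp_codes(codes, k))


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for j in range(k - 1, -1, -1):
        out.append("ACGT"[(code >> (2 * j)) & 3])
    return "".join(out)


def in_sorted(values: np.ndarray, sorted_arr: np.ndarray) -> np.ndarray:
    """Boolean membership of `values` in a sorted unique array."""
    if sorted_arr.size == 0:
        return np.zeros(values.shape, dtype=bool)
    idx = np.searchsorted(sorted_arr, values)
    idx_c = np.minimum(idx, sorted_arr.size - 1)
    return sorted_arr[idx_c] == values
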