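"""Vectorized k-mer encoding and a sorted-array k-mer position index.

Used for seeding genome-wide copy scans and for pairwise prefiltering in
window clustering.  k-mers containing ``N`` (or any non-ACGT base) are
excluded from indexing and querying.
"""

from __future__ import annotations

import numpy as np

__all__ = ["encode_kmers", "KmerIndex", "kmer_set"]

_CODE = np.full(256, -1, dtype=np.int64)
for i, base in enumerate(b"ACGT"):
    _CODE[base] = i


def encode_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (codes, positions) for every valid k-mer of ``seq``.

    Codes are 2-bit packed integers; k must satisfy 2k <= 62.
    """
    if k < 1 or 2 * k > 62:
        raise ValueError("k out of range")
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    valid = codes >= 0
    # rolling 2-bit pack
    acc = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        acc = (acc << 2) | np.where(codes[j : j + n] >= 0, codes[j : j + n], 0)
        ok &= valid[j : j + n]
    positions = np.nonzero(ok)[0]
    return acc[positions], positions


def kmer_set(seq: str, k: int) -> frozenset[int]:
    codes, _ = encode_kmers(seq, k)
    return frozenset(codes.tolist())


class KmerIndex:
    """Sorted-array index mapping k-mer code -> sorted positions."""

    def __init__(self, seq: str, k: int):
        self.k = k
        codes, positions = encode_kmers(seq, k)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._positions = positions[order]

    def lookup(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._positions[lo:hi]

    def lookup_many(self, codes: np.ndarray, qpos: np.ndarray, max_per_kmer: int = 64):
        """Yield (target_pos, query_pos) seed pairs for all query k-mers.

        k-mers with more than ``max_per_kmer`` genome occurrences are skipped
        as low-complexity noise.
        """
        tpos_all = []
        qpos_all = []
        lo = np.searchsorted(self._codes, codes, side="left")
        hi = np.searchsorted(self._codes, codes, side="right")
        counts = hi - lo
        for i in np.nonzero((counts > 0) & (counts <= max_per_kmer))[0]:
            tp = self._positions[lo[i] : hi[i]]
            tpos_all.append(tp)
            qpos_all.append(np.full(len(tp), qpos[i], dtype=np.int64))
        if not tpos_all:
            return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        return np.concatenate(tpos_all), np.concatenate(qpos_all)
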