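"""Independent brute-force oracles used to validate the package's alignment
and scanning code paths.

These deliberately avoid Biopython and the package's seeded-scan machinery:
plain dynamic programming (numpy row-vectorized for the genome scan, pure
Python for short pairs) with the same scoring contract: match +1, mismatch
-1, linear gap -2, N never matches.
"""

from __future__ import annotations

import numpy as np

MATCH, MISMATCH, GAP = 1, -1, -2


def _s(a: str, b: str) -> int:
    return MATCH if (a == b and a != "N") else MISMATCH


def dp_local_score(a: str, b: str) -> int:
    """Smith-Waterman optimal local alignment score, pure python."""
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            v = max(
                0,
                prev[j - 1] + _s(a[i - 1], b[j - 1]),
                prev[j] + GAP,
                cur[j - 1] + GAP,
            )
            cur[j] = v
            if v > best:
                best = v
        prev = cur
    return best


def dp_local_stats(a: str, b: str):
    """(score, matches, columns, a_span, b_span) of one optimal local
    alignment, full-matrix python DP with diagonal-first traceback."""
    n, m = len(a), len(b)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        Di, Dp = D[i], D[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            v = Dp[j - 1] + _s(ai, b[j - 1])
            w = Dp[j] + GAP
            if w > v:
                v = w
            w = Di[j - 1] + GAP
            if w > v:
                v = w
            if v < 0:
                v = 0
            Di[j] = v
            if v > best:
                best, bi, bj = v, i, j
    i, j = bi, bj
    matches = columns = 0
    while i > 0 and j > 0 and D[i][j] > 0:
        if D[i][j] == D[i - 1][j - 1] + _s(a[i - 1], b[j - 1]):
            matches += a[i - 1] == b[j - 1] and a[i - 1] != "N"
            columns += 1
            i -= 1
            j -= 1
        elif D[i][j] == D[i - 1][j] + GAP:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return best, matches, columns, (i, bi), (j, bj)


def dp_glocal_score(query: str, target: str) -> int:
    """Semi-global score: query end-to-end, target flanks free."""
    m, n = len(query), len(target)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [prev[0] + GAP] + [0] * n
        for j in range(1, n + 1):
            cur[j] = max(
                prev[j - 1] + _s(query[i - 1], target[j - 1]),
                prev[j] + GAP,
                cur[j - 1] + GAP,
            )
        prev = cur
    return max(prev)


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.int8)
    for i, c in enumerate("ACGT"):
        lut[ord(c)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _glocal_matrix(query: str, target: str) -> np.ndarray:
    """Full (m+1, n+1) semi-global DP matrix, vectorized over the target."""
    q = _encode(query)
    t = _encode(target)
    m, n = len(q), len(t)
    D = np.zeros((m + 1, n + 1), dtype=np.int32)
    jj = np.arange(n + 1, dtype=np.int64) * (-GAP)
    for i in range(1, m + 1):
        sub = np.where((t == q[i - 1]) & (t < 4) & (q[i - 1] < 4), MATCH, MISMATCH)
        row = np.empty(n + 1, dtype=np.int32)
        row[0] = D[i - 1, 0] + GAP
        np.maximum(D[i - 1, :-1] + sub, D[i - 1, 1:] + GAP, out=row[1:])
        # horizontal propagation: row[j] = max(row[j], max_k<j row[k]+GAP*(j-k))
        run = np.maximum.accumulate(row + jj)
        row = np.maximum(row, (run - jj).astype(np.int32))
        D[i] = row
    return D


def _traceback(D: np.ndarray, query: str, target: str, j_end: int):
    """Walk back from (m, j_end); returns (j_start, matches, columns)."""
    i = len(query)
    j = j_end
    matches = 0
    columns = 0
    while i > 0:
        here = D[i, j]
        if j > 0:
            diag = D[i - 1, j - 1] + _s(query[i - 1], target[j - 1])
            if here == diag:
                if query[i - 1] == target[j - 1] and query[i - 1] != "N":
                    matches += 1
                columns += 1
                i -= 1
                j -= 1
                continue
        if here == D[i - 1, j] + GAP:
            columns += 1
            i -= 1
            continue
        assert j > 0 and here == D[i, j - 1] + GAP, "inconsistent traceback"
        columns += 1
        j -= 1
    return j, matches, columns


def glocal_scan_oracle(
    query: str, target: str, min_identity: float
) -> list[tuple[int, int, float]]:
    """All non-overlapping loci where ``query`` aligns semi-globally into
    ``target`` at >= min_identity, by exhaustive DP over every end position
    plus greedy best-first overlap resolution (mirroring the scan contract).
    """
    m = len(query)
    D = _glocal_matrix(query, target)
    last = D[m]
    floor = int(np.floor(m * (3.0 * min_identity - 2.0))) - 3
    cand = np.nonzero(last[1:] >= floor)[0] + 1
    # canonical hit per start: max score, then shortest span (score-tied
    # gapped variants of the same alignment shift the end by a column)
    by_start: dict[int, tuple] = {}
    for j in cand:
        j0, matches, columns = _traceback(D, query, target, int(j))
        ident = matches / columns if columns else 0.0
        score = int(last[j])
        cur = by_start.get(j0)
        if cur is None or (score, -int(j)) > (cur[3], -cur[1]):
            by_start[j0] = (j0, int(j), ident, score)
    # suppress score-tied start-shifted variants of the same alignment:
    # greedy by (score desc, span asc, leftmost) over overlapping hits
    variants = sorted(
        by_start.values(), key=lambda h: (-h[3], h[1] - h[0], h[0])
    )
    canonical = []
    for h in variants:
        if any(h[0] < c[1] and c[0] < h[1] for c in canonical):
            continue
        canonical.append(h)
    hits = [(j0, j, ident) for j0, j, ident, _s in canonical if ident >= min_identity]
    # greedy best-first (higher identity, then leftmost)
    hits.sort(key=lambda h: (-h[2], h[0], h[1]))
    chosen = []
    for h in hits:
        if any(h[0] < c[1] and c[0] < h[1] for c in chosen):
            continue
        chosen.append(h)
    chosen.sort()
    return chosen


def scan_copies_oracle(query: str, contig_seq: str, min_identity: float):
    """Both-strand brute-force copy scan; returns (start, end, strand) set
    after cross-strand greedy overlap resolution."""
    from sinescout.seqcore_io import revcomp

    raw = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        for s, e, ident in glocal_scan_oracle(q, contig_seq, min_identity):
            raw.append((s, e, ident, strand))
    raw.sort(key=lambda h: (-h[2], h[0], h[1], h[3]))
    chosen = []
    for h in raw:
        if any(h[0] < c[1] and c[0] < h[1] for c in chosen):
            continue
        chosen.append(h)
    return {(s, e, strand) for s, e, _ident, strand in chosen}


def naive_substring_hits(reads, targets):
    """O(n*m) exact-substring oracle mirroring map_exact's contract."""
    from sinescout.seqcore_io import revcomp

    hits = set()
    for tid, tseq in targets:
        for r in reads:
            for seq, orient in ((r.seq, "F"), (revcomp(r.seq), "R")):
                start = 0
                while True:
                    idx = tseq.find(seq, start)
                    if idx < 0:
                        break
                    hits.add((r.seq, tid, idx, orient))
                    start = idx + 1
    return hits


def brute_promoter_pairs(seq: str, max_mm: int, spacing: tuple[int, int]):
    """Position-by-position brute scan for A/B box pairs on one strand."""
    from sinescout.promoter import ABOX_PATTERN, BBOX_PATTERN
    from sinescout.seqcore_io import iupac_mismatches

    L = 11
    a_pos = [
        i
        for i in range(len(seq) - L + 1)
        if iupac_mismatches(ABOX_PATTERN, seq[i : i + L]) <= max_mm
    ]
    b_pos = [
        i
        for i in range(len(seq) - L + 1)
        if iupac_mismatches(BBOX_PATTERN, seq[i : i + L]) <= max_mm
    ]
    pairs = []
    for a in a_pos:
        for b in b_pos:
            gap = b - (a + L)
            if spacing[0] <= gap <= spacing[1]:
                pairs.append((a, b))
    return pairs
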