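"""Low-level repeat primitives: direct-repeat (TSD) search and perfect
tandem-repeat detection with minimal-rotation unit canonicalization."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DirectRepeat",
    "TandemRun",
    "find_direct_repeat",
    "min_rotation",
    "find_tandem_runs",
]


@dataclass(frozen=True, slots=True)
class DirectRepeat:
    """A direct repeat flanking a candidate element inside one sequence.

    ``left_end`` is the (exclusive) end of the left copy == refined element
    start; ``right_start`` is the start of the right copy == refined element
    end.  Both coordinates are in the frame of the searched sequence.
    """

    left_end: int
    right_start: int
    length: int
    seq: str
    mismatches: int


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def find_direct_repeat(
    seq: str,
    start: int,
    end: int,
    min_len: int = 10,
    max_len: int = 15,
    max_mismatch: int = 0,
    max_offset: int = 0,
) -> DirectRepeat | None:
    """Longest direct repeat whose left copy ends at ``start`` and right copy
    begins at ``end``, allowing each junction to shift by up to
    ``max_offset`` bp.  Among equal lengths the pair closest to the stated
    element ends wins; further ties prefer fewer mismatches, then the
    smaller left shift.
    """
    n = len(seq)
    junctions = sorted(
        (
            (dl, dr)
            for dl in range(-max_offset, max_offset + 1)
            for dr in range(-max_offset, max_offset + 1)
        ),
        key=lambda j: (abs(j[0]) + abs(j[1]), abs(j[0]), j[0], j[1]),
    )
    for length in range(max_len, min_len - 1, -1):
        best: DirectRepeat | None = None
        best_key = None
        for dl, dr in junctions:
            s = start + dl
            e = end + dr
            if e <= s or s - length < 0 or e + length > n:
                continue
            mm = _hamming(seq[s - length : s], seq[e : e + length])
            if mm <= max_mismatch:
                key = (-(abs(dl) + abs(dr)), -mm, -abs(dl))
                if best is None or key > best_key:
                    best = DirectRepeat(
                        left_end=s, right_start=e, length=length,
                        seq=seq[s - length : s], mismatches=mm,
                    )
                    best_key = key
        if best is not None:
            return best
    return None


def direct_repeat_junctions(
    seq: str,
    start: int,
    end: int,
    min_len: int = 10,
    max_len: int = 15,
    max_offset: int = 15,
) -> set[tuple[int, int]]:
    """All (left_end, right_start) junction pairs near (start, end) delimited
    by a mismatch-free direct repeat of length in [min_len, max_len].

    Each junction is reported once regardless of how far its repeat extends;
    used for cross-member junction voting during boundary refinement."""
    n = len(seq)
    out: set[tuple[int, int]] = set()
    for dl in range(-max_offset, max_offset + 1):
        s = start + dl
        if s - min_len < 0:
            continue
        for dr in range(-max_offset, max_offset + 1):
            e = end + dr
            if e <= s or e + min_len > n:
                continue
            for length in range(min(max_len, s, n - e), min_len - 1, -1):
                if seq[s - length : s] == seq[e : e + length]:
                    out.add((s, e))
                    break
    return out


def min_rotation(unit: str) -> str:
    """Lexicographically minimal rotation (canonical tandem-repeat unit)."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


@dataclass(frozen=True, slots=True)
class TandemRun:
    start: int
    end: int
    unit: str  # canonical (minimal rotation)
    copies: int

    @property
    def span_length(self) -> int:
        return self.end - self.start


def find_tandem_runs(
    seq: str,
    max_unit: int = 6,
    min_copies: int = 3,
) -> list[TandemRun]:
    """All maximal perfect tandem runs with primitive unit length 1..max_unit
    and at least ``min_copies`` full copies.  Runs wholly contained in another
    run with the same canonical unit are suppressed.
    """
    n = len(seq)
    runs: list[TandemRun] = []
    for u in range(1, max_unit + 1):
        i = 0
        while i + u <= n:
            unit = seq[i : i + u]
            if not _is_primitive(unit):
                i += 1
                continue
            j = i + u
            while j + u <= n and seq[j : j + u] == unit:
                j += u
            # extend partial copy at the right edge
            extra = 0
            while j + extra < n and seq[j + extra] == unit[extra % u]:
                extra += 1
            copies = (j - i) // u
            if copies >= min_copies:
                runs.append(
                    TandemRun(start=i, end=j + extra, unit=min_rotation(unit),
                              copies=copies)
                )
                i = j + extra  # skip past the run for this unit size
            else:
                i += 1
    # suppress contained duplicates of the same canonical unit
    keep: list[TandemRun] = []
    for r in sorted(runs, key=lambda r: (-r.span_length, r.start)):
        if any(
            k.unit == r.unit and k.start <= r.start and r.end <= k.end
            for k in keep
        ):
            continue
        keep.append(r)
    keep.sort(key=lambda r: (r.start, r.end))
    return keep
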