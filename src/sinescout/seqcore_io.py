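"""Sequence/annotation I/O, coordinate conventions, degenerate-motif matching,
and pairwise alignment primitives.

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open intervals.  GFF3 output is
1-based inclusive; BED output is 0-based half-open.  Tabular reports use
1-based inclusive coordinates.

Alignment scoring defaults to match +1, mismatch -1, linear gap -2.  Percent
identity is defined as matches / alignment columns, counting internal gap
columns but not end gaps.  ``N`` never matches anything, including another
``N``, and scores as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSequence",
    "Interval",
    "AlignmentResult",
    "AlignScoring",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "iupac_match",
    "iupac_mismatches",
    "IUPAC_CODES",
    "align_local",
    "align_glocal",
    "write_bed6",
]

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)
_IUPAC_SET = frozenset(IUPAC_CODES)


class FastaError(ValueError):
    """Raised for malformed FASTA input."""


@dataclass(frozen=True, slots=True)
class Interval:
    """0-based half-open genomic interval."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def as_1based(self) -> tuple[int, int]:
        """(start, end) in 1-based inclusive convention."""
        return self.start + 1, self.end


@dataclass(frozen=True, slots=True)
class GenomeSequence:
    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence record with empty id")
        if not self.seq:
            raise FastaError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - _IUPAC_SET
        if bad:
            raise FastaError(
                f"record {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, slots=True)
class AlignmentResult:
    score: float
    aligned_length: int
    matches: int
    identity: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.matches > self.aligned_length:
            raise ValueError("matches exceed aligned_length")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-record, possibly wrapped) FASTA file, uppercasing."""
    path = Path(path)
    records: list[GenomeSequence] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(GenomeSequence(id=rec.id, seq=str(rec.seq).upper()))
    except ValueError as exc:
        raise FastaError(f"malformed FASTA in {path}: {exc}") from exc
    if not records and path.stat().st_size > 0:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed6(rows: Iterable[tuple], path: str | Path, header: bool = True) -> None:
    """rows: (contig, start, end, name, score, strand). 0-based half-open."""
    with open(path, "w") as fh:
        if header:
            fh.write("# BED6, 0-based half-open coordinates\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Elementary sequence ops

def revcomp(seq: str) -> str:
    """Reverse complement over the IUPAC DNA alphabet."""
    bad = set(seq) - _IUPAC_SET
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_mismatches(pattern: str, window: str) -> int:
    """Number of window positions outside the expansion of the pattern code.

    ``N`` in the *window* never matches any pattern base.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs window {len(window)}"
        )
    mm = 0
    for p, w in zip(pattern, window):
        if w == "N" or w not in IUPAC_CODES[p]:
            mm += 1
    return mm


def iupac_match(pattern: str, window: str) -> bool:
    return iupac_mismatches(pattern, window) == 0


# ---------------------------------------------------------------------------
# Pairwise alignment

@dataclass(frozen=True)
class AlignScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0

    def substitution_matrix(self):
        from Bio.Align import substitution_matrices

        alphabet = "ACGTN"
        m = substitution_matrices.Array(alphabet, dims=2)
        for a in alphabet:
            for b in alphabet:
                if a == b and a != "N":
                    m[a, b] = self.match
                else:
                    m[a, b] = self.mismatch
        return m


DEFAULT_SCORING = AlignScoring()

_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _get_aligner(scoring: AlignScoring, mode: str) -> Align.PairwiseAligner:
    key = (scoring.match, scoring.mismatch, scoring.gap, mode)
    aligner = _ALIGNER_CACHE.get(key)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = scoring.substitution_matrix()
        aligner.open_gap_score = scoring.gap
        aligner.extend_gap_score = scoring.gap
        if mode == "local":
            aligner.mode = "local"
        else:
            aligner.mode = "global"
            # free end gaps in the query row: the query aligns end-to-end
            # while the target's flanks stay unaligned (containment).
            try:
                aligner.end_deletion_score = 0.0
            except AttributeError:  # pragma: no cover - older Biopython
                aligner.query_end_gap_score = 0.0
        _ALIGNER_CACHE[key] = aligner
    return aligner


def _sanitize(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence passed to aligner")
    out = []
    for ch in seq:
        if ch in "ACGT":
            out.append(ch)
        elif ch in _IUPAC_SET:
            out.append("N")
        else:
            raise ValueError(f"non-IUPAC character {ch!r} in alignment input")
    return "".join(out)


def _segments(coords: np.ndarray) -> list[tuple[int, int, int, int]]:
    segs = []
    for k in range(coords.shape[1] - 1):
        t0, t1 = int(coords[0, k]), int(coords[0, k + 1])
        q0, q1 = int(coords[1, k]), int(coords[1, k + 1])
        if t1 > t0 or q1 > q0:
            segs.append((t0, t1, q0, q1))
    return segs


def _result_from_alignment(alignment, query: str, target: str) -> AlignmentResult:
    segs = _segments(alignment.coordinates)
    # trim flanking target-only segments (free end gaps in glocal mode)
    while segs and segs[0][2] == segs[0][3]:
        segs.pop(0)
    while segs and segs[-1][2] == segs[-1][3]:
        segs.pop()
    if not segs:
        return AlignmentResult(0.0, 0, 0, 0.0, (0, 0), (0, 0))
    matches = 0
    columns = 0
    for t0, t1, q0, q1 in segs:
        if t1 > t0 and q1 > q0:  # diagonal
            columns += t1 - t0
            for a, b in zip(target[t0:t1], query[q0:q1]):
                if a == b and a != "N":
                    matches += 1
        else:  # gap segment
            columns += max(t1 - t0, q1 - q0)
    qspan = (segs[0][2], segs[-1][3])
    tspan = (segs[0][0], segs[-1][1])
    identity = matches / columns if columns else 0.0
    return AlignmentResult(
        score=float(alignment.score),
        aligned_length=columns,
        matches=matches,
        identity=identity,
        query_span=qspan,
        target_span=tspan,
    )


def align_local(a: str, b: str, scoring: AlignScoring = DEFAULT_SCORING) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of ``a`` (query) within ``b`` (target)."""
    query, target = _sanitize(a), _sanitize(b)
    aligner = _get_aligner(scoring, "local")
    alignments = aligner.align(target, query)
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentResult(0.0, 0, 0, 0.0, (0, 0), (0, 0))
    return _result_from_alignment(alignments[0], query, target)


def align_glocal(query: str, target: str, scoring: AlignScoring = DEFAULT_SCORING) -> AlignmentResult:
    """Semi-global alignment: query end-to-end, target ends free."""
    q, t = _sanitize(query), _sanitize(target)
    aligner = _get_aligner(scoring, "glocal")
    alignments = aligner.align(t, q)
    return _result_from_alignment(alignments[0], q, t)
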