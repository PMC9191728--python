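"""Pol III type-2 promoter detection (A box + B box) and anchor handling.

The two 11-bp internal promoter boxes follow the canonical degenerate
consensi ``TRGYNNARNNG`` (A box) and ``RGTTCRANTCC`` (B box), spaced by a
configurable number of bases.  Anchors for downstream window extraction come
either from a tRNA-scanner tabular file (preferred when available) or from
the promoter scan itself, in which case the anchor is placed a fixed
transcription-start offset upstream of the A box.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqcore_io import GenomeSequence, Interval, IUPAC_CODES, iupac_mismatches

__all__ = [
    "ABOX_PATTERN",
    "BBOX_PATTERN",
    "BOX_LENGTH",
    "DEFAULT_TSS_OFFSET",
    "PromoterHit",
    "AnchorHit",
    "scan_promoters",
    "anchors_from_promoters",
    "read_trnascan",
    "measure_tss_offset",
]

ABOX_PATTERN = "TRGYNNARNNG"
BBOX_PATTERN = "RGTTCRANTCC"
BOX_LENGTH = 11
# observed distance from element 5' end to the A box start
DEFAULT_TSS_OFFSET = 11
DEFAULT_SPACING = (25, 70)


@dataclass(frozen=True, slots=True)
class PromoterHit:
    abox: Interval
    bbox: Interval
    spacing: int
    abox_mismatches: int
    bbox_mismatches: int
    strand: str

    def __post_init__(self) -> None:
        if len(self.abox) != BOX_LENGTH or len(self.bbox) != BOX_LENGTH:
            raise ValueError("promoter boxes must be 11 bp")


@dataclass(frozen=True, slots=True)
class AnchorHit:
    anchor: Interval  # 1-bp interval at the putative element 5' end
    source: str  # {"trnascan", "promoter_scan"}
    promoter: PromoterHit | None = None


def _pattern_mismatch_counts(seq_codes: np.ndarray, pattern: str) -> np.ndarray:
    """Per-start-position mismatch counts of ``pattern`` against the encoded
    sequence (uint8 ASCII codes).  Window N never matches."""
    L = len(pattern)
    n = len(seq_codes) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int32)
    mism = np.zeros(n, dtype=np.int32)
    for j, code in enumerate(pattern):
        allowed = np.zeros(256, dtype=bool)
        for base in IUPAC_CODES[code]:
            allowed[ord(base)] = True
        allowed[ord("N")] = False
        mism += ~allowed[seq_codes[j : j + n]]
    return mism


def _scan_strand(seq: str, max_mm: int, spacing: tuple[int, int]):
    """Yield (a_start, b_start, a_mm, b_mm) on the given sequence frame."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    a_mm = _pattern_mismatch_counts(codes, ABOX_PATTERN)
    b_mm = _pattern_mismatch_counts(codes, BBOX_PATTERN)
    a_pos = np.nonzero(a_mm <= max_mm)[0]
    b_pos = np.nonzero(b_mm <= max_mm)[0]
    lo, hi = spacing
    out = []
    if len(a_pos) and len(b_pos):
        starts = np.searchsorted(b_pos, a_pos + BOX_LENGTH + lo, side="left")
        ends = np.searchsorted(b_pos, a_pos + BOX_LENGTH + hi, side="right")
        for i, a in enumerate(a_pos):
            for b in b_pos[starts[i] : ends[i]]:
                out.append((int(a), int(b), int(a_mm[a]), int(b_mm[b])))
    return out


def scan_promoters(
    genome: list[GenomeSequence] | GenomeSequence,
    max_mismatch_per_box: int = 1,
    spacing_bounds: tuple[int, int] = DEFAULT_SPACING,
) -> list[PromoterHit]:
    """All A/B box pairs on both strands, sorted by coordinate.

    A pair qualifies when each box matches its degenerate consensus with at
    most ``max_mismatch_per_box`` substitutions and the gap between A-box end
    and B-box start lies within ``spacing_bounds`` (inclusive).
    """
    if isinstance(genome, GenomeSequence):
        genome = [genome]
    hits: list[PromoterHit] = []
    for contig in genome:
        n = contig.length
        for a, b, amm, bmm in _scan_strand(
            contig.seq, max_mismatch_per_box, spacing_bounds
        ):
            hits.append(
                PromoterHit(
                    abox=Interval(contig.id, a, a + BOX_LENGTH, "+"),
                    bbox=Interval(contig.id, b, b + BOX_LENGTH, "+"),
                    spacing=b - (a + BOX_LENGTH),
                    abox_mismatches=amm,
                    bbox_mismatches=bmm,
                    strand="+",
                )
            )
        from .seqcore_io import revcomp

        rc = revcomp(contig.seq)
        for a, b, amm, bmm in _scan_strand(rc, max_mismatch_per_box, spacing_bounds):
            # map rc coordinates back to forward frame
            a_iv = Interval(contig.id, n - (a + BOX_LENGTH), n - a, "-")
            b_iv = Interval(contig.id, n - (b + BOX_LENGTH), n - b, "-")
            hits.append(
                PromoterHit(
                    abox=a_iv, bbox=b_iv, spacing=b - (a + BOX_LENGTH),
                    abox_mismatches=amm, bbox_mismatches=bmm, strand="-",
                )
            )
    hits.sort(key=lambda h: (h.abox.contig, min(h.abox.start, h.bbox.start), h.strand))
    return hits


def anchors_from_promoters(
    hits: list[PromoterHit],
    contig_lengths: dict[str, int],
    tss_offset: int = DEFAULT_TSS_OFFSET,
    dedupe_window: int = 200,
) -> list[AnchorHit]:
    """Convert promoter hits to element-start anchors.

    The anchor is placed ``tss_offset`` bp upstream (in strand orientation) of
    the A box.  Overlapping hits within ``dedupe_window`` bp on the same
    strand are collapsed to the hit with the fewest total box mismatches
    (ties: 5'-most).
    """
    anchors: list[AnchorHit] = []
    for h in hits:
        if h.strand == "+":
            pos = h.abox.start - tss_offset
            if pos < 0:
                pos = 0
        else:
            pos = h.abox.end - 1 + tss_offset
            n = contig_lengths[h.abox.contig]
            if pos > n - 1:
                pos = n - 1
        anchors.append(
            AnchorHit(
                anchor=Interval(h.abox.contig, pos, pos + 1, h.strand),
                source="promoter_scan",
                promoter=h,
            )
        )
    # dedupe nearby anchors on the same strand
    anchors.sort(key=lambda a: (a.anchor.contig, a.anchor.strand, a.anchor.start))
    kept: list[AnchorHit] = []
    for a in anchors:
        if kept:
            p = kept[-1]
            if (
                p.anchor.contig == a.anchor.contig
                and p.anchor.strand == a.anchor.strand
                and abs(a.anchor.start - p.anchor.start) < dedupe_window
            ):
                pm = p.promoter.abox_mismatches + p.promoter.bbox_mismatches
                am = a.promoter.abox_mismatches + a.promoter.bbox_mismatches
                better = am < pm or (
                    am == pm
                    and (
                        (a.anchor.strand == "+" and a.anchor.start < p.anchor.start)
                        or (a.anchor.strand == "-" and a.anchor.start > p.anchor.start)
                    )
                )
                if better:
                    kept[-1] = a
                continue
        kept.append(a)
    kept.sort(key=lambda a: (a.anchor.contig, a.anchor.start, a.anchor.strand))
    return kept


def read_trnascan(path: str | Path) -> list[AnchorHit]:
    """Read tRNAscan-SE tabular output into anchors.

    Coordinates in the file are 1-based inclusive; rows with begin > end lie
    on the minus strand.  The anchor marks the tRNA's first base (its 5' end
    in strand orientation).
    """
    anchors: list[AnchorHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            low = stripped.lower()
            if low.startswith(("sequence", "name", "----")):
                continue  # the three-line tRNAscan-SE header
            fields = stripped.split()
            try:
                contig = fields[0]
                begin = int(fields[2])
                end = int(fields[3])
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"unparsable tRNAscan row at line {lineno}: {stripped!r}"
                ) from exc
            if begin <= end:
                pos = begin - 1
                strand = "+"
            else:
                pos = begin - 1  # first base of the tRNA on the minus strand
                strand = "-"
            anchors.append(
                AnchorHit(
                    anchor=Interval(contig, pos, pos + 1, strand),
                    source="trnascan",
                )
            )
    return anchors


def measure_tss_offset(element_seq: str, promoter: PromoterHit) -> int:
    """Distance in bp from the element 5' end to the A-box start.

    ``promoter`` must carry A-box coordinates in the element's own frame
    (plus strand, element start == position 0).
    """
    offset = promoter.abox.start
    if promoter.abox.end > len(element_seq) or offset < 0:
        raise ValueError("A box does not lie within the element")
    return offset
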