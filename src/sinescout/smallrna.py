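"""piRNA arm: 26-31 nt length filtering, tRNA-region masking of the copy
database, zero-mismatch strand-aware exact mapping, per-gene intron counting,
and a simplified density-based cluster caller.

"Zero mismatches" is implemented as exact substring search (per-length hash
lookup over sliding windows), not a rerun of an external aligner; multireads
are counted at every locus.  Counting weight is read multiplicity.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .discovery import SineModel
from .seqcore_io import GenomeSequence, Interval, align_glocal, revcomp

log = logging.getLogger(__name__)

__all__ = [
    "SmallRead",
    "GeneModel",
    "CountRecord",
    "MapHit",
    "read_small_reads",
    "filter_lengths",
    "mask_trna",
    "build_copy_db",
    "map_exact",
    "count_by_gene",
    "call_clusters",
    "select_sine_related",
    "read_genes_gff3",
    "write_genes_gff3",
    "write_count_table",
]

_ACGTN = frozenset("ACGTN")


@dataclass(frozen=True, slots=True)
class SmallRead:
    seq: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass(frozen=True, slots=True)
class GeneModel:
    gene_id: str
    full_name: str
    span: Interval
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        prev_end = self.span.start
        for ex in self.exons:
            if ex.start < prev_end or ex.end > self.span.end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted, disjoint, in span"
                )
            prev_end = ex.end

    @property
    def introns(self) -> tuple[Interval, ...]:
        out = []
        prev = None
        for ex in self.exons:
            if prev is not None and ex.start > prev:
                out.append(Interval(self.span.contig, prev, ex.start, self.strand))
            prev = ex.end
        return tuple(out)


@dataclass(frozen=True, slots=True)
class CountRecord:
    feature_id: str
    forward: int
    reverse: int

    @property
    def total(self) -> int:
        return self.forward + self.reverse


@dataclass(frozen=True, slots=True)
class MapHit:
    read: SmallRead
    target_id: str
    offset: int
    orientation: str  # {F, R}


# ---------------------------------------------------------------------------
# Read ingestion and filtering

def read_small_reads(path: str | Path) -> list[str]:
    """Raw read sequences from FASTA or FASTQ (format sniffed from the first
    character; quality values are ignored)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]


def filter_lengths(
    reads: list[str], lo: int = 26, hi: int = 31
) -> tuple[list[SmallRead], int]:
    """Length-filter and collapse identical sequences into multiplicities.

    Returns (collapsed reads, count of dropped non-ACGTN reads)."""
    counts: Counter[str] = Counter()
    dropped_bad = 0
    for seq in reads:
        if not (lo <= len(seq) <= hi):
            continue
        if set(seq) - _ACGTN:
            dropped_bad += 1
            continue
        counts[seq] += 1
    collapsed = [
        SmallRead(seq=s, multiplicity=m) for s, m in sorted(counts.items())
    ]
    return collapsed, dropped_bad


# ---------------------------------------------------------------------------
# Copy database with tRNA-head masking

def mask_trna(model: SineModel, copy_seq: str | None = None) -> str:
    """Element sequence with the tRNA-like head removed.

    For the consensus itself this is ``consensus[head_end:]``.  For a genomic
    copy, the head region is located by projecting ``head_end`` through the
    copy's alignment to the consensus rather than by fixed offset."""
    if model.head_end >= model.length:
        raise ValueError("head_end at or beyond consensus length")
    if copy_seq is None:
        return model.consensus[model.head_end :]
    if model.head_end == 0:
        return copy_seq
    res = align_glocal(model.consensus, copy_seq)
    # map consensus head_end onto the copy through the aligned spans
    q0, q1 = res.query_span
    t0, t1 = res.target_span
    if model.head_end <= q0:
        cut = t0
    elif model.head_end >= q1:
        cut = t1
    else:
        # proportional projection is exact for substitution-only divergence
        cut = t0 + round((model.head_end - q0) * (t1 - t0) / (q1 - q0))
    return copy_seq[cut:]


def build_copy_db(
    models: list[SineModel],
    copies80: dict[str, list],
    genome: list[GenomeSequence],
    min_body_length: int = 26,
) -> list[tuple[str, str]]:
    """One tRNA-masked sequence per >=80%-identity genomic copy.

    ``copies80`` maps family name -> GenomicCopy list.  Copies reduced below
    ``min_body_length`` bp by masking are excluded (logged)."""
    contigs = {c.id: c for c in genome}
    by_model = {m.name: m for m in models}
    db: list[tuple[str, str]] = []
    seen: set[str] = set()
    excluded = 0
    for family in sorted(copies80):
        model = by_model[family]
        for copy in copies80[family]:
            loc = copy.locus
            seq = contigs[loc.contig].seq[loc.start : loc.end]
            if copy.strand == "-":
                seq = revcomp(seq)
            masked = mask_trna(model, seq)
            if len(masked) < min_body_length:
                excluded += 1
                continue
            cid = f"{family}:{loc.contig}:{loc.start}-{loc.end}({copy.strand})"
            if cid in seen:
                continue
            seen.add(cid)
            db.append((cid, masked))
    if excluded:
        log.info("build_copy_db: %d head-only copies excluded", excluded)
    return db


# ---------------------------------------------------------------------------
# Exact mapping and counting

def map_exact(
    reads: list[SmallRead], targets: list[tuple[str, str]]
) -> list[MapHit]:
    """Every zero-mismatch occurrence of each read (or its reverse
    complement) as a substring of any target; all offsets reported."""
    by_len: dict[int, dict[str, list[tuple[SmallRead, str]]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for r in reads:
        by_len[len(r.seq)][r.seq].append((r, "F"))
        by_len[len(r.seq)][revcomp(r.seq)].append((r, "R"))
    hits: list[MapHit] = []
    for tid, tseq in targets:
        for length, lookup in by_len.items():
            for off in range(0, len(tseq) - length + 1):
                window = tseq[off : off + length]
                for read, orient in lookup.get(window, ()):
                    hits.append(MapHit(read, tid, off, orient))
    return hits


def count_by_gene(
    hits: list[MapHit], genes: list[GeneModel]
) -> tuple[list[CountRecord], dict[str, int]]:
    """Per-gene multiplicity-weighted counts split by orientation.

    Hit targets are gene spans (forward-strand genomic sequence); offsets are
    span-relative.  Hits overlapping any exon are excluded from the records
    and returned as a per-gene violation diagnostic (expected empty: intact
    small-RNA targets are intronic).  Records sort by total descending."""
    by_gene = {g.gene_id: g for g in genes}
    fwd: Counter[str] = Counter()
    rev: Counter[str] = Counter()
    violations: Counter[str] = Counter()
    for h in hits:
        gene = by_gene.get(h.target_id)
        if gene is None:
            continue
        g0 = gene.span.start + h.offset
        g1 = g0 + len(h.read.seq)
        if any(g0 < ex.end and ex.start < g1 for ex in gene.exons):
            violations[gene.gene_id] += h.read.multiplicity
            continue
        if h.orientation == "F":
            fwd[gene.gene_id] += h.read.multiplicity
        else:
            rev[gene.gene_id] += h.read.multiplicity
    records = [
        CountRecord(feature_id=g, forward=fwd[g], reverse=rev[g])
        for g in set(fwd) | set(rev)
    ]
    records.sort(key=lambda r: (-r.total, r.feature_id))
    return records, dict(violations)


def call_clusters(
    hits_on_genome: list[MapHit],
    window: int = 5000,
    min_unique: int = 5,
    min_density: float = 0.0,
) -> list[Interval]:
    """Simplified density-based cluster caller (a stand-in for a dedicated
    piRNA cluster predictor, whose BED output may be ingested instead).

    Windows of ``window`` bp anchored at each hit qualify when they contain
    at least ``min_unique`` distinct read sequences and at least
    ``min_density`` reads/bp (multiplicity-weighted); qualifying windows
    closer than ``window`` merge."""
    per_contig: dict[str, list[MapHit]] = defaultdict(list)
    for h in hits_on_genome:
        per_contig[h.target_id].append(h)
    clusters: list[Interval] = []
    for contig in sorted(per_contig):
        hs = sorted(per_contig[contig], key=lambda h: h.offset)
        positions = [h.offset for h in hs]
        qualifying: list[tuple[int, int]] = []
        import bisect

        for i, p in enumerate(positions):
            j = bisect.bisect_right(positions, p + window)
            in_win = hs[i:j]
            uniq = {h.read.seq for h in in_win}
            weight = sum(h.read.multiplicity for h in in_win)
            if len(uniq) >= min_unique and weight / window >= min_density:
                qualifying.append((p, min(p + window, max(
                    h.offset + len(h.read.seq) for h in in_win))))
        merged: list[list[int]] = []
        for s, e in qualifying:
            if merged and s - merged[-1][1] < window:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        clusters.extend(Interval(contig, s, e, "+") for s, e in merged)
    return clusters


def select_sine_related(
    cluster_reads: list[SmallRead], copy_db: list[tuple[str, str]]
) -> list[SmallRead]:
    """Sub-pool of cluster reads with at least one zero-mismatch hit in the
    tRNA-masked copy database, retaining full multiplicities."""
    hits = map_exact(cluster_reads, copy_db)
    hit_seqs = {h.read.seq for h in hits}
    return [r for r in cluster_reads if r.seq in hit_seqs]


# ---------------------------------------------------------------------------
# GFF3 gene models and the tabular count report

def write_genes_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("# coordinates 1-based inclusive\n")
        for g in genes:
            s1, e1 = g.span.as_1based()
            fh.write(
                "\t".join(
                    [
                        g.span.contig, "sinescout", "gene", str(s1), str(e1),
                        ".", g.strand, ".",
                        f"ID={g.gene_id};Name={g.gene_id};description={g.full_name}",
                    ]
                )
                + "\n"
            )
            for i, ex in enumerate(g.exons, start=1):
                xs, xe = ex.as_1based()
                fh.write(
                    "\t".join(
                        [
                            ex.contig, "sinescout", "exon", str(xs), str(xe),
                            ".", g.strand, ".",
                            f"ID={g.gene_id}.exon{i};Parent={g.gene_id}",
                        ]
                    )
                    + "\n"
                )


def _parse_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    """Genes with exon children from a GFF3 file (1-based inclusive)."""
    genes_raw: dict[str, dict] = {}
    exons_raw: dict[str, list[Interval]] = defaultdict(list)
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = f[:9]
            a = _parse_attrs(attrs)
            iv = Interval(contig, int(start) - 1, int(end), strand if strand in "+-" else "+")
            if ftype == "gene":
                gid = a.get("ID") or a.get("Name")
                if not gid:
                    raise ValueError(f"gene without ID: {line!r}")
                genes_raw[gid] = {
                    "span": iv,
                    "strand": iv.strand,
                    "name": a.get("description", a.get("Name", gid)),
                }
                order.append(gid)
            elif ftype == "exon":
                parent = a.get("Parent")
                if parent:
                    exons_raw[parent].append(iv)
    genes = []
    for gid in order:
        info = genes_raw[gid]
        exons = tuple(sorted(exons_raw.get(gid, []), key=lambda e: e.start))
        genes.append(
            GeneModel(
                gene_id=gid, full_name=info["name"], span=info["span"],
                strand=info["strand"], exons=exons,
            )
        )
    return genes


def write_count_table(
    records: list[CountRecord], genes: list[GeneModel], path: str | Path
) -> None:
    """Tabular report: Contig ID, Strand, Start, End, Gene ID, Gene full
    name, Reads count, F, R.  Coordinates 1-based inclusive."""
    by_gene = {g.gene_id: g for g in genes}
    with open(path, "w") as fh:
        fh.write("# coordinates 1-based inclusive\n")
        fh.write(
            "Contig ID\tStrand\tStart\tEnd\tGene ID\tGene full name\t"
            "Reads count\tF\tR\n"
        )
        for r in records:
            g = by_gene.get(r.feature_id)
            if g is None:
                continue
            s1, e1 = g.span.as_1based()
            strand = "F" if g.strand == "+" else "R"
            fh.write(
                f"{g.span.contig}\t{strand}\t{s1}\t{e1}\t{g.gene_id}\t"
                f"{g.full_name}\t{r.total}\t{r.forward}\t{r.reverse}\n"
            )
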