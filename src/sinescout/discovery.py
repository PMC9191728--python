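"""Core discovery algorithm: anchored 1000-nt windows, similarity clustering,
boundary calling, and family consensus construction.

Windows start a small pad upstream of each anchor so that boundary calling
can capture the true element 5' end (the transcription start lies upstream of
the A box, which itself is internal to the tRNA-like head).  Clusters are
single-linkage components over pairwise local alignments passing identity,
overlap and anchor-shift thresholds.  Element boundaries are called from a
smoothed column-conservation profile of a star alignment and, when possible,
refined by direct-repeat (target-site-duplication) votes from individual
members, which pins the element ends to single-base precision.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from ._kmers import kmer_set
from ._repeats import direct_repeat_junctions, find_direct_repeat
from .promoter import AnchorHit, PromoterHit, measure_tss_offset, scan_promoters
from .seqcore_io import (
    AlignmentResult,
    GenomeSequence,
    Interval,
    align_local,
    revcomp,
)

log = logging.getLogger(__name__)

__all__ = [
    "AnchorWindow",
    "CandidateCluster",
    "SineModel",
    "BoundaryCall",
    "ClusterRejected",
    "DiscoveryConfig",
    "extract_windows",
    "cluster_windows",
    "call_boundary",
    "build_consensus",
    "dedupe_overlapping_clusters",
    "discover",
]


class ClusterRejected(Exception):
    """A candidate cluster failed a structural criterion."""


@dataclass(frozen=True)
class DiscoveryConfig:
    window_length: int = 1000
    upstream_pad: int = 30
    min_identity: float = 0.90
    min_overlap: int = 150
    min_members: int = 3
    max_anchor_shift: int = 5
    boundary_conservation: float = 0.70
    boundary_window: int = 20
    min_element_length: int = 150
    prefilter_k: int = 12
    prefilter_min_shared: int = 8
    tsd_refine_jitter: int = 15
    head_tail_pad: int = 12  # bp of tRNA-like head retained past the B box
    promoter_max_mismatch: int = 1
    name_prefix: str = "fam"


@dataclass(frozen=True, slots=True)
class AnchorWindow:
    anchor: AnchorHit
    window: Interval
    seq: str
    anchor_offset: int  # position of the anchor base within seq
    truncated: bool = False

    def sort_key(self):
        return (self.window.contig, self.window.start, self.window.strand)


@dataclass
class CandidateCluster:
    members: list[AnchorWindow]
    pairwise_identities: dict[tuple[int, int], float] = field(default_factory=dict)
    anchor_shift_max: int = 0
    overlap_min: int = 0

    def __len__(self) -> int:
        return len(self.members)

    @property
    def mean_identity(self) -> float:
        vals = list(self.pairwise_identities.values())
        return float(np.mean(vals)) if vals else 0.0


@dataclass
class SineModel:
    name: str
    consensus: str
    promoter: PromoterHit
    tss_offset: int
    head_end: int
    tail: object | None = None  # TailAnnotation, filled by annotate
    n_members: int = 0
    flags: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True, slots=True)
class BoundaryCall:
    start: int  # element start, center-sequence coordinates
    end: int  # element end (exclusive)
    tsd_refined: bool
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Window extraction

def extract_windows(
    genome: list[GenomeSequence],
    anchors: list[AnchorHit],
    window_length: int = 1000,
    upstream_pad: int = 30,
) -> list[AnchorWindow]:
    """One strand-aware window per anchor, starting ``upstream_pad`` bp
    upstream of the anchor and extending ``window_length`` bp downstream.
    Minus-strand windows are reverse-complemented so the anchor sits near the
    window 5' end.  Windows are truncated (and flagged) at contig edges."""
    contigs = {c.id: c for c in genome}
    out: list[AnchorWindow] = []
    for a in anchors:
        contig = contigs[a.anchor.contig]
        n = contig.length
        pos = a.anchor.start
        if a.anchor.strand == "+":
            lo = max(0, pos - upstream_pad)
            hi = min(n, pos + window_length)
            seq = contig.seq[lo:hi]
            offset = pos - lo
            truncated = lo > pos - upstream_pad or hi < pos + window_length
        else:
            lo = max(0, pos + 1 - window_length)
            hi = min(n, pos + 1 + upstream_pad)
            seq = revcomp(contig.seq[lo:hi])
            offset = hi - 1 - pos
            truncated = hi < pos + 1 + upstream_pad or lo > pos + 1 - window_length
        out.append(
            AnchorWindow(
                anchor=a,
                window=Interval(contig.id, lo, hi, a.anchor.strand),
                seq=seq,
                anchor_offset=offset,
                truncated=truncated,
            )
        )
    out.sort(key=AnchorWindow.sort_key)
    return out


# ---------------------------------------------------------------------------
# Clustering

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _project_query_to_target(res: AlignmentResult, segments, qpos: int) -> int:
    """Map a query coordinate through diagonal alignment segments onto the
    target, extrapolating linearly outside the aligned span."""
    for t0, t1, q0, q1 in segments:
        if q0 <= qpos < q1:
            return t0 + (qpos - q0)
    # extrapolate from the nearest segment edge
    first = segments[0]
    last = segments[-1]
    if qpos < first[2]:
        return first[0] - (first[2] - qpos)
    return last[1] + (qpos - last[3])


def _diag_segments(a: str, b: str):
    """Diagonal segments of the optimal local alignment of a (query) in b
    (target), as (t0, t1, q0, q1) tuples, plus the AlignmentResult."""
    from .seqcore_io import _get_aligner, _result_from_alignment, _sanitize, DEFAULT_SCORING

    q, t = _sanitize(a), _sanitize(b)
    aligner = _get_aligner(DEFAULT_SCORING, "local")
    alns = aligner.align(t, q)
    if len(alns) == 0 or alns.score <= 0:
        return None, AlignmentResult(0.0, 0, 0, 0.0, (0, 0), (0, 0))
    aln = alns[0]
    res = _result_from_alignment(aln, q, t)
    coords = aln.coordinates
    segs = []
    for k in range(coords.shape[1] - 1):
        t0, t1 = int(coords[0, k]), int(coords[0, k + 1])
        q0, q1 = int(coords[1, k]), int(coords[1, k + 1])
        if t1 > t0 and q1 > q0:
            segs.append((t0, t1, q0, q1))
    return segs, res


def cluster_windows(
    windows: list[AnchorWindow],
    min_identity: float = 0.90,
    min_overlap: int = 150,
    min_members: int = 3,
    max_anchor_shift: int = 5,
    prefilter_k: int = 12,
    prefilter_min_shared: int = 8,
) -> list[CandidateCluster]:
    """Single-linkage clusters over the pairwise-similarity graph.

    An edge joins two windows when their optimal local alignment reaches
    ``min_identity`` over at least ``min_overlap`` columns and the anchor
    offset implied by the alignment is at most ``max_anchor_shift`` bp.
    Pairs sharing fewer than ``prefilter_min_shared`` k-mers are skipped, as
    are pairs already connected (single linkage is insensitive to redundant
    edges), which keeps the number of alignments near-linear per family.
    """
    windows = sorted(windows, key=AnchorWindow.sort_key)
    n = len(windows)
    uf = _UnionFind(n)
    ksets = [kmer_set(w.seq, prefilter_k) for w in windows]
    edges: dict[tuple[int, int], float] = {}
    shifts: dict[tuple[int, int], int] = {}
    overlaps: dict[tuple[int, int], int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if len(ksets[i] & ksets[j]) < prefilter_min_shared:
                continue
            if uf.find(i) == uf.find(j):
                continue
            segs, res = _diag_segments(windows[i].seq, windows[j].seq)
            if segs is None:
                continue
            if res.identity < min_identity or res.aligned_length < min_overlap:
                continue
            implied = _project_query_to_target(res, segs, windows[i].anchor_offset)
            shift = abs(implied - windows[j].anchor_offset)
            if shift > max_anchor_shift:
                continue
            uf.union(i, j)
            edges[(i, j)] = res.identity
            shifts[(i, j)] = shift
            overlaps[(i, j)] = res.aligned_length
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    clusters: list[CandidateCluster] = []
    for root in sorted(groups, key=lambda r: windows[groups[r][0]].sort_key()):
        idx = groups[root]
        if len(idx) < min_members:
            continue
        remap = {g: k for k, g in enumerate(idx)}
        pid = {
            (remap[i], remap[j]): v
            for (i, j), v in edges.items()
            if i in remap and j in remap
        }
        cl_shifts = [shifts[(i, j)] for (i, j) in shifts if i in remap and j in remap]
        cl_olap = [overlaps[(i, j)] for (i, j) in overlaps if i in remap and j in remap]
        clusters.append(
            CandidateCluster(
                members=[windows[g] for g in idx],
                pairwise_identities=pid,
                anchor_shift_max=max(cl_shifts) if cl_shifts else 0,
                overlap_min=min(cl_olap) if cl_olap else 0,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# Star alignment, boundary calling, consensus

_BASE_ORDER = "ACGT"  # fixed tie-break order


@dataclass
class StarAlignment:
    center_index: int
    rows: np.ndarray  # (n_members, len(center.seq)) uint8 ASCII, 0 = absent
    member_segments: list  # per member: diagonal segments onto center, or None


def star_align(cluster: CandidateCluster) -> StarAlignment:
    """Align every member to the member with the highest summed edge
    identity (the star center) and project bases onto center columns."""
    n = len(cluster.members)
    sums = [0.0] * n
    for (i, j), v in cluster.pairwise_identities.items():
        sums[i] += v
        sums[j] += v
    center = int(np.argmax(sums))
    cseq = cluster.members[center].seq
    rows = np.zeros((n, len(cseq)), dtype=np.uint8)
    rows[center] = np.frombuffer(cseq.encode("ascii"), dtype=np.uint8)
    member_segments: list = [None] * n
    member_segments[center] = [(0, len(cseq), 0, len(cseq))]
    for m in range(n):
        if m == center:
            continue
        segs, _res = _diag_segments(cluster.members[m].seq, cseq)
        if segs is None:
            continue
        member_segments[m] = segs
        mseq = cluster.members[m].seq
        for t0, t1, q0, q1 in segs:
            rows[m, t0:t1] = np.frombuffer(
                mseq[q0:q1].encode("ascii"), dtype=np.uint8
            )
    return StarAlignment(center_index=center, rows=rows,
                         member_segments=member_segments)


def _conservation_profile(rows: np.ndarray) -> np.ndarray:
    """Per-column modal-base fraction; absent/ambiguous positions count
    against the mode (denominator = number of members)."""
    n = rows.shape[0]
    counts = np.zeros((4, rows.shape[1]), dtype=np.int32)
    for k, base in enumerate(_BASE_ORDER):
        counts[k] = (rows == ord(base)).sum(axis=0)
    return counts.max(axis=0) / n


def _runs_above(profile: np.ndarray, threshold: float):
    above = profile >= threshold
    runs = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(above)))
    return runs


def call_boundary(
    cluster: CandidateCluster,
    conservation: float = 0.70,
    smooth_window: int = 20,
    min_element_length: int = 150,
    tsd_refine_jitter: int = 15,
    star: StarAlignment | None = None,
) -> BoundaryCall:
    """Call element boundaries on the star-alignment center.

    The initial call is the conservation run (smoothed modal-base fraction
    over ``smooth_window`` columns) containing the anchor column.  When at
    least two members carry a mismatch-free 10-15 bp direct repeat flanking
    the candidate element consistently, the modal repeat-delimited span
    refines the call exactly.  Raises :class:`ClusterRejected` when no
    qualifying run exists or the element would be shorter than
    ``min_element_length``.
    """
    if star is None:
        star = star_align(cluster)
    center = cluster.members[star.center_index]
    profile = _conservation_profile(star.rows)
    kernel = np.ones(smooth_window)
    weight = np.convolve(np.ones_like(profile), kernel, mode="same")
    smoothed = np.convolve(profile, kernel, mode="same") / weight
    runs = _runs_above(smoothed, conservation)
    anchor_col = center.anchor_offset
    probe = min(anchor_col + 5, len(profile) - 1)
    chosen = None
    for s, e in runs:
        if s <= probe < e:
            chosen = (s, e)
            break
    if chosen is None:
        # fall back to any run overlapping the anchor neighbourhood
        for s, e in runs:
            if s <= anchor_col + tsd_refine_jitter and e > anchor_col:
                chosen = (s, e)
                break
    if chosen is None:
        raise ClusterRejected("conservation never reaches threshold at anchor")
    start, end = chosen
    flags: list[str] = []
    if end >= len(profile):
        flags.append("no divergence observed - possible segmental duplication")
    # TSD refinement: vote across members over all candidate direct-repeat
    # junctions, in coordinates relative to each member's own anchor (no
    # alignment projection: gapped alignments wobble inside periodic tails).
    # The true insertion junction is delimited by a duplicated target site in
    # *every* member, while chance repeat extensions shift junctions in
    # member-specific ways, so a cross-member majority pins the element ends
    # exactly.
    anchor_col = cluster.members[star.center_index].anchor_offset
    rel0_s = start - anchor_col
    rel0_e = end - anchor_col
    votes: Counter[tuple[int, int]] = Counter()
    for m, segs in enumerate(star.member_segments):
        if segs is None:
            continue
        mem = cluster.members[m]
        aoff = mem.anchor_offset
        ms = max(0, min(aoff + rel0_s, len(mem.seq)))
        me = max(0, min(aoff + rel0_e, len(mem.seq)))
        if me - ms < min_element_length:
            continue
        for left_end, right_start in direct_repeat_junctions(
            mem.seq, ms, me, max_offset=tsd_refine_jitter
        ):
            votes[(left_end - aoff, right_start - aoff)] += 1
    refined = False
    if votes:
        # the duplicated target site trivially contains shifted sub-repeats
        # (drop m bases from the left copy, k from the right: same site
        # substring), which tie the true junction's vote count whenever the
        # site is long enough; the true junction is the innermost one
        top = max(votes.values())
        rel_s, rel_e = max(
            (j for j, v in votes.items() if v == top),
            key=lambda j: (j[0], -j[1]),
        )
        cs = anchor_col + rel_s
        ce = anchor_col + rel_e
        if (
            top >= 2
            and abs(cs - start) <= tsd_refine_jitter
            and abs(ce - end) <= tsd_refine_jitter
        ):
            start, end = cs, ce
            refined = True
    start = max(0, start)
    end = min(end, len(profile))
    if end - start < min_element_length:
        raise ClusterRejected(
            f"element length {end - start} below minimum {min_element_length}"
        )
    return BoundaryCall(start=start, end=end, tsd_refined=refined,
                        flags=tuple(flags))


def _project_member_to_center(segs, qpos: int) -> int:
    for t0, t1, q0, q1 in segs:
        if q0 <= qpos < q1:
            return t0 + (qpos - q0)
    first, last = segs[0], segs[-1]
    if qpos < first[2]:
        return first[0] - (first[2] - qpos)
    return last[1] + (qpos - last[3])


def _project_query_to_target_inverse(segs, tpos: int) -> int:
    """Map a center (target) coordinate back onto the member (query)."""
    for t0, t1, q0, q1 in segs:
        if t0 <= tpos < t1:
            return q0 + (tpos - t0)
    first, last = segs[0], segs[-1]
    if tpos < first[0]:
        return first[2] - (first[0] - tpos)
    return last[3] + (tpos - last[1])


def build_consensus(
    cluster: CandidateCluster,
    boundary: BoundaryCall,
    name: str = "fam1",
    head_tail_pad: int = 12,
    promoter_max_mismatch: int = 1,
    star: StarAlignment | None = None,
) -> SineModel:
    """Column-wise majority consensus over the star alignment between the
    called boundaries.  A column is emitted iff fewer than half the members
    *spanning* it are gapped there (members whose alignment does not reach a
    column cast no vote); base ties break in fixed order A<C<G<T.  The
    promoter is re-detected on the consensus -- among candidate hits the one
    nearest the A-box position implied by the cluster anchor wins -- and the
    TSS-to-A-box offset is recorded."""
    if star is None:
        star = star_align(cluster)
    ncols = boundary.end - boundary.start
    rows = star.rows[:, boundary.start : boundary.end]
    spanning = np.zeros(ncols, dtype=np.int32)
    for segs in star.member_segments:
        if segs is None:
            continue
        lo = max(segs[0][0] - boundary.start, 0)
        hi = min(segs[-1][1] - boundary.start, ncols)
        if hi > lo:
            spanning[lo:hi] += 1
    counts = np.zeros((4, ncols), dtype=np.int32)
    for k, base in enumerate(_BASE_ORDER):
        counts[k] = (rows == ord(base)).sum(axis=0)
    present = counts.sum(axis=0)
    with np.errstate(invalid="ignore"):
        gap_frac = np.where(spanning > 0, 1.0 - present / np.maximum(spanning, 1), 1.0)
    emit = gap_frac < 0.5
    best = counts.argmax(axis=0)  # argmax ties resolve to lowest index: A<C<G<T
    consensus = "".join(
        _BASE_ORDER[best[c]] for c in range(ncols) if emit[c]
    )
    if len(consensus) < 150:
        raise ClusterRejected("consensus shorter than 150 bp after emission")
    cons_rec = GenomeSequence(id=name, seq=consensus)
    hits = [
        h
        for h in scan_promoters(cons_rec, max_mismatch_per_box=promoter_max_mismatch)
        if h.strand == "+"
    ]
    if not hits:
        raise ClusterRejected("no promoter detected on consensus")
    # A-box position implied by the anchor that seeded the cluster
    anchor_col = cluster.members[star.center_index].anchor_offset
    if anchor_col >= boundary.start:
        anchor_pos = int(emit[: anchor_col - boundary.start].sum())
    else:
        anchor_pos = anchor_col - boundary.start
    from .promoter import DEFAULT_TSS_OFFSET

    expected_abox = anchor_pos + DEFAULT_TSS_OFFSET
    hits.sort(
        key=lambda h: (
            abs(h.abox.start - expected_abox),
            h.abox_mismatches + h.bbox_mismatches,
            h.abox.start,
        )
    )
    promoter = hits[0]
    tss_offset = measure_tss_offset(consensus, promoter)
    head_end = min(promoter.bbox.end + head_tail_pad, len(consensus))
    return SineModel(
        name=name,
        consensus=consensus,
        promoter=promoter,
        tss_offset=tss_offset,
        head_end=head_end,
        n_members=len(cluster.members),
        flags=boundary.flags,
    )


# ---------------------------------------------------------------------------
# Cluster-level dedup + end-to-end driver

def dedupe_overlapping_clusters(
    clusters: list[CandidateCluster],
) -> list[CandidateCluster]:
    """Suppress clusters whose member windows substantially re-cover the
    genomic loci of a better (larger, then higher-identity) cluster.  Guards
    against duplicate anchors inside the same element family spawning a
    shifted twin cluster."""
    ranked = sorted(
        range(len(clusters)),
        key=lambda i: (-len(clusters[i]), -clusters[i].mean_identity, i),
    )
    kept: list[CandidateCluster] = []
    for i in ranked:
        cand = clusters[i]
        dup_members = 0
        for m in cand.members:
            hit = any(
                m.window.contig == km.window.contig
                and _overlap_len(m.window, km.window) >= 0.5 * len(m.window)
                for kc in kept
                for km in kc.members
            )
            if hit:
                dup_members += 1
        if dup_members >= 0.5 * len(cand.members):
            continue
        kept.append(cand)
    kept.sort(key=lambda c: c.members[0].sort_key())
    return kept


def _overlap_len(a: Interval, b: Interval) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def dedupe_models(
    models: list[SineModel],
    min_identity: float = 0.80,
    min_self_coverage: float = 0.60,
) -> list[SineModel]:
    """Drop models whose consensus redundantly re-describes a better model.

    Secondary promoter-like matches inside an element (on either strand)
    can seed a shifted or reverse-complement twin cluster of the same
    family.  A candidate is suppressed when >= ``min_self_coverage`` of its
    own consensus aligns at >= ``min_identity`` to a kept model's consensus
    in either orientation.  Genuine head-to-tail composites survive: each
    parent covers well under the threshold of the composite's length."""
    ranked = sorted(models, key=lambda m: (-m.n_members, m.name))
    kept: list[SineModel] = []
    for cand in ranked:
        redundant = False
        for k in kept:
            for target in (k.consensus, revcomp(k.consensus)):
                r = align_local(cand.consensus, target)
                if (
                    r.identity >= min_identity
                    and r.aligned_length >= min_self_coverage * cand.length
                ):
                    redundant = True
                    break
            if redundant:
                break
        if not redundant:
            kept.append(cand)
    return kept


def discover(
    genome: list[GenomeSequence],
    anchors: list[AnchorHit] | None = None,
    config: DiscoveryConfig = DiscoveryConfig(),
) -> tuple[list[SineModel], list[CandidateCluster], list[str]]:
    """Anchors -> windows -> clusters -> boundaries -> consensus models."""
    from .promoter import anchors_from_promoters

    if anchors is None:
        hits = scan_promoters(genome, max_mismatch_per_box=config.promoter_max_mismatch)
        anchors = anchors_from_promoters(hits, {c.id: c.length for c in genome})
    log.info("discover: %d anchors", len(anchors))
    windows = extract_windows(
        genome, anchors, config.window_length, config.upstream_pad
    )
    log.info("discover: %d windows", len(windows))
    clusters = cluster_windows(
        windows,
        min_identity=config.min_identity,
        min_overlap=config.min_overlap,
        min_members=config.min_members,
        max_anchor_shift=config.max_anchor_shift,
        prefilter_k=config.prefilter_k,
        prefilter_min_shared=config.prefilter_min_shared,
    )
    clusters = dedupe_overlapping_clusters(clusters)
    log.info("discover: %d candidate clusters", len(clusters))
    models: list[SineModel] = []
    rejects: list[str] = []
    for i, cl in enumerate(clusters):
        star = star_align(cl)
        try:
            boundary = call_boundary(
                cl,
                conservation=config.boundary_conservation,
                smooth_window=config.boundary_window,
                min_element_length=config.min_element_length,
                tsd_refine_jitter=config.tsd_refine_jitter,
                star=star,
            )
            model = build_consensus(
                cl,
                boundary,
                name=f"cluster{i}",
                head_tail_pad=config.head_tail_pad,
                promoter_max_mismatch=config.promoter_max_mismatch,
                star=star,
            )
        except ClusterRejected as exc:
            rejects.append(str(exc))
            continue
        models.append(model)
    models = dedupe_models(models)
    models.sort(key=lambda m: (-m.n_members, m.name))
    for i, m in enumerate(models, start=1):
        m.name = f"{config.name_prefix}{i}"
        m.promoter = replace(
            m.promoter,
            abox=replace(m.promoter.abox, contig=m.name),
            bbox=replace(m.promoter.bbox, contig=m.name),
        )
    log.info("discover: %d families, %d rejected clusters", len(models), len(rejects))
    return models, clusters, rejects
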