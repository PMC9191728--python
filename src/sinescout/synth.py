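"""Synthetic-data generator: a genome with planted tRNA-head element
families, multi-exon gene models, and 26-31 nt small-RNA reads, all with a
ground-truth manifest.

Each family master is built as: an 11-bp 5' pad, an exact A box, a 30-60 bp
spacer, an exact B box, a short head remainder, a random body, and a tandem
tail (unit repeated >=4x).  Copies are mutated per-copy (substitution-only by
default so identity thresholds map cleanly onto planted divergence) and
inserted with duplicated 10-15 bp target sites; a configurable subset lands
in introns of synthetic 4-exon genes.  Reads are sampled from copy bodies
(never heads) in both orientations, alongside random background reads and
tRNA-fragment decoys sampled from head regions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .promoter import ABOX_PATTERN, BBOX_PATTERN, DEFAULT_TSS_OFFSET
from .seqcore_io import GenomeSequence, IUPAC_CODES, Interval, revcomp
from .smallrna import GeneModel

__all__ = [
    "FamilySpec",
    "SimConfig",
    "PlantedFamily",
    "PlantedCopy",
    "PlantedRead",
    "TruthManifest",
    "SimCapacityError",
    "simulate_genome",
    "simulate_reads",
    "write_manifest",
    "read_manifest",
]

_BASES = "ACGT"


class SimCapacityError(ValueError):
    """The genome is too small for the requested plants."""


@dataclass(frozen=True)
class FamilySpec:
    name: str
    copy_count: int
    body_length: int = 200
    tail_unit: str = "TTAG"
    tail_copies: int = 5
    max_divergence: float = 0.05
    n_intronic: int = 0
    divergences: tuple[float, ...] | None = None  # explicit per-copy override

    def __post_init__(self) -> None:
        if self.tail_copies < 4:
            raise ValueError("tail unit must repeat at least 4 times")
        if not (0.0 <= self.max_divergence <= 0.35):
            raise ValueError("divergence outside [0, 0.35]")
        if self.divergences is not None:
            if len(self.divergences) != self.copy_count:
                raise ValueError("divergences length != copy_count")
            if any(not (0.0 <= d <= 0.35) for d in self.divergences):
                raise ValueError("divergence outside [0, 0.35]")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 1
    genome_length: int = 300_000
    contig_name: str = "synth1"
    families: tuple[FamilySpec, ...] = ()
    n_genes: int = 0
    exon_length: int = 200
    intron_length: int = 1500
    n_sine_reads: int = 0
    n_background_reads: int = 0
    n_decoy_reads: int = 0
    fr_ratio: float = 0.5
    read_length_range: tuple[int, int] = (26, 31)
    indel_factor: float = 0.0  # 1-bp indels per substitution
    protect_promoter: bool = True  # keep A/B boxes mutation-free in copies
    enforce_gene_exclusivity: bool = True
    max_multiplicity: int = 5


@dataclass
class PlantedFamily:
    name: str
    master: str
    abox: tuple[int, int]
    bbox: tuple[int, int]
    head_end: int
    tail_unit: str
    tail_span: tuple[int, int]
    tss_offset: int = DEFAULT_TSS_OFFSET


@dataclass
class PlantedCopy:
    family: str
    contig: str
    start: int
    end: int
    strand: str
    divergence: float
    tsd_seq: str
    tsd_length: int
    gene_id: str | None
    element_seq: str  # strand-oriented (5'->3' of the element)


@dataclass
class PlantedRead:
    seq: str
    origin: str  # {sine, background, decoy}
    family: str | None
    copy_index: int | None
    gene_id: str | None
    orientation: str | None  # genome-forward F / R for sine & decoy reads
    multiplicity: int


@dataclass
class TruthManifest:
    config_seed: int
    contig: str
    genome_length: int
    families: list[PlantedFamily] = field(default_factory=list)
    copies: list[PlantedCopy] = field(default_factory=list)
    genes: list[dict] = field(default_factory=list)
    reads: list[PlantedRead] = field(default_factory=list)

    def expected_gene_counts(self) -> dict[str, tuple[int, int]]:
        """Per-gene (forward, reverse) multiplicity-weighted read totals for
        reads planted inside gene introns."""
        out: dict[str, list[int]] = {}
        for r in self.reads:
            if r.origin != "sine" or r.gene_id is None:
                continue
            fr = out.setdefault(r.gene_id, [0, 0])
            fr[0 if r.orientation == "F" else 1] += r.multiplicity
        return {g: (f, r) for g, (f, r) in out.items()}


# ---------------------------------------------------------------------------
# Helpers

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=n)])


def _expand_iupac(rng: np.random.Generator, pattern: str) -> str:
    return "".join(
        IUPAC_CODES[c][rng.integers(0, len(IUPAC_CODES[c]))] for c in pattern
    )


def _exact_box_positions(seq: str, pattern: str) -> list[int]:
    from .seqcore_io import iupac_mismatches

    return [
        i
        for i in range(len(seq) - len(pattern) + 1)
        if iupac_mismatches(pattern, seq[i : i + len(pattern)]) == 0
    ]


def _build_master(rng: np.random.Generator, spec: FamilySpec) -> PlantedFamily:
    # resample until the planted boxes are the only exact promoter-box
    # matches on the plus strand, so anchor choice inside copies is
    # unambiguous
    for _try in range(300):
        pad = _rand_seq(rng, DEFAULT_TSS_OFFSET)
        abox = _expand_iupac(rng, ABOX_PATTERN)
        spacer_len = int(rng.integers(30, 61))
        spacer = _rand_seq(rng, spacer_len)
        bbox = _expand_iupac(rng, BBOX_PATTERN)
        head_tail = _rand_seq(rng, 12)
        body = _rand_seq(rng, spec.body_length)
        tail = spec.tail_unit * spec.tail_copies
        master = pad + abox + spacer + bbox + head_tail + body + tail
        a0 = len(pad)
        b0 = a0 + 11 + spacer_len
        if _exact_box_positions(master, ABOX_PATTERN) == [a0] and _exact_box_positions(
            master, BBOX_PATTERN
        ) == [b0]:
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise ValueError(f"family {spec.name}: could not build unambiguous master")
    head_end = b0 + 11 + len(head_tail)
    if len(master) < 150:
        raise ValueError(f"family {spec.name}: master shorter than 150 bp")
    return PlantedFamily(
        name=spec.name,
        master=master,
        abox=(a0, a0 + 11),
        bbox=(b0, b0 + 11),
        head_end=head_end,
        tail_unit=spec.tail_unit,
        tail_span=(len(master) - len(tail), len(master)),
    )


def _mutate(
    rng: np.random.Generator,
    seq: str,
    divergence: float,
    protected: list[tuple[int, int]],
    indel_factor: float = 0.0,
) -> str:
    n_sub = round(divergence * len(seq))
    allowed = np.ones(len(seq), dtype=bool)
    for s, e in protected:
        allowed[s:e] = False
    pool = np.nonzero(allowed)[0]
    n_sub = min(n_sub, len(pool))
    chars = list(seq)
    for pos in rng.choice(pool, size=n_sub, replace=False):
        old = chars[pos]
        options = [b for b in _BASES if b != old]
        chars[pos] = options[rng.integers(0, 3)]
    seq = "".join(chars)
    n_indel = round(n_sub * indel_factor)
    for _ in range(n_indel):
        pos = int(rng.integers(1, len(seq) - 1))
        if rng.random() < 0.5:
            seq = seq[:pos] + _BASES[rng.integers(0, 4)] + seq[pos:]
        else:
            seq = seq[:pos] + seq[pos + 1 :]
    return seq


# ---------------------------------------------------------------------------
# Genome simulation

def simulate_genome(
    config: SimConfig,
) -> tuple[list[GenomeSequence], list[GeneModel], TruthManifest]:
    rng = np.random.default_rng(config.seed)
    L = L_genome = config.genome_length
    total_insert = sum(
        f.copy_count * (len_estimate(f) + 15) for f in config.families
    )
    gene_len = 4 * config.exon_length + 3 * config.intron_length
    if config.n_genes * (gene_len + 2000) > 0.6 * L or total_insert > 0.3 * L:
        raise SimCapacityError(
            f"genome of {L} bp cannot hold {config.n_genes} genes and "
            f"{total_insert} bp of planted elements"
        )

    background = _rand_seq(rng, L)
    manifest = TruthManifest(
        config_seed=config.seed, contig=config.contig_name, genome_length=L
    )

    # gene scaffolds in background coordinates
    genes_bg: list[dict] = []
    if config.n_genes:
        pitch = L // config.n_genes
        for i in range(config.n_genes):
            gstart = i * pitch + 1000
            exons = []
            pos = gstart
            for _e in range(4):
                exons.append((pos, pos + config.exon_length))
                pos += config.exon_length + config.intron_length
            gend = exons[-1][1]
            if gend > L - 1000:
                raise SimCapacityError("genes do not fit in the genome")
            genes_bg.append(
                {
                    "gene_id": f"gene{i + 1}",
                    "full_name": f"synthetic gene {i + 1}",
                    "strand": "+" if i % 2 == 0 else "-",
                    "span": (gstart, gend),
                    "exons": exons,
                }
            )

    families = [_build_master(rng, spec) for spec in config.families]
    manifest.families = families

    # choose insertion sites (background coordinates)
    margin = 60
    min_gap = 120
    sites: list[dict] = []
    site_positions: list[int] = []

    def _far_enough(pos: int) -> bool:
        return all(abs(pos - p) >= min_gap for p in site_positions)

    gene_cursor = 0
    for spec, fam in zip(config.families, families):
        if spec.divergences is not None:
            divs = list(spec.divergences)
        else:
            divs = [0.0] + [
                float(rng.uniform(0.0, spec.max_divergence))
                for _ in range(spec.copy_count - 1)
            ]
        for c in range(spec.copy_count):
            # terminal bases stay intact so the optimal full-length alignment
            # of the consensus lands exactly on the planted element ends
            protected = [(0, 1), (len(fam.master) - 1, len(fam.master))]
            if config.protect_promoter:
                protected += [fam.abox, fam.bbox]
            element = _mutate(
                rng, fam.master, divs[c], protected, config.indel_factor
            )
            tsd_len = int(rng.integers(10, 16))
            strand = "+" if rng.random() < 0.5 else "-"
            intronic = c < spec.n_intronic
            placed = False
            for _try in range(2000):
                if intronic:
                    if not genes_bg:
                        raise SimCapacityError("intronic copies requested, no genes")
                    g = genes_bg[gene_cursor % len(genes_bg)]
                    intr_idx = int(rng.integers(0, 3))
                    i0 = g["exons"][intr_idx][1]
                    i1 = g["exons"][intr_idx + 1][0]
                    lo, hi = i0 + margin, i1 - margin - tsd_len
                    if hi <= lo:
                        continue
                    pos = int(rng.integers(lo, hi))
                    gene_id = g["gene_id"]
                else:
                    pos = int(rng.integers(1000, L - 1000))
                    if any(
                        g["span"][0] - margin <= pos <= g["span"][1] + margin
                        for g in genes_bg
                    ):
                        continue
                    gene_id = None
                if not _far_enough(pos):
                    continue
                # the planted TSD must be the unique longest direct repeat in
                # its junction neighbourhood (+-4 bp), so detection with a
                # small locus jitter still recovers it exactly
                site_seq = background[pos : pos + tsd_len]
                inserted = element if strand == "+" else revcomp(element)
                local = (
                    background[max(0, pos - 25) : pos]
                    + site_seq + inserted + site_seq
                    + background[pos + tsd_len : pos + tsd_len + 25]
                )
                S = (pos - max(0, pos - 25)) + tsd_len  # element start in local
                E = S + len(inserted)
                ambiguous = False
                for dl in range(-4, 5):
                    for dr in range(-4, 5):
                        for rep_len in range(15, tsd_len - 1, -1):
                            if (dl, dr, rep_len) == (0, 0, tsd_len):
                                continue
                            ls, rs = S + dl, E + dr
                            if ls - rep_len < 0 or rs + rep_len > len(local):
                                continue
                            if local[ls - rep_len : ls] == local[rs : rs + rep_len]:
                                ambiguous = True
                                break
                        if ambiguous:
                            break
                    if ambiguous:
                        break
                if ambiguous:
                    continue
                placed = True
                break
            if not placed:
                raise SimCapacityError(
                    f"could not place copy {c} of {spec.name}"
                )
            if intronic:
                gene_cursor += 1
            site_positions.append(pos)
            sites.append(
                {
                    "pos": pos,
                    "family": fam.name,
                    "element": element,
                    "strand": strand,
                    "tsd_len": tsd_len,
                    "divergence": divs[c],
                    "gene_id": gene_id,
                }
            )

    # assemble the final sequence, duplicating each target site
    sites.sort(key=lambda s: s["pos"])
    parts: list[str] = []
    cursor = 0
    shift_points: list[int] = []
    shift_values: list[int] = []
    cumulative = 0
    for s in sites:
        pos, t = s["pos"], s["tsd_len"]
        site_seq = background[pos : pos + t]
        inserted = s["element"] if s["strand"] == "+" else revcomp(s["element"])
        parts.append(background[cursor : pos + t])
        parts.append(inserted + site_seq)
        cursor = pos + t
        s["tsd_seq"] = site_seq
        s["final_start"] = pos + t + cumulative
        s["final_end"] = pos + t + cumulative + len(inserted)
        cumulative += len(inserted) + t
        shift_points.append(pos + t)
        shift_values.append(cumulative)
    parts.append(background[cursor:])
    final_seq = "".join(parts)

    pts = np.array(shift_points, dtype=np.int64)
    vals = np.array([0] + shift_values, dtype=np.int64)

    def bg2final(x: int) -> int:
        return int(x + vals[np.searchsorted(pts, x, side="right")])

    contig = GenomeSequence(id=config.contig_name, seq=final_seq)

    gene_models: list[GeneModel] = []
    for g in genes_bg:
        span = Interval(
            config.contig_name, bg2final(g["span"][0]), bg2final(g["span"][1]),
            g["strand"],
        )
        exons = tuple(
            Interval(config.contig_name, bg2final(a), bg2final(b), g["strand"])
            for a, b in g["exons"]
        )
        gene_models.append(
            GeneModel(
                gene_id=g["gene_id"], full_name=g["full_name"], span=span,
                strand=g["strand"], exons=exons,
            )
        )
    manifest.genes = [
        {
            "gene_id": g.gene_id,
            "full_name": g.full_name,
            "span": (g.span.start, g.span.end),
            "strand": g.strand,
            "exons": [(e.start, e.end) for e in g.exons],
        }
        for g in gene_models
    ]
    manifest.copies = [
        PlantedCopy(
            family=s["family"],
            contig=config.contig_name,
            start=s["final_start"],
            end=s["final_end"],
            strand=s["strand"],
            divergence=s["divergence"],
            tsd_seq=s["tsd_seq"],
            tsd_length=s["tsd_len"],
            gene_id=s["gene_id"],
            element_seq=s["element"],
        )
        for s in sites
    ]
    return [contig], gene_models, manifest


def len_estimate(spec: FamilySpec) -> int:
    return (
        DEFAULT_TSS_OFFSET + 11 + 60 + 11 + 12 + spec.body_length
        + len(spec.tail_unit) * spec.tail_copies
    )


# ---------------------------------------------------------------------------
# Read simulation

def simulate_reads(
    manifest: TruthManifest,
    config: SimConfig,
    genome: list[GenomeSequence],
    genes: list[GeneModel],
) -> list[PlantedRead]:
    """Sample small-RNA reads with recorded origins; appends to and returns
    ``manifest.reads``."""
    rng = np.random.default_rng(config.seed + 10_007)
    contig = genome[0]
    fam_by_name = {f.name: f for f in manifest.families}
    gene_spans = {
        g.gene_id: contig.seq[g.span.start : g.span.end] for g in genes
    }
    lo, hi = config.read_length_range
    reads: list[PlantedRead] = []

    def _count_occurrences(hay: str, needle: str) -> int:
        n = 0
        start = 0
        while True:
            idx = hay.find(needle, start)
            if idx < 0:
                return n
            n += 1
            start = idx + 1

    def _gene_hits(seq: str) -> dict[str, int]:
        rc = revcomp(seq)
        out = {}
        for gid, gseq in gene_spans.items():
            n = _count_occurrences(gseq, seq) + _count_occurrences(gseq, rc)
            if n:
                out[gid] = n
        return out

    # --- sine-derived reads, sampled from copy bodies
    eligible = []
    for idx, copy in enumerate(manifest.copies):
        fam = fam_by_name[copy.family]
        tail_len = fam.tail_span[1] - fam.tail_span[0]
        body_lo = fam.head_end
        body_hi = len(copy.element_seq) - tail_len
        if body_hi - body_lo >= hi:
            eligible.append((idx, body_lo, body_hi))
    if config.n_sine_reads and not eligible:
        raise ValueError("no copies with a body long enough for reads")
    for _ in range(config.n_sine_reads):
        for _try in range(200):
            idx, body_lo, body_hi = eligible[rng.integers(0, len(eligible))]
            copy = manifest.copies[idx]
            length = int(rng.integers(lo, hi + 1))
            off = int(rng.integers(body_lo, body_hi - length + 1))
            fragment = copy.element_seq[off : off + length]
            # genome-forward representation of the sampled fragment
            gfwd = fragment if copy.strand == "+" else revcomp(fragment)
            orientation = "F" if rng.random() < config.fr_ratio else "R"
            seq = gfwd if orientation == "F" else revcomp(gfwd)
            if config.enforce_gene_exclusivity:
                hits = _gene_hits(seq)
                if copy.gene_id is None:
                    if hits:
                        continue
                elif list(hits.items()) != [(copy.gene_id, 1)]:
                    continue
            mult = int(min(rng.geometric(0.6), config.max_multiplicity))
            reads.append(
                PlantedRead(
                    seq=seq, origin="sine", family=copy.family,
                    copy_index=idx, gene_id=copy.gene_id,
                    orientation=orientation, multiplicity=mult,
                )
            )
            break
        else:
            raise ValueError("could not sample a gene-exclusive sine read")

    # --- tRNA-fragment decoys, sampled from heads of non-genic copies
    head_ok = [
        (idx, fam_by_name[c.family].head_end)
        for idx, c in enumerate(manifest.copies)
        if fam_by_name[c.family].head_end >= hi and c.gene_id is None
    ]
    if config.n_decoy_reads and not head_ok:
        raise ValueError("no non-genic copies with a head long enough for decoys")
    for _ in range(config.n_decoy_reads):
        for _try in range(200):
            idx, head_end = head_ok[rng.integers(0, len(head_ok))]
            copy = manifest.copies[idx]
            length = int(rng.integers(lo, hi + 1))
            off = int(rng.integers(0, head_end - length + 1))
            fragment = copy.element_seq[off : off + length]
            gfwd = fragment if copy.strand == "+" else revcomp(fragment)
            orientation = "F" if rng.random() < config.fr_ratio else "R"
            seq = gfwd if orientation == "F" else revcomp(gfwd)
            if config.enforce_gene_exclusivity and _gene_hits(seq):
                continue  # shared head sequence also present in a genic copy
            break
        else:
            raise ValueError("could not sample a gene-exclusive decoy read")
        mult = int(min(rng.geometric(0.6), config.max_multiplicity))
        reads.append(
            PlantedRead(
                seq=seq, origin="decoy", family=copy.family, copy_index=idx,
                gene_id=None, orientation=orientation, multiplicity=mult,
            )
        )

    # --- random background
    for _ in range(config.n_background_reads):
        for _try in range(200):
            length = int(rng.integers(lo, hi + 1))
            seq = _rand_seq(rng, length)
            if config.enforce_gene_exclusivity and (
                seq in contig.seq or revcomp(seq) in contig.seq
            ):
                continue
            break
        mult = int(min(rng.geometric(0.6), config.max_multiplicity))
        reads.append(
            PlantedRead(
                seq=seq, origin="background", family=None, copy_index=None,
                gene_id=None, orientation=None, multiplicity=mult,
            )
        )

    manifest.reads.extend(reads)
    return reads


def reads_to_fasta(reads: list[PlantedRead], path: str | Path) -> None:
    """Expand multiplicities into individual FASTA records."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            for j in range(r.multiplicity):
                fh.write(f">r{i:06d}_{j}\n{r.seq}\n")


# ---------------------------------------------------------------------------
# Manifest serialization

def write_manifest(manifest: TruthManifest, path: str | Path) -> None:
    payload = {
        "config_seed": manifest.config_seed,
        "contig": manifest.contig,
        "genome_length": manifest.genome_length,
        "families": [asdict(f) for f in manifest.families],
        "copies": [asdict(c) for c in manifest.copies],
        "genes": manifest.genes,
        "reads": [asdict(r) for r in manifest.reads],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_manifest(path: str | Path) -> TruthManifest:
    with open(path) as fh:
        payload = json.load(fh)
    m = TruthManifest(
        config_seed=payload["config_seed"],
        contig=payload["contig"],
        genome_length=payload["genome_length"],
    )
    for f in payload["families"]:
        f["abox"] = tuple(f["abox"])
        f["bbox"] = tuple(f["bbox"])
        f["tail_span"] = tuple(f["tail_span"])
        m.families.append(PlantedFamily(**f))
    m.copies = [PlantedCopy(**c) for c in payload["copies"]]
    m.genes = payload["genes"]
    m.reads = [PlantedRead(**r) for r in payload["reads"]]
    return m
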