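import numpy as np
import pytest

from sinescout.annotate import (
    AgeProfile,
    GenomicCopy,
    TailAnnotation,
    TSDPair,
    age_profile,
    check_sine_criteria,
    classify_tail,
    detect_dimers,
    detect_tsd,
    scan_copies,
)
from sinescout.discovery import SineModel
from sinescout.promoter import PromoterHit, scan_promoters
from sinescout.seqcore_io import GenomeSequence, Interval, revcomp

from conftest import mutate, random_dna
from oracles import scan_copies_oracle


def plant_genome(rng, query, idents, length=60_000, spacing=8000, start=2000):
    """Plant substitution-mutated copies of query at given identities; copies
    are strand-randomized.  Returns (genome string, list of planted spans)."""
    g = list(random_dna(rng, length))
    pos = start
    spans = []
    for ident in idents:
        copy = mutate(rng, query, round((1 - ident) * len(query)))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            copy = revcomp(copy)
        g[pos:pos] = list(copy)
        spans.append((pos, strand))
        pos += spacing
    return "".join(g), spans


class TestScanCopies:
    def test_threshold_counts_and_oracle(self, rng):
        query = random_dna(rng, 300)
        gs, _ = plant_genome(rng, query, [0.95] * 7 + [0.85] * 3, length=90_000)
        genome = [GenomeSequence("c", gs)]
        c90 = scan_copies(genome, query, 0.90, family="q")
        c80 = scan_copies(genome, query, 0.80, family="q")
        assert len(c90) == 7
        assert len(c80) == 10
        for thr, copies in ((0.90, c90), (0.80, c80)):
            impl = {(c.locus.start, c.locus.end, c.strand) for c in copies}
            oracle = scan_copies_oracle(query, gs, thr)
            assert len(impl) == len(oracle)
            for s, e, st in impl:
                assert any(
                    os_ == st and abs(s - os) <= 2 and abs(e - oe) <= 2
                    for os, oe, os_ in oracle
                )

    def test_no_false_positives_on_random(self, rng):
        query = random_dna(rng, 250)
        for seed in range(5):
            r = np.random.default_rng(900 + seed)
            gs = random_dna(r, 40_000)
            assert scan_copies([GenomeSequence("c", gs)], query, 0.80, family="q") == []
            assert scan_copies_oracle(query, gs, 0.80) == set()

    def test_minus_strand_copy(self, rng):
        query = random_dna(rng, 200)
        gs = random_dna(rng, 5000) + revcomp(query) + random_dna(rng, 5000)
        copies = scan_copies([GenomeSequence("c", gs)], query, 0.90, family="q")
        assert len(copies) == 1
        assert copies[0].strand == "-"
        assert copies[0].identity == 1.0
        assert (copies[0].locus.start, copies[0].locus.end) == (5000, 5200)

    def test_monotonicity(self, rng):
        query = random_dna(rng, 300)
        gs, _ = plant_genome(rng, query, [0.95, 0.92, 0.85, 0.82], length=50_000)
        genome = [GenomeSequence("c", gs)]
        loci90 = {(c.locus.start, c.locus.end) for c in scan_copies(genome, query, 0.90, family="q")}
        loci80 = {(c.locus.start, c.locus.end) for c in scan_copies(genome, query, 0.80, family="q")}
        assert loci90 <= loci80

    def test_short_consensus_rejected(self):
        with pytest.raises(ValueError):
            scan_copies([GenomeSequence("c", "ACGT" * 100)], "ACGT" * 10, 0.8)


class TestAgeProfile:
    def _copies(self, n, family="f"):
        return [
            GenomicCopy(family, Interval("c", i * 1000, i * 1000 + 300, "+"), "+", 0.9)
            for i in range(n)
        ]

    def test_ratio(self):
        p = age_profile(self._copies(100), self._copies(40))
        assert (p.n80, p.n90) == (100, 40)
        assert p.young_fraction == pytest.approx(0.40)

    def test_all_young(self):
        p = age_profile(self._copies(5), self._copies(5))
        assert p.young_fraction == 1.0

    def test_empty(self):
        p = age_profile([], [], family="f")
        assert p.n80 == 0 and p.young_fraction == 0.0

    def test_invariant(self):
        with pytest.raises(ValueError):
            AgeProfile("f", n90=6, n80=5)


class TestDetectTsd:
    def test_planted_12mer(self, rng):
        site = random_dna(rng, 12)
        copy = random_dna(rng, 200)
        gs = random_dna(rng, 500) + site + copy + site + random_dna(rng, 500)
        genome = [GenomeSequence("c", gs)]
        locus = Interval("c", 512, 712, "+")
        tsd = detect_tsd(genome, locus)
        assert tsd is not None
        assert tsd.length >= 12  # >= : flanking bases may extend by chance
        assert site in tsd.seq or tsd.seq in site + copy[:3]

    def test_below_min_length_absent(self, rng):
        site = random_dna(rng, 8)
        copy = random_dna(rng, 200)
        gs = random_dna(rng, 300) + site + copy + site + random_dna(rng, 300)
        locus = Interval("c", 308, 508, "+")
        assert detect_tsd([GenomeSequence("c", gs)], locus) is None

    def test_simulator_truth_exact(self, small_sim):
        cfg, genome, genes, manifest, reads = small_sim
        for c in manifest.copies:
            tsd = detect_tsd(genome, Interval(c.contig, c.start, c.end, c.strand))
            assert tsd is not None
            assert tsd.seq == c.tsd_seq
            assert tsd.length == c.tsd_length
            assert tsd.mismatches == 0

    def test_exact_pair_when_zero_mismatch(self, small_sim):
        cfg, genome, genes, manifest, reads = small_sim
        contig = genome[0]
        c = manifest.copies[0]
        tsd = detect_tsd(genome, Interval(c.contig, c.start, c.end, c.strand))
        left = contig.seq[tsd.left.start : tsd.left.end]
        right = contig.seq[tsd.right.start : tsd.right.end]
        assert left == right == tsd.seq

    def test_insufficient_flank(self, rng):
        gs = random_dna(rng, 300)
        assert detect_tsd([GenomeSequence("c", gs)], Interval("c", 2, 250, "+")) is None


class TestClassifyTail:
    def _pad(self, tail, rng):
        return random_dna(rng, 160) + tail

    def test_ttag_str(self, rng):
        t = classify_tail(self._pad("TTAGTTAGTTAGTTAG", rng))
        assert t.kind == "STR"
        assert t.unit == "AGTT"  # minimal rotation of TTAG
        assert t.unit_count == 4

    def test_polya(self, rng):
        t = classify_tail(self._pad("A" * 12, rng))
        assert t.kind == "polyA"
        assert t.unit == "A"
        assert t.unit_count == 12

    def test_none(self, rng):
        t = classify_tail(self._pad("ACGTACGATCGT", rng))
        assert t.kind == "none"

    def test_mixed_two_units(self, rng):
        t = classify_tail(self._pad("CACACACACA" + "TTAGTTAGTTAGTTAG", rng))
        assert t.kind == "mixed"
        assert t.unit == "AGTT"  # longest run wins

    def test_rotation_canonicalization(self, rng):
        a = classify_tail(self._pad("GTTAGTTAGTTAGTTA", rng))
        b = classify_tail(self._pad("TTAGTTAGTTAGTTAG", rng))
        assert a.unit == b.unit


def _model(name, consensus):
    hits = [h for h in scan_promoters(GenomeSequence(name, consensus), 1)
            if h.strand == "+"]
    promoter = hits[0] if hits else None
    return SineModel(
        name=name, consensus=consensus, promoter=promoter,
        tss_offset=promoter.abox.start if promoter else 0,
        head_end=min((promoter.bbox.end + 12) if promoter else 0, len(consensus)),
        n_members=3,
    )


class TestDetectDimers:
    def test_concatenation_detected(self, rng):
        a = random_dna(rng, 250)
        b = random_dna(rng, 250)
        models = [_model("p1", a), _model("p2", b), _model("dim", a + b)]
        dimers = detect_dimers(models)
        assert any(
            comp == "dim" and p1 == "p1" and p2 == "p2"
            and abs(bp[0] - 250) <= 15 and abs(bp[1] - 250) <= 15
            for comp, p1, p2, bp in dimers
        )

    def test_unrelated_models_empty(self, rng):
        models = [_model("a", random_dna(rng, 300)), _model("b", random_dna(rng, 300))]
        assert detect_dimers(models) == []

    def test_diverged_dimer_detected(self, rng):
        a = random_dna(rng, 250)
        b = random_dna(rng, 250)
        composite = mutate(rng, a + b, 25)  # 5% diverged from the parents
        models = [_model("p1", a), _model("p2", b), _model("dim", composite)]
        dimers = detect_dimers(models)
        assert any(comp == "dim" and p1 == "p1" and p2 == "p2"
                   for comp, p1, p2, _ in dimers)


class TestSineCriteria:
    def test_simulated_families_pass(self, small_sim, small_sim_models):
        cfg, genome, genes, manifest, reads = small_sim
        models, _, _ = small_sim_models
        for m in models:
            c80 = scan_copies(genome, m, 0.80)
            c80 = [
                GenomicCopy(c.family, c.locus, c.strand, c.identity,
                            tsd=detect_tsd(genome, c.locus), truncated=c.truncated)
                for c in c80
            ]
            assert check_sine_criteria(m, c80) == []

    def test_short_model_fails(self, rng):
        m = _model("x", random_dna(rng, 80) + "A" * 80)
        m.consensus = m.consensus[:140]
        assert "length below 150 bp" in check_sine_criteria(m, [])
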