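import numpy as np
import pytest

from sinescout.discovery import (
    AnchorWindow,
    ClusterRejected,
    DiscoveryConfig,
    build_consensus,
    call_boundary,
    cluster_windows,
    dedupe_models,
    discover,
    extract_windows,
    star_align,
)
from sinescout.promoter import AnchorHit
from sinescout.seqcore_io import GenomeSequence, Interval, revcomp

from conftest import mutate, random_dna
from oracles import dp_local_stats

ABOX = "TGGCAAAGTTG"
BBOX = "GGTTCGAATCC"


def make_element(rng, body=250, tail="TTAG" * 5):
    """11-bp pad + exact boxes + spacer + body + tail (planted anatomy)."""
    return (
        random_dna(rng, 11) + ABOX + random_dna(rng, 40) + BBOX
        + random_dna(rng, 12) + body * 0 * "" + random_dna(rng, body) + tail
    )


def make_window(rng, element, n_sub=0, pad=30, total=None, name="c", at=0,
                tsd_len=12):
    """AnchorWindow with the (optionally mutated) element at offset ``pad``,
    flanked by a duplicated target site, inside random flanks; the anchor
    marks the element start."""
    elem = mutate(rng, element, n_sub) if n_sub else element
    total = total or (pad + len(elem) + 150)
    site = random_dna(rng, tsd_len)
    right = site + random_dna(rng, max(0, total - pad - len(elem) - tsd_len))
    seq = random_dna(rng, max(0, pad - tsd_len)) + site + elem + right
    return AnchorWindow(
        anchor=AnchorHit(anchor=Interval(name, at + pad, at + pad + 1, "+"),
                         source="promoter_scan"),
        window=Interval(name, at, at + len(seq), "+"),
        seq=seq,
        anchor_offset=pad,
    )


class TestExtractWindows:
    def _genome(self, rng, n=10_000):
        return [GenomeSequence("ctg", random_dna(rng, n))]

    def test_plus_strand_arithmetic(self, rng):
        genome = self._genome(rng)
        anchors = [AnchorHit(Interval("ctg", 500, 501, "+"), "promoter_scan")]
        w = extract_windows(genome, anchors, 1000, 30)[0]
        assert (w.window.start, w.window.end) == (470, 1500)
        assert w.seq == genome[0].seq[470:1500]
        assert w.anchor_offset == 30
        assert not w.truncated

    def test_truncated_at_contig_end(self, rng):
        genome = self._genome(rng)
        anchors = [AnchorHit(Interval("ctg", 9800, 9801, "+"), "promoter_scan")]
        w = extract_windows(genome, anchors, 1000, 30)[0]
        assert w.truncated
        assert w.window.end == 10_000

    def test_minus_strand_revcomp(self, rng):
        genome = self._genome(rng)
        anchors = [AnchorHit(Interval("ctg", 5000, 5001, "-"), "promoter_scan")]
        w = extract_windows(genome, anchors, 1000, 30)[0]
        assert w.seq == revcomp(genome[0].seq[w.window.start : w.window.end])
        assert (w.window.start, w.window.end) == (4001, 5031)
        assert w.anchor_offset == 30


def _oracle_single_linkage(windows, min_identity=0.90, min_overlap=150,
                           max_shift=5, min_members=3):
    """Independent all-pairs DP clustering on the same inputs."""
    n = len(windows)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            score, matches, cols, aspan, bspan = dp_local_stats(
                windows[i].seq, windows[j].seq
            )
            if cols < min_overlap or matches / cols < min_identity:
                continue
            implied = bspan[0] + (windows[i].anchor_offset - aspan[0])
            if abs(implied - windows[j].anchor_offset) > max_shift:
                continue
            parent[find(j)] = find(i)
    groups = {}
    for k in range(n):
        groups.setdefault(find(k), set()).add(k)
    return {frozenset(g) for g in groups.values() if len(g) >= min_members}


class TestClusterWindows:
    def test_planted_family_plus_noise(self, rng):
        element = make_element(rng, body=120)
        windows = [make_window(rng, element, n_sub=6, at=i * 2000) for i in range(5)]
        windows += [make_window(rng, random_dna(rng, len(element)), at=50_000 + i * 2000)
                    for i in range(4)]
        clusters = cluster_windows(windows)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 5
        got = {
            frozenset(windows.index(m) for m in clusters[0].members)
        }
        assert got == _oracle_single_linkage(sorted(windows, key=lambda w: windows.index(w)))

    def test_two_members_below_minimum(self, rng):
        element = make_element(rng, body=120)
        windows = [make_window(rng, element, n_sub=4, at=i * 2000) for i in range(2)]
        assert cluster_windows(windows) == []

    def test_two_distinct_families(self, rng):
        e1 = make_element(rng, body=130)
        e2 = make_element(rng, body=170, tail="CA" * 8)
        windows = [make_window(rng, e1, n_sub=5, at=i * 2000) for i in range(4)]
        windows += [make_window(rng, e2, n_sub=5, at=40_000 + i * 2000) for i in range(4)]
        clusters = cluster_windows(windows)
        assert len(clusters) == 2
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [4, 4]
        member_sets = {frozenset(windows.index(m) for m in c.members) for c in clusters}
        assert member_sets == _oracle_single_linkage(windows)

    def test_order_independence(self, rng):
        e1 = make_element(rng, body=130)
        windows = [make_window(rng, e1, n_sub=5, at=i * 2000) for i in range(4)]
        windows += [make_window(rng, random_dna(rng, 400), at=30_000 + i * 2000)
                    for i in range(3)]
        ref = cluster_windows(windows)
        perm = [windows[i] for i in rng.permutation(len(windows))]
        shuffled = cluster_windows(perm)
        key = lambda cl: sorted((m.window.start, m.window.end) for m in cl.members)
        assert sorted(map(key, ref)) == sorted(map(key, shuffled))

    def test_retained_edges_meet_thresholds(self, rng):
        element = make_element(rng, body=200)
        windows = [make_window(rng, element, n_sub=8, at=i * 2000) for i in range(5)]
        (cl,) = cluster_windows(windows)
        assert cl.anchor_shift_max <= 5
        assert cl.overlap_min >= 150
        assert all(v >= 0.90 for v in cl.pairwise_identities.values())


class TestCallBoundary:
    def test_identical_elements_random_flanks(self, rng):
        element = make_element(rng, body=200)  # ~300 bp total
        windows = [make_window(rng, element, total=1000, at=i * 2000) for i in range(4)]
        (cl,) = cluster_windows(windows)
        bc = call_boundary(cl)
        assert abs(bc.start - 30) <= 10
        assert abs(bc.end - (30 + len(element))) <= 10

    def test_fully_identical_windows_flagged(self, rng):
        seq = random_dna(rng, 600)
        windows = []
        for i in range(3):
            windows.append(
                AnchorWindow(
                    anchor=AnchorHit(Interval("c", i * 2000 + 30, i * 2000 + 31, "+"),
                                     "promoter_scan"),
                    window=Interval("c", i * 2000, i * 2000 + 600, "+"),
                    seq=seq,
                    anchor_offset=30,
                )
            )
        (cl,) = cluster_windows(windows)
        bc = call_boundary(cl)
        assert bc.end == 600
        assert any("no divergence" in f for f in bc.flags)

    def test_divergent_elements(self, rng):
        element = make_element(rng, body=110)  # ~200 bp total
        windows = [make_window(rng, element, n_sub=10, total=900, at=i * 2000)
                   for i in range(5)]
        (cl,) = cluster_windows(windows)
        bc = call_boundary(cl)
        assert abs((bc.end - bc.start) - len(element)) <= 10

    def test_no_conserved_run_rejects(self, rng):
        # windows that only share a short 60-bp island fail the length floor
        island = random_dna(rng, 60)
        windows = []
        for i in range(3):
            seq = random_dna(rng, 30) + island + random_dna(rng, 500)
            windows.append(
                AnchorWindow(
                    anchor=AnchorHit(Interval("c", i * 2000 + 30, i * 2000 + 31, "+"),
                                     "promoter_scan"),
                    window=Interval("c", i * 2000, i * 2000 + len(seq), "+"),
                    seq=seq, anchor_offset=30,
                )
            )
        cl_list = cluster_windows(windows, min_overlap=40)
        if cl_list:
            with pytest.raises(ClusterRejected):
                call_boundary(cl_list[0])


class TestBuildConsensus:
    def _cluster(self, rng, element, subs):
        windows = [
            make_window(rng, element, n_sub=s, total=1000, at=i * 2000)
            for i, s in enumerate(subs)
        ]
        (cl,) = cluster_windows(windows)
        return cl

    def test_identical_members(self, rng):
        element = make_element(rng, body=200)
        cl = self._cluster(rng, element, [0, 0, 0])
        star = star_align(cl)
        bc = call_boundary(cl, star=star)
        model = build_consensus(cl, bc, star=star)
        assert model.consensus == element

    def test_single_substitution_outvoted(self, rng):
        element = make_element(rng, body=200)
        windows = [make_window(rng, element, total=1000, at=i * 2000) for i in range(3)]
        variant = element[:150] + {"A": "C", "C": "G", "G": "T", "T": "A"}[element[150]] + element[151:]
        windows.append(make_window(rng, variant, total=1000, at=8000))
        (cl,) = cluster_windows(windows)
        star = star_align(cl)
        model = build_consensus(cl, call_boundary(cl, star=star), star=star)
        assert model.consensus == element

    def test_simulated_family_consensus_near_master(self, small_sim, small_sim_models):
        cfg, genome, genes, manifest, reads = small_sim
        models, clusters, rejects = small_sim_models
        masters = {f.name: f.master for f in manifest.families}
        assert len(models) == len(masters)
        for m in models:
            best = max(
                masters.values(),
                key=lambda s: dp_local_stats(m.consensus[:80], s[:120])[0],
            )
            # within 1% of the planted master
            score, matches, cols, _, _ = dp_local_stats(m.consensus, best)
            assert cols >= 0.99 * len(best)
            assert matches / cols >= 0.99

    def test_tss_offset_recorded(self, small_sim_models):
        models, _, _ = small_sim_models
        for m in models:
            assert m.tss_offset == 11
            assert m.promoter is not None
            assert m.length >= 150


class TestDedupeModels:
    def test_shifted_twin_suppressed(self, rng, small_sim_models):
        models, _, _ = small_sim_models
        m = models[0]
        import copy

        twin = copy.deepcopy(m)
        twin.name = "twin"
        twin.consensus = m.consensus[25:]
        twin.n_members = max(1, m.n_members - 1)
        kept = dedupe_models([m, twin])
        assert [k.name for k in kept] == [m.name]

    def test_unrelated_models_kept(self, small_sim_models):
        models, _, _ = small_sim_models
        assert len(dedupe_models(list(models))) == len(models)


class TestDiscoverEndToEnd:
    def test_two_families_recovered(self, small_sim, small_sim_models):
        cfg, genome, genes, manifest, reads = small_sim
        models, clusters, rejects = small_sim_models
        assert len(models) == 2
        masters = {f.master for f in manifest.families}
        matched = {m.consensus for m in models}
        for cons in matched:
            assert any(
                dp_local_stats(cons, mast)[1] >= 0.98 * len(mast)
                for mast in masters
            )

    def test_random_genome_no_families(self, rng):
        genome = [GenomeSequence("r", random_dna(rng, 150_000))]
        models, clusters, rejects = discover(genome)
        assert models == []
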