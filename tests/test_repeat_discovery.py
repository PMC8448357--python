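"""Comparative clustering, consensus recovery, and the monomer scan."""

import numpy as np
import pytest

from msm_anatomy.errors import SamplingError, UsageError
from msm_anatomy.repeat_discovery import (
    RepeatCluster,
    build_similarity_graph,
    cluster_graph,
    derive_consensus,
    estimate_period,
    genome_proportion,
    lexicographically_minimal_rotation,
    rotational_identity,
    sample_reads,
    scan_satellite,
)
from msm_anatomy.seqio_align import SeqRecord, revcomp
from conftest import mutate, random_seq


class TestSampleReads:
    def test_full_set_returned(self, rng):
        reads = [SeqRecord(f"r{i}", random_seq(rng, 50)) for i in range(20)]
        out = sample_reads(reads, 20, seed=3)
        assert sorted(r.id for r in out) == sorted(r.id for r in reads)

    def test_deterministic(self, rng):
        reads = [SeqRecord(f"r{i}", random_seq(rng, 50)) for i in range(50)]
        a = sample_reads(reads, 10, seed=9)
        b = sample_reads(reads, 10, seed=9)
        assert [r.id for r in a] == [r.id for r in b]

    def test_different_seeds_differ(self, rng):
        reads = [SeqRecord(f"r{i}", random_seq(rng, 50)) for i in range(1000)]
        a = {r.id for r in sample_reads(reads, 100, seed=1)}
        b = {r.id for r in sample_reads(reads, 100, seed=2)}
        assert a != b
        # hypergeometric expectation: overlap ≈ 100·100/1000 = 10
        assert len(a & b) < 40

    def test_oversampling_rejected(self, rng):
        reads = [SeqRecord("r0", random_seq(rng, 50))]
        with pytest.raises(SamplingError):
            sample_reads(reads, 2, seed=0)


class TestSimilarityGraph:
    def test_dissimilar_reads_edgeless(self, rng):
        a = [SeqRecord(f"a{i}", random_seq(rng, 200)) for i in range(5)]
        b = [SeqRecord(f"b{i}", random_seq(rng, 200)) for i in range(5)]
        graph, ha, hb = build_similarity_graph(a, b)
        assert graph.number_of_edges() == 0
        assert all(v == 0 for v in ha.values()) and all(v == 0 for v in hb.values())

    def test_same_set_both_sides_symmetric_counts(self, rng):
        sat = random_seq(rng, 200)
        reads = [SeqRecord(f"r{i}", mutate(sat, 0.01, rng)) for i in range(6)]
        graph, ha, hb = build_similarity_graph(reads, reads)
        for rid in ha:
            assert ha[rid] == hb[rid]

    def test_satellite_clique_in_one_species(self, rng):
        sat = random_seq(rng, 200)
        sat_reads = [SeqRecord(f"s{i}", mutate(sat, 0.01, rng)) for i in range(10)]
        uniq_a = [SeqRecord(f"a{i}", random_seq(rng, 200)) for i in range(10)]
        uniq_b = [SeqRecord(f"b{i}", random_seq(rng, 200)) for i in range(10)]
        graph, ha, hb = build_similarity_graph(sat_reads + uniq_a, uniq_b)
        for r in sat_reads:
            assert ha[r.id] == 9  # the other clique members
            assert hb[r.id] == 0
        clusters = cluster_graph(graph)
        assert len(clusters) == 1
        assert clusters[0].size_a == 10 and clusters[0].size_b == 0


class TestClusters:
    def _cluster(self, size_a=15, size_b=5, n_a=1000, n_b=1000):
        return RepeatCluster(
            cluster_id="CL1",
            members_a=frozenset(f"a{i}" for i in range(size_a)),
            members_b=frozenset(f"b{i}" for i in range(size_b)),
            n_sampled_a=n_a,
            n_sampled_b=n_b,
        )

    def test_proportion_and_expansion_ratio(self):
        c = self._cluster()
        assert genome_proportion(c, "A") == pytest.approx(0.015)
        assert c.expansion_ratio == pytest.approx(16 / 6)

    def test_zero_members_zero_proportion(self):
        c = self._cluster(size_b=0)
        assert genome_proportion(c, "B") == 0.0

    def test_unknown_species_rejected(self):
        with pytest.raises(UsageError):
            genome_proportion(self._cluster(), "C")

    def test_ranking_by_total_size(self, rng):
        import networkx as nx

        g = nx.Graph()
        g.graph.update(n_sampled_a=100, n_sampled_b=100)
        for i in range(30):
            g.add_node(f"x{i}", in_a=True, in_b=False)
        for i in range(20):
            g.add_node(f"y{i}", in_a=False, in_b=True)
        g.add_edges_from((f"x{i}", f"x{i+1}") for i in range(29))
        g.add_edges_from((f"y{i}", f"y{i+1}") for i in range(19))
        g.add_node("lonely", in_a=True, in_b=False)
        clusters = cluster_graph(g)
        assert [len(c.members_a | c.members_b) for c in clusters] == [30, 20]
        assert clusters[0].cluster_id == "CL1"


class TestConsensus:
    def test_period_of_exact_tandem(self, monomer137):
        assert estimate_period(monomer137 * 4) == 137

    def test_exact_tandem_consensus_recovered(self, monomer137, rng):
        array = monomer137 * 20
        reads = {}
        members = set()
        positions = np.linspace(0, len(array) - 300, 8).astype(int)
        for i, p in enumerate(positions):
            rid = f"m{i}"
            reads[rid] = SeqRecord(rid, array[p : p + 300])
            members.add(rid)
        cluster = RepeatCluster(
            "CL1", frozenset(members), frozenset(), 100, 100,
            member_degrees={m: 1 for m in members},
        )
        cons = derive_consensus(cluster, reads)
        assert len(cons) == 137
        assert rotational_identity(cons.sequence, monomer137) == pytest.approx(1.0)

    def test_divergent_copies_high_identity(self, monomer137, rng):
        array = "".join(mutate(monomer137, 0.01, rng) for _ in range(30))
        reads = {}
        members = set()
        for i in range(12):
            p = int(rng.integers(0, len(array) - 320))
            rid = f"m{i}"
            reads[rid] = SeqRecord(rid, array[p : p + 320])
            members.add(rid)
        cluster = RepeatCluster(
            "CL1", frozenset(members), frozenset(), 100, 100,
            member_degrees={m: 2 for m in members},
        )
        cons = derive_consensus(cluster, reads)
        assert rotational_identity(cons.sequence, monomer137) >= 0.99

    def test_nonrepetitive_read_flagged(self, rng):
        rec = SeqRecord("solo", random_seq(rng, 300))
        cluster = RepeatCluster(
            "CL9", frozenset({"solo"}), frozenset(), 10, 10, member_degrees={"solo": 0}
        )
        cons = derive_consensus(cluster, {"solo": rec})
        assert "warning=no_period" in cons.description

    def test_minimal_rotation(self):
        assert lexicographically_minimal_rotation("CGTA") == "ACGT"


class TestScanSatellite:
    def test_three_intact_one_fragment(self, monomer137, rng):
        target = SeqRecord(
            "t",
            random_seq(rng, 70) + monomer137 * 3 + monomer137[:68] + random_seq(rng, 80),
        )
        hits = scan_satellite(SeqRecord("c", monomer137), target)
        klasses = [h.klass for h in hits]
        assert klasses.count("intact") == 3
        assert klasses.count("fragmental") == 1
        assert hits == sorted(hits, key=lambda h: h.start)

    def test_reverse_strand_copies_found(self, monomer137, rng):
        target = SeqRecord("t", random_seq(rng, 50) + revcomp(monomer137 * 2) + random_seq(rng, 50))
        hits = scan_satellite(SeqRecord("c", monomer137), target)
        assert [h.klass for h in hits] == ["intact", "intact"]
        assert all(h.strand == "-" for h in hits)

    def test_no_similarity_empty(self, monomer137, rng):
        target = SeqRecord("t", random_seq(rng, 800))
        assert scan_satellite(SeqRecord("c", monomer137), target) == []

    def test_hits_nonoverlapping(self, monomer137, rng):
        target = SeqRecord("t", monomer137 * 5)
        hits = scan_satellite(SeqRecord("c", monomer137), target)
        for a, b in zip(hits, hits[1:]):
            assert a.end <= b.start

    def test_short_consensus_rejected(self):
        with pytest.raises(UsageError):
            scan_satellite(SeqRecord("c", "ACGTACGT"), SeqRecord("t", "ACGT" * 100))
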