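"""Homology blocks, Kimura divergence, stratified sampling, repeat content."""

import math

import numpy as np
import pytest

from msm_anatomy.errors import ValidationError
from msm_anatomy.msm_homology import (
    Block,
    divergence_profile,
    hits_to_blocks,
    homologous_proportion,
    kimura_from_alignment,
    pairwise_msm_homology,
    repeat_content,
    sample_hits_for_divergence,
    te_copy_bin,
)
from msm_anatomy.seqio_align import SeqRecord
from conftest import make_hsp, mutate, random_seq


class TestHitsToBlocks:
    def test_merge_example(self):
        hsps = [
            make_hsp(t_start=10, t_end=100, mapq=30),
            make_hsp(t_start=90, t_end=150, mapq=30),
            make_hsp(t_start=200, t_end=250, mapq=30),
        ]
        blocks = hits_to_blocks(hsps)
        assert blocks == [Block("t", 10, 150, 2), Block("t", 200, 250, 1)]

    def test_low_mapq_filtered_strictly(self):
        hsps = [make_hsp(t_start=0, t_end=50, mapq=10)]  # not > 10
        assert hits_to_blocks(hsps) == []

    def test_single_hit_single_block(self):
        hsps = [make_hsp(t_start=5, t_end=60, mapq=20)]
        assert hits_to_blocks(hsps) == [Block("t", 5, 60, 1)]

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            hsps = []
            for _ in range(int(rng.integers(1, 12))):
                s = int(rng.integers(0, 400))
                e = s + int(rng.integers(1, 80))
                hsps.append(make_hsp(t_start=s, t_end=e, mapq=int(rng.integers(0, 61))))
            blocks = hits_to_blocks(hsps)
            marked = np.zeros(600, dtype=bool)
            for h in hsps:
                if h.mapq > 10:
                    marked[h.t_start : h.t_end] = True
            block_marked = np.zeros(600, dtype=bool)
            for b in blocks:
                assert not block_marked[b.start : b.end].any()  # disjoint
                block_marked[b.start : b.end] = True
            assert (marked == block_marked).all()


class TestHomologousProportion:
    def test_half_aligned(self, rng):
        reads = [SeqRecord("r1", random_seq(rng, 500)), SeqRecord("r2", random_seq(rng, 500))]
        hsps = [make_hsp(query_id="r1", q_start=0, q_end=500, target_id="A01")]
        frac, per_chrom = homologous_proportion(hsps, reads)
        assert frac == pytest.approx(0.5)
        assert per_chrom == {"A01": 500}

    def test_no_hits(self, rng):
        reads = [SeqRecord("r1", random_seq(rng, 100))]
        assert homologous_proportion([], reads)[0] == 0.0

    def test_adding_hits_never_decreases(self, rng):
        reads = [SeqRecord("r1", random_seq(rng, 300))]
        hsps = []
        prev = 0.0
        rng2 = np.random.default_rng(4)
        for _ in range(10):
            s = int(rng2.integers(0, 250))
            hsps.append(make_hsp(query_id="r1", q_start=s, q_end=s + 50, target_id="A01"))
            frac, _ = homologous_proportion(hsps, reads)
            assert frac >= prev - 1e-12
            prev = frac

    def test_tie_attribution_lexicographic(self, rng):
        reads = [SeqRecord("r1", random_seq(rng, 100))]
        hsps = [
            make_hsp(query_id="r1", q_start=0, q_end=100, target_id="B02", score=50),
            make_hsp(query_id="r1", q_start=0, q_end=100, target_id="A01", score=50),
        ]
        _, per_chrom = homologous_proportion(hsps, reads)
        assert per_chrom == {"A01": 100}


class TestKimura:
    def test_identical_zero(self):
        est = kimura_from_alignment("ACGTACGT", "ACGTACGT")
        assert est.P == 0 and est.Q == 0 and est.d == 0

    def test_single_transition_quarter(self):
        est = kimura_from_alignment("AAAA", "AGAA")
        assert est.P == pytest.approx(0.25)
        assert est.Q == 0
        assert est.d == pytest.approx(-0.5 * math.log(0.5), abs=1e-9)

    def test_hand_computed_mixed_case(self):
        # 100 sites: 10 transitions, 5 transversions → P=0.1, Q=0.05
        q = list("A" * 100)
        t = list("A" * 100)
        for i in range(10):
            t[i] = "G"
        for i in range(10, 15):
            t[i] = "C"
        est = kimura_from_alignment("".join(q), "".join(t))
        assert est.P == pytest.approx(0.1)
        assert est.Q == pytest.approx(0.05)
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert est.d == pytest.approx(expected, abs=1e-12)
        assert est.d == pytest.approx(0.1702, abs=1e-4)

    def test_gaps_and_ambiguity_skipped(self):
        est = kimura_from_alignment("AC-GTN", "ACCGTA")
        assert est.n_sites == 4
        assert est.d == 0

    def test_saturated_flagged_not_raised(self):
        est = kimura_from_alignment("A" * 10, "G" * 10)  # P=1 → domain violation
        assert est.saturated and math.isnan(est.d)

    def test_monotone_in_transitions(self):
        prev = -1.0
        for n_ts in range(0, 30):
            t = "G" * n_ts + "A" * (100 - n_ts)
            est = kimura_from_alignment("A" * 100, t)
            assert est.d > prev
            prev = est.d

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            kimura_from_alignment("ACGT", "ACG")


class TestHitSampling:
    def _hits(self, lengths):
        return [make_hsp(aligned_length=L, identities=L, q_end=L, t_end=L) for L in lengths]

    def test_all_returned_when_exact(self):
        hits = self._hits([250] * 30 + [700] * 30 + [1500] * 30 + [2500] * 30)
        assert len(sample_hits_for_divergence(hits, 120, seed=0)) == 120

    def test_single_stratum_redistribution(self):
        hits = self._hits([300] * 1000)
        out = sample_hits_for_divergence(hits, 120, seed=0)
        assert len(out) == 120

    def test_deterministic(self):
        hits = self._hits(list(np.random.default_rng(0).integers(200, 3000, 500)))
        a = sample_hits_for_divergence(hits, 120, seed=42)
        b = sample_hits_for_divergence(hits, 120, seed=42)
        assert [id(h) for h in a] == [id(h) for h in b]

    def test_fewer_than_requested_returns_all(self):
        hits = self._hits([400] * 50)
        assert len(sample_hits_for_divergence(hits, 120, seed=0)) == 50


class TestDivergenceProfile:
    def test_all_zero_single_bin(self):
        ests = [kimura_from_alignment("ACGT" * 10, "ACGT" * 10) for _ in range(5)]
        edges, counts, modes = divergence_profile(ests)
        assert counts[0] == 5 and counts[1:].sum() == 0
        assert modes == [pytest.approx(0.005)]

    def test_uniform_spread_fills_bins(self):
        # construct estimates with d ≈ 0.005, 0.015, ..., 0.045
        ests = []
        for k in range(5):
            n_sub = 2 * k + 1
            t = "G" * n_sub + "A" * (200 - n_sub)
            ests.append(kimura_from_alignment("A" * 200, t))
        edges, counts, _ = divergence_profile(ests)
        assert (counts[:5] == 1).all()

    def test_empty(self):
        edges, counts, modes = divergence_profile([])
        assert len(counts) == 0 and modes == []


class TestRepeatContent:
    def test_every_read_contains_repeat(self, rng):
        te = random_seq(rng, 300)
        lib = [SeqRecord("TE01", te, "class=TE:TE01")]
        reads = [
            SeqRecord(f"r{i}", random_seq(rng, 100) + mutate(te, 0.02, rng) + random_seq(rng, 100))
            for i in range(6)
        ]
        summary = repeat_content(reads, lib)
        assert summary.reads_with_repeat == 1.0
        assert summary.repeat_bp_fraction["TE"] == pytest.approx(0.6, abs=0.1)

    def test_empty_library_zero(self, rng):
        reads = [SeqRecord("r1", random_seq(rng, 100))]
        summary = repeat_content(reads, [])
        assert summary.reads_with_repeat == 0.0

    def test_copy_bins(self):
        assert te_copy_bin(5) == "low"
        assert te_copy_bin(50) == "medium"
        assert te_copy_bin(101) == "high"
        with pytest.raises(ValidationError):
            te_copy_bin(0)

    def test_class_fractions_additive(self, rng):
        sat = random_seq(rng, 137)
        te = random_seq(rng, 200)
        lib = [SeqRecord("sat", sat, "class=satellite"), SeqRecord("TE01", te, "class=TE:TE01")]
        reads = [SeqRecord("r1", sat * 3 + te + random_seq(rng, 100))]
        s = repeat_content(reads, lib)
        assert sum(s.repeat_bp_fraction.values()) <= 1.0 + 1e-9


class TestPairwiseHomology:
    def test_identical_sets_full_homology(self, rng):
        reads = [SeqRecord(f"r{i}", random_seq(rng, 1200)) for i in range(5)]
        frac = pairwise_msm_homology(reads, [SeqRecord(f"b{i}", r.sequence) for i, r in enumerate(reads)])
        assert frac >= 0.95

    def test_dissimilar_near_zero(self, rng):
        a = [SeqRecord(f"a{i}", random_seq(rng, 1200)) for i in range(4)]
        b = [SeqRecord(f"b{i}", random_seq(rng, 1200)) for i in range(4)]
        assert pairwise_msm_homology(a, b) < 0.05

    def test_empty_rejected(self, rng):
        with pytest.raises(ValidationError):
            pairwise_msm_homology([], [SeqRecord("b", random_seq(rng, 100))])
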