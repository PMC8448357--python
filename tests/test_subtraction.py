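"""The two-round subtraction rule, fragment definition, and collapse."""

import numpy as np
import pytest

from msm_anatomy.seqio_align import Hsp, SeqRecord
from msm_anatomy.subtraction_pipeline import (
    Fragment,
    collapse_fragments,
    define_fragments,
    longest_orf_length,
    run_subtraction,
    second_round,
    subtract,
    subtraction_decision,
)
from conftest import make_hsp, mutate, random_seq


def _aligner_returning(hsps):
    return lambda queries, reference: hsps


def _hsp_cov_id(qid, coverage, identity, qlen=1000, target="ref1"):
    """One HSP giving exactly the requested coverage and identity."""
    alen = int(round(coverage * qlen))
    return make_hsp(
        query_id=qid,
        target_id=target,
        q_start=0,
        q_end=alen,
        t_start=0,
        t_end=alen,
        aligned_length=alen,
        identities=int(round(identity * alen)),
    )


class TestSubtractRule:
    def setup_method(self):
        self.q = SeqRecord("q1", "A" * 1000)
        self.ref = [SeqRecord("ref1", "C" * 2000)]

    def test_high_coverage_high_identity_discarded(self):
        hsps = [_hsp_cov_id("q1", 0.95, 0.99)]
        kept, discarded = subtract([self.q], self.ref, aligner=_aligner_returning(hsps))
        assert kept == [] and [d.id for d in discarded] == ["q1"]

    def test_identity_boundary_strict(self):
        hsps = [_hsp_cov_id("q1", 0.95, 0.98)]  # identity exactly 98%
        kept, _ = subtract([self.q], self.ref, aligner=_aligner_returning(hsps))
        assert [k.id for k in kept] == ["q1"]

    def test_coverage_boundary_strict(self):
        hsps = [_hsp_cov_id("q1", 0.90, 0.99)]  # coverage exactly 90%
        kept, _ = subtract([self.q], self.ref, aligner=_aligner_returning(hsps))
        assert [k.id for k in kept] == ["q1"]

    def test_empty_reference_keeps_all(self):
        kept, discarded = subtract([self.q], [])
        assert [k.id for k in kept] == ["q1"] and discarded == []

    def test_per_target_not_pooled(self):
        # two targets each explaining half the query never trigger a discard
        a = _hsp_cov_id("q1", 0.5, 1.0, target="ref1")
        b = make_hsp(query_id="q1", target_id="ref2", q_start=500, q_end=1000,
                     t_start=0, t_end=500, aligned_length=500, identities=500)
        kept, _ = subtract([self.q], self.ref + [SeqRecord("ref2", "G" * 2000)],
                           aligner=_aligner_returning([a, b]))
        assert [k.id for k in kept] == ["q1"]

    def test_counts_conserved(self, rng):
        queries = [SeqRecord(f"q{i}", random_seq(rng, 300)) for i in range(10)]
        hsps = [_hsp_cov_id(f"q{i}", 0.95, 0.99, qlen=300) for i in range(0, 10, 2)]
        kept, discarded = subtract(queries, self.ref, aligner=_aligner_returning(hsps))
        assert len(kept) + len(discarded) == len(queries)
        assert {k.id for k in kept} | {d.id for d in discarded} == {q.id for q in queries}


class TestDefineFragments:
    def test_definitional_thresholds(self, rng):
        read = SeqRecord("read1", random_seq(rng, 1000))
        good = make_hsp(query_id="t1", target_id="read1", t_start=100, t_end=350,
                        aligned_length=250, identities=200, q_end=250)  # 0.80 over 250
        short = make_hsp(query_id="t2", target_id="read1", t_start=400, t_end=550,
                         aligned_length=150, identities=143, q_end=150)  # 0.95 over 150
        frags = define_fragments(
            [SeqRecord("t1", "A" * 300), SeqRecord("t2", "A" * 300)],
            [read],
            aligner=_aligner_returning([good, short]),
        )
        assert len(frags) == 1
        f = frags[0]
        assert (f.start, f.end) == (100, 350)
        assert f.sequence == read.sequence[100:350]

    def test_transcript_matching_two_reads_two_fragments(self, rng):
        reads = [SeqRecord("r1", random_seq(rng, 600)), SeqRecord("r2", random_seq(rng, 600))]
        hsps = [
            make_hsp(query_id="t1", target_id=r.id, t_start=0, t_end=250,
                     aligned_length=250, identities=240, q_end=250)
            for r in reads
        ]
        frags = define_fragments([SeqRecord("t1", "A" * 300)], reads,
                                 aligner=_aligner_returning(hsps))
        assert len(frags) == 2
        assert {f.msm_read_id for f in frags} == {"r1", "r2"}

    def test_empty_inputs(self):
        assert define_fragments([], [], aligner=_aligner_returning([])) == []


def _frag(fid, seq, start=0):
    return Fragment(
        fragment_id=fid,
        msm_read_id="read1",
        start=start,
        end=start + len(seq),
        source_transcript_id="t1",
        identity=0.9,
        sequence=seq,
    )


class TestSecondRound:
    def test_genome_contained_fragment_removed(self, rng):
        seq = random_seq(rng, 400)
        frag = _frag("f1", seq)
        out = second_round([frag], [], [SeqRecord("chr1", "TTT" + seq + "GGG")])
        assert out[0].status == "removed_genome"

    def test_novel_fragment_stays_candidate(self, rng):
        frag = _frag("f1", random_seq(rng, 400))
        out = second_round([frag], [[SeqRecord("x", random_seq(rng, 500))]],
                           [SeqRecord("chr1", random_seq(rng, 2000))])
        assert out[0].status == "candidate"

    def test_transcriptome_cause_takes_precedence(self, rng):
        seq = random_seq(rng, 400)
        frag = _frag("f1", seq)
        out = second_round([frag], [[SeqRecord("tr", seq)]], [SeqRecord("chr1", seq)])
        assert out[0].status == "removed_transcriptome"


class TestCollapse:
    def test_identical_fragments_one_representative(self, rng):
        seq = random_seq(rng, 300)
        frags = [_frag("f1", seq), _frag("f2", seq)]
        reps = collapse_fragments(frags)
        assert [r.fragment_id for r in reps] == ["f1"]
        assert frags[1].status == "collapsed_into:f1"

    def test_dissimilar_fragments_kept_apart(self, rng):
        frags = [_frag("f1", random_seq(rng, 300)), _frag("f2", random_seq(rng, 300))]
        assert len(collapse_fragments(frags)) == 2

    def test_single_linkage_chain(self, rng):
        # a≈b and b≈c through different halves of b; a and c share nothing
        left, right = random_seq(rng, 260), random_seq(rng, 260)
        a = _frag("fa", left)
        b = _frag("fb", left + right)
        c = _frag("fc", right)
        reps = collapse_fragments([a, b, c])
        assert [r.fragment_id for r in reps] == ["fb"]  # longest of the chain
        assert a.status == "collapsed_into:fb" and c.status == "collapsed_into:fb"

    def test_matches_bruteforce_grouping_on_planted_families(self, rng):
        # planted truth: fragments within a family are near-copies, between
        # families unrelated — expected representatives = one per family
        n_fam = 4
        fams = [random_seq(rng, 280) for _ in range(n_fam)]
        frags = []
        k = 0
        for fi, fam in enumerate(fams):
            for _ in range(int(rng.integers(1, 4))):
                frags.append(_frag(f"f{k:02d}", mutate(fam, 0.02, rng)))
                k += 1
        reps = collapse_fragments(frags)
        assert len(reps) == n_fam


class TestRunSubtraction:
    def test_references_equal_to_transcripts_remove_everything(self, rng):
        transcripts = [SeqRecord(f"t{i}", random_seq(rng, 500)) for i in range(3)]
        report = run_subtraction(
            msm_linked_transcripts=transcripts,
            msm_reads=[SeqRecord("read1", random_seq(rng, 800))],
            transcriptome_refs=[[SeqRecord(f"ref{i}", t.sequence) for i, t in enumerate(transcripts)]],
            genome_ref=[SeqRecord("chr1", random_seq(rng, 2000))],
        )
        assert report.stage_counts["after_transcriptome_1"] == 0
        assert report.stage_counts["unique_candidates"] == 0

    def test_empty_read_set_clean_report(self, rng):
        transcripts = [SeqRecord("t1", random_seq(rng, 500))]
        report = run_subtraction(
            msm_linked_transcripts=transcripts,
            msm_reads=[],
            transcriptome_refs=[[SeqRecord("x", random_seq(rng, 500))]],
            genome_ref=[SeqRecord("chr1", random_seq(rng, 2000))],
        )
        assert report.stage_counts["fragments"] == 0
        assert report.stage_counts["unique_candidates"] == 0

    def test_planted_unique_transcript_survives(self, rng):
        shared = random_seq(rng, 600)
        unique = random_seq(rng, 600)
        reads = [SeqRecord("read1", random_seq(rng, 100) + unique + random_seq(rng, 100))]
        report = run_subtraction(
            msm_linked_transcripts=[SeqRecord("t_shared", shared), SeqRecord("t_unique", unique)],
            msm_reads=reads,
            transcriptome_refs=[[SeqRecord("ref1", shared)]],
            genome_ref=[SeqRecord("chr1", random_seq(rng, 3000))],
        )
        assert report.removed_round1 == {"t_shared": "transcriptome_1"}
        assert report.stage_counts["unique_candidates"] == 1
        rep = report.representatives[0]
        assert rep.source_transcript_id == "t_unique"


def test_longest_orf_detects_planted_frame(rng):
    inner = "".join(np.random.default_rng(5).choice(
        ["GCA", "CTG", "GAA", "TTC"], 40))  # stop-free codons
    seq = random_seq(rng, 30) + "ATG" + inner + "TAA" + random_seq(rng, 30)
    assert longest_orf_length(seq) >= 3 + 120 + 3
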