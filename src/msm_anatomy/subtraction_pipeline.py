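"""Two-round transcriptome/genome subtraction for male-specific fragments.

Transcripts linked to the male-specific microchromosomes are first purged of
anything explainable by MSM-free references: a transcript is discarded when,
against ANY single reference sequence, its aligned coverage exceeds 90% of
its full length AND the cumulative identity of those alignments exceeds 98%
(both strict).  Survivors are re-anchored on the MSM reads as *gene
fragments* (identity > 75% over ≥ 200 bp — the definitional minimum), the
same subtraction is applied to the fragments themselves, and redundant
candidates are collapsed by single-linkage overlap clustering into unique
representatives.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace  # noqa: F401

import networkx as nx

from ._kmers import candidates_against
from .errors import ValidationError
from .seqio_align import AlignParams, Hsp, SeqRecord, local_align, merge_intervals, minimap2_align

logger = logging.getLogger(__name__)


@dataclass
class Fragment:
    """An MSM-read interval matched by a subtraction-surviving transcript."""

    fragment_id: str
    msm_read_id: str
    start: int
    end: int
    source_transcript_id: str
    identity: float
    sequence: str
    status: str = "candidate"

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValidationError("empty fragment interval")


@dataclass
class SubtractionReport:
    """Per-stage accounting of one full subtraction run."""

    kept_round1: list[SeqRecord] = field(default_factory=list)
    removed_round1: dict[str, str] = field(default_factory=dict)  # id -> cause
    fragments: list[Fragment] = field(default_factory=list)
    candidates: list[Fragment] = field(default_factory=list)
    representatives: list[Fragment] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)


def _auto_aligner(queries: list[SeqRecord], reference: list[SeqRecord]) -> list[Hsp]:
    """local SW for small references, minimap2 beyond desk scale."""
    total_ref = sum(len(r) for r in reference)
    if total_ref > 200_000:
        return minimap2_align(queries, reference, preset="map-ont", reconstruct=False)
    cands = candidates_against(queries, reference, min_shared=8)
    params = AlignParams(min_score=100.0, max_hsps=10)
    out: list[Hsp] = []
    for q in queries:
        out.extend(local_align(q, cands[q.id], params))
    return out


def subtraction_decision(
    hsps_by_target: dict[str, list[Hsp]],
    query_length: int,
    cov_threshold: float = 0.90,
    id_threshold: float = 0.98,
) -> bool:
    """The discard rule for one query: True when ANY reference target
    explains it at coverage > cov_threshold AND identity > id_threshold
    (both strict).  Coverage is the union of the query intervals of that
    target's HSPs over the query's full length; identity is the cumulative
    (length-weighted) identity of those HSPs."""
    for hs in hsps_by_target.values():
        covered = sum(e - s for s, e in merge_intervals((h.q_start, h.q_end) for h in hs))
        coverage = covered / query_length
        sum_al = sum(h.aligned_length for h in hs)
        identity = sum(h.identities for h in hs) / sum_al if sum_al else 0.0
        if coverage > cov_threshold and identity > id_threshold:
            return True
    return False


def subtract(
    queries: list[SeqRecord],
    reference: list[SeqRecord],
    cov_threshold: float = 0.90,
    id_threshold: float = 0.98,
    aligner=None,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Partition queries into (kept, discarded) against one reference set."""
    if not (0 < cov_threshold <= 1) or not (0 < id_threshold <= 1):
        raise ValidationError("thresholds must be in (0, 1]")
    if not reference:
        logger.warning("empty reference: keeping all %d queries", len(queries))
        return list(queries), []
    if aligner is None:
        aligner = _auto_aligner
    hsps = aligner(queries, reference)
    by_query: dict[str, dict[str, list[Hsp]]] = defaultdict(lambda: defaultdict(list))
    for h in hsps:
        by_query[h.query_id][h.target_id].append(h)
    kept, discarded = [], []
    for q in queries:
        if subtraction_decision(by_query.get(q.id, {}), len(q), cov_threshold, id_threshold):
            discarded.append(q)
        else:
            kept.append(q)
    return kept, discarded


def define_fragments(
    transcripts: list[SeqRecord],
    msm_reads: list[SeqRecord],
    id_threshold: float = 0.75,
    min_len: int = 200,
    aligner=None,
) -> list[Fragment]:
    """Anchor surviving transcripts on MSM reads as gene fragments.

    Every HSP with identity strictly above ``id_threshold`` and aligned
    length ≥ ``min_len`` becomes one fragment carrying the read subsequence;
    ids are deterministic in (read, start, transcript) order.
    """
    if not transcripts or not msm_reads:
        return []
    if aligner is None:
        cands = candidates_against(transcripts, msm_reads, min_shared=8)
        params = AlignParams(min_score=150.0, max_hsps=10)
        hsps = []
        for t in transcripts:
            hsps.extend(local_align(t, cands[t.id], params))
    else:
        hsps = aligner(transcripts, msm_reads)
    read_seq = {r.id: r.sequence for r in msm_reads}
    raw = [
        h
        for h in hsps
        if h.identity > id_threshold and h.aligned_length >= min_len and h.target_id in read_seq
    ]
    raw.sort(key=lambda h: (h.target_id, h.t_start, h.t_end, h.query_id))
    fragments = []
    for i, h in enumerate(raw, start=1):
        fragments.append(
            Fragment(
                fragment_id=f"frag{i:05d}",
                msm_read_id=h.target_id,
                start=h.t_start,
                end=h.t_end,
                source_transcript_id=h.query_id,
                identity=h.identity,
                sequence=read_seq[h.target_id][h.t_start : h.t_end],
            )
        )
    return fragments


def second_round(
    fragments: list[Fragment],
    transcriptome_refs: list[list[SeqRecord]],
    genome_ref: list[SeqRecord],
    cov_threshold: float = 0.90,
    id_threshold: float = 0.98,
    aligner=None,
) -> list[Fragment]:
    """Re-apply the subtraction rule to the fragments themselves.

    Fragments explainable by any MSM-free transcriptome are labelled
    ``removed_transcriptome``, then survivors explainable by the female
    genome are labelled ``removed_genome``; the rest stay ``candidate``.
    """
    out: dict[str, Fragment] = {f.fragment_id: replace(f) for f in fragments}
    current = [SeqRecord(f.fragment_id, f.sequence) for f in fragments]
    for refs, cause in [*((r, "removed_transcriptome") for r in transcriptome_refs), (genome_ref, "removed_genome")]:
        if not current:
            break
        kept, discarded = subtract(current, refs, cov_threshold, id_threshold, aligner=aligner)
        for rec in discarded:
            out[rec.id].status = cause
        current = kept
    return [out[f.fragment_id] for f in fragments]


def collapse_fragments(
    fragments: list[Fragment],
    overlap_id: float = 0.90,
    overlap_cov: float = 0.80,
) -> list[Fragment]:
    """Collapse highly overlapping candidate fragments (single linkage).

    Two fragments link when a pairwise alignment covers ≥ ``overlap_cov``
    of the shorter at identity ≥ ``overlap_id``.  Each group's longest
    member (ties: lexicographically smallest id) represents it; the rest are
    labelled ``collapsed_into:<representative>``.
    """
    cands = [f for f in fragments if f.status == "candidate"]
    records = {f.fragment_id: SeqRecord(f.fragment_id, f.sequence) for f in cands}
    g = nx.Graph()
    g.add_nodes_from(records)
    params = AlignParams(min_score=60.0, max_hsps=3)
    recs = [records[f.fragment_id] for f in cands]
    cand_map = candidates_against(recs, recs, min_shared=5)
    for a in recs:
        for b in cand_map[a.id]:
            if b.id <= a.id:
                continue
            shorter = min(len(a), len(b))
            for h in local_align(a, [b], params):
                span = min(h.q_end - h.q_start, h.t_end - h.t_start)
                if h.identity >= overlap_id and span >= overlap_cov * shorter:
                    g.add_edge(a.id, b.id)
                    break
    by_id = {f.fragment_id: f for f in cands}
    representatives = []
    for comp in nx.connected_components(g):
        # longest fragment represents the group; ties go to the smallest id
        best_len = max(by_id[f].end - by_id[f].start for f in comp)
        rep = sorted(f for f in comp if by_id[f].end - by_id[f].start == best_len)[0]
        representatives.append(by_id[rep])
        for fid in comp:
            if fid != rep:
                by_id[fid].status = f"collapsed_into:{rep}"
    representatives.sort(key=lambda f: f.fragment_id)
    return representatives


def longest_orf_length(seq: str) -> int:
    """Longest open reading frame (start-to-stop, either strand), in bp.

    A light coding-potential indicator reported for collapsed candidates.
    """
    from .seqio_align import revcomp

    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for s in (seq, revcomp(seq)):
        for frame in range(3):
            start = None
            for i in range(frame, len(s) - 2, 3):
                codon = s[i : i + 3]
                if codon == "ATG" and start is None:
                    start = i
                elif codon in stops and start is not None:
                    best = max(best, i + 3 - start)
                    start = None
    return best


def run_subtraction(
    msm_linked_transcripts: list[SeqRecord],
    msm_reads: list[SeqRecord],
    transcriptome_refs: list[list[SeqRecord]],
    genome_ref: list[SeqRecord],
    cov_threshold: float = 0.90,
    id_threshold: float = 0.98,
    fragment_identity: float = 0.75,
    fragment_min_len: int = 200,
    overlap_id: float = 0.90,
    overlap_cov: float = 0.80,
    aligner=None,
) -> SubtractionReport:
    """The full two-round subtraction with per-stage accounting."""
    report = SubtractionReport()
    current = list(msm_linked_transcripts)
    report.stage_counts["input_transcripts"] = len(current)
    for i, refs in enumerate(transcriptome_refs, start=1):
        kept, discarded = subtract(current, refs, cov_threshold, id_threshold, aligner=aligner)
        for rec in discarded:
            report.removed_round1[rec.id] = f"transcriptome_{i}"
        report.stage_counts[f"after_transcriptome_{i}"] = len(kept)
        current = kept
    kept, discarded = subtract(current, genome_ref, cov_threshold, id_threshold, aligner=aligner)
    for rec in discarded:
        report.removed_round1[rec.id] = "genome"
    report.stage_counts["after_genome"] = len(kept)
    report.kept_round1 = kept

    fragments = define_fragments(
        kept, msm_reads, id_threshold=fragment_identity, min_len=fragment_min_len, aligner=aligner
    )
    report.stage_counts["fragments"] = len(fragments)
    fragments = second_round(
        fragments, transcriptome_refs, genome_ref, cov_threshold, id_threshold, aligner=aligner
    )
    report.fragments = fragments
    report.candidates = [f for f in fragments if f.status == "candidate"]
    report.stage_counts["fragments_removed_round2"] = sum(
        1 for f in fragments if f.status.startswith("removed")
    )
    report.stage_counts["candidate_fragments"] = len(report.candidates)
    report.representatives = collapse_fragments(fragments, overlap_id, overlap_cov)
    report.stage_counts["unique_candidates"] = len(report.representatives)
    return report
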