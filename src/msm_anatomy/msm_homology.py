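"""Homology anatomy of microchromosome read sets.

Reads from a microdissected microchromosome are mapped to a reference
genome; confidently placed hits (MapQ strictly above a cut-off, matching the
mapper's uniqueness convention) are merged into homology blocks per linkage
group, the fraction of read bases with a homologous placement is tallied,
and the age structure of the homology is profiled with Kimura two-parameter
distances computed on the actual alignment columns of a length-stratified
hit sample.  The same machinery summarises repeat content against a labelled
repeat library.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._kmers import shared_kmer_filter
from .errors import ValidationError
from .seqio_align import AlignParams, Hsp, SeqRecord, local_align, merge_intervals, minimap2_align

logger = logging.getLogger(__name__)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
VALID = set("ACGT")


@dataclass(frozen=True)
class Block:
    """A merged homology block on one reference linkage group."""

    chrom: str
    start: int
    end: int
    n_hits: int


@dataclass(frozen=True)
class KimuraEstimate:
    """Kimura two-parameter divergence of one aligned hit.

    ``d = −½·ln((1−2P−Q)·sqrt(1−2Q))`` with P the transition and Q the
    transversion proportion over ungapped, unambiguous columns.  Outside the
    formula's domain the estimate is flagged saturated and ``d`` is NaN.
    """

    P: float
    Q: float
    d: float
    n_sites: int
    saturated: bool = False


@dataclass
class RepeatSummary:
    reads_with_repeat: float
    repeat_bp_fraction: dict[str, float]
    te_copy_bins: dict[str, int]
    te_family_hits: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------


def hits_to_blocks(hsps: list[Hsp], mapq_min: int = 10) -> list[Block]:
    """Merge confidently mapped hits into per-chromosome blocks.

    The MapQ filter is strict (``mapq > mapq_min``); overlapping or
    bookended target intervals merge, and each block records how many hits
    support it.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for h in hsps:
        if h.mapq > mapq_min:
            by_chrom[h.target_id].append((h.t_start, h.t_end))
    blocks: list[Block] = []
    for chrom in sorted(by_chrom):
        ivs = by_chrom[chrom]
        for s, e in merge_intervals(ivs):
            n = sum(1 for hs, he in ivs if min(he, e) - max(hs, s) > 0 or (hs, he) == (s, e))
            blocks.append(Block(chrom, s, e, n))
    return blocks


def homologous_proportion(
    hsps: list[Hsp], reads: list[SeqRecord]
) -> tuple[float, dict[str, int]]:
    """Fraction of read bases with a homologous placement, plus the
    per-linkage-group base tally.

    Each read base is attributed to the best-scoring hit covering it (ties
    to the lexicographically smallest chromosome); the overall proportion is
    attributed bases over all read bases, unmapped reads included.
    """
    read_len = {r.id: len(r) for r in reads}
    by_query: dict[str, list[Hsp]] = defaultdict(list)
    for h in hsps:
        if h.query_id in read_len:
            by_query[h.query_id].append(h)
    total = sum(read_len.values())
    per_chrom: dict[str, int] = defaultdict(int)
    covered_total = 0
    for qid, qh in by_query.items():
        qh.sort(key=lambda h: (-h.score, h.target_id))
        claimed = np.zeros(read_len[qid], dtype=bool)
        for h in qh:
            span = slice(h.q_start, h.q_end)
            newly = ~claimed[span]
            n_new = int(newly.sum())
            if n_new:
                per_chrom[h.target_id] += n_new
                claimed[span] = True
        covered_total += int(claimed.sum())
    overall = covered_total / total if total else 0.0
    return overall, dict(per_chrom)


# ---------------------------------------------------------------------------
# divergence


def kimura_from_alignment(q_aln: str, t_aln: str) -> KimuraEstimate:
    """K2P divergence from a pair of equal-length gapped strings."""
    if len(q_aln) != len(t_aln):
        raise ValidationError("aligned strings must have equal length")
    transitions = transversions = n_sites = 0
    for a, b in zip(q_aln.upper(), t_aln.upper()):
        if a not in VALID or b not in VALID:
            continue
        n_sites += 1
        if a == b:
            continue
        if (a, b) in TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    if n_sites == 0:
        raise ValidationError("no ungapped, unambiguous columns in alignment")
    P = transitions / n_sites
    Q = transversions / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return KimuraEstimate(P=P, Q=Q, d=float("nan"), n_sites=n_sites, saturated=True)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return KimuraEstimate(P=P, Q=Q, d=d, n_sites=n_sites)


def kimura_from_hsp(hsp: Hsp) -> KimuraEstimate:
    if hsp.q_aln is None or hsp.t_aln is None:
        raise ValidationError("hit carries no aligned strings")
    return kimura_from_alignment(hsp.q_aln, hsp.t_aln)


def alignment_gap_fraction(hsp: Hsp) -> float:
    """Fraction of alignment columns that are gaps.

    Gap-heavy hits are usually chains stitched across unrelated flanking
    sequence; their substitution proportions do not estimate the divergence
    of any one homologous segment, so divergence profiling screens them out.
    """
    if hsp.q_aln is None or hsp.t_aln is None:
        raise ValidationError("hit carries no aligned strings")
    gaps = sum(1 for a, b in zip(hsp.q_aln, hsp.t_aln) if a == "-" or b == "-")
    return gaps / max(1, len(hsp.q_aln))


STRATA = ((200, 500), (500, 1000), (1000, 2000), (2000, None))


def sample_hits_for_divergence(hsps: list[Hsp], n_total: int = 120, seed: int = 0) -> list[Hsp]:
    """Stratified hit sample for divergence profiling.

    Hits are bucketed by aligned length into the strata [200,500), [500,1000),
    [1000,2000), [2000,∞) with an equal quota per stratum; deficits in thin
    strata are redistributed to the others.  Deterministic under seed.
    """
    if not hsps:
        raise ValidationError("no hits to sample")
    rng = np.random.default_rng(seed)
    buckets: list[list[Hsp]] = [[] for _ in STRATA]
    for h in hsps:
        L = h.aligned_length
        for i, (lo, hi) in enumerate(STRATA):
            if L >= lo and (hi is None or L < hi):
                buckets[i].append(h)
                break
    eligible = sum(len(b) for b in buckets)
    if eligible <= n_total:
        if eligible < n_total:
            logger.warning(
                "only %d hits in the sampling strata (requested %d); returning all",
                eligible,
                n_total,
            )
        return [h for b in buckets for h in b]
    quota = [n_total // len(STRATA)] * len(STRATA)
    quota[0] += n_total - sum(quota)
    # redistribute deficits until quotas are feasible
    for _ in range(len(STRATA)):
        deficit = 0
        for i, b in enumerate(buckets):
            if quota[i] > len(b):
                deficit += quota[i] - len(b)
                quota[i] = len(b)
        if deficit == 0:
            break
        spare = [i for i in range(len(STRATA)) if quota[i] < len(buckets[i])]
        while deficit and spare:
            for i in list(spare):
                if deficit == 0:
                    break
                if quota[i] < len(buckets[i]):
                    quota[i] += 1
                    deficit -= 1
                else:
                    spare.remove(i)
    chosen: list[Hsp] = []
    for i, b in enumerate(buckets):
        order = sorted(b, key=lambda h: (h.query_id, h.target_id, h.t_start))
        idx = rng.choice(len(order), size=quota[i], replace=False)
        chosen.extend(order[j] for j in sorted(idx))
    return chosen


def divergence_profile(
    estimates: list[KimuraEstimate], bin_width: float = 0.01
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Histogram of K2P distances plus its modes.

    Returns (bin_edges, counts, modes).  Mode detection runs on a 1-2-1
    smoothed copy of the histogram (a broad divergence peak spreads over
    neighbouring bins; smoothing keeps it from losing to a narrow spurious
    spike): local maxima with ≥15% of the tallest smoothed bin, reported
    tallest first, located at the weighted centre of the maximum and its
    neighbours.  Saturated estimates are excluded.
    """
    ds = np.array([e.d for e in estimates if not e.saturated])
    if ds.size == 0:
        return np.array([0.0]), np.array([], dtype=int), []
    n_bins = int(np.ceil((ds.max() + 1e-9) / bin_width)) + 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, edges = np.histogram(ds, bins=edges)
    padded = np.concatenate([[0], counts.astype(float), [0]])
    smooth = (padded[:-2] + 2 * padded[1:-1] + padded[2:]) / 4
    centres = (edges[:-1] + edges[1:]) / 2
    modes = []
    for i in range(len(smooth)):
        left = smooth[i - 1] if i > 0 else -1.0
        right = smooth[i + 1] if i < len(smooth) - 1 else -1.0
        if smooth[i] > left and smooth[i] >= right and smooth[i] >= 0.15 * smooth.max():
            lo, hi = max(0, i - 1), min(len(smooth), i + 2)
            w = counts[lo:hi].astype(float)
            centre = float(np.average(centres[lo:hi], weights=w)) if w.sum() else float(centres[i])
            modes.append((smooth[i], centre))
    modes.sort(key=lambda m: -m[0])
    return edges, counts, [round(float(m[1]), 10) for m in modes]


# ---------------------------------------------------------------------------
# pairwise homology + repeat content


def pairwise_msm_homology(
    msm_a_reads: list[SeqRecord],
    msm_b_reads: list[SeqRecord],
    aligner=None,
) -> float:
    """Fraction of MSM-a read bases homologous to MSM-b reads (directional)."""
    if not msm_a_reads or not msm_b_reads:
        raise ValidationError("both read sets must be non-empty")
    if aligner is None:
        aligner = lambda q, r: minimap2_align(
            q, r, preset="map-ont", reconstruct=False, base_level=False
        )
    hsps = aligner(msm_a_reads, msm_b_reads)
    frac, _ = homologous_proportion(hsps, msm_a_reads)
    return frac


def repeat_content(
    reads: list[SeqRecord],
    repeat_library: list[SeqRecord],
    min_identity: float = 0.80,
    min_length: int = 30,
) -> RepeatSummary:
    """Mask reads with a labelled repeat library and summarise.

    Library records carry ``class=satellite``, ``class=TE:<family>`` or
    ``class=unknown`` in their descriptions.  Overlapping masks resolve to
    the higher-scoring hit, so per-class base fractions are additive.
    TE families are binned by masked copy count: low 1–10, medium 11–100,
    high >100.
    """
    if not repeat_library:
        logger.warning("empty repeat library: returning all-zero summary")
        return RepeatSummary(0.0, {"satellite": 0.0, "TE": 0.0, "unknown": 0.0}, {})
    klass_of = {}
    for rec in repeat_library:
        klass = "unknown"
        for tok in rec.description.split():
            if tok.startswith("class="):
                klass = tok[len("class="):]
        klass_of[rec.id] = klass

    params = AlignParams(min_score=36.0, max_hsps=60)
    pair_ok = shared_kmer_filter(k=13, min_shared=3)
    total_bp = sum(len(r) for r in reads)
    class_bp: dict[str, int] = defaultdict(int)
    family_hits: dict[str, int] = defaultdict(int)
    n_with_repeat = 0
    for read in reads:
        lib = [t for t in repeat_library if pair_ok(t, read)]
        hits: list[Hsp] = []
        for target in lib:
            # library record is the query so monomer-sized hits are found
            hits.extend(
                h
                for h in local_align(SeqRecord(target.id, target.sequence), [read], params)
                if h.identity >= min_identity and (h.t_end - h.t_start) >= min_length
            )
        if not hits:
            continue
        n_with_repeat += 1
        hits.sort(key=lambda h: (-h.score, h.t_start, h.query_id))
        claimed = np.zeros(len(read), dtype=bool)
        for h in hits:
            span = slice(h.t_start, h.t_end)
            newly = ~claimed[span]
            n_new = int(newly.sum())
            if n_new == 0:
                continue
            klass = klass_of[h.query_id]
            key = "TE" if klass.startswith("TE:") else klass
            class_bp[key] += n_new
            claimed[span] = True
            if klass.startswith("TE:"):
                family_hits[klass[3:]] += 1
    bins = {"low": 0, "medium": 0, "high": 0}
    for fam, n in family_hits.items():
        if n <= 10:
            bins["low"] += 1
        elif n <= 100:
            bins["medium"] += 1
        else:
            bins["high"] += 1
    fractions = {
        k: class_bp.get(k, 0) / total_bp if total_bp else 0.0
        for k in ("satellite", "TE", "unknown")
    }
    return RepeatSummary(
        reads_with_repeat=n_with_repeat / len(reads) if reads else 0.0,
        repeat_bp_fraction=fractions,
        te_copy_bins=bins,
        te_family_hits=dict(sorted(family_hits.items())),
    )


def te_copy_bin(n_copies: int) -> str:
    """Copy-number bin of one TE family: low 1–10, medium 11–100, high >100."""
    if n_copies <= 0:
        raise ValidationError("bin defined for ≥1 copy")
    if n_copies <= 10:
        return "low"
    if n_copies <= 100:
        return "medium"
    return "high"
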