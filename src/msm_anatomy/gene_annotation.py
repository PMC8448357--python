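"""Gene content of microchromosome read sets.

Genes are identified on MSM reads by two complementary routes against two
reference sets (a gonadal transcriptome and a multi-species CDS pool):

* a mapping route — hits with MapQ ≥ 10 and aligned length ≥ 200 bp;
* a similarity route — hits with identity > 75% and aligned length ≥ 200 bp.

A gene is called on an MSM when either route fires.  Per-query homology is
summarised with the cumulative statistics

* CIP (cumulative identity percentage) = 100·ΣID / ΣAL over the query's
  HSPs, and
* CALP (cumulative alignment length percentage) = 100·ΣAL / query length
  (deliberately uncapped: overlapping HSPs can push it past 100),

which also link CDS-pool entries to transcripts (CIP ≥ 60 and CALP ≥ 70).
Gene integrity is the fraction of the full-length coding sequence covered by
the union of its MSM hit intervals, binned as <10%, 10–50% and >50% (the
top bin strictly above 50%).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from ._kmers import candidates_against
from .errors import UsageError, ValidationError
from .seqio_align import AlignParams, Hsp, SeqRecord, local_align, merge_intervals, minimap2_align

BIN_LOW, BIN_MID, BIN_HIGH = "<10%", "10-50%", ">50%"


@dataclass(frozen=True)
class CallThresholds:
    mapping_min_mapq: int = 10          # non-strict (≥)
    mapping_min_len: int = 200
    similarity_min_identity: float = 0.75  # strict (>)
    similarity_min_len: int = 200
    link_min_cip: float = 60.0
    link_min_calp: float = 70.0


@dataclass
class GeneCall:
    gene_id: str
    msm_id: str
    route: str  # "transcriptome" | "cds_pool"
    cip: float | None
    calp: float
    supporting: list[Hsp] = field(default_factory=list)


@dataclass(frozen=True)
class IntegrityScore:
    gene_id: str
    covered_fraction: float
    bin: str


def cip_calp(hsps: list[Hsp], query_length: int) -> tuple[float | None, float]:
    """Cumulative identity and alignment-length percentages of one query.

    CIP = 100·Σidentities/Σaligned_length; CALP = 100·Σaligned_length/query
    length.  With no HSPs the CIP is undefined (None) and CALP is 0.
    """
    if query_length <= 0:
        raise ValidationError("query_length must be positive")
    if not hsps:
        return None, 0.0
    qids = {h.query_id for h in hsps}
    if len(qids) > 1:
        raise ValidationError(f"cip_calp expects one query, got {sorted(qids)}")
    sum_al = sum(h.aligned_length for h in hsps)
    sum_id = sum(h.identities for h in hsps)
    return 100.0 * sum_id / sum_al, 100.0 * sum_al / query_length


def _route_mapping(h: Hsp, thr: CallThresholds) -> bool:
    return h.mapq >= thr.mapping_min_mapq and h.aligned_length >= thr.mapping_min_len


def _route_similarity(h: Hsp, thr: CallThresholds) -> bool:
    return h.identity > thr.similarity_min_identity and h.aligned_length >= thr.similarity_min_len


def call_genes(
    msm_reads: dict[str, list[SeqRecord]],
    transcriptome: list[SeqRecord],
    cds_pool: list[SeqRecord],
    gene_map: dict[str, str],
    thresholds: CallThresholds = CallThresholds(),
    mapping_aligner=None,
    similarity_hsps: dict[str, list[Hsp]] | None = None,
) -> tuple[list[GeneCall], dict[frozenset[str], set[str]]]:
    """Call genes per MSM and compute the cross-MSM shared sets.

    ``msm_reads`` maps MSM id → read set.  Reference ids collapse to gene
    ids through ``gene_map`` (transcript/CDS id → gene id).  The mapping
    route uses minimap2 by default (injectable for tests); the similarity
    route uses the internal local aligner unless precomputed HSPs per MSM
    are supplied.  CDS-pool calls additionally require a CIP/CALP link to a
    transcript of the same gene when the transcriptome is given.
    """
    if not transcriptome and not cds_pool:
        raise UsageError("at least one reference set is required")
    if mapping_aligner is None:
        # one base-level run feeds both routes: MapQ for the mapping route,
        # identity for the similarity route (secondaries kept for multi-copy
        # genes; mapq of secondaries is 0 so only the similarity route sees
        # them)
        mapping_aligner = lambda q, r: minimap2_align(
            q, r, preset="map-ont", reconstruct=False, extra_args=["-N", "10", "-p", "0.3"]
        )
    ref_len = {r.id: len(r) for r in [*transcriptome, *cds_pool]}

    # CDS → transcript linking by CIP/CALP
    linked_genes: set[str] | None = None
    if cds_pool and transcriptome:
        linked_genes = set()
        cands = candidates_against(cds_pool, transcriptome, min_shared=8)
        params = AlignParams(min_score=100.0, max_hsps=10)
        for cds in cds_pool:
            by_target: dict[str, list[Hsp]] = defaultdict(list)
            for h in local_align(cds, cands[cds.id], params):
                by_target[h.target_id].append(h)
            for tid, hs in by_target.items():
                cip, calp = cip_calp(hs, len(cds))
                if cip is not None and cip >= thresholds.link_min_cip and calp >= thresholds.link_min_calp:
                    if gene_map.get(cds.id) == gene_map.get(tid):
                        linked_genes.add(gene_map[cds.id])

    calls: list[GeneCall] = []
    genes_per_msm: dict[str, set[str]] = {}
    for msm_id, reads in sorted(msm_reads.items()):
        found: dict[tuple[str, str], list[Hsp]] = defaultdict(list)
        for refs, route in ((transcriptome, "transcriptome"), (cds_pool, "cds_pool")):
            if not refs:
                continue
            hits = mapping_aligner(refs, reads)
            if similarity_hsps is not None:
                ref_ids = {r.id for r in refs}
                sim = [h for h in similarity_hsps.get(msm_id, []) if h.query_id in ref_ids]
            else:
                sim = hits
            added: set[int] = set()
            for h in hits:
                if _route_mapping(h, thresholds):
                    found[(h.query_id, route)].append(h)
                    added.add(id(h))
            for h in sim:
                if _route_similarity(h, thresholds) and id(h) not in added:
                    found[(h.query_id, route)].append(h)
        genes_here: set[str] = set()
        # one call per (gene, route): CIP/CALP from the reference sequence
        # with the largest cumulative aligned length
        per_gene_route: dict[tuple[str, str], dict[str, list[Hsp]]] = defaultdict(dict)
        for (ref_id, route), hs in found.items():
            gene = gene_map.get(ref_id, ref_id)
            per_gene_route[(gene, route)][ref_id] = hs
        for (gene, route), by_ref in sorted(per_gene_route.items()):
            if route == "cds_pool" and linked_genes is not None and gene not in linked_genes:
                continue
            best_ref = max(by_ref, key=lambda rid: (sum(h.aligned_length for h in by_ref[rid]), rid))
            hs = by_ref[best_ref]
            cip, calp = cip_calp(hs, ref_len[best_ref])
            calls.append(GeneCall(gene_id=gene, msm_id=msm_id, route=route, cip=cip, calp=calp, supporting=hs))
            genes_here.add(gene)
        genes_per_msm[msm_id] = genes_here

    shared: dict[frozenset[str], set[str]] = {}
    msm_ids = sorted(genes_per_msm)
    import itertools

    for r in range(1, len(msm_ids) + 1):
        for combo in itertools.combinations(msm_ids, r):
            inset = set.intersection(*(genes_per_msm[m] for m in combo)) if combo else set()
            shared[frozenset(combo)] = inset
    return calls, shared


def gene_integrity(
    gene_id: str, cds_intervals: list[tuple[int, int]], cds_length: int
) -> IntegrityScore:
    """Integrity of one gene: union CDS coverage by its MSM hits, binned.

    Bins follow the reporting convention: <10% strict, 10–50% inclusive of
    both bounds, >50% strict.
    """
    if cds_length <= 0:
        raise ValidationError("cds_length must be positive")
    for s, e in cds_intervals:
        if s < 0 or e > cds_length or s >= e:
            raise ValidationError(f"interval ({s},{e}) outside CDS [0,{cds_length})")
    covered = sum(e - s for s, e in merge_intervals(cds_intervals))
    frac = covered / cds_length
    if frac < 0.10:
        b = BIN_LOW
    elif frac <= 0.50:
        b = BIN_MID
    else:
        b = BIN_HIGH
    return IntegrityScore(gene_id=gene_id, covered_fraction=frac, bin=b)


def integrity_from_hits(
    msm_reads: dict[str, list[SeqRecord]],
    cds_pool: list[SeqRecord],
    gene_map: dict[str, str],
    min_identity: float = 0.80,
    min_length: int = 40,
    aligner=None,
) -> list[IntegrityScore]:
    """Integrity scores for every CDS with at least one MSM hit.

    Uses a permissive alignment (identity ≥ 0.80, ≥ 40 bp, short-seed
    sensitive mapping) so even heavily truncated copies register, mirroring
    the lenient settings used for integrity scoring as opposed to gene
    calling.
    """
    if aligner is None:
        aligner = lambda q, r: minimap2_align(
            q,
            r,
            preset="map-ont",
            reconstruct=False,
            extra_args=["-k", "11", "-w", "5", "-m", "25", "-s", "40", "-N", "50", "-p", "0.3"],
        )
    per_gene: dict[str, list[tuple[int, int]]] = defaultdict(list)
    lengths: dict[str, int] = {}
    all_reads = [r for reads in msm_reads.values() for r in reads]
    for cds in cds_pool:
        gene = gene_map.get(cds.id, cds.id)
        lengths[gene] = max(lengths.get(gene, 0), len(cds))
    for h in aligner(cds_pool, all_reads):
        if h.identity >= min_identity and (h.q_end - h.q_start) >= min_length:
            per_gene[gene_map.get(h.query_id, h.query_id)].append((h.q_start, h.q_end))
    return [
        gene_integrity(gene, ivs, lengths[gene]) for gene, ivs in sorted(per_gene.items())
    ]
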