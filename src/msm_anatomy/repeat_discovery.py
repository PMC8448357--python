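"""Comparative graph-based repeat discovery.

Equal-size read samples from two genomes (species A and B) are compared
all-to-all; reads joined by a strong local-alignment edge form clusters that
correspond to repeat families.  A family expanded in one genome shows a
lopsided per-species membership, and its per-species read share estimates the
fraction of that genome occupied by the repeat (reads are equal-length, so
read fraction approximates base fraction).  The top expanded cluster's
monomer is recovered by periodicity analysis and column-majority voting, and
a consensus monomer can then be scanned against any sequence to annotate
intact and fragmental satellite copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._kmers import candidate_pairs
from .errors import SamplingError, UsageError
from .seqio_align import AlignParams, Hsp, SeqRecord, local_align, revcomp

logger = logging.getLogger(__name__)


@dataclass
class RepeatCluster:
    """A connected component of the read-similarity graph."""

    cluster_id: str
    members_a: frozenset[str]
    members_b: frozenset[str]
    n_sampled_a: int
    n_sampled_b: int
    member_degrees: dict[str, int] = field(default_factory=dict)
    consensus: str | None = None

    @property
    def size_a(self) -> int:
        return len(self.members_a)

    @property
    def size_b(self) -> int:
        return len(self.members_b)

    @property
    def genome_proportion_a(self) -> float:
        return self.size_a / self.n_sampled_a if self.n_sampled_a else 0.0

    @property
    def genome_proportion_b(self) -> float:
        return self.size_b / self.n_sampled_b if self.n_sampled_b else 0.0

    @property
    def expansion_ratio(self) -> float:
        # +1 smoothing keeps clusters absent from one species finite
        return (self.size_a + 1) / (self.size_b + 1)


@dataclass(frozen=True)
class MonomerHit:
    """One satellite monomer copy found on a target sequence."""

    target_id: str
    start: int
    end: int
    strand: str
    consensus_coverage: float
    identity: float
    klass: str  # "intact" | "fragmental"
    score: float = 0.0


@dataclass(frozen=True)
class EdgeParams:
    """Similarity-edge criterion: identity ≥ min_identity over a local
    alignment covering ≥ min_cov of the shorter read."""

    min_identity: float = 0.90
    min_cov: float = 0.55
    kmer: int = 13
    min_shared_kmers: int = 5


def sample_reads(reads: list[SeqRecord], n: int, seed: int) -> list[SeqRecord]:
    """Uniform sample without replacement, deterministic under seed."""
    if n > len(reads):
        raise SamplingError(f"requested {n} reads from a set of {len(reads)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in idx]


def build_similarity_graph(
    reads_a: list[SeqRecord],
    reads_b: list[SeqRecord],
    params: EdgeParams = EdgeParams(),
) -> tuple[nx.Graph, dict[str, int], dict[str, int]]:
    """All-to-all comparison of the pooled samples.

    Returns the undirected similarity graph plus, for every read, the number
    of qualifying hits against each species' sample (the coordinates of the
    comparative read-vs-read scatter).  A read never counts a hit against
    itself.
    """
    ids_a = {r.id for r in reads_a}
    ids_b = {r.id for r in reads_b}
    pooled: dict[str, SeqRecord] = {}
    for r in [*reads_a, *reads_b]:
        pooled.setdefault(r.id, r)
    records = sorted(pooled.values(), key=lambda r: r.id)

    graph = nx.Graph()
    graph.graph["n_sampled_a"] = len(reads_a)
    graph.graph["n_sampled_b"] = len(reads_b)
    for r in records:
        graph.add_node(r.id, in_a=r.id in ids_a, in_b=r.id in ids_b)

    aln_params = AlignParams(min_score=20.0, max_hsps=1)
    pairs = candidate_pairs(records, k=params.kmer, min_shared=params.min_shared_kmers)
    for i, j in pairs:
        q, t = records[i], records[j]
        if _is_edge(q, t, params, aln_params):
            graph.add_edge(q.id, t.id)

    hits_in_a = {r.id: 0 for r in records}
    hits_in_b = {r.id: 0 for r in records}
    for rid in graph.nodes:
        for nb in graph.neighbors(rid):
            if nb in ids_a:
                hits_in_a[rid] += 1
            if nb in ids_b:
                hits_in_b[rid] += 1
    return graph, hits_in_a, hits_in_b


def _is_edge(q: SeqRecord, t: SeqRecord, params: EdgeParams, aln_params: AlignParams) -> bool:
    shorter = min(len(q), len(t))
    hsps = local_align(q, [t], aln_params)
    for h in hsps:
        span = min(h.q_end - h.q_start, h.t_end - h.t_start)
        if h.identity >= params.min_identity and span >= params.min_cov * shorter:
            return True
    return False


def cluster_graph(graph: nx.Graph) -> list[RepeatCluster]:
    """Connected components (singletons excluded), ranked by total size
    descending; ties broken by smallest member id for reproducibility."""
    comps = [c for c in nx.connected_components(graph) if len(c) > 1]
    comps.sort(key=lambda c: (-len(c), min(c)))
    clusters = []
    for i, comp in enumerate(comps, start=1):
        members_a = frozenset(r for r in comp if graph.nodes[r]["in_a"])
        members_b = frozenset(r for r in comp if graph.nodes[r]["in_b"])
        degrees = {r: graph.degree[r] for r in comp}
        clusters.append(
            RepeatCluster(
                cluster_id=f"CL{i}",
                members_a=members_a,
                members_b=members_b,
                n_sampled_a=graph.graph.get("n_sampled_a", 0),
                n_sampled_b=graph.graph.get("n_sampled_b", 0),
                member_degrees=degrees,
            )
        )
    return clusters


def genome_proportion(cluster: RepeatCluster, species: str) -> float:
    """Fraction of one genome occupied by the cluster's repeat family."""
    if species == "A":
        return cluster.genome_proportion_a
    if species == "B":
        return cluster.genome_proportion_b
    raise UsageError(f"species must be 'A' or 'B', got {species!r}")


# ---------------------------------------------------------------------------
# consensus monomer


def estimate_period(seq: str, min_period: int = 20, min_match_fraction: float = 0.8) -> int | None:
    """Tandem period via self-comparison: the smallest shift at which the
    sequence matches itself (the strongest off-diagonal).  Returns None when
    no shift reaches ``min_match_fraction``.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    best: list[tuple[int, float]] = []
    for s in range(min_period, n // 2 + 1):
        frac = float(np.mean(arr[s:] == arr[:-s]))
        best.append((s, frac))
    if not best:
        return None
    top = max(f for _, f in best)
    if top < min_match_fraction:
        return None
    # prefer the smallest shift close to the optimum: multiples of the true
    # period score equally well
    for s, f in best:
        if f >= 0.95 * top and f >= min_match_fraction:
            return s
    return None


def lexicographically_minimal_rotation(seq: str) -> str:
    doubled = seq + seq
    n = len(seq)
    best = min(doubled[i : i + n] for i in range(n))
    return best


def derive_consensus(
    cluster: RepeatCluster,
    reads: dict[str, SeqRecord],
    monomer_cov: float = 0.8,
) -> SeqRecord:
    """Majority-vote consensus monomer of a repeat cluster.

    The highest-degree member read seeds the monomer: its tandem period is
    estimated by self-comparison, a window of that period is cut out, and
    every monomer-sized hit of the seed across all member reads votes
    per-column.  The result is canonicalised to its lexicographically minimal
    rotation.  If no period is detectable the seed read itself is returned
    with ``warning=no_period`` in the description.
    """
    members = sorted(cluster.members_a | cluster.members_b)
    if not members:
        raise UsageError("cluster has no members")
    seed_id = max(members, key=lambda r: (cluster.member_degrees.get(r, 0), r))
    seed = reads[seed_id]
    period = estimate_period(seed.sequence)
    if period is None:
        logger.warning("cluster %s: tandem period undetectable", cluster.cluster_id)
        return SeqRecord(f"{cluster.cluster_id}_consensus", seed.sequence, "warning=no_period")
    offset = (len(seed) - period) // 2
    monomer = SeqRecord("seed_monomer", seed.sequence[offset : offset + period])

    votes = np.zeros((period, 4), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    aln_params = AlignParams(min_score=max(20.0, 1.0 * period), max_hsps=50)
    for rid in members:
        for hit in local_align(monomer, [reads[rid]], aln_params):
            if (hit.q_end - hit.q_start) < monomer_cov * period:
                continue
            q_aln, t_aln = hit.q_aln, hit.t_aln
            # q_aln follows alignment orientation; map columns back to the
            # forward monomer frame
            qpos = hit.q_start if hit.strand == "+" else len(monomer) - hit.q_end
            for qc, tc in zip(q_aln, t_aln):
                if qc != "-":
                    if tc in base_idx:
                        col = qpos if hit.strand == "+" else period - 1 - qpos
                        base = tc if hit.strand == "+" else revcomp(tc)
                        votes[col, base_idx[base]] += 1
                    qpos += 1
    consensus_chars = []
    for col in range(period):
        if votes[col].sum() == 0:
            consensus_chars.append(monomer.sequence[col])
        else:
            consensus_chars.append("ACGT"[int(np.argmax(votes[col]))])
    consensus = lexicographically_minimal_rotation("".join(consensus_chars))
    return SeqRecord(f"{cluster.cluster_id}_consensus", consensus, f"period={period}")


# ---------------------------------------------------------------------------
# monomer scan


def _chop_hit_to_monomers(hsp: Hsp, monomer_len: int) -> list[tuple[int, int, int, int, int]]:
    """Split an alignment into successive pieces of ≤ monomer_len query bases.

    The doubled-consensus query lets one local alignment run through up to
    two tandem copies; chopping turns it back into per-copy hits.  Returns
    (q_span, t_start, t_end, identities, aligned_length) per piece in target
    coordinates.
    """
    if hsp.q_end - hsp.q_start <= monomer_len:
        return [(hsp.q_end - hsp.q_start, hsp.t_start, hsp.t_end, hsp.identities, hsp.aligned_length)]
    pieces = []
    q_used = t_pos = ident = cols = 0
    t_piece_start = hsp.t_start
    for qc, tc in zip(hsp.q_aln, hsp.t_aln):
        cols += 1
        if qc != "-":
            q_used += 1
        if tc != "-":
            t_pos += 1
        if qc == tc and qc != "-":
            ident += 1
        if q_used == monomer_len:
            t_piece_end = hsp.t_start + t_pos
            pieces.append((q_used, t_piece_start, t_piece_end, ident, cols))
            t_piece_start = t_piece_end
            q_used = ident = cols = 0
    if q_used > 0:
        pieces.append((q_used, t_piece_start, hsp.t_start + t_pos, ident, cols))
    return pieces


def scan_satellite(
    consensus: SeqRecord,
    target: SeqRecord,
    intact_threshold: float = 0.90,
    fragment_threshold: float = 0.25,
) -> list[MonomerHit]:
    """Annotate monomer copies of ``consensus`` on ``target``.

    The consensus is doubled so copies at any rotational phase align
    contiguously; alignments spanning more than one monomer length are
    trimmed back to a single copy.  Hits are selected greedily by score with
    no target overlap, classified intact (coverage ≥ intact_threshold) or
    fragmental (≥ fragment_threshold), and returned sorted by start.
    """
    L = len(consensus)
    if L < 20:
        raise UsageError("consensus too short to scan (<20 bp)")
    doubled = SeqRecord(consensus.id, consensus.sequence * 2)
    min_score = max(20.0, 0.6 * 2.0 * fragment_threshold * L)
    max_hsps = max(10, 4 * len(target) // L)
    params = AlignParams(min_score=min_score, max_hsps=max_hsps)
    raw: list[tuple[float, int, int, float, float, str]] = []
    for h in local_align(doubled, [target], params):
        for q_span, t_s, t_e, ident, cols in _chop_hit_to_monomers(h, L):
            if cols == 0 or t_e <= t_s:
                continue
            coverage = min(q_span, L) / L
            identity = ident / cols
            score = 2.0 * ident - 3.0 * (cols - ident)
            raw.append((score, t_s, t_e, coverage, identity, h.strand))
    # greedy non-overlapping selection by score (cross-strand duplicates of
    # one copy are removed here; same-strand hits are disjoint by masking)
    raw.sort(key=lambda r: (-r[0], r[1]))
    chosen: list[tuple[float, int, int, float, float, str]] = []
    occupied: list[tuple[int, int]] = []
    for cand in raw:
        _, s, e, *_ = cand
        overlap = any(min(e, oe) - max(s, os_) > 0 for os_, oe in occupied)
        if not overlap:
            chosen.append(cand)
            occupied.append((s, e))
    hits = []
    for score, s, e, cov, ident, strand in chosen:
        if cov >= intact_threshold:
            klass = "intact"
        elif cov >= fragment_threshold:
            klass = "fragmental"
        else:
            continue
        hits.append(
            MonomerHit(
                target_id=target.id,
                start=s,
                end=e,
                strand=strand,
                consensus_coverage=cov,
                identity=ident,
                klass=klass,
                score=score,
            )
        )
    hits.sort(key=lambda h: h.start)
    return hits


def rotational_identity(a: str, b: str) -> float:
    """Best identity between two monomers over all rotations and strands."""
    target = SeqRecord("b2", b + b)
    query = SeqRecord("a", a)
    params = AlignParams(min_score=10.0, max_hsps=1)
    hsps = local_align(query, [target], params)
    if not hsps:
        return 0.0
    best = hsps[0]
    # identity over the full monomer length, not just the aligned stretch
    return best.identities / max(len(a), min(len(b), best.aligned_length))
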