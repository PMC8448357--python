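"""Canonical k-mer prefilters.

Exhaustive Smith–Waterman over every pair of reads is quadratic in sample
size; pairs that could pass the similarity-edge criterion necessarily share
many exact k-mers, so candidate pairs are generated from an inverted k-mer
index first.  Strand is handled by canonicalising each k-mer to the smaller
of itself and its reverse complement.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from .seqio_align import SeqRecord, revcomp


def canonical_kmers(seq: str, k: int = 13) -> set[str]:
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        out.add(kmer if kmer <= rc else rc)
    return out


def candidate_pairs(
    records: Sequence[SeqRecord], k: int = 13, min_shared: int = 5
) -> list[tuple[int, int]]:
    """Indices (i < j) of record pairs sharing ≥ ``min_shared`` canonical k-mers."""
    sets = [canonical_kmers(r.sequence, k) for r in records]
    index: dict[str, list[int]] = defaultdict(list)
    for i, s in enumerate(sets):
        for kmer in s:
            index[kmer].append(i)
    counts: dict[tuple[int, int], int] = defaultdict(int)
    for members in index.values():
        if len(members) < 2:
            continue
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                counts[(members[a], members[b])] += 1
    return sorted(p for p, c in counts.items() if c >= min_shared)


def candidates_against(
    queries: Sequence[SeqRecord],
    targets: Sequence[SeqRecord],
    k: int = 13,
    min_shared: int = 5,
) -> dict[str, list[SeqRecord]]:
    """For each query, the targets sharing ≥ ``min_shared`` canonical k-mers
    (inverted index over the target set; linear in total k-mer postings)."""
    index: dict[str, list[int]] = defaultdict(list)
    for ti, t in enumerate(targets):
        for kmer in canonical_kmers(t.sequence, k):
            index[kmer].append(ti)
    out: dict[str, list[SeqRecord]] = {}
    for q in queries:
        counts: dict[int, int] = defaultdict(int)
        for kmer in canonical_kmers(q.sequence, k):
            for ti in index.get(kmer, ()):
                counts[ti] += 1
        out[q.id] = [targets[ti] for ti in sorted(ti for ti, c in counts.items() if c >= min_shared)]
    return out


def shared_kmer_filter(k: int = 13, min_shared: int = 5):
    """Pair filter for :func:`seqio_align.local_align_many` with memoised sets."""
    cache: dict[str, set[str]] = {}

    def _get(rec: SeqRecord) -> set[str]:
        s = cache.get(rec.id)
        if s is None:
            s = canonical_kmers(rec.sequence, k)
            cache[rec.id] = s
        return s

    def _filter(q: SeqRecord, t: SeqRecord) -> bool:
        qs, ts = _get(q), _get(t)
        if len(qs) > len(ts):
            qs, ts = ts, qs
        n = 0
        for kmer in qs:
            if kmer in ts:
                n += 1
                if n >= min_shared:
                    return True
        return False

    return _filter
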