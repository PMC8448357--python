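"""Sequence I/O and the local-alignment contract used by every pipeline stage.

All coordinates are 0-based half-open internally.  High-scoring pairs (HSPs)
come from three sources, normalised to one :class:`Hsp` record:

* :func:`local_align` — an exhaustive Smith–Waterman search (Biopython's
  C ``PairwiseAligner``) that reports multiple HSPs per query/target pair by
  iteratively masking the best hit and re-aligning;
* :func:`minimap2_align` — a wrapper around the ``minimap2`` executable for
  genome-scale mapping, with aligned strings reconstructed from the ``cs``
  tag so downstream divergence estimation sees the actual alignment columns;
* :func:`load_alignments` — ingest of externally produced SAM or PAF.

Identity is defined as matched columns over alignment columns (gap columns
included), the convention behind the cumulative identity statistics computed
downstream.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, SeqIO

from .errors import ParseError, UsageError, ValidationError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence (read, contig, transcript, CDS, consensus)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("SeqRecord id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"SeqRecord {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Hsp:
    """One local-alignment high-scoring pair.

    ``identities``/``aligned_length`` follow the gap-inclusive definition:
    ``aligned_length`` counts every alignment column (matches, mismatches and
    internal gap columns) and ``identities`` the matched columns.  Query
    coordinates always refer to the forward strand of the query, whatever the
    alignment strand, so interval arithmetic downstream never sees strand.
    """

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    aligned_length: int
    identities: int
    mapq: int = 0
    score: float = 0.0
    q_aln: str | None = None  # gapped query string, target orientation
    t_aln: str | None = None

    def __post_init__(self):
        if not (0 <= self.q_start < self.q_end):
            raise ValidationError(
                f"invalid query interval [{self.q_start},{self.q_end}) for {self.query_id}"
            )
        if not (0 <= self.t_start < self.t_end):
            raise ValidationError(
                f"invalid target interval [{self.t_start},{self.t_end}) for {self.target_id}"
            )
        if self.identities > self.aligned_length:
            raise ValidationError("identities exceed aligned_length")
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def identity(self) -> float:
        return self.identities / self.aligned_length


@dataclass(frozen=True)
class AlignParams:
    """Scoring and reporting parameters for :func:`local_align`.

    Defaults are megablast-like (match 2, mismatch −3, gap −5/−2); the
    minimum reported score of 40 corresponds to a 20 bp exact match.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_score: float = 40.0
    max_hsps: int = 25
    both_strands: bool = True


# ---------------------------------------------------------------------------
# sequence I/O


def read_sequences(path: str | Path, fmt: str | None = None) -> list[SeqRecord]:
    """Read FASTA/FASTQ into SeqRecords (order-preserving, uppercased).

    FASTQ qualities are discarded.  Duplicate ids raise ValidationError.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    fmt = fmt.lower()
    if fmt not in {"fasta", "fastq"}:
        raise UsageError(f"unsupported sequence format {fmt!r}")
    records: list[SeqRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), fmt):
            if rec.id in seen:
                raise ValidationError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(SeqRecord(rec.id, str(rec.seq).upper(), desc))
    except ValidationError:
        raise
    except ValueError as exc:  # Biopython's malformed-record errors
        raise ParseError(f"malformed {fmt} in {path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# internal Smith–Waterman search


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="local",
        match_score=params.match,
        mismatch_score=params.mismatch,
        open_gap_score=params.gap_open,
        extend_gap_score=params.gap_extend,
    )


def _hsps_one_strand(
    aligner: Align.PairwiseAligner,
    query: SeqRecord,
    target: SeqRecord,
    strand: str,
    params: AlignParams,
) -> list[Hsp]:
    """Repeated best-local-alignment with target masking → multiple HSPs."""
    qseq = query.sequence if strand == "+" else revcomp(query.sequence)
    tseq = list(target.sequence)
    out: list[Hsp] = []
    qlen = len(qseq)
    for _ in range(params.max_hsps):
        alns = aligner.align("".join(tseq), qseq)
        try:
            aln = alns[0]
        except IndexError:
            break
        if aln.score < params.min_score:
            break
        (tb, qb) = aln.aligned  # blocks in target, then query
        t_start, t_end = int(tb[0][0]), int(tb[-1][1])
        q_start, q_end = int(qb[0][0]), int(qb[-1][1])
        t_gapped = str(aln[0])
        q_gapped = str(aln[1])
        counts = aln.counts()
        identities = int(counts.identities)
        aligned_length = len(t_gapped)
        if strand == "-":
            fq_start, fq_end = qlen - q_end, qlen - q_start
        else:
            fq_start, fq_end = q_start, q_end
        out.append(
            Hsp(
                query_id=query.id,
                target_id=target.id,
                q_start=fq_start,
                q_end=fq_end,
                t_start=t_start,
                t_end=t_end,
                strand=strand,
                aligned_length=aligned_length,
                identities=identities,
                score=float(aln.score),
                q_aln=q_gapped,
                t_aln=t_gapped,
            )
        )
        # mask the matched target stretch and search for the next HSP
        for i in range(t_start, t_end):
            tseq[i] = "N"
    return out


def local_align(
    query: SeqRecord,
    targets: Sequence[SeqRecord],
    params: AlignParams = AlignParams(),
) -> list[Hsp]:
    """All HSPs of one query against a target set, both strands.

    Returns HSPs with score ≥ ``params.min_score`` sorted by
    (score desc, t_start, target_id); mapq is the uniqueness surrogate
    ``60·(1 − second_best/best)`` over the query's HSP scores (60 when the
    query matches a single place, 0 when the two best scores tie).
    """
    hsps: list[Hsp] = []
    aligner = _make_aligner(params)
    strands = "+-" if params.both_strands else "+"
    for target in targets:
        for strand in strands:
            hsps.extend(_hsps_one_strand(aligner, query, target, strand, params))
    hsps.sort(key=lambda h: (-h.score, h.t_start, h.target_id, h.strand))
    _assign_mapq(hsps)
    return hsps


def _assign_mapq(hsps: list[Hsp]) -> None:
    if not hsps:
        return
    best = hsps[0].score
    second = hsps[1].score if len(hsps) > 1 else 0.0
    mapq = 0 if best <= 0 else int(round(60.0 * (1.0 - second / best)))
    mapq = max(0, min(60, mapq))
    for h in hsps:
        h.mapq = mapq if h.score == best else 0


def local_align_many(
    queries: Sequence[SeqRecord],
    targets: Sequence[SeqRecord],
    params: AlignParams = AlignParams(),
    pair_filter=None,
) -> list[Hsp]:
    """Convenience loop over queries; ``pair_filter(q, t) -> bool`` can skip
    target evaluation (k-mer prefilters at scale)."""
    out: list[Hsp] = []
    for q in queries:
        if pair_filter is None:
            cand = targets
        else:
            cand = [t for t in targets if pair_filter(q, t)]
        out.extend(local_align(q, cand, params))
    return out


# ---------------------------------------------------------------------------
# external alignments: PAF / SAM


def _parse_paf_line(line: str, lineno: int) -> tuple[Hsp | None, dict]:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise ParseError(f"PAF line {lineno}: expected ≥12 columns, got {len(cols)}")
    tags = {}
    for col in cols[12:]:
        parts = col.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]
    if cols[5] == "*":  # unmapped
        return None, tags
    qs, qe = int(cols[2]), int(cols[3])
    ts, te = int(cols[7]), int(cols[8])
    matches, alen = int(cols[9]), int(cols[10])
    hsp = Hsp(
        query_id=cols[0],
        target_id=cols[5],
        q_start=qs,
        q_end=qe,
        t_start=ts,
        t_end=te,
        strand=cols[4],
        aligned_length=alen,
        identities=min(matches, alen),
        mapq=int(cols[11]),
        score=float(tags.get("AS", matches)),
    )
    return hsp, tags


def _aln_from_cs(cs: str, tseq: str, t_start: int) -> tuple[str, str]:
    """Rebuild gapped (target, query) strings from a short-form cs tag."""
    t_parts: list[str] = []
    q_parts: list[str] = []
    pos = t_start
    i = 0
    n = len(cs)
    while i < n:
        op = cs[i]
        j = i + 1
        while j < n and cs[j] not in ":*+-=~":
            j += 1
        val = cs[i + 1 : j]
        if op == ":":
            ln = int(val)
            seg = tseq[pos : pos + ln]
            t_parts.append(seg)
            q_parts.append(seg)
            pos += ln
        elif op == "*":
            t_parts.append(val[0].upper())
            q_parts.append(val[1].upper())
            pos += 1
        elif op == "+":  # insertion in query
            t_parts.append("-" * len(val))
            q_parts.append(val.upper())
        elif op == "-":  # deletion from target
            t_parts.append(val.upper())
            q_parts.append("-" * len(val))
            pos += len(val)
        else:
            raise ParseError(f"unsupported cs op {op!r}")
        i = j
    return "".join(t_parts), "".join(q_parts)


def load_alignments(path: str | Path, fmt: str) -> list[Hsp]:
    """Load SAM or PAF into Hsps, 0-based half-open; unmapped records dropped
    (count logged)."""
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "paf":
        hsps = []
        dropped = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                hsp, _tags = _parse_paf_line(line, lineno)
                if hsp is None:
                    dropped += 1
                else:
                    hsps.append(hsp)
        if dropped:
            logger.info("dropped %d unmapped PAF records from %s", dropped, path)
        return hsps
    if fmt == "sam":
        return _load_sam(path)
    raise UsageError(f"unknown alignment format {fmt!r}")


def _load_sam(path: Path) -> list[Hsp]:
    import pysam

    hsps: list[Hsp] = []
    dropped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                dropped += 1
                continue
            qlen = rec.infer_read_length() or rec.query_length
            qs = rec.query_alignment_start
            qe = rec.query_alignment_end
            if rec.is_reverse:
                qs, qe = qlen - qe, qlen - qs
            stats = rec.get_cigar_stats()[0]
            m = stats[0] + stats[7] + stats[8]  # M + = + X
            ins, dele = stats[1], stats[2]
            alen = m + ins + dele
            nm = rec.get_tag("NM") if rec.has_tag("NM") else ins + dele
            mismatches = max(0, nm - ins - dele)
            hsps.append(
                Hsp(
                    query_id=rec.query_name,
                    target_id=rec.reference_name,
                    q_start=qs,
                    q_end=qe,
                    t_start=rec.reference_start,
                    t_end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    aligned_length=alen,
                    identities=m - mismatches,
                    mapq=rec.mapping_quality,
                    score=float(rec.get_tag("AS")) if rec.has_tag("AS") else float(m - mismatches),
                )
            )
    if dropped:
        logger.info("dropped %d unmapped SAM records from %s", dropped, path)
    return hsps


def write_paf(
    hsps: Iterable[Hsp],
    path: str | Path,
    query_lengths: dict[str, int],
    target_lengths: dict[str, int],
) -> None:
    """Deterministic minimal PAF writer (12 columns + AS tag)."""
    rows = sorted(hsps, key=lambda h: (h.query_id, -h.score, h.target_id, h.t_start))
    with open(path, "w") as fh:
        for h in rows:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        query_lengths[h.query_id],
                        h.q_start,
                        h.q_end,
                        h.strand,
                        h.target_id,
                        target_lengths[h.target_id],
                        h.t_start,
                        h.t_end,
                        h.identities,
                        h.aligned_length,
                        h.mapq,
                        f"AS:i:{int(h.score)}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# minimap2 wrapper


def minimap2_align(
    queries: Sequence[SeqRecord],
    reference: Sequence[SeqRecord],
    preset: str = "map-ont",
    extra_args: Sequence[str] = (),
    reconstruct: bool = True,
    base_level: bool = True,
) -> list[Hsp]:
    """Map queries to a reference with the minimap2 executable.

    With ``base_level`` the run uses ``-c --cs`` and aligned strings are
    reconstructed from the cs tag against the reference sequence (query
    bases are implied by the tag), enabling divergence estimation on the
    exact alignment columns.  Interval-only work (coverage fractions) can
    skip base-level alignment, which is much faster on repeat-rich inputs.
    """
    if shutil.which("minimap2") is None:
        raise UsageError("minimap2 executable not found on PATH")
    if not queries or not reference:
        return []
    ref_by_id = {r.id: r.sequence for r in reference}
    with tempfile.TemporaryDirectory(prefix="msm_mm2_") as tmp:
        qpath = Path(tmp) / "q.fa"
        rpath = Path(tmp) / "r.fa"
        opath = Path(tmp) / "out.paf"
        write_fasta(queries, qpath)
        write_fasta(reference, rpath)
        detail = ["-c", "--cs"] if base_level else []
        cmd = ["minimap2", *detail, "-x", preset, *extra_args, str(rpath), str(qpath)]
        with open(opath, "w") as out:
            subprocess.run(cmd, stdout=out, stderr=subprocess.DEVNULL, check=True)
        hsps: list[Hsp] = []
        with open(opath) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                hsp, tags = _parse_paf_line(line, lineno)
                if hsp is None:
                    continue
                if reconstruct and "cs" in tags:
                    t_aln, q_aln = _aln_from_cs(tags["cs"], ref_by_id[hsp.target_id], hsp.t_start)
                    hsp.t_aln, hsp.q_aln = t_aln, q_aln
                hsps.append(hsp)
    hsps.sort(key=lambda h: (h.query_id, -h.score, h.target_id, h.t_start))
    return hsps


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; overlapping or bookended runs merge."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def query_coverage(hsps: Sequence[Hsp], query_length: int) -> float:
    """|union of query intervals| / query_length for one query's HSPs."""
    if query_length <= 0:
        raise ValidationError("query_length must be positive")
    if not hsps:
        return 0.0
    qids = {h.query_id for h in hsps}
    if len(qids) > 1:
        raise ValidationError(f"query_coverage expects a single query, got {sorted(qids)}")
    covered = sum(e - s for s, e in merge_intervals((h.q_start, h.q_end) for h in hsps))
    return covered / query_length
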