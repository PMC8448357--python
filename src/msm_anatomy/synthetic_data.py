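"""Synthetic study-system generator with machine-readable truth.

The generator emulates the comparative design the pipeline is built for:

* an *ancestor* genome (tetraploid progenitor stand-in) carrying a handful of
  copies of a satellite monomer;
* a *derived* genome (the gynogenetic hexaploid's female genome) whose
  autosomes diverged slightly from the ancestor and which gained
  microchromosomes carrying a massive tandem expansion of the same monomer;
* three male-specific microchromosomes (MSMs) composed of satellite arrays,
  transposable-element copies, autosome-derived homology segments planted at
  known divergence ages, and truncated copies of protein-coding genes at a
  configured integrity mix — male-specific genes exist nowhere else, all
  other genes have an intact autosomal locus;
* gonadal transcriptomes per sex and a stage × sex count table in which
  male-specific genes are silent in every female sample and male-biased
  genes carry a configured log2 fold change during the sex-determination
  window (stages before 40 days after hatch).

Every random draw flows from one root seed through named substreams, so any
single product is reproducible in isolation.  Read ids carry their true
origin (``origin=chrom:start-end:strand``); the pipeline never parses it,
the truth-set accessors do.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .seqio_align import SeqRecord, revcomp, write_fasta

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
BIN_LOW, BIN_MID, BIN_HIGH = "<10%", "10-50%", ">50%"
DEFAULT_STAGES = (18, 22, 26, 30, 35, 40, 47, 58, 70)


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Named deterministic substream of the root seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 1
    # genomes
    monomer_length: int = 137
    ancestor_genome_length: int = 2_000_000
    n_autosomes: int = 4
    ancestor_satellite_copies: int = 5
    derived_expansion_copies: int = 2000
    n_microchromosomes: int = 4
    autosome_divergence: float = 0.005
    satellite_copy_divergence: float = 0.01
    # MSMs
    n_msm: int = 3
    msm_length: int = 60_000
    msm_satellite_fraction: float = 0.30
    msm_homology_fraction: float = 0.30
    # per-MSM divergence ages of the planted autosomal homology segments
    msm_homology_ages: tuple[tuple[float, ...], ...] = ((0.01, 0.10), (0.03,), (0.01, 0.08))
    # repeats
    n_te_families: int = 8
    te_length: int = 500
    # genes
    n_planted_genes: int = 30
    n_decoy_genes: int = 10
    n_background_genes: int = 470
    gene_length: int = 1500
    integrity_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # <10%, 10-50%, >50%
    n_male_specific_genes: int = 4
    n_male_biased_genes: int = 5
    biased_log2fc: float = 2.0
    # expression
    n_stages: int = 9
    nb_dispersion: float = 0.1
    mean_expression: float = 200.0
    # reads
    read_length: int = 300
    read_error_rate: float = 0.002
    reads_per_sample: int = 800
    msm_read_length: int = 2000
    msm_coverage: float = 8.0

    def __post_init__(self):
        if self.seed < 0 or self.seed >= 2**31:
            raise ConfigurationError("seed must be in [0, 2^31)")
        for name in (
            "monomer_length",
            "ancestor_genome_length",
            "n_autosomes",
            "msm_length",
            "gene_length",
            "read_length",
            "msm_read_length",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if abs(sum(self.integrity_mix) - 1.0) > 1e-9:
            raise ConfigurationError("integrity_mix must sum to 1")
        if self.n_male_specific_genes + self.n_male_biased_genes > self.n_planted_genes:
            raise ConfigurationError(
                "n_male_specific_genes + n_male_biased_genes exceeds n_planted_genes"
            )
        if min(self.integrity_mix) < 0:
            raise ConfigurationError("integrity_mix proportions must be non-negative")
        if self.derived_expansion_copies < 0 or self.ancestor_satellite_copies < 0:
            raise ConfigurationError("satellite copy counts must be non-negative")
        if len(self.msm_homology_ages) < self.n_msm:
            raise ConfigurationError("msm_homology_ages must cover every MSM")
        if self.biased_log2fc < 0:
            raise ConfigurationError("biased_log2fc must be ≥ 0")

    @property
    def stages(self) -> tuple[int, ...]:
        if self.n_stages <= len(DEFAULT_STAGES):
            return DEFAULT_STAGES[: self.n_stages]
        extra = tuple(DEFAULT_STAGES[-1] + 10 * (i + 1) for i in range(self.n_stages - len(DEFAULT_STAGES)))
        return DEFAULT_STAGES + extra

    @property
    def biased_stages(self) -> tuple[int, ...]:
        """Sex-determination window: sampled stages before 40 dah."""
        return tuple(s for s in self.stages if s < 40)


@dataclass
class PlantedGene:
    gene_id: str
    msm_id: str
    start: int
    end: int
    integrity: float
    bin: str
    end_used: str  # "5p" or "3p"


@dataclass
class TruthSet:
    """Everything the generator planted, for use as an oracle."""

    satellite_consensus: str
    satellite_intervals: dict[str, list[tuple[int, int]]]
    repeat_annotation: dict[str, list[tuple[int, int, str]]]
    planted_genes: list[PlantedGene]
    gene_autosome_loci: dict[str, tuple[str, int, int]]
    male_specific_gene_ids: set[str]
    male_biased_gene_ids: set[str]
    biased_lfc: dict[str, dict[int, float]]
    msm_homology_segments: list[tuple[str, int, int, str, int, int, float]]
    derived_satellite_fraction: float
    msm_ids: list[str]

    def integrity_bin_counts(self) -> dict[str, int]:
        counts = {BIN_LOW: 0, BIN_MID: 0, BIN_HIGH: 0}
        for g in self.planted_genes:
            counts[g.bin] += 1
        return counts

    def satellite_bp(self, chrom: str) -> int:
        return sum(e - s for s, e in self.satellite_intervals.get(chrom, []))

    def overlaps_satellite(self, chrom: str, start: int, end: int) -> bool:
        """Does [start, end) on this chromosome touch a planted satellite
        interval (either genome's annotation)?"""
        for key in (chrom, f"ancestor:{chrom}"):
            for s, e in self.satellite_intervals.get(key, []):
                if min(e, end) - max(s, start) > 0:
                    return True
        return False


# ---------------------------------------------------------------------------
# low-level sequence helpers


def _random_seq_arr(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _mutate_arr(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitution-only mutation at the given per-base rate."""
    if rate <= 0:
        return arr.copy()
    out = arr.copy()
    mask = rng.random(len(arr)) < rate
    n_mut = int(mask.sum())
    if n_mut:
        # shift each mutated base by 1..3 in the ACGT alphabet: never silent
        idx = np.searchsorted(BASES, out[mask])
        shift = rng.integers(1, 4, size=n_mut)
        out[mask] = BASES[(idx + shift) % 4]
    return out


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    return _arr_to_str(_mutate_arr(np.frombuffer(seq.encode(), dtype=np.uint8), rate, rng))


def _tandem_array(monomer: str, copies: int, divergence: float, rng: np.random.Generator) -> str:
    parts = [mutate_sequence(monomer, divergence, rng) for _ in range(copies)]
    return "".join(parts)


def _largest_remainder_counts(n: int, proportions: tuple[float, ...]) -> list[int]:
    raw = [n * p for p in proportions]
    counts = [int(x) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# genome construction


def generate_genomes(
    config: SimulationConfig,
) -> tuple[list[SeqRecord], list[SeqRecord], list[SeqRecord], TruthSet]:
    """Build ancestor genome, derived genome and MSMs, plus the truth set."""
    rng = rng_for(config.seed, "genomes")
    monomer = _arr_to_str(_random_seq_arr(rng_for(config.seed, "monomer"), config.monomer_length))

    satellite_intervals: dict[str, list[tuple[int, int]]] = {}
    repeat_annotation: dict[str, list[tuple[int, int, str]]] = {}

    # --- gene repertoires ------------------------------------------------
    gene_rng = rng_for(config.seed, "genes")
    gene_ids = [f"G{i + 1:03d}" for i in range(config.n_planted_genes)]
    gene_seqs = {
        g: _arr_to_str(_random_seq_arr(gene_rng, config.gene_length)) for g in gene_ids
    }
    ms_ids = set(gene_ids[: config.n_male_specific_genes])
    mb_ids = set(
        gene_ids[config.n_male_specific_genes : config.n_male_specific_genes + config.n_male_biased_genes]
    )
    autosomal_gene_ids = [g for g in gene_ids if g not in ms_ids]

    # --- autosomes -------------------------------------------------------
    auto_len = config.ancestor_genome_length // config.n_autosomes
    ancestor: list[SeqRecord] = []
    derived: list[SeqRecord] = []
    gene_autosome_loci: dict[str, tuple[str, int, int]] = {}

    per_chrom_genes: dict[int, list[str]] = {i: [] for i in range(config.n_autosomes)}
    for i, g in enumerate(autosomal_gene_ids):
        per_chrom_genes[i % config.n_autosomes].append(g)

    # each autosome is zoned so planted features never overwrite each other:
    # genes in [0, n/4), TEs in [n/4, n/2), homology source in [n/2, n-10kb),
    # ancestor satellite relic near the end of A01
    for ci in range(config.n_autosomes):
        chrom = f"A{ci + 1:02d}"
        arr = _random_seq_arr(rng, auto_len)
        genes_here = per_chrom_genes[ci]
        if genes_here:
            zone = auto_len // 4
            slot_size = zone // (len(genes_here) + 1)
            if slot_size < config.gene_length + 200:
                raise ConfigurationError(
                    "autosomes too short for the requested number of planted genes"
                )
            for slot, g in enumerate(genes_here):
                start = slot * slot_size + (slot_size - config.gene_length) // 2
                gseq = np.frombuffer(gene_seqs[g].encode(), dtype=np.uint8)
                arr[start : start + config.gene_length] = gseq
                gene_autosome_loci[g] = (chrom, start, start + config.gene_length)
        if ci == 0 and config.ancestor_satellite_copies:
            # the ancestral low-copy relic array, shared by both genomes: the
            # satellite pre-dates the expansion
            sat = _tandem_array(
                monomer, config.ancestor_satellite_copies, config.satellite_copy_divergence, rng
            )
            pos = auto_len - len(sat) - 1000
            arr[pos : pos + len(sat)] = np.frombuffer(sat.encode(), dtype=np.uint8)
            satellite_intervals.setdefault(chrom, []).append((pos, pos + len(sat)))
            repeat_annotation.setdefault(chrom, []).append((pos, pos + len(sat), "satellite"))
        ancestor.append(SeqRecord(chrom, _arr_to_str(arr)))
        der_arr = _mutate_arr(arr, config.autosome_divergence, rng)
        derived.append(SeqRecord(chrom, _arr_to_str(der_arr)))

    # --- TE library planted on autosomes (shared, unexpanded) ------------
    te_rng = rng_for(config.seed, "tes")
    te_seqs = {
        f"TE{i + 1:02d}": _arr_to_str(_random_seq_arr(te_rng, config.te_length))
        for i in range(config.n_te_families)
    }
    ancestor, derived = _plant_tes_on_autosomes(
        config, te_rng, te_seqs, ancestor, derived, repeat_annotation
    )

    # --- derived microchromosomes with the expansion ----------------------
    micro_rng = rng_for(config.seed, "micros")
    copies_per_micro = _largest_remainder_counts(
        config.derived_expansion_copies, tuple([1 / config.n_microchromosomes] * config.n_microchromosomes)
    )
    for mi in range(config.n_microchromosomes):
        chrom = f"mic{mi + 1}"
        left = _arr_to_str(_random_seq_arr(micro_rng, 2000))
        right = _arr_to_str(_random_seq_arr(micro_rng, 2000))
        sat = _tandem_array(monomer, copies_per_micro[mi], config.satellite_copy_divergence, micro_rng)
        seq = left + sat + right
        if sat:
            satellite_intervals.setdefault(chrom, []).append((len(left), len(left) + len(sat)))
            repeat_annotation.setdefault(chrom, []).append((len(left), len(left) + len(sat), "satellite"))
        derived.append(SeqRecord(chrom, seq))

    derived_ids = {r.id for r in derived}
    derived_total = sum(len(r) for r in derived)
    derived_sat_bp = sum(
        e - s
        for chrom, ivs in satellite_intervals.items()
        for s, e in ivs
        if chrom in derived_ids
    )

    # --- MSMs -------------------------------------------------------------
    msm_records, planted_genes, homology_segments = _build_msms(
        config,
        monomer,
        te_seqs,
        gene_seqs,
        ms_ids,
        derived,
        satellite_intervals,
        repeat_annotation,
    )

    biased_lfc = {
        g: {s: (config.biased_log2fc if s in config.biased_stages else 0.0) for s in config.stages}
        for g in sorted(mb_ids)
    }

    truth = TruthSet(
        satellite_consensus=monomer,
        satellite_intervals=satellite_intervals,
        repeat_annotation=repeat_annotation,
        planted_genes=planted_genes,
        gene_autosome_loci=gene_autosome_loci,
        male_specific_gene_ids=ms_ids,
        male_biased_gene_ids=mb_ids,
        biased_lfc=biased_lfc,
        msm_homology_segments=homology_segments,
        derived_satellite_fraction=derived_sat_bp / derived_total,
        msm_ids=[r.id for r in msm_records],
    )
    return ancestor, derived, msm_records, truth


def _plant_tes_on_autosomes(config, rng, te_seqs, ancestor, derived, repeat_annotation):
    """Scatter each TE family over the autosomes of both genomes (identical
    orthologous positions; TEs are shared, only the satellite expands)."""
    new_anc, new_der = [], []
    n_autosomes = config.n_autosomes
    copies_per_family = 24  # ≈1% of genome per family at the default sizes
    placements: dict[str, list[tuple[str, int]]] = {f: [] for f in te_seqs}
    for fam, seq in sorted(te_seqs.items()):
        for _ in range(copies_per_family):
            ci = int(rng.integers(0, n_autosomes))
            chrom = f"A{ci + 1:02d}"
            placements[fam].append((chrom, 0))
    for anc, der in zip(ancestor, derived):
        if not anc.id.startswith("A"):
            new_anc.append(anc)
            new_der.append(der)
            continue
        anc_arr = np.frombuffer(anc.sequence.encode(), dtype=np.uint8).copy()
        der_arr = np.frombuffer(der.sequence.encode(), dtype=np.uint8).copy()
        n = len(anc_arr)
        for fam, seq in sorted(te_seqs.items()):
            k = sum(1 for chrom, _ in placements[fam] if chrom == anc.id)
            for _ in range(k):
                pos = int(rng.integers(n // 4, n // 2 - len(seq) - 1))
                te_arr = np.frombuffer(
                    mutate_sequence(seq, 0.01, rng).encode(), dtype=np.uint8
                )
                anc_arr[pos : pos + len(seq)] = te_arr
                der_arr[pos : pos + len(seq)] = te_arr
                repeat_annotation.setdefault(anc.id, []).append((pos, pos + len(seq), f"TE:{fam}"))
        new_anc.append(SeqRecord(anc.id, _arr_to_str(anc_arr)))
        new_der.append(SeqRecord(der.id, _arr_to_str(der_arr)))
    return new_anc, new_der


def _build_msms(
    config: SimulationConfig,
    monomer: str,
    te_seqs: dict[str, str],
    gene_seqs: dict[str, str],
    ms_ids: set[str],
    derived: list[SeqRecord],
    satellite_intervals,
    repeat_annotation,
):
    rng = rng_for(config.seed, "msms")
    gene_ids = sorted(gene_seqs)
    n_bins = _largest_remainder_counts(config.n_planted_genes, config.integrity_mix)
    if n_bins[2] < len(ms_ids):
        raise ConfigurationError(
            "the >50% integrity bin quota is smaller than n_male_specific_genes; "
            "male-specific genes must be plantable as high-integrity copies"
        )
    # male-specific genes occupy >50% slots first; remaining genes fill the
    # rest of the configured mix in shuffled order
    others = [g for g in gene_ids if g not in ms_ids]
    rng.shuffle(others)
    assignment: dict[str, str] = {}
    bin_slots = [BIN_LOW] * n_bins[0] + [BIN_MID] * n_bins[1] + [BIN_HIGH] * (n_bins[2] - len(ms_ids))
    rng.shuffle(bin_slots)
    for g in sorted(ms_ids):
        assignment[g] = BIN_HIGH
    for g, b in zip(others, bin_slots):
        assignment[g] = b

    bin_ranges = {BIN_LOW: (0.04, 0.09), BIN_MID: (0.15, 0.45), BIN_HIGH: (0.55, 0.90)}

    autosomes = [r for r in derived if r.id.startswith("A")]
    msm_records: list[SeqRecord] = []
    planted_genes: list[PlantedGene] = []
    homology_segments: list[tuple[str, int, int, str, int, int, float]] = []

    genes_per_msm: dict[int, list[str]] = {i: [] for i in range(config.n_msm)}
    for i, g in enumerate(gene_ids):
        genes_per_msm[i % config.n_msm].append(g)

    for mi in range(config.n_msm):
        msm_id = f"MSM{mi + 1}"
        blocks: list[tuple[str, str, object]] = []  # (kind, seq, meta)

        sat_bp = int(config.msm_satellite_fraction * config.msm_length)
        n_arrays = 3
        copies_each = max(1, sat_bp // (config.monomer_length * n_arrays))
        for _ in range(n_arrays):
            arr = _tandem_array(monomer, copies_each, config.satellite_copy_divergence, rng)
            blocks.append(("satellite", arr, None))

        te_plan = _te_copy_plan(config, mi)
        for fam, k in te_plan.items():
            for _ in range(k):
                blocks.append(("te", mutate_sequence(te_seqs[fam], 0.01, rng), fam))

        hom_bp = int(config.msm_homology_fraction * config.msm_length)
        ages = config.msm_homology_ages[mi]
        per_age = hom_bp // len(ages)
        for age in ages:
            used = 0
            while used < per_age:
                seg_len = int(rng.integers(300, 2500))
                src = autosomes[int(rng.integers(0, len(autosomes)))]
                # draw from the feature-free zone so segments carry no planted
                # gene or TE copies
                pos = int(rng.integers(len(src) // 2, len(src) - 10_000 - seg_len))
                seg = mutate_sequence(src.sequence[pos : pos + seg_len], age, rng)
                blocks.append(("homology", seg, (src.id, pos, pos + seg_len, age)))
                used += seg_len

        for g in genes_per_msm[mi]:
            frac = float(rng.uniform(*bin_ranges[assignment[g]]))
            cut = max(30, int(round(frac * config.gene_length)))
            end_used = "5p" if rng.random() < 0.5 else "3p"
            gseq = gene_seqs[g]
            sub = gseq[:cut] if end_used == "5p" else gseq[len(gseq) - cut :]
            blocks.append(("gene", sub, (g, cut / config.gene_length, assignment[g], end_used)))

        rng.shuffle(blocks)
        parts: list[str] = []
        pos = 0
        for kind, seq, meta in blocks:
            filler = _arr_to_str(_random_seq_arr(rng, int(rng.integers(50, 300))))
            parts.append(filler)
            pos += len(filler)
            start, end = pos, pos + len(seq)
            parts.append(seq)
            pos = end
            if kind == "satellite":
                satellite_intervals.setdefault(msm_id, []).append((start, end))
                repeat_annotation.setdefault(msm_id, []).append((start, end, "satellite"))
            elif kind == "te":
                repeat_annotation.setdefault(msm_id, []).append((start, end, f"TE:{meta}"))
            elif kind == "homology":
                src_id, src_s, src_e, age = meta
                homology_segments.append((msm_id, start, end, src_id, src_s, src_e, age))
            elif kind == "gene":
                g, frac, b, end_used = meta
                planted_genes.append(PlantedGene(g, msm_id, start, end, frac, b, end_used))
        parts.append(_arr_to_str(_random_seq_arr(rng, int(rng.integers(50, 300)))))
        msm_records.append(SeqRecord(msm_id, "".join(parts)))
    return msm_records, planted_genes, homology_segments


def _te_copy_plan(config: SimulationConfig, msm_index: int) -> dict[str, int]:
    """Genomic TE copy counts per family on one MSM: a spread of low and
    medium copy numbers (read-level masked-copy counts scale up by read
    coverage)."""
    fams = sorted(f"TE{i + 1:02d}" for i in range(config.n_te_families))
    plan: dict[str, int] = {}
    pattern = [1, 2, 3, 4, 6, 8, 10, 12]
    for i, fam in enumerate(fams):
        plan[fam] = pattern[(i + msm_index) % len(pattern)]
    return plan


# ---------------------------------------------------------------------------
# reads


def generate_reads(
    genome: list[SeqRecord],
    n: int,
    length: int,
    error_rate: float,
    seed: int,
    id_prefix: str = "r",
) -> list[SeqRecord]:
    """Uniform error-bearing reads over positions and strands.

    Read ids encode the true origin (``{prefix}{i}|chrom:start-end:strand``)
    for oracle use only.
    """
    if n < 0:
        raise ValidationError("n must be ≥ 0")
    eligible = [r for r in genome if len(r) >= length]
    if n > 0 and not eligible:
        raise ValidationError(f"no contig is ≥ read length {length}")
    rng = np.random.default_rng(seed)
    weights = np.array([len(r) - length + 1 for r in eligible], dtype=float)
    weights /= weights.sum()
    reads: list[SeqRecord] = []
    for i in range(n):
        ci = int(rng.choice(len(eligible), p=weights))
        contig = eligible[ci]
        start = int(rng.integers(0, len(contig) - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = contig.sequence[start : start + length]
        if strand == "-":
            seq = revcomp(seq)
        seq = mutate_sequence(seq, error_rate, rng)
        rid = f"{id_prefix}{i}|{contig.id}:{start}-{start + length}:{strand}"
        reads.append(SeqRecord(rid, seq))
    return reads


def read_origin(read_id: str) -> tuple[str, int, int, str]:
    """Parse the provenance suffix of a generated read id."""
    _, loc = read_id.split("|", 1)
    chrom, span, strand = loc.rsplit(":", 2)
    s, e = span.split("-")
    return chrom, int(s), int(e), strand


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    config: SimulationConfig, truth: TruthSet
) -> tuple[dict[str, list[SeqRecord]], pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Transcript sets per sex plus a stage × sex count table.

    Returns ``(transcripts, counts, lengths, gene_map)`` where ``counts`` is
    indexed by transcript id with columns ``{M,F}{stage}``.  Male-specific
    genes get structural zeros in all female samples; male-biased genes get a
    ``biased_log2fc`` shift in the male mean at the sex-determination stages;
    everything else is exchangeable between the sexes.  Counts are negative
    binomial with fixed dispersion.
    """
    rng = rng_for(config.seed, "expression")
    gene_rng = rng_for(config.seed, "genes")  # same stream as generate_genomes
    gene_ids = [f"G{i + 1:03d}" for i in range(config.n_planted_genes)]
    gene_seqs = {g: _arr_to_str(_random_seq_arr(gene_rng, config.gene_length)) for g in gene_ids}

    decoy_rng = rng_for(config.seed, "decoys")
    for i in range(config.n_decoy_genes):
        g = f"D{i + 1:03d}"
        gene_ids.append(g)
        gene_seqs[g] = _arr_to_str(_random_seq_arr(decoy_rng, config.gene_length))
    bg_rng = rng_for(config.seed, "background")
    for i in range(config.n_background_genes):
        g = f"B{i + 1:03d}"
        gene_ids.append(g)
        gene_seqs[g] = _arr_to_str(_random_seq_arr(bg_rng, config.gene_length))

    gene_map = {f"T_{g}": g for g in gene_ids}
    transcripts_all = [SeqRecord(f"T_{g}", gene_seqs[g]) for g in gene_ids]
    male_set = transcripts_all
    female_set = [t for t in transcripts_all if gene_map[t.id] not in truth.male_specific_gene_ids]

    stages = config.stages
    mu_base = rng.lognormal(mean=np.log(config.mean_expression), sigma=1.0, size=len(gene_ids))
    disp = config.nb_dispersion
    nb_n = 1.0 / disp

    cols = {}
    for sex in ("M", "F"):
        for stage in stages:
            mus = []
            for gi, g in enumerate(gene_ids):
                mu = mu_base[gi]
                if g in truth.male_specific_gene_ids:
                    mu = mu if sex == "M" else 0.0
                elif g in truth.male_biased_gene_ids and sex == "M":
                    mu = mu * 2.0 ** truth.biased_lfc[g][stage]
                mus.append(mu)
            mus = np.asarray(mus)
            counts = np.zeros(len(gene_ids), dtype=np.int64)
            pos = mus > 0
            p = nb_n / (nb_n + mus[pos])
            counts[pos] = rng.negative_binomial(nb_n, p)
            cols[f"{sex}{stage}"] = counts
    counts = pd.DataFrame(cols, index=[f"T_{g}" for g in gene_ids])
    lengths = pd.DataFrame(
        {"length": [len(gene_seqs[g]) for g in gene_ids]}, index=[f"T_{g}" for g in gene_ids]
    )
    transcripts = {"M": male_set, "F": female_set}
    return transcripts, counts, lengths, gene_map


# ---------------------------------------------------------------------------
# bundle + writers


@dataclass
class SimulationResult:
    config: SimulationConfig
    ancestor: list[SeqRecord]
    derived: list[SeqRecord]
    msms: list[SeqRecord]
    truth: TruthSet
    reads_ancestor: list[SeqRecord]
    reads_derived: list[SeqRecord]
    msm_reads: dict[str, list[SeqRecord]]
    transcripts: dict[str, list[SeqRecord]]
    counts: pd.DataFrame
    lengths: pd.DataFrame
    gene_map: dict[str, str]

    @property
    def cds_pool(self) -> list[SeqRecord]:
        """Reference CDS set: planted genes plus decoys absent from the MSMs
        (re-derived from the generator's named substreams)."""
        gene_rng = rng_for(self.config.seed, "genes")
        pool = [
            SeqRecord(f"CDS_G{i + 1:03d}", _arr_to_str(_random_seq_arr(gene_rng, self.config.gene_length)))
            for i in range(self.config.n_planted_genes)
        ]
        decoy_rng = rng_for(self.config.seed, "decoys")
        pool += [
            SeqRecord(f"CDS_D{i + 1:03d}", _arr_to_str(_random_seq_arr(decoy_rng, self.config.gene_length)))
            for i in range(self.config.n_decoy_genes)
        ]
        return pool

    @property
    def repeat_library(self) -> list[SeqRecord]:
        """Satellite consensus + TE family sequences with class labels."""
        lib = [SeqRecord("satellite_CL1", self.truth.satellite_consensus, "class=satellite")]
        te_rng = rng_for(self.config.seed, "tes")
        for i in range(self.config.n_te_families):
            fam = f"TE{i + 1:02d}"
            lib.append(
                SeqRecord(fam, _arr_to_str(_random_seq_arr(te_rng, self.config.te_length)), f"class=TE:{fam}")
            )
        return lib


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator: genomes, MSMs, reads, expression, truth."""
    ancestor, derived, msms, truth = generate_genomes(config)
    seed = config.seed
    reads_anc = generate_reads(
        ancestor,
        config.reads_per_sample,
        config.read_length,
        config.read_error_rate,
        int(rng_for(seed, "reads_ancestor").integers(2**31)),
        id_prefix="anc",
    )
    reads_der = generate_reads(
        derived,
        config.reads_per_sample,
        config.read_length,
        config.read_error_rate,
        int(rng_for(seed, "reads_derived").integers(2**31)),
        id_prefix="der",
    )
    msm_reads = {}
    for msm in msms:
        n_per_msm = int(len(msm) * config.msm_coverage / config.msm_read_length)
        msm_reads[msm.id] = generate_reads(
            [msm],
            n_per_msm,
            config.msm_read_length,
            config.read_error_rate,
            int(rng_for(seed, f"reads_{msm.id}").integers(2**31)),
            id_prefix=f"{msm.id.lower()}_",
        )
    transcripts, counts, lengths, gene_map = generate_expression(config, truth)
    return SimulationResult(
        config=config,
        ancestor=ancestor,
        derived=derived,
        msms=msms,
        truth=truth,
        reads_ancestor=reads_anc,
        reads_derived=reads_der,
        msm_reads=msm_reads,
        transcripts=transcripts,
        counts=counts,
        lengths=lengths,
        gene_map=gene_map,
    )


def write_simulation(result: SimulationResult, outdir: str | Path) -> None:
    """Write FASTA/TSV/BED/JSON products of one simulation, deterministically."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(result.ancestor, out / "ancestor.fa")
    write_fasta(result.derived, out / "derived.fa")
    write_fasta(result.msms, out / "msms.fa")
    write_fasta(result.reads_ancestor, out / "reads_ancestor.fa")
    write_fasta(result.reads_derived, out / "reads_derived.fa")
    for msm_id, reads in result.msm_reads.items():
        write_fasta(reads, out / f"reads_{msm_id}.fa")
    for sex, recs in result.transcripts.items():
        write_fasta(recs, out / f"transcripts_{sex}.fa")
    write_fasta(result.repeat_library, out / "repeat_library.fa")
    result.counts.to_csv(out / "counts.tsv", sep="\t", index_label="feature_id")
    result.lengths.to_csv(out / "lengths.tsv", sep="\t", index_label="feature_id")
    pd.DataFrame(
        sorted(result.gene_map.items()), columns=["transcript_id", "gene_id"]
    ).to_csv(out / "gene_map.tsv", sep="\t", index=False)

    truth = result.truth
    with open(out / "truth_planted_genes.tsv", "w") as fh:
        fh.write("gene_id\tmsm_id\tstart\tend\tintegrity\tbin\tend_used\n")
        for g in sorted(truth.planted_genes, key=lambda x: (x.msm_id, x.start)):
            fh.write(
                f"{g.gene_id}\t{g.msm_id}\t{g.start}\t{g.end}\t{g.integrity:.4f}\t{g.bin}\t{g.end_used}\n"
            )
    with open(out / "truth_repeats.bed", "w") as fh:
        for chrom in sorted(truth.repeat_annotation):
            for s, e, klass in sorted(truth.repeat_annotation[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\t{klass}\n")
    meta = {
        "config": asdict(result.config),
        "derived_satellite_fraction": truth.derived_satellite_fraction,
        "male_specific_gene_ids": sorted(truth.male_specific_gene_ids),
        "male_biased_gene_ids": sorted(truth.male_biased_gene_ids),
        "satellite_consensus": truth.satellite_consensus,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# synthetic stand-in for the published male-marker worked example


def synthetic_marker_standin(seed: int = 20) -> tuple[SeqRecord, SeqRecord]:
    """SYNTHETIC stand-in for the male-specific marker worked example.

    Constructs a marker-like sequence containing exactly five intact and four
    fragmental copies of a 137 bp monomer (2% per-copy divergence, mixed
    strands and truncations), mirroring the structure reported for the real
    male-specific marker sequence.  This is generated data, not the GenBank
    record; it exercises the same scan logic with a known answer.

    Returns ``(consensus, marker)``.
    """
    rng = np.random.default_rng(seed)
    monomer = _arr_to_str(BASES[rng.integers(0, 4, 137)])

    def copy(frac: float, strand: str, end: str) -> str:
        cut = int(round(frac * len(monomer)))
        seq = monomer[:cut] if end == "5p" else monomer[len(monomer) - cut :]
        seq = mutate_sequence(seq, 0.02, rng)
        return revcomp(seq) if strand == "-" else seq

    def linker(n: int) -> str:
        return _arr_to_str(BASES[rng.integers(0, 4, n)])

    parts = [
        linker(120),
        copy(1.0, "+", "5p"),
        copy(1.0, "+", "5p"),
        linker(90),
        copy(0.55, "+", "5p"),
        linker(60),
        copy(1.0, "-", "5p"),
        linker(140),
        copy(0.40, "-", "3p"),
        linker(70),
        copy(1.0, "+", "5p"),
        linker(55),
        copy(0.62, "+", "3p"),
        copy(1.0, "+", "5p"),
        linker(80),
        copy(0.33, "+", "5p"),
        linker(110),
    ]
    marker = SeqRecord(
        "synthetic_marker_standin",
        "".join(parts),
        "synthetic stand-in: 5 intact + 4 fragmental planted monomer copies",
    )
    return SeqRecord("synthetic_consensus", monomer), marker
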