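"""End-to-end orchestration on simulated data, with truth-based scoring.

``run_demo`` generates a study system from one seed, runs every analysis
stage, and scores the results against the generator's truth set: repeat
discovery (top comparative cluster, consensus recovery, genome proportion),
homology and divergence profiling, repeat content, gene calling and
integrity, two-round subtraction with fragment collapse, and the sex-biased
expression screen.  The returned summary carries only quantities computed
during the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import repeat_discovery as rd
from . import msm_homology as mh
from . import gene_annotation as ga
from . import subtraction_pipeline as sp
from . import expression_screen as es
from .seqio_align import SeqRecord, minimap2_align, write_fasta
from .synthetic_data import (
    SimulationConfig,
    SimulationResult,
    read_origin,
    rng_for,
    simulate,
    write_simulation,
)

logger = logging.getLogger(__name__)


@dataclass
class DemoSummary:
    config: SimulationConfig
    repeat: dict = field(default_factory=dict)
    homology: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)
    subtraction: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "config": asdict(self.config),
            "repeat": self.repeat,
            "homology": self.homology,
            "genes": self.genes,
            "subtraction": self.subtraction,
            "expression": self.expression,
        }


def fragment_msm_interval(result: SimulationResult, frag: sp.Fragment) -> tuple[str, int, int]:
    """Truth-side helper: a fragment's interval in MSM coordinates, via the
    provenance of the read it sits on."""
    chrom, r_start, r_end, strand = read_origin(frag.msm_read_id)
    if strand == "+":
        return chrom, r_start + frag.start, r_start + frag.end
    return chrom, r_end - frag.end, r_end - frag.start


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return min(a[1], b[1]) - max(a[0], b[0]) > 0


# ---------------------------------------------------------------------------


def run_repeat_stage(result: SimulationResult) -> dict:
    cfg = result.config
    n = cfg.reads_per_sample
    sample_a = rd.sample_reads(
        result.reads_derived, n, int(rng_for(cfg.seed, "sample_a").integers(2**31))
    )
    sample_b = rd.sample_reads(
        result.reads_ancestor, n, int(rng_for(cfg.seed, "sample_b").integers(2**31))
    )
    graph, hits_a, hits_b = rd.build_similarity_graph(sample_a, sample_b)
    clusters = rd.cluster_graph(graph)
    out: dict = {"n_clusters": len(clusters)}
    if not clusters:
        return out
    top = clusters[0]
    reads_by_id = {r.id: r for r in [*sample_a, *sample_b]}
    consensus = rd.derive_consensus(top, reads_by_id)
    truth = result.truth

    purity_hits = 0
    for rid in top.members_a | top.members_b:
        chrom, s, e, _ = read_origin(rid)
        if truth.overlaps_satellite(chrom, s, e):
            purity_hits += 1
    out.update(
        top_cluster_id=top.cluster_id,
        top_size_a=top.size_a,
        top_size_b=top.size_b,
        top_genome_proportion_a=top.genome_proportion_a,
        top_genome_proportion_b=top.genome_proportion_b,
        top_expansion_ratio=top.expansion_ratio,
        max_other_expansion_ratio=max((c.expansion_ratio for c in clusters[1:]), default=0.0),
        top_cluster_satellite_purity=purity_hits / (top.size_a + top.size_b),
        consensus_length=len(consensus),
        consensus_identity_to_truth=rd.rotational_identity(
            consensus.sequence, truth.satellite_consensus
        ),
        truth_satellite_fraction=truth.derived_satellite_fraction,
        consensus_sequence=consensus.sequence,
    )
    return out


def run_homology_stage(result: SimulationResult, repeat_subsample: int = 60) -> dict:
    cfg = result.config
    out: dict = {"per_msm": {}}
    for mi, msm_id in enumerate(sorted(result.msm_reads)):
        reads = result.msm_reads[msm_id]
        hsps = minimap2_align(reads, result.derived, preset="map-ont")
        confident = [h for h in hsps if h.mapq > 10]
        blocks = mh.hits_to_blocks(hsps, mapq_min=10)
        frac, per_chrom = mh.homologous_proportion(confident, reads)
        with_aln = [
            h
            for h in confident
            if h.q_aln is not None and mh.alignment_gap_fraction(h) <= 0.15
        ]
        entry = {
            "n_hits_confident": len(confident),
            "n_blocks": len(blocks),
            "homologous_proportion": frac,
            "top_linkage_group": max(
                (c for c in per_chrom if c.startswith("A")),
                key=lambda c: per_chrom[c],
                default=None,
            ),
        }
        if with_aln:
            sampled = mh.sample_hits_for_divergence(
                with_aln, 120, seed=int(rng_for(cfg.seed, f"div_{msm_id}").integers(2**31))
            )
            ests = [mh.kimura_from_hsp(h) for h in sampled]
            _, _, modes = mh.divergence_profile([e for e in ests if not e.saturated])
            entry["divergence_modes"] = modes[:3]
            entry["truth_ages"] = list(cfg.msm_homology_ages[mi])
        rng = np.random.default_rng(int(rng_for(cfg.seed, f"rc_{msm_id}").integers(2**31)))
        sub_idx = rng.choice(len(reads), size=min(repeat_subsample, len(reads)), replace=False)
        summary = mh.repeat_content([reads[i] for i in sorted(sub_idx)], result.repeat_library)
        entry["reads_with_repeat"] = summary.reads_with_repeat
        entry["repeat_bp_fraction"] = summary.repeat_bp_fraction
        entry["te_copy_bins"] = summary.te_copy_bins
        out["per_msm"][msm_id] = entry
    msm_ids = sorted(result.msm_reads)
    if len(msm_ids) >= 3:
        pair_fracs = {}
        for a, b in [(0, 2), (1, 0), (1, 2)]:
            key = f"{msm_ids[a]}_vs_{msm_ids[b]}"
            # query-side subsample: the proportion is a per-read statistic
            qreads = result.msm_reads[msm_ids[a]]
            rng = np.random.default_rng(int(rng_for(cfg.seed, f"pw_{key}").integers(2**31)))
            idx = rng.choice(len(qreads), size=min(80, len(qreads)), replace=False)
            pair_fracs[key] = mh.pairwise_msm_homology(
                [qreads[i] for i in sorted(idx)], result.msm_reads[msm_ids[b]]
            )
        out["pairwise"] = pair_fracs
    return out


def run_gene_stage(result: SimulationResult) -> dict:
    gene_map = dict(result.gene_map)
    for rec in result.cds_pool:
        gene_map[rec.id] = rec.id.removeprefix("CDS_")
    calls, shared = ga.call_genes(
        result.msm_reads,
        transcriptome=result.transcripts["M"],
        cds_pool=result.cds_pool,
        gene_map=gene_map,
    )
    called_genes = sorted({c.gene_id for c in calls})
    truth = result.truth
    plantable = {
        g.gene_id
        for g in truth.planted_genes
        if (g.end - g.start) >= 200
    }
    recovered = plantable & set(called_genes)
    decoys_called = [g for g in called_genes if g.startswith("D")]
    integrity = ga.integrity_from_hits(result.msm_reads, result.cds_pool, gene_map)
    bin_counts = {ga.BIN_LOW: 0, ga.BIN_MID: 0, ga.BIN_HIGH: 0}
    for sc in integrity:
        if sc.gene_id.startswith("G"):
            bin_counts[sc.bin] += 1
    return {
        "n_calls": len(calls),
        "n_genes_called": len(called_genes),
        "plantable_genes": len(plantable),
        "recovered_plantable": len(recovered),
        "recall_plantable": len(recovered) / len(plantable) if plantable else 0.0,
        "decoy_calls": len(decoys_called),
        "shared_all_msms": sorted(shared.get(frozenset(sorted(result.msm_reads)), set())),
        "integrity_bins_estimated": bin_counts,
        "integrity_bins_truth": truth.integrity_bin_counts(),
        "called_genes": called_genes,
    }


def run_subtraction_stage(result: SimulationResult, called_genes: list[str]) -> dict:
    truth = result.truth
    m_counts = result.counts[[c for c in result.counts.columns if c.startswith("M")]]
    male_present = set(m_counts.index[m_counts.sum(axis=1) > 0])
    by_id = {t.id: t for t in result.transcripts["M"]}
    msm_linked = [
        by_id[f"T_{g}"]
        for g in sorted(called_genes)
        if f"T_{g}" in by_id and f"T_{g}" in male_present
    ]
    all_reads = [r for reads in result.msm_reads.values() for r in reads]
    report = sp.run_subtraction(
        msm_linked_transcripts=msm_linked,
        msm_reads=all_reads,
        transcriptome_refs=[result.transcripts["F"]],
        genome_ref=result.derived,
    )
    ms_intervals: dict[str, list[tuple[int, int]]] = {}
    for g in truth.planted_genes:
        if g.gene_id in truth.male_specific_gene_ids:
            ms_intervals.setdefault(g.msm_id, []).append((g.start, g.end))
    tp = 0
    hit_genes: set[str] = set()
    for frag in report.representatives:
        chrom, s, e = fragment_msm_interval(result, frag)
        ok = any(_overlaps((s, e), iv) for iv in ms_intervals.get(chrom, []))
        if ok:
            tp += 1
            for g in truth.planted_genes:
                if (
                    g.gene_id in truth.male_specific_gene_ids
                    and g.msm_id == chrom
                    and _overlaps((s, e), (g.start, g.end))
                ):
                    hit_genes.add(g.gene_id)
    n_rep = len(report.representatives)
    n_ms = len(truth.male_specific_gene_ids)
    return {
        "stage_counts": report.stage_counts,
        "n_candidates": len(report.candidates),
        "n_representatives": n_rep,
        "precision": tp / n_rep if n_rep else 0.0,
        "recall": len(hit_genes) / n_ms if n_ms else 0.0,
        "orf_lengths": sorted(
            (sp.longest_orf_length(f.sequence) for f in report.representatives), reverse=True
        )[:10],
        "_report": report,
    }


def run_expression_stage(result: SimulationResult, report: sp.SubtractionReport | None) -> dict:
    cfg = result.config
    truth = result.truth
    table, lfc_df, flags_df = es.expression_flags(
        result.counts, result.lengths["length"], cfg.stages
    )
    biased_cols = [s for s in cfg.biased_stages]
    mb = [f"T_{g}" for g in sorted(truth.male_biased_gene_ids)]
    flagged = [
        t for t in mb if any(flags_df.loc[t, s] == "male_biased" for s in biased_cols)
    ]
    neutral = [
        t
        for t in flags_df.index
        if t.startswith("T_B")
    ]
    neutral_flagged = [
        t for t in neutral if any(flags_df.loc[t, s] == "male_biased" for s in biased_cols)
    ]
    ms = [f"T_{g}" for g in sorted(truth.male_specific_gene_ids)]
    out = {
        "male_biased_sensitivity": len(flagged) / len(mb) if mb else 0.0,
        "neutral_flagged_rate": len(neutral_flagged) / len(neutral) if neutral else 0.0,
        "male_specific_detected": int(flags_df.loc[ms, "male_specific"].sum()),
        "n_male_specific_truth": len(ms),
    }
    if report is not None and report.representatives:
        screened = es.male_candidate_screen(
            report.representatives, lfc_df, stages_before=cfg.biased_stages
        )
        kept_ids = set(screened["fragment_id"]) if not screened.empty else set()
        ms_frags = {
            f.fragment_id
            for f in report.representatives
            if result.gene_map.get(f.source_transcript_id) in truth.male_specific_gene_ids
        }
        out["screen_kept"] = len(kept_ids)
        out["screen_kept_truth_ms"] = len(kept_ids & ms_frags)
        out["n_truth_ms_fragments"] = len(ms_frags)
    return out


def run_demo(
    seed: int = 1,
    config: SimulationConfig | None = None,
    outdir: str | Path | None = None,
) -> DemoSummary:
    """Simulate, run every stage, and score against truth."""
    cfg = config if config is not None else SimulationConfig(seed=seed)
    result = simulate(cfg)
    summary = DemoSummary(config=cfg)
    logger.info("repeat discovery …")
    summary.repeat = run_repeat_stage(result)
    logger.info("homology …")
    summary.homology = run_homology_stage(result)
    logger.info("gene annotation …")
    summary.genes = run_gene_stage(result)
    logger.info("subtraction …")
    summary.subtraction = run_subtraction_stage(result, summary.genes["called_genes"])
    report = summary.subtraction.pop("_report")
    logger.info("expression screen …")
    summary.expression = run_expression_stage(result, report)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_simulation(result, outdir / "simulation")
        if "consensus_sequence" in summary.repeat:
            write_fasta(
                [SeqRecord("recovered_consensus", summary.repeat["consensus_sequence"])],
                outdir / "consensus.fa",
            )
        write_fasta(
            [SeqRecord(f.fragment_id, f.sequence) for f in report.representatives],
            outdir / "candidate_fragments.fa",
        )
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary.as_dict(), fh, indent=2, sort_keys=True, default=str)
    return summary
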