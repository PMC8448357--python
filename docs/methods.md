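# Methods

`msm-anatomy` re-implements, at desk scale and with a fully seeded synthetic
study system, the sequence-anatomy workflow used to characterise
male-specific supernumerary microchromosomes (MSMs) in a gynogenetic fish:
comparative repeat discovery between an ancestor-like and a derived genome,
homology and divergence profiling of microdissected chromosome read sets,
gene-content statistics, a two-round transcriptome/genome subtraction, and a
sex-biased expression screen.  This note records the models, the parameter
choices, and the places where the design was genuinely open.

## The synthetic study system

The generator (`synthetic_data`) builds the comparative design the analysis
assumes, with every feature recorded in a machine-readable truth set:

* **Genomes.** An ancestor genome (default 2 Mb over 4 autosomes) carries a
  low-copy relic array (5 copies) of a random 137 bp satellite monomer.  The
  derived genome shares the autosomes (0.5% substitution divergence — two
  closely related congeners) and adds microchromosomes carrying a massive
  tandem expansion of the same monomer (default 2,000 copies over 4
  microchromosomes, ≈12% of the derived genome).  Tandem copies diverge 1%
  per copy, so consensus recovery is non-trivial but unambiguous.
* **MSMs.** Three ~75 kb MSM sequences composed of satellite arrays (~30%
  of length), transposable-element copies from 8 planted TE families,
  autosome-derived homology segments (~30%) planted at known divergence
  ages (MSM1: 1% and 10%; MSM2: 3%; MSM3: 1% and 8% — a bimodal and a
  unimodal age structure), truncated gene copies, and random filler.
* **Genes.** 30 planted genes of 1,500 bp.  Each gets one truncated copy on
  an MSM — a contiguous 5′ or 3′ subsequence (coin flip) — with integrity
  fractions drawn per configured bin (defaults 0.4 / 0.3 / 0.3 for <10%,
  10–50%, >50%).  Fractions are drawn away from the bin edges
  (0.04–0.09, 0.15–0.45, 0.55–0.90) so that measurement noise cannot
  straddle a boundary; this is a deliberate identifiability choice, not a
  claim about real integrity distributions.  Four genes are male-specific:
  they exist **only** on MSMs (no autosomal locus, absent from the female
  transcriptome).  Because a fragment is definitionally ≥200 bp, the
  male-specific genes occupy >50%-integrity slots — transcriptionally
  active, near-intact copies, consistent with how confirmed candidates
  present.  Five further genes are male-biased.  Ten decoy genes appear in
  the references but nowhere on the MSMs; ~470 background genes pad the
  expression tables to a realistic multiple-testing burden.
* **Expression.** One pooled sample per sex per stage (no replicates), nine
  stages at 18–70 days after hatch (dah).  Counts are negative binomial
  (dispersion 0.1, exposed in config) around lognormal per-gene means
  (median 200).  Male-specific genes have structural zeros in every female
  sample; male-biased genes carry a log2 fold change of 2 in the male mean
  at the five stages before 40 dah (the sex-determination window).
* **Reads.** Uniform substitution-only reads (error 0.002).  Clustering
  samples are 800 reads × 300 bp per genome; 300 bp (rather than a short-read
  125–150 bp) keeps a full monomer period detectable inside single reads.
  MSM read sets are 2 kb reads at 8× coverage (~300 reads per MSM).  Read
  ids carry their true origin; only tests and truth-scoring parse it.

What the generator does **not** emulate: indel-rich long-read error models,
amplification bias of whole-chromosome amplification, polyploid haplotype
structure, intron structure (transcripts equal their genomic loci), and
library-size imbalance between sexes.  Passing tests therefore demonstrate
the correctness of the pipeline's logic and statistics under the stated
generative model, not robustness to those real-data complications.

## Alignment layer

All stages consume one HSP record with 0-based half-open coordinates (query
coordinates always on the forward query strand).  Identity is matched
columns over all alignment columns, gaps included — the convention that the
cumulative statistics below aggregate.  Two engines sit behind the same
surface:

* an exhaustive Smith–Waterman (Biopython's C `PairwiseAligner`;
  megablast-like scores 2/−3, gaps −5/−2) that reports multiple HSPs per
  pair by masking the best hit's target interval and re-aligning, used
  wherever sensitivity and rotation handling matter (similarity edges,
  monomer scans, CIP/CALP linking, fragment collapse); candidate pairs are
  prefiltered by shared canonical 13-mers so the all-to-all stays tractable;
* the `minimap2` executable for genome-scale mapping (the class of mapper
  the original analyses used), run with `-c --cs` when base-level columns
  are needed; aligned strings are reconstructed from the `cs` tag so
  divergence is estimated on the actual alignment columns.  A mapper-grade
  MapQ comes directly from minimap2; the internal aligner's MapQ surrogate
  is `60·(1 − second_best/best)` over a query's HSP scores.

## Comparative repeat discovery

Equal-size read samples from the two genomes are compared all-to-all; an
edge requires a local alignment at ≥90% identity covering ≥55% of the
shorter read (the conventional comparative-clustering edge criterion;
configurable).  Clusters are connected components, ranked by size;
singletons are excluded.  Per-species cluster share of the sample
approximates the genome fraction occupied by the repeat (reads are
equal-length).  The expansion ratio uses +1 smoothing so clusters absent
from one species rank finitely.

The consensus monomer is recovered without assembly: the highest-degree
member read seeds the monomer; its period is the smallest self-comparison
shift whose match fraction is within 5% of the optimum (multiples of the
true period score equally, hence "smallest"); monomer-sized hits of the
seed across all members vote per column; the majority consensus is
canonicalised to its lexicographically minimal rotation so comparisons are
rotation-invariant.

The monomer scan doubles the consensus so copies at any rotational phase
align contiguously, chops alignments back into per-copy pieces, selects
non-overlapping hits greedily by score, and classifies copies as intact
(consensus coverage ≥0.90) or fragmental (≥0.25).  These two thresholds are
this package's operational definition of "intact"; the source analyses never
state one.

Because the original male-marker sequence and published consensus are not
available as local inputs, the worked example for the scan is a *synthetic
stand-in* constructed with the same reported structure (five intact plus
four fragmental copies, mixed strands and truncations, 2% copy divergence);
it exercises the same code path with a known answer.

## Homology and divergence

MSM reads are mapped to the derived (female) genome; hits with MapQ
strictly >10 are merged into homology blocks per linkage group (overlapping
or bookended intervals).  The homologous proportion is the union of aligned
read bases over all read bases — a base fraction, not a read fraction (the
reported statistic does not say which; base fraction is documented here as
the package's choice).  Each base is attributed to its best-scoring hit,
ties to the lexicographically smallest chromosome, for determinism.

Divergence uses the Kimura two-parameter distance
`d = −½·ln((1−2P−Q)·√(1−2Q))` computed on ungapped, unambiguous alignment
columns of each hit; outside the formula's domain the estimate is flagged
saturated and excluded rather than raised.  Hits whose alignment is more than 15% gap
columns are screened out first: such hits are chains stitched across
unrelated flanking sequence (a known artifact of chaining around interspersed
repeats), and their substitution proportions estimate no single segment's
divergence.  120 of the remaining hits per MSM are sampled stratified by
aligned length ([200,500), [500,1000), [1000,2000), [2000,∞); equal quotas,
deficits redistributed) — the stratum bounds are package-defined, the
source says only "different length sections".  The histogram (0.01 bins)
reports as modes the local maxima of a 1-2-1-smoothed copy (≥15% of the
tallest smoothed bin), each located at the count-weighted centre of the
maximum and its neighbours; smoothing keeps a genuinely broad divergence
peak from losing to a narrow spurious spike.  Note the planted substitution rates are uniform across substitution
types, so a planted rate *r* appears at K2P distance slightly above *r*
(e.g. 10% → ≈0.11); modes are compared against planted ages with a ±0.02
band, which absorbs this plus the 0.002 read error.

Repeat content masks reads against a labelled library (satellite / TE
family / unknown) at identity ≥0.80 over ≥30 bp, resolves overlaps to the
higher-scoring class (class fractions are additive), and bins TE families
by masked-copy count (low 1–10, medium 11–100, high >100).  In the
end-to-end run this statistic is computed on a 60-read subsample per MSM
and pairwise MSM homology on an 80-read query subsample — both are
per-read statistics for which subsampling changes only the standard error;
the problem sizes are stated in the summary.

## Gene content

Two routes call a gene on an MSM: a mapping route (MapQ ≥10, aligned length
≥200 bp — non-strict, following that step's stated rule, in contrast to the
strict >10 of the block step) and a similarity route (identity >75%, length
≥200 bp).  In this implementation both routes are fed by one base-level
mapping run per reference set; they remain distinct filters, and tests
drive them independently through injected hit lists.  Cumulative statistics
per query: CIP = 100·ΣID/ΣAL across HSPs, CALP = 100·ΣAL/query length.
CALP is deliberately uncapped when HSPs overlap, since the defining formula
does not deduplicate aligned length.  CDS-pool calls are linked to
transcripts of the same gene when CIP ≥60 and CALP ≥70; transcript ids
collapse to genes via an explicit id-mapping table (orthology clustering is
out of scope; the generator ships the mapping).

Integrity is the union coverage of a gene's full-length CDS by its MSM
hits, measured with a permissive short-seed mapping (identity ≥0.80,
≥40 bp) so heavily truncated copies register, and binned <10% (strict),
10–50% (inclusive), >50% (strict, "over 50%").

## Subtraction

A query is discarded when **any single reference sequence** explains it at
coverage >90% of the query's full length AND cumulative identity >98% —
both strict ("over", "higher than"), evaluated per target rather than
pooled across targets, because the rule describes one aligned sequence's
coverage.  Round 1 removes MSM-linked, male-present transcripts explainable
by an MSM-free transcriptome and then by the female genome.  Survivors are
re-anchored on MSM reads as gene fragments (identity >75% over ≥200 bp, the
definitional minimum), round 2 applies the same rule to the fragments, and
the surviving candidates are collapsed by single-linkage clustering (link:
pairwise alignment covering ≥80% of the shorter at ≥90% identity — an
automated, threshold-explicit version of a manual overlap subtraction),
keeping the longest member of each group.  Stage counts are conserved at
every step (kept + discarded = input), and a longest-ORF length is reported
per representative as a light coding-potential indicator in place of a full
homology-based conservation call.

## Expression screen

FPKM = count·10⁹/(length·library size), with any exact zero replaced by
0.001 afterwards so ratios against silent features stay finite.  The effect
size is log2(male/female) of substituted FPKM.  With one pooled sample per
sex and stage there is no replicate-aware model; the p-value comes from a
pluggable two-sample count test, by default a two-proportion normal test of
the feature's count against the library total, with Benjamini–Hochberg FDR
across features within each stage.  The defining thresholds are |log2FC| ≥1
and FDR ≤0.05; the original MARS-model parameters are accepted in config
for provenance but unused by the default test, because the screen's
definitional cut-offs are the fold-change and FDR rules.  Sex-specificity
is a raw-count property: zero in every sample of the other sex.  The
candidate screen keeps fragments (quantified through their source
transcript) with log2FC ≥1 at ≥1 stage before 40 dah and ranks by the
maximum fold change — "higher transcription level" operationalised as the
same ≥1 threshold used for biased calls.

## Determinism and problem sizes

All randomness descends from one root seed via named substreams
(`SeedSequence([seed, crc32(name)])`), so each stage is independently
reproducible and two runs with one config are byte-identical in every
output.  The default end-to-end run (seed 1) uses the sizes above and
completes in a few minutes on one CPU; `scripts/acceptance.py` recomputes
every summary quantity from scratch at those sizes.

## Known limitations

* The comparative clustering is connected components, not community
  detection; at much larger scale a single spurious edge can bridge
  families (community detection is left behind a flag-level extension).
* Pairwise MSM homology in the synthetic system is dominated by the repeat
  classes all MSMs share, so relative pairwise orderings between specific
  MSM pairs are not a planted signal.
* The MapQ surrogate of the internal aligner understates uniqueness for
  multi-HSP queries whose HSPs are complementary rather than alternative;
  pipeline steps that filter on MapQ use mapper-produced values.
* The subtraction's per-target rule means a reference set that explains a
  query only piecewise (each piece <90% coverage) never discards it; this
  matches the quoted rule but differs from a pooled-coverage reading.
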