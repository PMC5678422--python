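# Methods

`tetrap` re-implements, as a tested library and pipeline, the computational
framework used to characterise transposable-element (TE) control during
induced global DNA demethylation in mouse embryonic stem cells: TE-class
expression quantitation, detection of pervasive antisense ("trap")
transcription over genes, endogenous-siRNA signature analysis of
AGO2-bound small RNAs, bisulfite methylation quantitation, and
repressive-chromatin enrichment over TE classes. Because the framework is
meant to be verifiable without access to genome-scale sequencing data, a
synthetic-data generator produces inputs with the statistical structure
the analyses assume, at desk scale, so every stage can be checked against
its own generating parameters.

## The synthetic time course

The generator emulates a conditional *Dnmt1*-knockout-like experiment
sampled at days 0, 3, 6 and 9:

- **Genome and annotation.** Two chromosomes totalling 2 Mb carry 200
  non-overlapping genes (1.5–2.5 kb) and 60 instances each of six TE
  classes (IAP-like, MERVL-like, ETn-like, L1-like, MMERVK-like, and a
  transcriptionally neutral SINE-like class; 0.4–1.2 kb). Ten percent of
  each class is embedded in gene bodies, antisense to the host gene with
  probability 0.7 (the reported insertion bias); the remainder is placed
  intergenic, deliberately more than 2 kb from any gene so it survives
  the genic-exclusion filter downstream. Feature kinds are dealt
  round-robin across chromosomes and interleaved in shuffled order, so
  per-chromosome load is balanced and placement cannot overflow for any
  seed; an impossible request raises a placement error naming the
  constraint.
- **Methylome.** CpG sites sit on a fixed 1-per-100-bp grid (~20,000
  sites). Coverage is Poisson(10); methylated calls are Binomial with a
  per-site rate drawn from a Beta centred on the global mean for that day
  (0.85 / 0.35 / 0.20 / 0.20) with concentration 20 for realistic
  overdispersion. IAP-like CpGs use the global mean + 0.20 (capped at 1),
  emulating the relative resistance of IAPs to demethylation. Dynamics
  are parameterised directly as per-day target means, not a kinetic
  model: the system being emulated is described by level snapshots, not
  rate constants.
- **Stranded RNA-seq.** Reads are allocated multinomially over genes
  (log-normal expression weights, σ = 0.5, fixed per genome) and TE
  instances. A TE's rate is `0.1 × activation[class][day] ×
  (1 − methylation mean of that class at that day)` — a linear coupling
  between methylation loss and transcription. The coupling itself is a
  modeling choice; nothing in the emulated system fixes its functional
  form. The neutral SINE-like class is methylation-uncoupled (it keeps
  its day-0 rate): without this, *any* class would rise several-fold as
  global methylation falls, and no class could serve as a
  negative control for the differential tests. Read strand equals
  transcript strand; ingestion of real dUTP-protocol data is where a
  reverse-strand convention would be applied. Five percent of reads draw
  MAPQ below 20 and are discarded by every counter.
- **Small RNA libraries.** 350,000 reads per library: 90% miRNA (fixed
  mature species at 50 annotated loci), 2% rRNA background, and a
  remainder of which 40% (at the day-9 reference) are TE-derived duplex
  siRNAs, the rest unannotated genomic fragments kept clear of repeats.
  Each duplex draws guide lengths from {20: .05, 21: .15, 22: .55,
  23: .15, 24: .10}, places the antisense guide with a 2-nt 3′ overhang
  (so the 5′-5′ overlap of a 22-mer pair is 20 nt), and gives each guide
  a 5′ U with probability 0.75. Total siRNA abundance scales with the
  summed class-wise product of sense rate and antisense-insertion count —
  the dsRNA-trap assumption that both strands are required — normalised
  to the final timepoint; per-class allocation follows the same product.
  Guide sequences are drawn i.i.d. with the 5′ bias applied directly;
  consensus-space coordinates are carried as generator truth rather than
  recovered by sequence matching, since a Bernoulli 5′ base cannot be
  guaranteed to match a fixed consensus and base-level sequence realism
  is out of scope.
- **ChIP tiles.** Per-1-kb-tile counts are Poisson(20 × multiplier), with
  per-mark, per-class, per-day multipliers: H3K9me3 constitutively high
  at IAP-like elements (4× at day 0), H3K27me3 and H3K9me2 gained there
  during demethylation (1× → 3× and 1× → 2.5× by day 9).

All randomness flows from one root seed through named child streams
(stage, sample, day), so identical (config, seed) pairs give
byte-identical outputs and distinct samples are independent.

## Analysis stages

- **Coordinates.** 0-based half-open everywhere internally; BED is native,
  GFF3 and Bismark-coverage positions are converted on read. Readers
  reject malformed records with line numbers instead of clamping.
- **Genic exclusion.** TEs intersecting gene bodies ± 2 kb are removed
  before TE quantitation (half-open boundary: a TE starting exactly at
  `gene.end + 2000` survives). "Uniquely mapped" is operationalised as
  MAPQ ≥ 20.
- **TE expression.** Overlap counts (a read overlapping k features
  increments all k; sense = read strand equals feature strand) are summed
  per class after an instance-level outlier cutoff (kept if count > 3 in
  at least one sample), normalised as
  `log2(count / (library/10^6) / (class length/10^3) + 1)` and
  standardised per class across samples (population SD; constant rows are
  flagged and zeroed). Differential activation uses a Welch t-test on
  log2 RPM with Benjamini–Hochberg control at q < 0.05 — an unmoderated
  replacement for package-internal tests, which is why the generator
  defaults to 3 replicates per condition: with n = 2 an unmoderated
  per-gene t has at most one degree of freedom and cannot reach q < 0.05
  over hundreds of features regardless of effect size.
- **Antisense trap.** Per gene, sense/antisense counts pooled over KO
  replicates feed an exact one-sided upper-tail binomial test,
  `P(X ≥ antisense | n = total, p0)`, with p0 the global antisense
  proportion (total antisense / total reads over all genes). One-sided,
  because the hypothesis is antisense *excess*. Genes with zero total
  reads — and, in the replicate-aware Welch test, genes with zero
  antisense in every replicate — are excluded before BH correction:
  structurally untestable rows would only dilute FDR (their counts are
  logged). The pervasive-antisense gene set is the intersection of the
  binomial- and differential-significant sets; the summary reports the KO
  and WT antisense proportions and both their difference and ratio, since
  the headline "KO relative to WT" quantity is ambiguous between the two.
- **Methylome.** Genome-wide levels use consecutive, non-overlapping
  blocks of 50 CpGs with coverage ≥ 3, call-weighted within the block;
  feature-level methylation averages per-CpG levels (site-weighted) over
  features with ≥ 50 qualifying CpGs — two deliberately different
  weightings matching the two quantitation conventions being reproduced.
  TE-class methylation pools raw calls per class and reports a class only
  with ≥ 1000 observations in every sample. Distribution comparisons use
  the two-sided Wilcoxon rank-sum test (exact for small tie-free samples,
  normal approximation with tie correction otherwise) with Bonferroni
  correction scoped to the comparisons requested in one invocation.
- **Small RNA.** Reads are filtered to 20–24 nt (inclusive), then
  partitioned by first-match-wins hierarchy: rRNA → miRNA → non-repeat
  genome → repeat. The 5′-5′ overlap signature counts every intersecting
  opposite-strand pair with 5′-end distance 1–30 nt, with multiplicity;
  each length's z-score is taken against the mean/SD of the other
  lengths (the piRNA-pipeline convention). A clean signal over a
  zero-variance background reports ±inf rather than NaN. Class-level
  differential abundance uses reads-per-million of the filtered library
  and a two-tailed Student t (tiers: * p < 0.05, ** p < 0.005); RPM
  rather than raw counts, matching normalised per-class figures.
- **Chromatin.** Tile enrichment is `log2((obs + 1)/(exp + 1))` with the
  expectation from a uniform genome-wide distribution (partial tiles
  pro-rated). Class enrichment is the mean over tiles intersecting
  retained instances (tiles touching several classes count toward each);
  the KO-vs-WT rule flags classes with linear enrichment ≥ 2× WT,
  i.e. Δ mean log2 O/E ≥ 1. Note a structural property of depth-
  normalised enrichment: a multiplier m on a class inflates that
  library's size by its own enrichment, so the measured fold concentrates
  at m/(1 + p(m − 1)) (p = the enriched tiles' library share, ~5% at
  defaults) — a configured 2.0× is recovered at ≈ 1.9, inside a ±10%
  recovery band but at the flag boundary. The flag is therefore
  demonstrated on configured enrichment comfortably above 2× and on
  uniform data (no flags); the boundary behaviour is inherent to the
  estimator, not a calibration artefact.

## What the simulations do and do not show

The generator reproduces the *statistical shapes* the analyses consume:
orientation structure, count overdispersion, duplex geometry, composition
fractions, tile enrichment. It does not model sequence divergence or
mappability (no mismatches, no multi-mapping beyond a scalar MAPQ
fraction), PCR duplication, coverage biases, kinetic trajectories between
sampled days, or miRNA regulation at imprinted loci. Passing recovery
tests therefore demonstrates that the analysis code implements its
definitions correctly and has the power claimed under clean conditions —
not that those conditions hold in any particular sequencing experiment.

## Problem sizes and numerical choices

Default simulations use a 2 Mb genome, ~20,000 CpGs, 100,000 RNA reads and
350,000 small RNA reads per library — sizes chosen so a full pipeline run
takes seconds while every recovery lands well inside its tolerance
(window-mean methylation ± 1.5 points; composition fractions ± 2 points;
overlap and length modes exact). Overlap counting uses a sorted-array
identity (#starts < end − #ends ≤ start per chromosome/strand), which is
exact for interval intersection and O((n + m) log n). Pseudocounts of 1
appear inside both log2 RPM and log2 O/E to handle zeros; both are stated
in the corresponding docstrings. Ties in the Wilcoxon test switch the
implementation to the corrected normal approximation. BH q-values come
from the standard step-up procedure and are validated in the test suite
against an independent implementation of the definition.
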