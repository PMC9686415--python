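# Methods

This note describes the models and procedures crispmeth implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the analysis left
room for them.

## Site- and region-level methylation

The primitive observation is a reference cytosine covered by `total` reads
of which `meth` report methylation (an unconverted C).  The site level is
`meth / total`; every region-, window- or group-level statistic pools raw
read counts before dividing (`ΣNm / (ΣNm + ΣNnm)`), so deep sites carry
more weight than shallow ones.  Sites are only used where coverage meets a
floor (default `total ≥ 4`, configurable) — a common WGBS reporting floor;
the analysis upstream never defines one, so it is surfaced rather than
hidden.

A cytosine counts as *methylated* (for context-proportion tables) when
`meth ≥ 1`.  This headline rule is assumption-light but counts conversion
failures as methylation; a rigorous alternative — a one-sided binomial test
per site against the measured conversion-failure rate with
Benjamini–Hochberg control — is available via
`summarize_methylome(..., conversion_failure_rate=...)`.

Context (CG / CHG / CHH, H = A, C or T) is read from the two bases 3′ of
the cytosine on its own strand; minus-strand cytosines are classified on
the reverse complement.  Within 2 bp of a contig end, or next to an
ambiguous base, the context is `NA` and the site is ignored.

## DMR calling

Replicate call tables are pooled per group into one count table per site
(the "all replicates" reading of the pooled-level formula; a per-replicate
sign-consistency filter is deliberately *not* applied, matching the
procedure being reproduced).  For the CG context, the two cytosines of a
symmetric CpG are merged onto the forward-strand position — standard
because CpG methylation is symmetric — while CHG/CHH stay strand-specific.

Windows slide along each chromosome (default width 1,000 bp, step 500 bp;
the source procedure states only the ≥ 5-CpG rule, so the geometry is a
design choice matching common fixed-window WGBS practice and is fully
configurable).  A window is tested only if it contains at least `min_cpg`
(default 5) sites covered at the floor in *both* pooled groups.  The test
is a two-sided Fisher exact test on the pooled 2×2 table, computed by
enumerating the conditional hypergeometric distribution and summing the
probabilities of all tables no more likely than the observed one; a
relative tolerance of 1e-12 keeps exact ties (symmetric tables) inside the
sum.  Probabilities are computed with log-gamma arithmetic; against exact
rational enumeration the error is below 1e-14 for margins ≤ 30.

A window is significant when fold change ≥ 2 and p ≤ 0.05 (raw, matching
the reproduced procedure; Benjamini–Hochberg q values are reported
alongside for users who want FDR control).  Fold change is
`max(levelA, levelB) / max(min(levelA, levelB), 1e-6)` — the pseudocount
keeps 0-versus-x windows callable.  Overlapping or book-ended significant
windows with the same direction merge into a DMR whose statistics are
recomputed from the pooled site table over the merged span, so a DMR's
printed level, fold and p always describe its actual extent.

Known limitation: pooling replicates into one 2×2 table ignores
between-replicate variance, so with overdispersed replicates the Fisher
test is mildly anti-conservative (measured type-I rate ≈ 0.055–0.065 at
the generator's default dispersion instead of the nominal ≤ 0.05).  This
is inherent to the pooled-Fisher procedure itself, which this package
reproduces deliberately; beta-binomial regression callers address it but
are out of scope.

## Profiles

* **Level histograms** assign each methylated site to `floor(level × 10)`
  (level 1.0 to the top bin) and normalize by the context's mC count.
* **CpG-density × methylation matrices** use non-overlapping 200 bp tiles
  (tiling, not sliding, so no window is double-counted).  Density is the
  CpG-dinucleotide count from the sequence; the y value is the unweighted
  mean level of covered CG sites (each covered site counts once; a
  read-weighted mean is available by pooling first).  Tiles without a
  covered CpG are excluded; a per-density-column median accompanies the
  matrix, and an interval mask restricts the tiles to a genomic feature
  track (CGI, promoters, exons, ...).
* **Metagene profiles** split each of the seven gene features (upstream,
  first exon, first intron, internal exons, internal introns, last exon,
  downstream; upstream/downstream spans default to 2 kb) into equal bins —
  the integer remainder goes to the 5′-most bins — and average site levels
  within a bin across genes, per context.  Genes lacking a feature
  (single-exon genes) contribute only to the features they have, so the
  per-feature gene counts differ; they are reported with the profile.  A
  centered 5-bin moving average with a shrinking window at the edges is
  attached to each series.
* **CpG islands**, when no island track is supplied, are called with the
  classic sliding criteria (window 200 bp, GC ≥ 0.5, observed/expected
  CpG ≥ 0.6, merged runs ≥ 200 bp).

One representative transcript per gene is used throughout (longest exonic
span; ties broken by smallest transcript id) — isoform-aware profiling is
out of scope.  All coordinates are 0-based half-open internally; 1-based
dialects are converted only at I/O boundaries.

## Integration

DEGs: `|log2FC| > 1` (strict) and `FDR ≤ 0.001` (inclusive).  Promoter
DMGs and DEGs are intersected by gene id.  Concordance is *canonical* when
the promoter methylation change and the expression change have opposite
signs.  Enrichment is a one-sided hypergeometric upper tail per gene set
(sets intersected with the universe, which defaults to all annotated
genes) with Benjamini–Hochberg correction across sets (Bonferroni by
flag); the correction method is a design choice, since the reproduced
analysis names only "corrected p".  Candidate genes must be in the
DMG∩DEG overlap, in at least one supplied pathway set, and in a curated
literature list (a packaged 34-gene muscle structure/development list is
the default).  PPI edges on the STRING integer scale are rescaled by 1/1000
and kept at confidence ≥ 0.400; self-loops are dropped and counted.
The fiber-diameter helper inverts `s = πr²` to `d = 2√(s/π)`.

## The synthetic-data generator

The generator emulates the *structure* of a two-group (3 + 3 replicates)
fish-muscle WGBS + RNA-seq comparison at desk scale; defaults are the study
conditions of the test suite.

* **Genome**: 2 chromosomes × 1 Mb, 200 non-overlapping multi-exon genes
  placed on a slotted grid with room for 2 kb promoters and downstream
  regions.  CpG dinucleotides are stamped into an iid background at
  ~0.035/bp genome-wide and ~0.08/bp inside island patches (placed at ~30%
  of TSSs plus intergenic sites).  The toy genome is therefore *not*
  CpG-depleted: this keeps CG sites at ~30% of all cytosines so that, with
  the mean-level baselines below, >90% of methylated cytosines fall in the
  CG context — the regime reported for fish muscle methylomes.  A
  consequence is that background CpG density per 200 bp tile is higher
  than in a real vertebrate genome.
* **Methylomes**: per-site true levels are a two-component mixture — a
  site is methylated with probability `baseline / 0.95` and then draws its
  level from Beta(mean 0.95, concentration 30), otherwise its level is
  exactly 0 — so the mean level equals the configured baseline (CG 0.80,
  CHG 0.02, CHH 0.03; island CG boosted to mean 0.92) while the landscape
  stays bimodal.  Replicates add beta-binomial noise (dispersion 0.02, a
  standard WGBS overdispersion stand-in), coverage is Poisson(20) (desk
  scale for a ~30× experiment), and methylated reads are binomial.
  Contexts are classified from the actual simulated sequence, exercising
  the classifier end to end.
* **Planted DMRs**: 50 gene promoters get a dedicated intermediate base
  level (0.45) and the second group's mean shifts by ±0.5, clipped to
  [0, 1] with a warning.  The intermediate base is deliberate: from a 0.80
  baseline an upward shift clips and can never satisfy the two-fold rule,
  which would make half the planted truth undetectable by construction.
* **Lambda spike-in**: a 48.5 kb unmethylated control; apparent
  methylation is pure conversion failure (default rate 0.0095, i.e. a
  99.05% conversion rate).
* **Expression**: genes with a planted promoter DMR receive
  |log2FC| ~ U(1.5, 3) with sign opposite the methylation change with
  probability 0.8 (and tiny FDR); all other genes are null (log2FC ~
  N(0, 0.3), FDR ≥ 0.01).

All randomness flows through one `numpy.random.Generator` seeded from
`SimulationConfig.seed`; a fixed seed reproduces every output byte for
byte.

**What passing tests show — and do not.**  The generator has no sequencing
error, no SNPs, no M-bias, no copy-number structure, no read-level
artifacts, and its replicate noise is exactly the beta-binomial the
dispersion knob declares.  Recovery results (recall/precision ≥ 0.9 at
effect 0.5, coverage 20) therefore validate the *implementation* of the
windowed-Fisher procedure under its own assumptions, not its power or
error control on real libraries.

## Problem sizes and tolerances

The test and acceptance runs use the 2 Mb default genome (≈ 880k cytosine
sites per sample, ≈ 4,000 scanned windows), 200 genes, 3 + 3 replicates —
sizes chosen so a full run completes in seconds on one core while keeping
enough sites for law-of-large-numbers checks (baseline recovery to ±0.01,
conversion rate to ±0.05 percentage points over ≥ 10⁵ lambda cytosines).
Fisher parity is checked exhaustively for all 2×2 tables with margins
≤ 30 against exact rational enumeration at 1e-10.  Percentages are
reported at 2 decimals to match the tabular convention of the field.
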