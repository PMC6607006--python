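# Methods

This note records the models, parameter choices and numerical conventions
behind `tsrnakit`, and what the synthetic-data generator does and does not
emulate.

## tRNA reference and clustering

A mature-tRNA reference (GtRNAdb-style FASTA plus a TSV of isotype,
anticodon and anticodon position) is collapsed by **exact identity of the
first 50 nt**. "Similarity" of 5′ halves is implemented as identity
because it is the only parameter-free reading and it is exactly what
removes multi-mapping for 5′ fragments: two loci identical over the first
50 nt are indistinguishable to any read ending before the anticodon loop.
Genes shorter than 50 nt use their full sequence as key. The cluster
representative is the **longest member** (ties broken by smallest
gene_id) so that 3′-end classification remains possible; note the caveat
that 3′ labels are relative to that representative, since members may
differ beyond nt 50. Cluster ids are assigned in order of smallest member
gene_id, making clustering independent of record order.

The anticodon triplet, when not annotated, is located by searching for its
first occurrence starting within positions 30–40 (canonical cloverleaf
geometry), falling back to the first occurrence anywhere; an absent
triplet is an error.

## Read model and cleanup

Reads are cleaned in a fixed order: adapter trim → rRNA filter → length
selection; each stage is idempotent and never lengthens a read or edits
surviving bases.

- **Adapter trimming** uses the TruSeq small-RNA 3′ adapter
  `TGGAATTCTCGGGTGCCAAGG` with minimum overlap 5 and minimum retained
  length 6. The leftmost full-adapter occurrence is removed with
  everything 3′ of it; otherwise the longest adapter *prefix* (≥ 5 nt)
  that is a suffix of the read is removed. Trimming is exact-match: all
  libraries modelled here are 3′-ligated, and no adapter error rate is
  assumed. `N` counts as a mismatch everywhere.
- **rRNA filtering** drops a read iff it has an ungapped placement on
  either strand of any rRNA sequence with ≤ 2 mismatches. The 2-mismatch
  bound is the same constant used for all alignments; it is exposed as a
  parameter.
- **Length selection** keeps 18–35 nt inclusive, the window spanning
  miRNA-sized through tRNA-half-sized species.

## Alignment and tsRNA calling

Alignment is ungapped Hamming matching with at most 2 mismatches (the
bowtie `-v 2` contract: no indels, no quality use). For each read, *all*
placements at the minimal mismatch count over every target, strand and
offset (the best stratum) are reported, and the read's unit weight is
split equally among them; fractional assignment keeps totals conserved
under residual multi-mapping. tRNA clusters are searched forward-strand
only; genomic decoy contigs on both strands. The scan itself is exact and
vectorized (one-hot encoding, match counts by matrix product, grouped by
read length); no seeding heuristic is involved, so oracle equivalence
with a naive scan is structural, not approximate.

A read is called a **tsRNA** when it is 30–35 nt long and has a tRNA
alignment; 18–24-mers mapping to tRNA are deliberately not tsRNAs.
Species labels: `5prime` if the 1-based start ≤ 4, `3prime` if the end is
within the last 4 nt of the cluster representative, else `internal`.
Having a tRNA alignment is not forfeited by additional genomic
placements — tRNA loci are themselves genomic, and the clustering is the
multi-mapping remedy.

**Per-base coverage** of cluster c at base b is the weighted number of
tRNA-mapped reads spanning b divided by the total weighted tRNA-mapped
reads of the sample; the shared denominator makes profiles comparable
across clusters and gives the conservation identity
Σ_c Σ_b cov · denom = Σ weighted aligned bases.

**tRNA fraction by length** is, per read length s in 18–35, the number of
distinct reads with a tRNA alignment over the number with a genome
alignment; the genome set is taken to *include* the tRNA placements
(tRNA loci are part of the genome — a desk-scale decoy reference would
otherwise exclude tsRNA reads from their own denominator). Lengths with
zero denominator report NA.

**Counting** sums weights per cluster (or anticodon) over 5′ tsRNA calls
and rounds half-up to integers for count models, keeping the unrounded
values for reports.

## Normalization and the NB test

Size factors are median-of-ratios: s_j = median over features (positive
in all samples) of count/geometric-mean, rescaled to unit geometric mean.
Differential abundance uses a negative binomial with variance μ + αμ².
Per-feature α is estimated by the method of moments on normalized counts
(subtracting the Poisson part ξ·μ with ξ = mean(1/s_j)), then moderated
toward a fitted mean-dispersion trend α(μ) = a₀ + a₁/μ (gamma-family
identity-link regression, falling back to the median dispersion if the
regression is degenerate). Moderation is a weighted average with prior
weight 10 residual df — with 2–3 samples per group the per-feature
estimate carries 2–4 df, so the trend dominates, which is what makes the
2v2 null calibrated. Dispersions are floored at 1e-8.

For designs with ≤ 5 samples per group the two-group comparison is the
conditional exact NB test: group sums of iid NB(μ, α) are NB with size
n/α, and given the total the conditional split probability is free of μ,
so the two-sided p-value sums conditional probabilities ≤ the observed
one (1e-7 relative tie tolerance). Counts enter the test as normalized
counts rounded to integers — the unit-geomean size factors already put
them on the common (geometric-mean library) scale. Larger designs fall
back to a Wald test on the log scale. Features all-zero in one group get
a reporting-only 0.5 pseudo-count in the fold change; the test itself
sees the counts. BH and Bonferroni corrections are implemented in closed
form.

Declared limitations: no covariates/GLM designs, no outlier refitting, no
independent filtering; the exact-test p-values are invariant under group
relabelling but only approximately invariant under rescaling a single
sample (the common-scale rounding shifts by c^(1/m)).

## Pulldown enrichment

Four libraries (bait and scramble in LIF and RA states) are normalized
together; transcripts need a normalized count strictly > 200 in at least
one sample. Per condition the 2×2 Fisher table is **transcript vs
rest-of-library × bait vs scramble** on half-up-rounded normalized
counts — the standard construction for count enrichment against a control
pulldown; it is isolated behind `fisher_association` so alternatives are
pluggable. The two-sided Fisher p sums hypergeometric point probabilities
≤ the observed (1e-7 relative tie slack), computed in log space so
million-read margins are exact and fast. Bonferroni m = number of
transcripts surviving the expression filter, per condition. A transcript
is significant if fold change > 2 AND adjusted p < 0.05 in ≥ 1 condition;
significant transcripts are allocated by the bait-count RA/LIF ratio
(> 2 → RA-enriched, < 1/2 → LIF-enriched, in between with > 2-fold
enrichment in both conditions → ubiquitous). Target classes come from a
user-supplied reference fold-change table (RA-vs-stem): > 2 →
differentiation-responsive, < 0.5 → pluripotency-associated.

## Interactome

emPAI tables carry a −1 non-detect sentinel, replaced by the minimum
detected value of the table; bead-control values are subtracted from each
condition, and records whose bead value exceeds the condition value in
*all* conditions are discarded as bead-dominant (the conservative
reading; a per-condition mode would discard more). Enrichment requires a
> 2-fold ratio of bead-subtracted values, floored at 0.01 to keep ratios
finite. Gene-set over-representation uses the shared Fisher test on
(hits∩set, hits∖set, bg∩set∖hits, bg∖set∖hits) with BH-FDR across sets.

Binding series are fit by unweighted least squares to y = Bmax·C/(Kd+C)
on signal normalized to the highest-concentration point. Bmax is left
free because normalization to the top concentration does not imply
saturation there; no error model is assumed. Fits are multi-start (Kd₀ at
the min, median and max concentration) with tight tolerances (1e-14); a
fit driven to the Kd→0 boundary (flat signal) is flagged non-converged.
Kd scales with the concentration unit and is invariant to signal
rescaling.

## Synthetic data

The generator emulates the statistical structure of tsRNA-rich
differentiating-mESC libraries and the associated assays; it is
first-class, tested code, and every output carries a manifest of truth
labels.

- **Reference**: 72–90 nt genes, anticodon planted at position 34–36,
  genes grouped so that several share an identical first-50-nt prefix
  (the planted cluster count is recorded). Prefixes are rejected if the
  anticodon triplet occurs elsewhere in the 30–40 search window.
- **Libraries**: reads are drawn multinomially from four classes — 5′
  tsRNAs (start uniform on 1–4, end uniform on the 1–3 nt before the
  anticodon, length clipped to 30–35, impossible geometries redrawn),
  miRNA-like 21–23 nt decoy substrings, 28–35 nt rRNA substrings, and
  18–35 nt genomic background. Inserts get the 3′ adapter appended and
  are truncated to the 50 nt machine read length (so 30–35 nt inserts
  retain ≥ 15 adapter nt, comfortably above the trim overlap), then
  per-base substitutions at the configured error rate; qualities are a
  constant `I` because no stage uses them. Default composition 0.4/0.2/
  0.1/0.3 puts the expected tRNA share among 30–35-mers at 0.8. Not
  modelled: ligation bias, PCR duplicates, quality-dependent errors —
  so passing tests show correctness of the analysis logic, not
  robustness to those artefacts.
- **Count matrices**: NB with variance μ + αμ² (Poisson at α = 0),
  per-feature abundances lognormal around the baseline mean (σ = 0.5 on
  the log scale; a flat profile would make library-total tests trivial).
  Pulldown matrices default to dispersion 0.01: bait-vs-scramble
  pulldowns have no biological replicates, so count noise is at the
  technical level, which is also the regime in which a Fisher test on
  single libraries is the appropriate tool. Planted transcripts are
  split near-evenly into RA-only, LIF-only and both-condition effects.
- **emPAI tables** plant exactly fold-times bead-subtracted changes plus
  non-detect and bead-dominant records; at cv = 0 the downstream enriched
  set equals the planted set exactly.
- **Binding series**: y = Bmax·C/(Kd+C) times lognormal noise with median
  1 and coefficient of variation cv, at the assay concentrations
  20/40/80/200/400 nM.

All generators are byte-deterministic given their integer seed.

## Problem sizes and determinism

The bundled pipeline config simulates 60 genes / 12 anticodons, four
3,000-read libraries (two conditions × two replicates), a 2,000-transcript
pulldown and a 400-protein emPAI table — sizes chosen so a full run
completes in seconds while every statistic still has working replication;
all stage seeds derive from the single top-level seed, and rerunning a
config reproduces every table byte for byte (table headers carry the tool
version and a hash of the analysis-relevant config). The acceptance
script uses 20,000-read libraries and a 5,000-transcript pulldown, the
scale at which binomial standard errors on composition statistics are
small relative to the checked tolerances.
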