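# Methods

This note documents the models and procedures `apakit` implements, the
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical choices that affect results.

## Coordinate conventions

All coordinates are 0-based half-open internally.  BED and bedGraph are
native; GFF3 is converted at the I/O boundary.  A read record stores the
position of its 3'-most aligned base; for a plus-strand read ending at `p`
the internal-priming window is `genome[p+1 : p+11]`, for a minus-strand read
it is the reverse complement of `genome[p-10 : p]`.  "Upstream of the mapped
location" is therefore interpreted along the read strand, past the read's 3'
end — the position where the poly(A) tail (or a genomic A-stretch that
misleads the oligo-dT primer) sits.  The simulator and the filter share this
convention, which is the one that matters: an inconsistent pair would plant
artifacts the filter cannot see.

## Internal-priming filter

A read is removed when its 10-base window contains six consecutive adenines
or at least 7 adenines in total; genomic `N` counts as adenine so assembly
quality cannot mask an A-stretch.  The two printed variants of the rule
("≥70% adenine" and "7 of 10") coincide at window 10 and are implemented as
one rule.  Reads whose window would cross a contig end are discarded: they
cannot be certified artifact-free.  Classification is a pure function of the
10-mer, so filtering is idempotent.

## Peak calling and the cross-species catalog

Within one species (samples pooled), covered positions on a (contig, strand)
are clustered; neighboring covered bases at most `merge_distance` apart
(default 30 bp) stay in one cluster, and clusters with summed support below
`min_reads` (default 5) are dropped.  The apex is the most 3' covered base of
the cluster, strand-aware.  These two defaults are exposed in the API because
the reference peak caller's parameters are not published with the analysis
this mirrors; 30 bp/5 reads suit the narrow peaks 3' Seq produces.

Apexes are extended to `[apex−100, apex+101)` clipped to the contig.  A
region projects through the block map when ≥90% of its bases fall in blocks
pointing to a single (contig, orientation); it is *reciprocal* when the
projected span projects back onto ≥90% of the original.  The 0.9 threshold is
a design choice (no threshold is published); strict reciprocity is preferred
because downstream statistics assume the two species' regions describe the
same locus.  Reciprocal regions of the two species merge into one catalog
entry when their projected spans overlap by ≥1 bp — regions are already
±100 bp, so looser matching would fuse distinct sites.  When a projection
overlaps several peaks, the nearest apex wins; exact ties go to the more 3'
apex.  Unmatched reciprocal regions stay in the catalog as single-origin
entries quantifiable in both species through the projection.

## Annotation and quantification

Catalog entries are assigned to genes by apex position in the annotation
species against feature classes in priority order **3' UTR > 5 kb downstream
("end") > CDS > 5' UTR > intron**, strand-matched, first hit winning.
Overlapping genes at the same priority resolve to the nearer transcript end,
then lexicographic gene id.  Apexes matching no feature are excluded.

Reads are counted into ±100 bp regions strand-specifically.  Regions of the
same gene are trimmed at the apex midpoint where they would overlap, so a
read counts to at most one PAS per gene; regions of different genes may
overlap and a read then counts once per gene.  Usage is the count fraction
within (gene, sample); a gene with zero reads in a sample has *missing*
usage, not zero — a ratio is undefined without reads, and means per species
skip missing samples.

Filters run in the stated order: (1) drop PAS whose mean usage is below 5% in
both species; (2) drop genes failing log2 CPM > 2 in at least 8 samples
(capped at the sample count for small designs), with CPM computed from the
gene's summed PAS counts against the sample's total PAS-assigned reads and a
0.5 pseudo-count before scaling (avoids −∞; configurable); (3) recompute
usage over the survivors.  A PAS is species-specific when its mean usage
reaches 5% in one species and is exactly 0 in the other; a species with no
defined sample cannot certify a zero.

## Differential usage

Per gene with ≥2 PAS and ≥2 nonzero-total samples per species, per-sample PAS
counts are modeled Dirichlet-multinomial.  The null fits one usage vector and
one concentration for all samples; the alternative fits species-specific
usage vectors with the concentration still shared between species.  Both fits
maximize the exact DM likelihood (softmax-parameterized usage, log
concentration; analytic gradients; L-BFGS-B from three deterministic starts
at concentration 10, 1, 100 — a gene whose fits all fail is reported with
missing p).  Twice the log-likelihood gap is referred to chi-square with
(#PAS − 1) df.  A plain multinomial variant (`method="multinomial"`, closed
form) is available for overdispersion-free data; the DM statistic converges
to it as the concentration grows.

ΔPAU is the empirical per-species mean of per-sample usage fractions,
species A minus species B (negative = higher usage in B); in the saturated
two-group design this coincides with the fitted difference.  Gene-level
p-values get Benjamini–Hochberg FDR (implemented directly as the step-up with
monotone enforcement; missing p propagate).  A PAS is divergent when its gene
passes the FDR cutoff (default 5%) and |ΔPAU| strictly exceeds 0.2; a gene is
divergent when it has ≥1 divergent PAS.  "Top PAS per gene" per location
class ranks by |ΔPAU| (the gene p is shared by its sites) with ties broken by
grand-mean usage.

**Known limitation — small-sample calibration.**  With 11 samples the
chi-square reference is anticonservative: in a null DM simulation
(concentration 50, 200 reads/gene/sample, 5 vs 6 samples) the LRT rejects at
nominal p < 0.05 about 8–10% of the time.  The likelihood, gradients and
optimizer have been verified against independent oracles, so this is a
property of the asymptotic reference, not of the code: the test's information
grows with the number of samples, not reads.  No empirical correction is
applied.  The downstream divergence call is far more conservative than the
raw p-values because of the |ΔPAU| > 0.2 gate: in the same simulation zero of
2,000 null genes were classified divergent, while power for planted
|ΔPAU| = 0.3 shifts exceeded 0.99 and the effect-size recovery slope was
within 1% of unity.

## Diversity and dominance

Simpson's D = 1 − Σp² and Shannon H = −Σp log2 p (bits; zero-usage terms
contribute 0) summarize a gene's usage vector.  Species differences in
diversity are tested per gene on per-individual D values with an exact
two-sided Wilcoxon rank-sum: mid-ranks for ties, the null enumerated over all
C(n, n_A) rank assignments (doubled smaller tail, capped at 1 — complete
separation at 5 vs 6 gives 2·5!·6!/11! = 0.004329), BH FDR across genes.
Enumeration is exact up to 200,000 arrangements, far beyond the 5-vs-6
design; larger groups fall back to the tie-corrected normal approximation.
Genes with one PAS are not tested.

Dominance within a species is u(1) − u(2) over descending mean usage (top-tie
broken toward the more 3' apex).  Across the 0.1–0.9 cutoff grid, a gene
enters the sharing classification when either species' dominance exceeds the
cutoff; it is `same_dominant` when the two species' top sites are the same
catalog entry.  The entered set shrinks weakly as the cutoff grows.

## Sequence features

Signal-site scanning searches the full strand-oriented PAS region for the 12
hexamers in the fixed priority order AATAAA, ATTAAA, AAAAAG, AAAAAA, TATAAA,
AATATA, AGTAAA, AATACA, GATAAA, AATAGA, CATAAA, ACTAAA; the call is the first
motif present, regardless of position or multiplicity.  The printed order is
adopted as fixed rather than recomputed from data.  Species-specific signal
calls count only the two usage-promoting motifs (AATAAA, ATTAAA).  U content
is the T fraction of the transcribed strand with Ns excluded from numerator
and denominator.  The AU-rich-element fraction of a 3' UTR is the fraction of
positions covered by maximal A/T-only runs of length ≥5.  Conservation
profiles tile `[apex−700, apex+700)` into seven 200 bp windows (labels follow
transcription direction); a window containing any unscored base is missing,
and profile rows are flagged complete only when all seven windows are scored.

## The synthetic world

The generator states one world and the tests measure it; none of its defaults
were chosen to satisfy a test after the fact.

* **Genomes** — uniform-random contigs; genome B applies per-base
  substitutions at the configured divergence (default 1%, about the
  human/chimp neutral scale) and a block-order shuffle recorded in the map.
* **Genes** — fixed-layout models (300 bp 5' UTR, split CDS, 1.5 kb intron,
  1.8 kb 3' UTR, 5 kb free downstream) placed inside single blocks so every
  gene maps contiguously.
* **PAS** — 1–8 per gene (mean ≈3.3, near the reported ≈3.9/3.5 per-species
  means); genic placement 0.40 3' UTR / 0.32 intron / 0.10 CDS / 0.05 5' UTR
  / 0.13 downstream, mirroring the observed distribution; ≥250 bp apart so
  ±100 bp regions are disjoint within a gene.
* **Usage** — Dirichlet(0.9) per gene, shared between species; a configured
  fraction of multi-PAS genes transfers 0.2–0.4 usage mass between two sites
  in one species (the planted divergence); species-specific sites get usage
  exactly 0 in the other species.
* **Signal sites** — 0.70 AATAAA / 0.15 ATTAAA / 0.15 none written 10–30 bp
  upstream of each apex in both genomes at mapped positions, with 3%
  cross-species discordance (higher motif-loss probability at
  species-specific sites).
* **Reads** — genes drawn proportional to log-normal(log 200, 1) expression,
  sites by the species usage vector, positions jittered by a symmetric
  geometric(0.5) offset truncated at ±5 bp (the distance between read ends
  and cleavage sites is not published; this keeps peaks narrow but nonzero
  width).  Artifact reads (default 2%) are sampled uniformly from a
  precomputed index of genomic placements whose upstream window genuinely
  fires the filter rule, so the filter can in principle recover all of them.

What the generator does **not** emulate: read sequences and qualities,
alignment error, PCR duplicates, annotation disagreement between species,
overlapping genes on one strand, and expression differences between species.
A green end-to-end test therefore establishes that the pipeline recovers the
planted structure under clean mapping — not that it is robust to alignment
artifacts or annotation error.

External effect tables (expression / translation / protein / ubiquitination)
are consumed as TSVs with a declared column contract (`gene_id, effect, sig,
source`); the synthetic module emits coupled stand-ins (configurable
significance-rate multiplier for APA-divergent genes and location-signed
ΔPAU coupling) for testing the integration statistics.

## Numerical choices

* Concentration bounded in [1e−3, 1e7]; usage logits in ±30 — wide enough to
  reach the multinomial limit without overflowing `gammaln`.
* BH q-values use a stable mergesort and reverse cumulative minimum.
* Hypergeometric upper tails include the observed count, P(X ≥ k).
* Usage-sum invariants are enforced to 1e−9; Wilcoxon tie comparisons use a
  1e−9 tolerance on rank sums.
* The pipeline defaults `cpm_min_samples = min(8, n_samples)` so the 8-of-12
  rule degrades sensibly for small designs.
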