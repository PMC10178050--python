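# Methods

## Scope and data model

`edikit` begins where read alignment and site calling end: its inputs are
per-sample, per-position base-count tables (REDItools v2 column layout)
for RNA and for the matched genomic DNA of each individual, an Ensembl
GTF, a genome FASTA, known-variant and per-individual VCFs, read-count
matrices, and a sample sheet (individual, tissue, diet arm). All
coordinates are 1-based inclusive throughout, matching GTF and the call
tables; strands are normalized at parse time (0→`-`, 1→`+`, 2→unknown)
and chromosome names are compared by exact string equality. Base counts
and reference bases in call tables are expressed on the annotated strand,
so an A-to-I site always reads as reference A with edited reads under G,
regardless of strand.

## Candidate selection and filtration

A site enters the per-sample candidate set iff RNA coverage ≥ 5, a DNA
record exists with coverage ≥ 5, ≥ 5 reads support the RNA substitution,
the substitution is single, and the DNA non-variation frequency
(reference reads / coverage) is ≥ 0.95. The editing level is edited
reads over RNA coverage.

The pooled candidates then pass a fixed-order cascade: non-autosomal and
unknown-strand sites are dropped first (counts logged), then (1) known
variant positions, (2) positions where any study individual carries a SNP
or INDEL, (3) sites not detected in ≥ 3 samples within at least one
tissue, (4) sites 100 % edited in every detected sample. Step 2 removes
the site globally by default — the conservative reading, mirroring step
1 — with a `per_individual` switch that instead masks only the carrier's
samples. Step 1 uses every record in the known-variant file regardless of
type, matching positional-intersection semantics. Step 3 counts samples
per tissue pooled across diet arms; the per-arm ≥ 3 rule belongs to the
differential stage. Non-redundant site identity is (chromosome,
position, strand): the same position on opposite strands is two sites.

## Annotation and enrichment

Sites are intersected with per-transcript features (exon, intron,
5′-UTR, CDS, 3′-UTR, start/stop codon) under the **union rule**: a site
receives every class it overlaps in any transcript, with no precedence
hierarchy, so per-class counts are non-exclusive. Matching is
strand-aware by default because the assumed library is strand-specific; a
switch disables it. A site overlapping no gene body is intergenic.
Introns are derived as inter-exon gaps; feature lengths are merged
genomic footprints (strand-collapsed), and intergenic length is the
complement of the gene-body union. Splice proximity is |site −
nearest exon boundary| ≤ 10 bp, inclusive, with the signed distance
(negative = left of the boundary) reported for both exon-interior and
intron-side positions.

Two enrichment designs are exposed. Length backgrounds build
`[[sites_in, sites_out], [bp_in, bp_out]]`; base pairs as pseudo-counts
make the Fisher model too literal, so Chi-squared (with Yates correction)
is the default there, Fisher optional. Set backgrounds (focal site set vs
all A-to-I sites) use Fisher exact on a **nested** background — the
background includes the foreground — so the reported fold is a plain
ratio of proportions. Zero cells get the Haldane–Anscombe +0.5 for the
odds ratio and are flagged. P-values are two-sided; families are BH-FDR
adjusted at 0.05.

## Differential analysis

"Wilcoxon" is always the two-sample rank-sum (Mann–Whitney) test: the
groups are different animals and group sizes diverge after detection
filtering, so a paired design is not available. Tie-free groups of size
≤ 10 use the exact null distribution; otherwise the normal approximation
with mid-ranks, tie correction and continuity correction is used. One
consequence worth knowing: with exactly 3 vs 3 detected samples the
smallest attainable exact two-sided p is 2/20 = 0.1, so no 3v3 site can
pass α = 0.05 on the exact path; both paths are exposed and the default
(`auto`) follows the exact route. Per-site tests use raw p < 0.05 by
default (a `fdr` switch adds BH), with direction from group means.
Treatment-specific classification (≥ 3 samples in one arm, zero in the
other, per tissue) and per-site testing are mutually exclusive by
construction. The pooled "functional" set is the non-redundant union of
differential and specific sites over tissues.

Tissue-level comparisons pool all detected per-site levels of each arm by
default (a per-sample-mean mode exists). PCA centers but does not scale
the missing-filled (default 0) site × sample matrix and reports explained
fractions as sd(PCk)/Σsd — the SD-ratio convention, not variance ratios.

## Recoding

For a CDS site, the spliced offset from the start codon is accumulated
over CDS intervals (introns removed); minus-strand transcripts count from
the rightmost CDS base leftward on the complemented sequence. Offsets and
codon indices are 0-based internally (codon = offset div 3, position
within codon = offset mod 3). The codon is read from the
strand-corrected genome sequence, must carry A at the edited position,
and A→G is applied. Consequences follow the standard genetic code; A→G
editing can never create a stop codon (reverting the G in TAG or TGA
yields TAA, itself a stop), which the code asserts. Every (site,
transcript) pair is evaluated separately; a transcript is
isoform-divergent when the same site is synonymous in one of its gene's
transcripts and nonsynonymous in another. Transcripts whose CDS length
is not a multiple of 3 are skipped and counted.

## Correlation

Expression is RPKM (count / kb of feature / million library reads; total
exon length for transcripts). Each site is paired with every gene whose
body contains it; Pearson r is computed over samples where the site is
detected, excluding missing values pairwise, never imputing. Pairs with
fewer than `min_pairs = 5` complete observations are skipped — the
study design nominally offers all samples, but detection missingness
makes 3-point correlations meaningless; the knob goes down to 3.
|r| ≥ 0.5 inclusive is "strong". ADAR-family genes (ADAR, ADARB1,
ADARB2) can be paired against every site regardless of location.
Enrichment of correlated sites over all A-to-I sites delegates to the
nested-background Fisher design above.

## The synthetic study

The generator emulates the target design: 8 individuals × 9 tissues
(duodenum, jejunum, ileum, cecum, colon, rectum, abdominal aorta, liver,
testis), 4 individuals per diet arm chosen at random, one RNA call table
per sample and one DNA table per individual (one genome per animal), a
two-autosome genome (150 kb each) plus a sex chromosome and an unplaced
scaffold, ~30 two-exon protein-coding genes with UTRs and clean open
reading frames (plus ADAR/ADARB1/ADARB2 and a minority of single-exon
non-coding genes), and ~500 planted sites: stable, differential
(Δ = 0.3), HED- and ND-specific, CDS recoding sites on both strands,
3′-UTR sites correlated with host-gene expression (ρ = 0.9), and decoy
classes exercising every filtration step plus C→T sites for the A-to-I
subset. Half the stable sites are placed within 20 bp of another site to
reproduce the observed clustering tendency.

Key modelling choices, all single-seed deterministic:

* **Levels.** True per-site levels are Beta(3, 7) (mean 0.3), clipped to
  [0.18, 0.95], with per-sample Gaussian jitter (sd 0.02). The floor is a
  deliberate generator condition: the ≥ 5-edited-reads threshold censors
  low-level sites sample-by-sample, and without the floor that dropout
  manufactures spurious "treatment-specific" calls that are detection
  artifacts rather than planted biology. The clipped mean (~0.32) sits
  at the editing level bulk RNA-seq studies typically report (~0.33).
* **Counts.** Observed edited reads are Binomial(coverage, level); RNA
  coverage is 50 + NB(mean 20, size 8) (mean ≈ 70, floor 50 — deep,
  rRNA-free libraries), DNA coverage 10 + NB(mean 30, size 8). DNA
  tables are homozygous reference at every site.
* **Correlated sites.** The planted ρ targets the *observed*
  level–expression correlation: levels are generated from the
  standardized realized counts of the host gene, with the latent mixing
  coefficient inflated by √(1 + σ²_binom/σ²_slope) to compensate for the
  known binomial read-sampling noise. Expression for these genes varies
  log-normally (σ = 0.8) across samples.
* **Specific sites** are emitted for every sample of one arm and no
  sample of the other; differential sites shift one arm by Δ in a random
  direction; full-edit decoys are exactly 1.0 everywhere; low-sample
  decoys appear in 2 samples of one tissue.

What the generator does **not** emulate: read-level artifacts (mapping
error, strand bleed-through, quality-score effects), hyper-editing
clusters as a biological process, linkage between neighbouring sites,
per-tissue mean-level differences, batch effects, and realistic
transcript-isoform diversity (most genes have one transcript, so
isoform-divergent recoding counts are near zero by construction).
Passing recovery tests therefore demonstrates the correctness of the
downstream statistics under the stated noise model, not robustness to
upstream calling errors in real data.

## Problem sizes and verification

The test suite verifies each statistic against an independent oracle:
exact rank-sum p-values against full enumeration of rank assignments for
all group sizes ≤ 6; Fisher p-values against an explicit hypergeometric
tail sum (exhaustive for small tables plus randomized coverage to margins
of 200); recoding against a hand-written genetic-code table, exhaustively
over every A-containing codon; the filtration cascade against a
nested-loop brute force on 50-site toys; PCA SD-ratios against a direct
eigendecomposition. Recovery checks pool 20 seeded default studies
(~500 sites, 72 samples each) and require treatment-specific precision
≥ 0.9, differential sensitivity ≥ 0.6 (4v4, Δ = 0.3), planted correlated
sites significant in ≥ 80 % of cases with single-tissue (n = 8) r > 0.5
in ≥ 90 % of pairs, and 3′-UTR set enrichment at Fisher p < 0.05 in
≥ 90 % of seeds. `scripts/acceptance.py` re-runs the same measurements
on five seeded replicates, a size chosen so a complete from-scratch
reproduction stays in the tens of seconds on a laptop.

## Numerical conventions and degenerate inputs

Percentages and one-decimal averages round half-up (decimal arithmetic,
not binary). Frequencies in call tables are written with full float
precision so round-trips are exact. Zero-variance vectors and
under-sampled pairs are skipped with counters, not errors; empty
foregrounds return empty results with a warning; a 2×2 with an empty
margin gets p = 1 under Chi-squared. UpSet-style intersections are
guarded at ≤ 10 groups (2^k cells). Matrix values are validated to
[0, 1]; detection is exactly "value present".

## Known limitations

Raw p < 0.05 per-site testing at 4v4 admits a ~2.9 % false-positive rate
per tissue by construction (the exact test's attainable p floor), so the
"functional" set is a screening set, not an FDR-controlled discovery set
— matching the upstream convention the pipeline reproduces, with the
`fdr` switch available when control is wanted. Length-background Fisher
tests treat base pairs as counts and overstate certainty; Chi-squared is
the default for that reason. GO/pathway enrichment, differential
expression itself, and read-level processing are out of scope.
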