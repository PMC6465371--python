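# Methods

## Background and scope

Inhibition of the transcription-elongation kinases CDK12/13 shifts RNA
polymerase II toward premature cleavage and polyadenylation (PCPA):
transcription terminates at cryptic intronic poly(A) sites, yielding
truncated transcripts, a 5′-proximal accumulation of nascent signal and a
loss of 3′ reads that grows with gene length. `pcpakit` implements the
computational side of that analysis — from spike-in-normalised nascent-RNA
(TT-seq) coverage and poly(A) 3′-end peak tables to per-gene PCPA calls and
the gene-architecture features that predispose to them — together with a
synthetic-data generator that plants every effect with known ground truth.

Read alignment, peak calling and transcript quantification are upstream of
this package: coverage arrives as bedGraph, peak candidates as a BED-like
table with a −log10 q column, abundances as a TPM table.

## Annotation model

Transcripts are filtered by abundance (gene TPM ≥ 2; isoform fraction ≥ 0.2
unless the isoform's own TPM exceeds 5) and each gene is reduced to the
union of its retained isoforms' exons; introns are the complement within the
gene span, so exons and introns partition the span exactly. Coordinates are
0-based half-open internally; GTF input is converted on read.

Genes are grouped into protein-coding, long non-coding and short non-coding.
Raw biotypes with fewer than 20 members are left unclassified; the remaining
non-coding genes are split by k-means (k = 2, 10 restarts, fixed seed 1729)
on log10 length, the larger-centroid cluster being long non-coding. The fit
is performed on sorted inputs and genes are labelled by nearest centroid, so
the assignment is independent of input order.

Protein-coding genes receive six length classes from the quartiles of the
observed length distribution (type-7 quantiles; values exactly on a boundary
fall to the shorter class), with the shortest quartile subdivided at its own
0.33/0.66 quantiles into short / very-short / ultra-short. Boundaries are
always recomputed from the data at hand and reported alongside the labels —
printed boundaries from any particular dataset are not hard-coded.

The representative isoform per gene is the one with the highest 3′UTR-
assigned poly(A) read sum, ties broken by longer transcript, then
lexicographic id.

## Coverage and normalisation

Spike-in size factors use the median-of-ratios estimator: the reference is
the per-spike-in geometric mean across samples (spike-ins with any zero are
excluded from the reference); a sample's factor is the median ratio of its
counts to the reference. Factors are defined up to a common scale; only
ratios between samples matter downstream.

bedGraph tracks are binned strand-specifically (100 bp for TT-seq analysis,
50 bp for TSS dynamics); a bin's value is the interval-length-weighted
signal sum divided by bin width and size factor. Binning conserves signal
mass exactly. Region read counts used by the score formulas are sums of
per-bp values over the region, rounded to integers (Fisher's test needs
counts).

Metagene profiles resample each gene body (TSS→TES) into 50 equal bins by
area-weighted aggregation — robust for lengths not divisible by 50 — with
2 kb flanks in 100 bp bins; bin 1 sits at the TSS on either strand. Genes
are weighted equally (an expression-weighting flag exists); genes shorter
than 50 bp are excluded and counted. The antisense profile reads the
opposite-strand track over the same coordinates. Rescaling to [1, 100] is
available for cross-assay display.

TSS-proximal dynamics: the per-bin mean treated-minus-control change over
−500..+10 000 bp of the TSS (50 bp bins), its first difference (the rate of
accumulation change) linearly rescaled to the range of the change curve,
and loess smooths (span 0.2) of both. The smooths are presentational; all
quantitative statements use the raw curves.

## Poly(A) peak filtering and annotation

A peak is an internal-priming artifact when its 100 bp transcript-sense
upstream window contains none of the twelve PAS hexamers (AATAAA, ATTAAA,
AGTAAA, TATAAA, AATATA, AATACA, CATAAA, GATAAA, AATGAA, ACTAAA, AAGAAA,
AATAGA) *and* its 50 bp downstream window contains a 25-mer with ≥ 22
adenosines on the peak's strand (a 25-A stretch with at most 3 mismatches).
Both windows are clipped at sequence ends; the recorded motif is the first
match in the order above. Peak position is the summit column when present,
else the interval midpoint.

Retained peaks are annotated hierarchically: TES window (−200/+600 bp along
transcription) → 3′UTR; then exon/intron by the reduced model; else
intergenic. Overlap conflicts resolve protein-coding first, then longer
gene. Condition-specific peaks require −log10 q ≥ 5, a combined read
minimum of 64 (a per-condition flag exists) and |log2((a+1)/(b+1))| > 1.

## Per-gene statistics

* **IR index** = log2[(intron_T+1)/(intron_C+1)] − log2[(exon_T+1)/(exon_C+1)]
  over the reduced intronic/exonic territory; genes need ≥ 10 exonic and ≥ 5
  intronic reads in at least one condition. Significance by Fisher's exact
  test on the 2×2 count table, Benjamini–Hochberg adjusted; retention means
  adj p < 0.05 and IR > 1, loss adj p < 0.05 and IR < −1.
* **PCPA**: exon-score = last-exon log2(T/C) − first-exon log2(T/C);
  iQ-score = log2(iQ1/iQ4) of treated reads in the first vs last quarter of
  the internal region between the first 5′ splice site and the last 3′
  splice site (genomic span, introns included, strand-aware). Both use a +1
  pseudocount (the IR formulas print it; adopted in the PCPA formulas for
  zero-safety, with a flag to disable). A gene is called PCPA when
  exon-score < −1 and iQ-score > 1; single-exon genes are not assessable.
* **Usage odds ratio** per gene:
  [(intronic+0.5)/(UTR+0.5)]_treated / [(intronic+0.5)/(UTR+0.5)]_control
  (Haldane–Anscombe correction), genes with TPM > 1, excluding genes with no
  intronic poly(A) reads in either condition; OR distributions are compared
  with a two-sample Kolmogorov–Smirnov test.
* **Differential expression** is a deliberately simple negative-binomial
  Wald test on size-factor-normalised exonic counts: per-gene
  method-of-moments dispersion stabilised with the cohort median, delta-
  method standard error on the log2 fold change, BH adjustment; significant
  means |log2FC| > 1 and adj p < 0.1, and genes below a total-count floor
  are never significant. Its acceptance surface is recovery of planted
  effects on synthetic truth, not equality with any external fitter.
* **Flanking windows** for expression counting: −50..−2050 of the TSS and
  +50..+2050 of the TES along transcription, same-strand gene overlaps
  subtracted, fragments < 200 bp dropped.
* **Gene-set shift**: z-score of the set's mean log2FC against 1000 random
  equal-sized sets drawn without replacement (seeded).
* **Length relation**: Spearman correlation of log2 length vs log2FC with a
  loess smooth for reporting.

## Genetic determinants

Per gene, on the sense strand TSS→TES: overlapping occurrences of the U1
motifs (GGTGAG, GGTAAG, GTGAGT) and the canonical PAS (AATAAA); GC fraction;
length; first-intron length (transcription order); intron count; expression
(control-condition TPM); annotated intronic poly(A) peak count; and the
pseudocounted U1/PAS ratio (u1+1)/(pas+1). Group comparisons (all genes vs
PCPA genes) use the two-sided Wilcoxon rank-sum test and Cohen's d with
pooled Bessel-corrected SD (d > 0 = larger in PCPA genes). The relation
between length and intronic poly(A) site count is a least-squares quadratic
fitted to all genes and to DDR genes separately; the per-DDR-gene prediction
difference is tested with the Wilcoxon signed-rank test. Note the all-genes
fit includes the DDR genes, so a planted DDR excess of +k reappears as a
median difference slightly below k.

Splice-site position weight matrices are built from all GT..AG introns:
donors contribute a 9-mer (last 3 exonic + first 6 intronic bases, GT fixed
at +1/+2), acceptors the 15-mer ending at the intron's final base (..AG).
Column frequencies use a 0.5 pseudocount; scores are log2 odds against a
uniform 0.25 background, and an intron's combined score is donor + acceptor.
Introns shorter than 24 bp are excluded (windows would overlap).

## Synthetic-data generator

The generator is first-class, tested code. It writes a single ~2.5 Mb
chromosome ("chrS") carrying (by default) 200 protein-coding genes of 2–12
exons with canonical splice sites sampled from consensus profiles, separated
by ≥ 2.2 kb spacers. Lengths are log-normal (median 8 kb, σ = 0.55); genes
destined for PCPA are drawn 2.5× longer, matching the long-gene bias of the
phenotype. Each gene gets a 3′UTR cleavage site with AATAAA 30 bp upstream;
PCPA genes additionally get 1 + Poisson(1.5) intronic cleavage sites in
introns 1–4 and non-PCPA genes one site with probability 0.5. The premature
termination site itself is placed in the 28–55 % band of the internal
region: a truncation upstream of the first internal quarter removes iQ1
together with iQ4 and is undetectable by the iQ statistic by construction,
whereas proximal-but-not-immediate truncation is the phenotype the statistic
describes. U1 motifs are planted at 1.5/kb (×0.25 in PCPA genes) and extra
body AATAAA at 0.1/kb (×6 in PCPA genes), so PCPA genes carry the low
U1/PAS ratio the determinant analysis should find. Internal-priming decoys
(25-A runs, default 50) are placed in intergenic spacers with their 100 bp
upstream windows scrubbed of all twelve PAS motifs.

Coverage: control expectation is uniform over exons (introns at 0.4×,
nascent RNA retaining intron signal) at ~0.5 reads/bp per gene (log-normal
gene-to-gene variation); the treated expectation adds a Gaussian 5′ gain
(amplitude 3× the gene rate, centre +1000 bp, σ 300 bp), multiplies
coverage downstream of the PCPA site by the truncation survival (default
0.1), scales introns by ±4× for planted retention/loss genes and by 2^lfc
for differential-expression genes (|lfc| = 2). Counts are Poisson per 50 bp
bin, two replicates per condition, with per-sample library scaling shared
with the spike-ins (30 spike-ins, ~5000 counts each). Poly(A) reads per gene
are Poisson-multinomial across the gene's sites; treated PCPA genes move
80 % of reads to intronic sites (control baseline 10 %). True peaks carry
−log10 q ≥ 5; a configurable fraction of artifact peaks does too, so q-score
filtering alone cannot remove them.

What the generator does **not** emulate: mappability and GC bias, read-level
errors, overlapping or nested genes, antisense transcription, alternative
isoforms (one isoform per gene), 3′UTR length heterogeneity, and biological
replicate variability beyond Poisson noise. Passing recovery tests therefore
demonstrates correctness of the statistics under their own generative
assumptions, not performance on real libraries.

## Calibration and confounding

Each recovery experiment isolates its planted effect (e.g. the truncation
experiment switches the 5′ gain off), because the statistics interact: the
treated 5′ accumulation raises iQ1 in *every* gene and inflates the PCPA
false-call rate under composite conditions — an informative reproduction of
why the exon-score and iQ-score are applied jointly, visible in the master
table of the default run. Null calibration (false-call rates, gene-set
z-score coverage) is defined on runs with all effect sizes zero. The "noise
floor" for the null dynamics check is the maximum per-bin Poisson standard
deviation of the gene-averaged change curve, computed analytically from the
generative expectations.

## Numerical and degenerate-input choices

Type-7 quantiles with ties-to-lower classes; k-means restarts 10, seed 1729;
equal gene lengths collapse all length boundaries without error; constant
tracks yield missing correlations; constant fold changes yield a missing
length correlation; a determinant constant in both groups yields missing d;
fewer than 2 non-coding genes are all assigned long non-coding with a
warning; fewer than 3 DDR genes skip the regression deviation test; fewer
than 20 canonical introns abort PWM construction. All randomness flows from
explicit seeds; reruns of the orchestrated pipeline are byte-identical.

## Problem sizes

Defaults were chosen so a full simulate-and-analyse run takes a few seconds
on one CPU: 200 genes, ~2.5 Mb genome, 2 replicates × 2 conditions, ~400
poly(A) peaks. The test suite and the acceptance script each complete in
well under a minute at these sizes.
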