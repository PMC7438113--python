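# Methods

`germchrom` quantifies how trimethylation of histone H3 lysine 27
(H3K27me3), the Polycomb repressive mark, is distributed over a genome
partitioned into four chromatin classes — active, inactive, PcG (Polycomb
domains), and Hp1 heterochromatin — and how that distribution changes
between cell states (e.g. undifferentiated germline stem cells vs
differentiated nurse cells) and genotypes (control vs germline RNAi
knockdowns).  This note records the models, estimators, numerical choices,
and known limitations.

## Genome model and binning

Coordinates are 0-based half-open throughout (BED convention).  A
nine-state chromatin segmentation collapses onto the four classes (states
1–5 → active, 6 → PcG, 7–8 → Hp1, 9 → inactive), merging touching
same-class segments.  For ChIP quantification the genome is tiled with
5 kb windows starting every 500 b, so each position is covered by up to ten
overlapping windows; windows are dropped if they run past a chromosome end
or touch a configurable exclusion mask (blacklisted chromosomes,
pericentric heterochromatin, hyper-amplified loci).  Masks are inputs
because their coordinates are assembly-specific; a window partially
overlapping a mask is dropped entirely (the conservative reading when
"residing in" an excluded region is not otherwise defined).

Each window is assigned the single class that covers it completely;
windows overlapping two classes or uncovered sequence are `mixed` and are
excluded from every class-stratified statistic, which slightly
under-represents domain edges.  Full single-class coverage (not merely
absence of a second class) is required, so assembly gaps yield `mixed`.
PcG windows containing at least one PRE-protein peak-summit position
(half-open containment) carry a `pre_flag`; the composite summit list is a
concatenation deduplicated by position, with no merging radius.

Genes are reduced to the largest interval shared by all isoform spans
(intersection); genes whose isoform spans are disjoint are flagged and
excluded.  Classification precedence is PcG > active > inactive: any
single-base overlap with a PcG segment makes a gene PcG.  Hp1 is
constructed and carried through binning but has no dedicated analyses
here.

## Spike-normalized enrichment

Libraries carry per-read species tags (`target` vs `spike`), standing in
for alignment to a hybrid genome containing exogenous spike-in chromatin.
For bins, a read is counted in every window containing its fragment
midpoint; midpoint assignment avoids edge double-counting ambiguity within
one bin lattice.  Coverage is scaled to reads per million of the
*library total* (target + spike).  The spike normalization factor is

    alpha = (spike fraction in Input) / (spike fraction in IP)

and per-bin enrichment is `E = (alpha * RPM_IP + eps) / (RPM_Input + eps)`
with pseudocount `eps` defaulting to the RPM equivalent of one read in the
smaller library (bounds log-ratios in empty bins without distorting
typical ones).  With library-total RPM the estimator is exactly calibrated
under the generative model: writing S and T for spike and target input
chromatin mass and ⟨m⟩ for the genome-mean IP rate, the odds ratios cancel
so that E over a class equals that class's IP rate multiplier in
expectation, independent of the spike fraction.  A genome-wide gain of
target signal dilutes the IP spike fraction, raising alpha and preserving
the gain after per-million scaling — the property that makes total-signal
comparisons between samples meaningful.  Disabling spike normalization
fixes alpha = 1 and is recorded in the run manifest.

Class-stratified densities of log2 E use a Gaussian kernel with Silverman
bandwidth and are renormalized to unit area per class on the evaluation
grid, so curves compare the *proportion* of windows of each class, not raw
window numbers.

Domain-level calls average E over the class-assigned windows lying fully
inside each domain of at least 10 kb and threshold the mean at 2.0 by
default.  The threshold is exposed because "highly enriched" has no single
numeric definition; sharing counts are therefore threshold-dependent on
real data.  Sharing across samples reports domains enriched in all / some
/ none, and `pct_shared = 100 * |enriched in all| / |union|`.

Genotype contrasts at window level use per-window `log2(E_A/E_B)` with
per-class boxplot statistics; the notch half-width `1.58 * IQR / sqrt(n)`
is the conventional approximate 95% CI of a median.  Peak-centered
matrices report raw read-midpoint depth (not RPM) in fixed-width columns
over ±10 kb around each summit, padding columns that run off a chromosome
with NaN.  TSS-proximal activity is measured in the single 500 b window
immediately downstream of each transcription start site, strand-aware.

## Expression

TPM divides counts by gene length (the collapsed-interval length) and
scales each sample to 10^6.  Cross-sample normalization uses
median-of-ratios size factors: the reference is the per-gene geometric
mean over samples (genes with any zero excluded) and a sample's factor is
the median ratio to that reference.  Per-gene fold changes are ratios of
group means of normalized counts with a prior count (default 0.5) that
bounds log-ratios for zero-count genes.  No dispersion shrinkage or Wald
testing is performed: the downstream claims are distributional medians,
not per-gene significance calls.

The trajectory statistic is the *relative median*: per stage and class,
the class median fold change against a common undifferentiated baseline,
divided by the active-class median at the same stage.  Active is exactly 1
by construction.  This controlled comparison is also what the recovery
tests measure, deliberately: when a quarter of genes are differentially
expressed and the negative-binomial noise overlaps the effect size, the
per-sample median ratio shifts inside the DE/non-DE mixture and raw class
medians acquire a systematic offset of several percent (a property shared
by median-of-ratios normalizers generally); the ratio to the active median
cancels this global term.  95% CIs come from a seeded nonparametric
bootstrap over genes (resampling both the class and the active reference);
classes under 10 genes are flagged unreliable.

## Reporter induction

The silencing reporter is a heat-shock-inducible GFP read out as mean
fluorescence per germ-cell region, with the ovary pair as the replication
unit (cells within one ovary are averaged upstream, avoiding
pseudo-replication).  For one line/stage/genotype, induction replicates
are each heat-shocked intensity minus the pooled mean of the
non-heat-shocked arm; the statistic is invariant to additive background
and equivariant to multiplicative rescaling.  Genotype contrasts use an
unpaired two-tailed pooled-variance t-test on the induction replicates
with tiers * (p < 0.05), ** (p < 0.01), N.S.; tests across lines and
stages are not multiplicity-corrected by default (each insertion site is
an independent question), with optional Benjamini–Hochberg adjustment.

A calibration caveat: because every induction replicate subtracts the same
baseline estimate, replicates are positively correlated, and with a
baseline arm of size n0 comparable to the n heat-shocked replicates the t
statistic is inflated by about sqrt(1 + n/n0) under the null (~15% of null
p-values below 0.05 at n = n0 = 5 in simulation).  The test is calibrated
when the baseline pools many more measurements than there are induction
replicates, which is how the assay's per-stage baseline is constructed;
the generator exposes the baseline arm size so both regimes can be
studied.

## Synthetic data

The generator provides ground truth for every stage.  Chromosomes are
partitioned into class segments with geometric lengths (memoryless;
configurable mean, default 20 kb so domains comfortably span many 5 kb
windows), class weights defaulting to a euchromatin-rich genome (active
0.45, inactive 0.35, PcG 0.10, Hp1 0.10), adjacent segments always
differing in class, and the final segment truncated to conserve chromosome
length.  Genes are placed wholly inside segments of their intended class
with 1–3 isoforms extending a shared core.

ChIP pairs: Input target reads are uniform; IP target reads land with
per-base rate proportional to the class multiplier, default
{active 0.2, inactive 2, PcG 10, Hp1 2} — an approximately tenfold PcG
enrichment over background with depleted active chromatin.  Spike reads
live on a dedicated spike chromosome; the Input spike fraction is
configured (default 0.10) and the IP spike fraction is *derived* by
holding spike mass fixed while target IP mass scales with the genome-mean
multiplier, so global methylation changes move the spike fraction exactly
as spike-in normalization assumes.  Library sizes match the configured
depths (default 5 × 10^5 reads) exactly.

Expression counts are negative-binomial (dispersion 0.1, mean 200 with a
log-normal per-gene spread of σ = 0.5) with condition-2 means multiplied
by `2^class_log2fc`.  Reporter intensities are Gaussian around a
background of 10 units, with heat shock adding
`base_induction × silencing_factor` (defaults 100 × 1.0) and noise SD 5.
One master seed drives everything; stage seeds derive by stable hashing of
stage names, so identical configurations are byte-reproducible.

What the generator does *not* emulate: mappability and GC bias, fragment
length distributions, PCR duplicates, copy-number structure, cross-species
read mis-assignment, isoform-level expression, cell-type admixture, and
image-derived intensity artifacts.  Passing recovery tests therefore
demonstrates estimator correctness under the stated sampling model, not
robustness to those real-data complications.

## Problem sizes used in tests

Unit tests run on one 200 kb chromosome with 2 × 10^4-read libraries;
recovery tests use the default two 1 Mb chromosomes with 5 × 10^5-read
libraries, 2000 genes per class for expression, 50 reporter replicates,
and 500 simulations for the null-calibration study; the end-to-end
determinism check runs the full pipeline twice on a 300 kb genome.  These
sizes put every sampling error well inside the stated tolerances while
keeping the whole suite inside a couple of minutes.

## Known limitations

* Domain "enrichment" is a thresholded mean; no uncertainty is attached to
  individual domain calls.
* The 4-class model is an input; states are never learned from data.
* Fold-change summaries assume the two samples share one bin lattice; no
  re-binning or liftover is provided.
* The raw (non-relative) class median fold change inherits the
  normalization offset described above when a large gene fraction is
  differentially expressed.
* The t-test calibration caveat above applies whenever baseline arms are
  small.
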