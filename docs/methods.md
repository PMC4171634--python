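# Methods

## Scope and model

`methcrosstalk` analyses methylated-DNA capture sequencing (MBD/5mC-seq): an
affinity reagent enriches methylated fragments, reads are mapped, and local
read density proxies CpG methylation.  The package covers the downstream
analysis of a knockdown-versus-control study design: calling enriched
methylation islands against a uniform Poisson background, calling
differentially enriched regions between conditions, attributing changes to
gene features and CpG-island context, profiling tag density along genes and
around anchor points, classifying promoters by CpG density, and testing
whether hyper-/hypomethylated promoters are over- or under-represented in
chromatin-state strata (H3K4me3 / H3K27me3 / H2AK119ub combinations) or in
external gene lists.

All coordinates are 0-based half-open.  A tag is stored by its 5' position;
for a minus-strand read the 5' coordinate is the rightmost aligned base, and
fragment extension therefore proceeds leftward.

## Island calling

The genome is tiled into `window_size` (200 bp) windows.  Tags are
deduplicated to at most `redundancy_allowed` (1) per (chromosome, position,
strand), notionally lengthened to `fragment_size` (300 bp) toward their 3'
end, and counted by fragment midpoint.  The background is uniform Poisson
with rate

    lambda = library_size * window_size / (genome_length * effective_genome_fraction)

with `effective_genome_fraction` defaulting to 0.854.  A window with count c
is *eligible* when P(X >= c; lambda) < `window_pvalue` (default 0.20, the
convention of spatial-clustering broad-domain callers) and carries score
-ln p(c; lambda).  Eligible windows separated by at most `gap_size` (600 bp)
of ineligible sequence merge into islands whose score is the sum of member
scores.  Islands are filtered at a score threshold chosen so that the
expected number of equal-or-better-scoring islands in a pure-background
genome does not exceed `e_value` (1000): we estimate this expectation from
20 Monte-Carlo background genomes drawn with a fixed internal seed rather
than by the analytic score-distribution recursion; the two agree to within
Monte-Carlo sampling error, and the approximation is itself calibrated by a
test (null genomes pass at most twice the E-value in >= 95% of replicates).

A caveat that matters at desk scale: the E-value is an absolute expected
count, tuned in common practice to genomes of ~1e7 windows.  On a toy
genome of ~3e4 windows an E-value of 1000 exceeds the total number of
background islands, so the score filter passes essentially all of them
(~70 background islands per Mb in our benchmark at ~0.5 tags/window).
Recovery of planted enriched domains is unaffected (50/50 at 8x
enrichment); users who need specificity on small genomes should scale the
E-value with genome size (E ~ 2 on 6 Mb matches the stringency that 1000
provides on a mammalian genome) or tighten `window_pvalue`.  We deliberately
do not change the defaults, which mirror the published parameterization.

## Differential regions and feature-level calls

Differential testing runs over a region set (usually the union of islands
called in either library).  Counts are normalized to tags per million; the
p-value is a two-sided Poisson test of count_a against count_b scaled by the
library-size ratio (the study design has no replicates, so a
replicate-aware dispersion model is out of reach by construction);
Benjamini-Hochberg q-values are computed across regions and regions with
q < `fdr` (0.01) are flagged.  log2 fold changes use a pseudocount of 1
normalized count and are computed as log2(a+c) - log2(b+c), which makes the
library-swap antisymmetry bit-exact.

Because islands are broad, an island spanning a 2-kb promoter plus several
kb of unchanged flank dilutes the promoter's fold change (a true 2.5-fold
promoter change measured over a 7-kb island can fall below 2-fold).  The
package therefore provides two provenances for gene-level calls, mirroring
the two natural readouts:

* **island-based** — differential islands are classified by maximal overlap
  (precedence promoter > body > 3' end > intergenic, ties by overlap then
  gene name) and rolled up per gene;
* **feature-based (FPKM)** — promoter, body, 3'-end, CGI and shore
  intervals are counted directly in both libraries and tested with the same
  normalized Poisson/BH machinery.

The pipeline uses the feature-based route for its per-gene call tables; the
island route remains available.  A gene is hyper- (hypo-)methylated for a
feature class when at least one passing feature/region reaches the fold
threshold (default 2-fold, boundary inclusive); a gene may be both hyper and
hypo in its body through distinct regions and both calls are kept.

## Annotation

Promoters default to TSS +/- 1 kb (the source convention "-1 kb - +1" is
read as symmetric +/- 1 kb, consistent with the +/- 5 kb promoter profiles;
configurable), gene 3' ends to TTS + 1 kb, both strand-aware.  CGI shores
are the 2 kb flanking a CGI (a field-standard width; configurable) with any
base inside another CGI removed.  Promoter CpG classes scan 500-bp windows
at a 5-bp step: HCP requires a window with CpG observed/expected >= 0.75
and GC >= 0.55; LCP requires no window at o/e >= 0.48; everything else is
ICP.  CpG o/e is (#CG x length)/(#C x #G) with N bases excluded.

## Density profiles

Profiles report midpoint-counted tags per kb of bin per million tags
(FPKM-style).  Metagenes use 100 fixed-width bins per 10-kb flank and 100
relative-length body bins (0% = TSS, 100% = TTS), minus-strand genes
reversed; point profiles use 100 fixed-width bins across +/- 5 kb.  Bin
counts are not prescribed by the source analysis; 100 is a resolution
choice.  Before profiling, at most two tags per position are kept (the
profiling arm's stricter duplicate rule, distinct from the caller's
redundancy 1).  Log2 display adds a pseudocount of 0.1 x the mean bin
coverage.  Genes shorter than the body bin count are excluded and logged.

## Validation assays

Array (Infinium-like) calls: delta beta = mean(kd) - mean(control) across
replicate beta values; a probe is differential when |delta beta| > 0.2 and
p < 0.05.  The per-probe test behind the original array software's p-values
is unspecified; we use Welch's t across replicates and record the test name
in the output (with a single replicate the call degrades to delta-beta-only
and is flagged).  Probes map to genes through the array arm's own promoter
rule, the 1700 bp immediately upstream of the TSS.  MeDIP-qPCR enrichment
relative to input is 2^-(sample Ct - input Ct).

## Enrichment statistics

The two-tailed Fisher exact test uses the probability-mass convention (sum
of hypergeometric probabilities of tables, at the observed margins, no more
probable than the observed table) and is computed by direct enumeration
over the support — exact at any practical universe size, and cross-checked
in the tests against both rational-arithmetic enumeration and an
independent library implementation.  For stringency every test is EASE
adjusted: one gene is moved out of the overlap cell (a-1, b+1, floored at
an empty overlap) before testing.  This is conservative for enrichment; for
depleted overlaps the adjustment can sharpen the p-value, so directionality
is always reported alongside.  Bivalency means K4me3 and K27me3 together at
the promoter regardless of H2AK119ub; the K27/ub stratification is computed
among all promoters with its own universe, and both universes are explicit
parameters.  "Marked" means >= 1 bp of peak overlap with the promoter
(minimum-overlap option available).  Observed-vs-expected differences are
reported both in percentage points and as relative percent, because the
phrase "X% greater than expected" is ambiguous between the two.

Clustering of the promoter log2-change matrix is agglomerative with
Euclidean distance and average linkage; unchanged/missing cells are 0 (no
change) so the matrix is complete, with an NA-masking mode.  None of these
choices is dictated by the source analysis; they are the common defaults.

## Synthetic data generator

The generator emulates the study design, not the raw assay: a toy genome
(default 3 chromosomes x 2 Mb, 300 non-overlapping genes of 2-20 kb) with
CGIs at 60% of promoters plus intragenic and intergenic CGIs; promoter
sequences constructed so CGI promoters satisfy the HCP criterion, half of
the non-CGI promoters are LCP and the rest ICP; one chromatin-state
category per promoter sampled from configurable probabilities (default 25%
bivalent) with mark peak sets emitted consistently.  Methylation truth is
per feature: CGIs 0.10, promoters 0.25, bodies 0.60, 3' ends 0.50,
intergenic 0.40 — CGIs hypomethylated against a methylated default state.
Knockdown effects multiply the methylation of a target stratum (a chromatin
state's promoters and their promoter CGIs, or a whole feature class) by a
planted fold, clipped to [0, 1].

Tags are Poisson per 200-bp window with rate proportional to methylation x
CpG-dinucleotide count of the window, scaled to the configured depth
(default 5e5 per library), plus a uniform floor of 5% of depth that
prevents zero-count degeneracy.  The CpG weight ties capture efficiency to
CpG density, as MBD affinity does; it also means CpG-poor (LCP) promoters
yield few fragments and are genuinely untestable by the capture assay —
planted changes there are invisible, which bounds whole-genome sensitivity
by the CGI-promoter fraction.  Passing tests therefore demonstrate recovery
at capture-detectable (CpG-dense) features, matching what the assay can
claim on real data.  The generator does not model read-level sequences,
mapping error, GC bias beyond the CpG weight, copy number, or bisulfite
chemistry.

Beta matrices place three probes per gene inside the -1700 bp promoter
window with N(0, 0.05) noise over 4 replicates, clipped to [0, 1].  MeDIP
Ct pairs encode a locus's enrichment (promoter methylation relative to the
genome-average control methylation) as a delta-Ct with N(0, 0.15) noise.
Library depths per sample are not reported for the original study; the 5e5
default is a toy-genome choice giving coverage comparable, per window, to a
typical capture experiment.

All randomness flows from a single integer seed through per-component
`numpy` generator streams, so every output is byte-reproducible.

## Pipeline

`run_all` executes simulate -> libraries -> islands -> differential ->
rollup -> profiles -> matrix/cluster -> enrichment, persisting plain text
files and a JSON manifest of parameters, seeds, row counts and timings.
Stage outputs are memoized by file existence under `--resume`: a deleted
intermediate is regenerated (byte-identically, by determinism) while
existing outputs are reused.  Problem sizes throughout the tests and the
acceptance script (6-Mb genomes, 300 genes, 5e5-tag libraries, 5-20 seeds
per property) are chosen so the full suite exercises every stage at
realistic per-window coverage.

## Known limitations

* No replicate-aware dispersion modelling in the differential test.
* The E-value filter's absolute scale makes specificity genome-size
  dependent (see island calling above).
* Chromatin states are promoter-level and categorical; no peak strength.
* The EASE adjustment is applied two-tailed; see the conservativeness note.
* Array normalization, detection p-values and qPCR efficiency correction
  are out of scope.
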