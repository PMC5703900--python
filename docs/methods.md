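# Methods

This note records the models the pipeline implements, the parameters
that matter, what the synthetic generator does and does not emulate,
and the choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Coordinates and formats

All region logic is 0-based half-open (BED convention); GTF is
converted to 1-based inclusive only at the I/O boundary, and converters
are round-trip tested in both directions. Floating-point TSV output is
fixed at 6 significant digits so repeated runs diff cleanly.

## ChIP bin enrichment

Reads (50-bp single-end in the synthetic data) are extended to
`extension` = 200 bp from the 5′ end in the strand direction and
increment every 25-bp bin their extended span overlaps. A read longer
than the extension keeps its original span (with a warning); reads
outside the chromosome are counted and dropped.

A bin with count `c` is enriched iff

1. P(X ≥ c) < `p_threshold` (default 10⁻⁹) for X ~ Poisson(λ), where
   λ is the genome-wide mean *allocated* count per bin of the sample
   track. The tail is the exact survival function; at these thresholds
   a normal approximation would misclassify bins near the boundary, so
   the implementation is cross-checked against a brute-force
   term-summation oracle (exact agreement on 1000 random (c, λ) pairs,
   λ ∈ [0.1, 50]).
2. `c ≥ min_fold · max(ĉ, ε)` (default 5-fold), where ĉ is the pooled
   input count rescaled by the library-size ratio and ε is the rescaled
   genome-wide input mean — the floor keeps zero-input bins from
   passing vacuously. Input replicates are pooled per condition before
   use.

Open choices resolved here: λ is global rather than local (a
per-chromosome switch `local_lambda` is exposed); the fold test uses
library-size-rescaled raw counts. Both bins of uncertainty are noted in
the module docstrings and configurable.

Per condition, replicate masks are ANDed; constituent enhancers are
maximal runs of positive bins, unioned (and overlap-merged) across the
three conditions, kept at ≥ 200 bp.

## Super-enhancer calling

CEs are stitched transitively when the gap to the previous CE is
≤ 12 500 bp. The ranking signal of a stitched locus is
max(0, rpm_sample − rpm_input) summed over the bins it covers — per
ROSE convention no length normalization for ranking (a
length-normalized variant exists for signal-density comparisons). No
promoter/TSS exclusion is applied during stitching.

The SE cutoff operationalizes "the point where the slope of the ranked
signal curve is 1": with ranks scaled by (N−1) and signals by the
maximum, the threshold is the signal at the point minimizing y − x,
i.e. where a slope-1 line approached from below first touches the
curve (the last such index on ties, which is the conservative side).
This tangent form is robust to noise and to exactly-tied top signals,
where a rule based on consecutive discrete slopes degenerates (equal
top signals give zero slopes and would force an empty SE set).
Signals exactly at the threshold are *not* SEs ("above a cut-off" is
strict). Degenerate inputs — all signals equal, or all zero — yield
threshold = max, hence zero SEs; a single stitched region has no
distribution to place a cutoff on and is conservatively not SE.

Region identity across replicates and conditions is any-length
coordinate overlap, matching the activity-matrix rule: each condition's
stitched list is scored in both replicates, SE-per-condition requires
both flags, the global list is the merged union, and TEs are the CEs
with zero overlap of it.

## lncRNA filters and classification

Filters run in a fixed order and log the first failure per transcript:
novel-lncRNA structure (mature exonic length ≥ 200 bp, ≥ 2 exons), then
coding potential (score > 4 discards; the score itself is an external
input), then expression (mean FPKM > 0.1 in ≥ 1 condition; a missing
expression row counts as zero). "Length" is mature (exonic) length,
matching transcript-reconstruction semantics.

Classification precedence is plncRNA → SE lncRNA → TE lncRNA →
unmarked, evaluated over all transcripts of a gene: any transcript
qualifying at a higher rule sets the gene class. "Any part of the
transcript" is read as the full gene span (exons + introns), because
chromatin regions are not exon-restricted. Chromatin marks count if
positive in any of the three conditions (a per-condition mode can be
had by passing per-condition region lists). The H3K4me3 TSS window is
±1 kb inclusive.

## Expression statistics

ND is computed on condition means (replicates collapsed first). For k
nonnegative values, mean ≥ max/k gives 0 ≤ ND ≤ k, so 3 here; ND is
scale-invariant and NaN for an all-zero gene (such genes should have
been filtered). Rank-sum comparisons use the exact null when the pooled
data is tie-free and the smaller group has ≤ 20 observations, otherwise
the tie-corrected normal approximation with continuity correction; the
exact path is verified against full C(n, nA) enumeration for all group
sizes ≤ 6. Density summaries use a Gaussian kernel with Silverman's
bandwidth. Fold-change sets add a configurable pseudocount π = 0.01
FPKM to both means (zero-handling is not otherwise pinned down) and,
when p-values are supplied, additionally require BH-adjusted p ≤ 0.05.
Size factors re-implement the DESeq median-of-ratios estimator
(geometric-mean reference over genes positive in all samples) and are
cross-checked against pydeseq2 in the test suite. The Welch-t test on
log2(x + π) is pipeline plumbing — a stand-in differential test so the
synthetic pipeline runs end to end, not an empirical-Bayes model.

## Tissue enrichment

Panel preprocessing: strand sum → replicate mean → size-factor
normalization → keep genes ≥ 0.1 in at least one tissue. The HE
denominator uses the *sample* (n−1) standard deviation — the population
form is the other defensible reading; the choice is recorded here and
in the output metadata. The denominator is read as μ + 2σ (mean plus
two standard deviations), the only dimensionally coherent arrangement
of the printed formula. Scores are computed on linear expression. A
zero denominator with positive numerator yields an `inf` sentinel
(serialized as `inf` in TSV) and counts as enriched; HE of a constant
gene is exactly 1 and therefore *not* enriched (strict >). The heart
column of the per-tissue score vector is computed by the same code path
as the HE score and is bit-identical to it. Enrichment ratios between
two gene sets divide enriched percentages; a zero denominator
percentage returns NaN with a warning.

## Conservation

Tracks are sparse runs of per-base scores. Fragment scores treat
uncovered bases as 0 in the numerator but keep them in the denominator
(probability-like phastCons semantics); TSS-window maxima ignore
uncovered bases entirely, since a max over signed phyloP-like scores
must not be dragged toward 0 by missing data. Promoters are the 1000 bp
strand-aware upstream of the TSS ('+': [tss−1000, tss), '−': mirrored);
overlapping transcript promoters of one gene are merged before scoring,
while exon/intron scores are per-transcript and averaged per gene.
Intergenic background fragments are uniform in length over
3400 bp ± 20% and placed by rejection sampling (≤ 10·n attempts) in the
complement of gene spans; inter-fragment overlap is allowed, gene
overlap is not.

## Synthetic data

The generator emulates the study's data shapes: a toy genome (default
2 Mb over two chromosomes) with placed, non-overlapping gene loci
(protein-coding genes, annotated and novel lncRNAs); H3K27Ac/H3K4me3/
input read sets for three conditions × two replicates; an FPKM matrix
(3 conditions × 4 replicates); a stranded 12-tissue × 2-replicate count
panel; and a conservation track. All randomness flows from one seed
through sub-streams keyed by purpose and (mark, condition, replicate),
so adding one track never perturbs another, and fixed seed means
byte-identical outputs.

Reads are a piecewise-constant-intensity Poisson process: uniform
background, multiplied by a site's fold inside planted enhancers (or
promoter marks, for H3K4me3) active in the condition; input sees
background only; totals are Poisson around `reads_per_replicate`;
strands are uniform and read length is fixed at 50 bp with fragment
extension left to the caller. Expression noise is mean-1 log-normal
with configured CV (exactly 1 at CV = 0, so noiseless arithmetic is
testable); strand counts split a gene's total by a random fraction and
sum back exactly. Planted SE clusters place ≥ 3 constituents within
12.5 kb so stitching is exercised by construction; novel lncRNAs
include deliberate single-exon, sub-200-bp, and coding-score > 4 decoys
whose identities the truth records; a few novel lncRNAs are placed
*on* planted sites (one per SE cluster first, then isolated sites,
without promoter marks) so the SE/TE lncRNA classes occur end to end.
Condition-specific genes are drawn with 3× weight on lncRNA genes, so
the synthetic transcriptome reproduces the qualitative
population-specificity skew of lncRNAs that the ND comparison exists to
detect. No published noise parameters exist for any of these datasets;
all generator settings are explicit config knobs chosen as plausible
defaults (e.g. 20× enhancer fold, CV 0.2, 8× heart effect, promoter
conservation elevation +0.3 over a 0.1 background), not claims about
the real data.

Deliberately not emulated: fragment-size distributions, GC bias,
mappability, duplicated reads, allele-specific expression. Passing
tests therefore demonstrate correctness of the calling logic and
statistics under the stated model, not robustness to those real-data
artifacts.

## Problem sizes

The validation studies run at desk scale by design: the planted-
enhancer study uses a 2 × 5 Mb genome with 50 constituents at 20× over
a 10⁶-read background (≈ λ 21 per 25-bp bin, comparable bin occupancy
to a deep real library on a small genome); the heart-enrichment study
uses 1000 genes × 20 seeds; conservation uses 200 genes against 1000
intergenic fragments (the published analysis used 50 000 on a full
genome; 1000 is ample for a rank-sum comparison at n = 200). The
deep-sequencing headline counts of a real study (tens of thousands of
reconstructed transcripts) depend on > 500M-read libraries and are out
of reach of, and out of scope for, the synthetic validation.

## Known limitations

- The Poisson background is globally (or per-chromosome) homogeneous;
  no local-λ or input-conditional background.
- The stand-in differential test (Welch t on log FPKM) is not a
  moderated/voom-style model and is only used on synthetic data.
- Real-mode inputs accept BED/GTF/TSV/bedGraph; BAM and bigWig are out
  of scope (convert upstream with standard tooling).
- The branch of the published conservation analysis that compares
  promoter constraint across external adult-tissue datasets requires
  those datasets and is not reproduced here.
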