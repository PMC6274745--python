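# Methods

This note documents the models and procedures implemented in `bovlnc`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter.

## Study design assumed throughout

Two dietary treatments (LSO: linseed oil, SFO: safflower oil), three biopsy
timepoints (D-14 control period, D+7 early treatment, D+28 late treatment),
six cows per treatment — 36 libraries, 18 per treatment. Differential
expression compares timepoints within a treatment over the three contrasts
D-14 vs D+7, D+7 vs D+28, D-14 vs D+28. Cis-target correlations are
computed within a treatment over its 18 libraries; the t transform of a
Pearson r therefore uses 16 degrees of freedom.

## Identification cascade

1. **Length filter.** Spliced length ≥ 200 nt, strict (a 199-nt transcript
   is removed). Removals are logged with reasons, never silently dropped.
2. **Class codes.** Each assembled transcript is compared with every
   reference transcript on its chromosome and receives exactly one of
   `= c j o x i u`, with precedence `=` > `c` > `j` > `o` > `x` > `i` > `u`
   (most specific first; the upstream tools do not publish a tie-break, so
   this is our choice, and permuting reference order provably cannot change
   the result because ties on code fall back to reference id). Definitions:
   `=` identical intron chain (single-exon: same-strand exonic overlap with
   a single-exon reference); `c` exon chain contained with matching
   internal splice sites; `j` same strand with ≥1 shared intron; `o`
   same-strand exonic overlap otherwise; `x` antisense exonic overlap; `i`
   entirely inside one reference intron, assigned regardless of strand
   (an antisense intronic transcript is `i`, not `x`, because `x` requires
   exonic overlap); `u` none of the above. "Overlap" means ≥1 shared base.
   Codes `i o u x` are retained as lncRNA candidates; `= c j` are removed
   as matching annotated genes.
3. **Coding potential.** Four features per sequence: longest sense-strand
   ORF (ATG to in-frame stop, stop included; a both-strands mode exists
   behind a flag for unstranded assemblies), ORF coverage, the Fickett
   TESTCODE statistic (classic position-asymmetry and composition lookup
   tables with the published weights), and the mean natural-log likelihood
   ratio of in-frame hexamers (step 3, frame 0, tables pseudocount-1
   smoothed) between coding and non-coding training sets. A logistic
   regression on the standardized features is trained on user-supplied
   labeled sequences (≥50 per class); candidates with coding probability
   ≥ 0.4 are removed. The boundary value 0.4 counts as coding — the
   conservative direction for a filter whose job is removing possibly
   coding transcripts. This single pluggable classifier stands in for
   multi-tool cascades (profile-based classifiers followed by
   regression-based ones); externally computed scores can be supplied
   through the feature interface, which makes stage-order questions moot.
4. **Exclusion list.** An optional externally produced list of transcripts
   with protein database hits is subtracted (set difference, logged). The
   sequence search itself is out of scope; this consumes its output.
5. **Known/novel labels.** Candidates are compared against a known-lncRNA
   annotation; codes `= c j` ⇒ known, else novel. The pipeline carries the
   gene-type distinction through biotypes on a single reference object:
   filtering uses the protein-coding (plus small ncRNA) subset, labeling
   uses the lncRNA subset — mirroring the two databases such workflows
   consult.

## Positional taxonomy (reconstruction)

The 11 mutually exclusive classes are a reconstruction from the standard
location/orientation vocabulary: intergenic >1 kb; exonic overlap
sense/antisense; intronic sense/antisense; protein-coding gene contained in
a lncRNA intron; within 1 kb upstream of the TSS sense/antisense; within
1 kb downstream of the TES sense/antisense; and a bidirectional-promoter
class. Because an upstream antisense lncRNA is always geometrically
divergent, the bidirectional class is defined as the tight subcase: gap
≤ 500 bp between the divergent pair (for an upstream lncRNA on the opposite
strand the gap equals the TSS-to-TSS distance); divergent pairs at
500–1000 bp are upstream-antisense. Boundary semantics: a gap of exactly
1000 bp is "within 1 kb"; 1001 bp is not.

Precedence when several genes/classes are eligible: exonic overlap >
intronic > gene-in-lncRNA-intron > upstream/downstream > bidirectional >
intergenic, with nearer genes breaking ties. A lncRNA overlapping a gene
span without exonic overlap or full intron containment (straddling a gene
boundary) is resolved to the upstream/downstream side of its midpoint so
every input receives exactly one class. A lncRNA on a chromosome absent
from the annotation is reported intergenic at infinite distance with a
warning.

## Expression and differential expression

* **Size factors** are plain median-of-ratios: features with a zero in any
  library are excluded from the geometric-mean reference; the median is
  taken on the linear ratio scale (exponentiating a log-scale median
  differs whenever the median averages two values).
* **Truly-expressed filter**: normalized count ≥ 5 in at least
  ⌈0.10·m⌉ libraries — "at least 10%" is read as a ceiling, so 36
  libraries require 4. The filter is monotone in counts.
* **FPKM** uses the column sums of the supplied count matrix as the
  per-library totals N_j; the original aligner-level mapped-read totals are
  not visible to a count-matrix consumer, which is a documented divergence
  from FPKM computed upstream of counting.
* **NB Wald test**, per feature and contrast: group means on the
  normalized scale (pseudo-ML, q̂ = Σk/Σs), gene-wise dispersion by
  Cox–Reid adjusted maximum likelihood (floored at 1e-8, optimized on the
  log scale), Wald statistic on the log group ratio with variance
  1/ΣW_A + 1/ΣW_B, W = μ/(1+αμ). The statistic is referred to a
  **t distribution with n_A+n_B−2 df** rather than a normal: with the
  dispersion estimated from 12 observations the normal reference is
  measurably anticonservative (null fraction p<0.05 ≈ 0.07), while the t
  reference restores nominal behavior (≈ 0.046, with essentially no false
  BH discoveries at adjusted p<0.1 in a 2,000-feature null). Reported
  log2FC uses a prior count of 0.5 on normalized group means. Cow pairing
  is ignored (plain two-group comparison per contrast); a paired or
  repeated-measures design is a known limitation. Reported fold changes
  follow the table convention FC = 2^|log2FC| (3 decimals) with the sign
  carried by log2FC.
* **BH adjustment** is the step-up procedure, implemented once and shared
  by the DE and enrichment modules.

## Cis targets and enrichment

Candidate cis genes are those whose span lies within 50 kb of the lncRNA
span (inclusive at exactly 50,000 bp; distance is the minimal span gap,
0 for overlap). A pair is called when the per-treatment Pearson
correlation of expression strictly exceeds 0.7. Expression values default
to log2(normalized count + 1); a linear-scale option exists because the
upstream convention (FPKM vs normalized counts, raw vs log) is not
standardized. The same calling runs once over all identified lncRNAs and
once restricted to the DE-significant subset.

Enrichment is an upper-tail hypergeometric test P(X ≥ k) per term, BH
adjusted within each ontology source (per-source rather than global
adjustment — a choice, since tools differ). Significance follows the dual
regime: GO sources at adjusted p ≤ 0.05 (inclusive), pathway source at raw
p < 0.05 (strict). The gene universe defaults to the genes present in the
expression data after filtering, exposed as an argument because enrichment
platforms differ in their universe definitions.

## qPCR

2^−ΔΔCt with two reference genes combined by the arithmetic mean of their
Cts (equivalent to a geometric mean of linear quantities); replicates are
averaged on the Ct scale within group before differencing. The calibrator
group is an explicit required argument. Fold changes are invariant to
global Ct shifts and reciprocal under group exchange.

## Synthetic-data generator

The generator's defaults encode the assumed study: 36 libraries
(2 treatments × 3 days × 6 cows), 150 lncRNA candidates allocated across
all 11 positional classes (largest-remainder allocation, ≥5 per requested
class), 1–10-exon protein-coding genes, ≥3 sub-200-nt decoys for the length
filter, and ≥5 decoys per removed class code (`=`, `c`, `j`). 40% of
candidates are planted as known (an exact copy or a containing chain in the
lncRNA reference), which also provides the non-coding training pool.
Coding training sequences carry an in-frame ORF covering ≥55% of the
transcript with codons drawn from a fixed biased usage table; non-coding
sequences are uniform ACGT. Counts are NB with dispersion 0.05 by default —
a moderate bulk-RNA-seq value; the real study's dispersion regime is
unknown, so this is a free parameter, not an estimate. Library depth
defaults to 100,000 fragments over ~360 features so that most features
clear the expression filter while the lognormal tail does not.

Planted log2 fold changes multiply the (treatment, dayB) cell of a
contrast by 2^lfc; because the three contrasts are linearly dependent, the
truth table exposes the *effective* lfc per contrast implied by all planted
multipliers. Planted cis pairs share a per-library latent normal factor on
the log2 scale; the factor's weight is found by bisection against
simulated realized correlations (150 replicates per evaluation, n = 18),
so the mean realized r matches the target (measured: 0.900 ± 0.04 across
seeds for a 0.9 target). The multiplier is mean-corrected
(E[2^{sZ}] = e^{(s ln 2)²/2}) so planting correlation does not shift
expression level.

One integer seed drives everything through split `SeedSequence` streams —
one per placed unit, per sequence, per feature row of the count matrix and
per cis pair — so identical configurations give byte-identical GTF, FASTA
and TSV outputs, and adding features does not perturb earlier draws.

**What the generator does not emulate:** read-level artifacts (no FASTQ,
alignment noise, positional bias), batch/lane effects, GC and length bias
in counting, gene–gene correlation beyond the planted pairs, cow-level
repeated-measures correlation, and annotation errors. Passing tests
therefore demonstrate correctness of the algorithms under a clean
generative model, not robustness to the messiness of real libraries.

**Expected stochastic behavior:** a decoy pair planted at r = 0.3 clears
the 0.7 calling threshold in roughly 2% of draws at n = 18 (the upper
Fisher-z tail), so across 20 decoys an occasional false call per dataset
is correct behavior of the statistics, not a defect; recovery of pairs
planted at r = 0.9 is essentially complete.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; GTF I/O converts to/from
  1-based inclusive.
* Dispersion optimization: bounded scalar minimization on log α in
  [log 1e-8, log 100], xatol 1e-4; group-label swap symmetry holds to that
  tolerance.
* All-zero features in a contrast: p = 1, log2FC = 0, flagged.
* Constant expression vectors are excluded from correlation calling with a
  warning (r undefined).
* Terms with no universe genes or no overlap: p = 1, never significant.
* Top-expressed ties break lexicographically by transcript id; length
  histogram bins are [200, 999], [1000, 2499], [≥2500] nt.
* Size-factor computation refuses matrices with no all-nonzero feature and
  advises filtering.

## Problem sizes used in validation

The test suite and the acceptance script run: ≥500 random transcripts
against the class-code oracle; the default 150-lncRNA fixture for
positional and label recovery; 2,000 null plus 200 alternative features for
NB calibration and sensitivity; 1,000 random vectors for BH; 200 random
configurations for the hypergeometric tail; 10 generated datasets with
20 + 20 planted/decoy pairs for cis recovery; and two full pipeline runs
for byte-identical reproducibility. These sizes give stable estimates of
each property while keeping a full validation run in the low minutes on a
single core.
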