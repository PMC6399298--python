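# Methods

## Problem and approach

`somanet` detects somatic SNVs and small INDELs from a coordinate-sorted
tumor/normal BAM pair.  The pipeline has four stages:

1. **Scan.** The tumor alignment is scanned once; every locus with at
   least one non-reference observation (mismatch, CIGAR insertion or
   deletion) is summarized and passed through deliberately liberal
   filters.  The filters bound the candidate count without deciding
   anything subtle — the classifier does that later.
2. **Featurize.** Each candidate is summarized into a k x 5 x 32 matrix
   over a window of seven reference bases centered on the candidate.  The
   reference is augmented with gap columns wherever any overlapping read
   carries an insertion, which turns the BAM into a local multiple
   sequence alignment without realignment; rows are (A, C, G, T, gap).
3. **Classify.** A small residual CNN reads the matrix and emits a 4-way
   mutation-type posterior (non-somatic / SNV / insertion / deletion), a
   4-way length-class posterior (0 / 1 / 2 / >=3) and a position estimate
   (candidate column / 32).
4. **Call.** Somatic-typed candidates are resolved to REF/ALT alleles by
   CIGAR consensus over supporting reads, scored with
   p = 1 - P(non-somatic), Phred-scaled into QUAL = -10 log10(1 - p)
   (capped at 99), and written as VCF v4.2.

## Candidate filters

SNVs are kept iff (AF >= 0.03 OR alt support >= 3 reads) AND mean alt
base quality > 19 Phred; the quality condition gates both branches
because base quality is a property of the supporting observations, not of
either branch.  1-base INDELs: AF >= 0.02 OR support >= 2.  Longer
INDELs: AF >= 0.03.  Presets: `wes`/`panel` lower the SNV quality bound
to > 14; `pacbio` uses AF-only rules (0.1 for SNVs and multi-base INDELs,
0.15 for 1-base INDELs) with the support branches disabled, because raw
read-count support carries no signal at long-read error rates.  All AF
denominators count reads spanning the locus, including those carrying a
deletion.  INDELs are left-aligned against the reference before keying so
scan evidence, truth records and external VCFs unify on one
representation.

## Input matrix

The stand-alone layout has 26 channels: reference one-hot (gap row for
insertion slots), tumor base frequencies, normal base frequencies, a
candidate-position one-hot column marker, and 11 alignment-feature
channels per sample: depth, mean base quality, mean mapping quality,
forward- and reverse-strand fractions, soft-clip and any-clip fractions,
mean edit distance, mean alignment score, properly-paired and
mate-unmapped fractions.  Ensemble mode appends 93 opaque slots for
external-caller features (119 channels total); slot semantics are the
caller configuration's contract.

Numerical conventions (all cells clipped to [0, 1]): base quality is
divided by 41 and mapping quality by 70 (Illumina-convention caps); depth
by 100 (configurable); edit distance and alignment score by read length.
Frequency columns with coverage sum to 1; zero-coverage columns are
all-zero.  Coverage channels are column-constant across the five rows,
and the reference channel is one-hot — both conventions chosen here and
fixed in the channel registry, whose hash binds checkpoints to datasets.
Where insertions would inflate the window beyond 32 columns, insertion
slots farthest from the candidate are truncated first, so the seven
reference columns always survive.  Gap symbols carry no base quality and
contribute zero to the quality channel.

## Network

Nine convolutional layers: one initial 1x3 convolution with 64 output
channels, then four residual blocks (3x3 convolution, batch norm, ReLU,
5x5 convolution, identity added), with batch norm + width-only max
pooling (kernel 3, stride 2; schedule 32 -> 16 -> 8 -> 4 -> 2) after the
initial convolution and between blocks.  The five base rows are
categorical, not spatial, so pooling never touches them.  The final
64 x 5 x 2 = 640 feature map feeds a fully connected layer of 240 units
and three heads.  The default stand-alone network has 719,657 trainable
parameters (737,513 in ensemble mode) — the two differ only in the first
convolution (93 x 3 x 64 = 17,856).

Everything (convolution, batch norm, pooling, SGD with momentum, the
losses and their gradients) is implemented directly on NumPy with
explicit forward/backward passes; convolutions use a shift-and-add
decomposition (one channel-axis GEMM per kernel offset), which is the
right trade-off for these small 5 x W feature maps on CPU.  Analytic
gradients are verified against central differences in the test suite.
Initialization is He-scaled and deterministic per seed.

The loss is weighted cross-entropy on the type head plus weighted
cross-entropy on the length head plus smooth-L1 (transition 1.0) on the
position.  Per-record cross-entropy terms are scaled by the true class's
weight and averaged over the batch, so uniform weights reduce exactly to
the unweighted mean.  Class weights default to uniform; the non-somatic
weight is a knob for precision tuning on imbalanced data.

## Training

Labels: a candidate matching a somatic truth record on position + type
(and allele, for SNVs) takes that record's type and length class
(SNVs and 1-base INDELs are class 1, 2-base INDELs class 2, longer
class 3); everything else is non-somatic (0, 0).  Truth records with no
surviving candidate are logged — they cap recall but are not an error.

Each epoch uses all somatic records plus a fresh uniform draw of twice as
many non-somatic records (ratio configurable; drawn with replacement only
when the pool is smaller than the request), shuffled.  The optimizer is
SGD with momentum 0.9, learning rate 0.01 multiplied by 0.1 every 400
epochs.  The batch-size default is 1000; at desk scale we set it to 32 in
the reference experiment so that a ~600-record epoch still provides ~19
optimizer steps — with one batch per epoch the schedule would allow only
as many SGD steps as epochs, far too few to converge.

**Base-row relabeling augmentation** (on by default): each training
record is presented with its four base rows permuted by a random
relabeling of A/C/G/T, applied consistently across all channels, with the
gap row fixed.  The somatic/germline decision is invariant under base
relabeling, so every permutation is an equally valid sample; this
enlarges a small training set 24-fold.  Without it, a ~200-somatic-record
training set lets the 720K-parameter network key on incidental
base-identity patterns and generalization collapses (we observed held-out
type accuracy dropping from ~0.9 to ~0.65); large-corpus training escapes
this by volume, and spiking in extra synthetic mutations serves the same
purpose at larger scales.  Train/test splitting is always by genomic
interval (10 kb chunks assigned 50/50 at a recorded seed), never by
candidate, to prevent leakage.

## Calling

The type head wins disagreements: a candidate typed SNV gets length 1
regardless of the length head; an INDEL typed with length class 0 takes
the most probable non-zero class.  Allele resolution is CIGAR consensus
among reads overlapping the call: for length classes 1 and 2 the majority
event of exactly that length, for class >=3 the most frequent event
sequence (insertions) or span (deletions); ties break lexicographically.
A call with no supporting CIGAR event at call time is dropped.  Calls
whose predicted matrix column differs from the candidate column by more
than 2 are demoted to LowScore (the position head acts as a consistency
check).  PASS thresholds on p: 0.97 for `wgs` and `pacbio` (genome-wide
regimes), 0.6 for `wes` and `panel` (enrichment regimes; only the WGS and
WES values are externally prescribed — the other two presets reuse the
nearest regime's threshold).  The VCF QUAL column carries the Phred
value; the probability itself is kept in INFO/SCORE.

## Evaluation

Matching is one-to-one, greedy in descending score order, on
left-normalized representations.  SNVs always require position + alt.
INDELs match exactly (position, REF, ALT) or in position-only mode
(position + type), the relaxed criterion that isolates localization
accuracy from allele-resolution accuracy.  PR curves sweep thresholds
over the distinct scores (ties included; threshold is >=); the best F1
over the sweep is the headline number.  Size-stratified tables assign
false positives by the call's own resolved length; AF-stratified tables
report recall only, since a false-positive call has no truth AF.

## Synthetic data

The simulator emulates a single random contig ("chrS", uniform base
composition), planted germline variants (80% SNVs, 20% 1-5 bp INDELs,
het/hom at random) and somatic SNVs/INDELs with per-variant target AFs
drawn from a configurable list.  Reads are single-end, uniform-start,
constructed pre-aligned with CIGARs derived from the known variant
placement; a tumor-sample read comes from the tumor genome with
probability `tumor_purity` and carries each somatic allele with
probability equal to its target AF, so observed alt counts are
Binomial(depth, purity x target_af) — the same mechanism reproduces both
fixed-purity mixtures and binomial spike-ins.  The normal sample is
contaminated with tumor reads at rate 1 - normal_purity.  Sequencing
errors are uniform substitutions (default 0.002/base); the INDEL error
rate defaults to zero so truth AFs stay clean.  Somatic INDEL lengths are
drawn from {1..10} with 1, 2 and 3 forced so all length classes appear.
Variants keep >= 20 bp apart (default) so one candidate window never
contains two truth events, and are planted left-normalized.

Defaults are the reference experiment's conditions: 200 kb contig,
100 bp reads, 50x tumor and 50x normal, pure tumor and pure normal, 300
somatic SNVs + 100 INDELs at target AFs in {0.25, 0.5, 1.0}, 300
germline variants (~1.5/kb, roughly human-like heterozygosity scaled for
desk size).

What the simulator does **not** model — and hence what passing tests do
not certify about real data: quality ramps and GC/context-dependent error
profiles, INDEL sequencing errors, mapping ambiguity and soft-clipping
(reads are placed at their true origin with MAPQ 60), paired-end
structure (reads are unpaired, so the properly-paired and mate-unmapped
channels are constant on simulated data), repeats and low-complexity
regions beyond what a uniform-random contig contains, and copy-number or
structural variation.

## Reference experiment and numerical choices

The acceptance script and the heavyweight tests run one experiment:
simulate the default pair, scan + featurize (~1,200 candidates), split
the contig 50/50 by 10 kb chunks, train 100 epochs (~4 minutes on one
CPU core), evaluate on the held-out regions, then regenerate the tumor at
25% purity with identical truth and measure the recall drop.  Problem
sizes were chosen so the whole run completes in minutes on a laptop-class
CPU while leaving >= 50 held-out truth events per variant class.

Degenerate inputs: an empty candidate window yields an all-zero frequency
matrix (the network sees "no evidence"); zero-coverage columns stay zero;
a non-finite training loss aborts with a diagnostic rather than
continuing; empty call sets produce header-only VCFs; strata without
truth are reported as absent, not as zero.

## Known limitations

* The 26-channel identities realize the named feature families but the
  original tool's exact channel list is not public in the text we build
  from; the registry hash guards against silently mixing conventions.
* Allele resolution is pure CIGAR consensus; there is no local
  realignment, so high-error long-read support would need the wider-window
  consensus preset and still resolves alleles less accurately.
* The simulator's clean error model makes the classification task easier
  than real tumors; headline F1 values here are a correctness check of
  the pipeline, not a benchmark claim.
* Single-contig simulation only; multi-chromosome BAMs are supported at
  scan/call time but untested beyond that.
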