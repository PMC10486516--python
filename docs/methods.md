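# Methods

## Featurization model

A sample is a bag of reads over {A,C,G,T,N}. For k-mer length k, every
length-(k+1) window of a read that contains only A/C/G/T contributes one
unit of weight to the De Bruijn edge from its first k bases to its last
k bases (the two k-mers overlap by k−1 bases by construction). Windows
never span read boundaries — concatenating reads would fabricate junction
k-mers that exist in no molecule — and a window containing N is skipped
rather than discarding the whole read, which maximizes retained signal;
the number of skipped windows is counted and logged.

The graph is flattened over the complete node set: the feature vector has
one slot per (k-mer, next base) pair, laid out node-major with next-base
order A,C,G,T, so entry `4·id(kmer) + code(base)` counts how often `base`
follows `kmer`. K-mer ids are the base-4 positional encoding A=0, C=1,
G=2, T=3, i.e. lexicographic rank; this assignment is a convention of
this package, chosen because it is self-inverting, and it fixes column
names (`<kmer>_<nextbase>`) bit-exactly for interchange. The vector is
therefore identical to a (k+1)-mer count profile, and its sum equals
Σ_reads max(0, L−k) for N-free reads — a conservation law the tests
check against an independent brute-force substring counter.

Counting is forward-strand only. Reverse-complement canonicalization
would halve the feature space and collapse strand information; the
representation here is deliberately the full 4^k × 4 grid. Counts are
raw occurrences by default; per-sample total-sum normalization exists
behind a flag (off by default) for libraries of very different depth.
k is accepted in [2, 12] — 4^(k+1) columns grow fast, and 12 keeps the
dense matrix within ordinary memory.

## FASTQ handling

Only strict 4-line records are accepted (identifier `@…`, sequence, `+…`,
quality of equal length); wrapped FASTQ is rejected, and parse errors
name the offending record. Quality strings are validated for length but
never otherwise used: no quality trimming, primer removal or paired-end
merging is performed, because the featurization consumes raw base
composition only. Beyond A/C/G/T, only N is tolerated; rarer IUPAC codes
are rejected at parse time so that every retained character has a defined
place in the 4-letter alphabet. Samples with fewer than `min_reads` reads
(default 10, configurable) are excluded before featurization — public
amplicon cohorts occasionally contain near-empty files, and no universal
threshold exists, so the value is surfaced as a parameter. Diagnosis
labels binarize as CD/UC/IC (forms of IBD) → 1, control strings → 0.

## Synthetic cohorts

The generator emulates the statistical structure the featurization
assumes and nothing else. Reads are drawn from a class-conditional
order-m Markov chain: the first m bases uniform, each later base from the
transition row of the preceding m-mer. The healthy matrix's rows are
drawn from a Dirichlet(40·1) around the uniform point — mild background
structure without strong composition bias. The diseased matrix is the
healthy one with, in each of a small set of perturbed contexts (default
8), one designated base's probability raised by `delta` and the other
three renormalized; `delta = 0` yields byte-identical class
distributions, the null case. Defaults — m = 3, delta = 0.12, 500 reads
of 150 bp per sample — are desk-scale stand-ins for V4 amplicon
libraries chosen so that the signal is fully visible at k = 3 and
partially at k = 4, 5.

What the generator does *not* model: sequencing error, chimeras, length
variation, taxonomic abundance structure, batch effects. Passing tests
therefore show that the pipeline recovers planted transition-frequency
signal, not that real cohorts are this separable — at these defaults each
sample carries ~73,000 windows, so per-sample transition frequencies are
estimated far more precisely than real biological class differences
would allow, and benchmark accuracies on synthetic cohorts saturate near
1.0 where real-data accuracies sit much lower.

Seeding is hierarchical (`SeedSequence`: cohort → class → sample), so any
subset of samples is reproducible independently, and regeneration from
the same design is byte-identical, FASTQ files included (constant dummy
quality `I`).

## Benchmark protocol

Per k: featurize, split once, tune, evaluate. The split is 80/20,
stratified (protecting the minority class), seed 42 by default; the
single split is shared by all seven families so their test predictions
are paired. Grid search scores every grid point by mean accuracy over 5
stratified CV folds of the training rows only — the test rows are never
visible to selection — with ties broken by the first occurrence in grid
order and failing points recorded and excluded (an all-failed grid is an
error). Accuracy is the selection metric because it is the benchmark's
headline metric. Default grids are modest and fully overridable:
RF n_estimators {100,300,500} × max_depth {None,10,20};
SVM C {0.1,1,10} × kernel {rbf,linear};
XGB/LGBM learning_rate {0.05,0.1} × n_estimators {100,300} × max_depth
({3,6} / {−1,3,6}); LR C {0.1,1,10}; kNN k {3,5,11}; GNB has no grid.

Features enter the models as raw counts by default; a standardization
flag exists because SVM, LR and kNN are scale-sensitive, but it is off
by default to keep the feature semantics untouched. Scores for AUC are
class-1 probabilities where the model provides them and the signed SVM
decision value otherwise (no probability calibration). Precision and
F-score are binary with positive class = diseased. Cohen's κ comes from
the same confusion counts that are stored in every report, so all
threshold metrics are recomputable from the report itself. A single-class
test truth makes AUC undefined; it is reported as missing with a warning
rather than guessed. All estimators run single-threaded with fixed
seeds, making the full benchmark bit-for-bit reproducible from (cohort
seed, split seed, model seed).

## Pairwise model comparison

Two models sharing a test set are compared only through their discordant
predictions: N_sf (first right, second wrong) and N_fs (the reverse),
"right" meaning hard-label agreement with the truth. The statistic is
the continuity-corrected z = (|N_sf − N_fs| − 1)/√(N_sf + N_fs), defined
as 0 when there is no discordance at all. When the counts differ by at
most one the raw expression is negative; z is treated here as a
magnitude — direction travels separately as an arrow toward the model
with more discordant wins — so the raw value is clamped at 0 by default,
with `signed=True` exposing it. z maps to one-tailed confidence Φ(z)·100
and two-tailed (2Φ(z)−1)·100. No multiple-testing correction is applied
across the C(7,2) = 21 pairs; the rendered report says so in its header.
Exact-binomial and mid-p McNemar variants are out of scope.

## Problem sizes and numerical notes

The test suite and the acceptance script run their end-to-end checks on
200-sample cohorts (100 per class) at the default library size, with the
signal benchmark at k = 3 (and the acceptance script additionally at
k = 4, 5) — sizes chosen so a full run completes in minutes on one CPU
while the held-out set (n = 40) still gives the binomial chance bound
meaningful width. Chance calibration uses the exact binomial 99% quantile
at p = 0.5 rather than a normal approximation. Degenerate inputs are
defined, not special-cased: empty reads contribute no windows, an empty
edge list flattens to the zero vector, and constant features reduce
every model to majority voting.

## Known limitations

* The saturation of synthetic benchmarks (above) means model rankings on
  synthetic cohorts carry little information; the machinery, not the
  ranking, is the tested object.
* Dense 4^(k+1) feature matrices are wasteful at large k for shallow
  samples; a sparse representation would be needed beyond k ≈ 8 at
  cohort scale.
* The McNemar z uses the normal approximation; with very few discordant
  pairs (N_sf + N_fs < ~10) its confidence levels are approximate.
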