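# Methods

## Problem and representation

The task is binary coding-potential classification of plant transcripts:
ncRNA (positive class, label 1) versus mRNA (negative class, label 0),
from nucleotide sequence alone. Each transcript is mapped to a fixed
91-dimensional vector:

| block | count | definition |
|---|---|---|
| k-mer frequencies, k = 1–3 | 4 + 16 + 64 = 84 | count of each k-mer over sliding windows that contain only A/C/G/T, divided by the number of such valid windows; all-zero if no valid window |
| CDS features | 5 | `score`, `cds_start`, `cds_stop`, `cds_size`, `cds_percent` of the best predicted ORF |
| length | 1 | total nucleotide count |
| gc_content | 1 | (C+G)/(A+C+G+T); 0 for an all-N sequence |

Input normalization maps U→T (RNA and DNA FASTA are equivalent) and every
other non-ACGTN character to N with a logged warning; public transcript
sets carry IUPAC ambiguity codes and rejecting them would be hostile.
Excluding N-containing windows from both numerator and denominator of the
k-mer frequencies avoids deflating the frequencies of real k-mers; the
alternative (denominator L−k+1) penalizes every k-mer of an ambiguous
sequence uniformly. Feature-name order is frozen (k-mers lexicographic
with A<C<G<T, then CDS, length, GC) so tables and models are portable.

## ORF scoring

The internal CDS caller scans the forward strand only (inputs are
transcripts, not genomes), all three frames, for ATG-initiated reading
frames. A candidate ends at the first in-frame stop codon (stop included
in the CDS span) or, if none occurs, at the last complete in-frame codon —
truncated 3′ ends are common in transcript databases, so open-ended ORFs
are legitimate candidates. Candidate score:

    score = 1.0 · cds_size + 50 · [A or G at position −3 of the ATG]
                           + 50 · [in-frame stop present]

ORF length dominates by design; the Kozak-context and stop bonuses only
separate near-equal candidates. Ties break toward smaller `cds_start`,
then lower frame index, making the call fully deterministic. Coordinates
are 0-based half-open, which makes `cds_size = cds_stop − cds_start`
exact. A codon containing N never counts as a start or a stop.

This scorer is a deliberately simple protein-likeness proxy, not a port of
UCSC `txCdsPredict`; users who need that program's exact values import its
native output (`import_txcdspredict`), from which `cds_size` and
`cds_percent` are recomputed for consistency. Two coverage conventions
exist in circulation; the default is `cds_percent = cds_size/length`, with
`(cds_start + cds_stop)/length` available as `percent_mode="start_stop_sum"`.

## Feature selection

Variance thresholding compares variances across features, which is only
meaningful on a common scale — raw `length` (~10³) would otherwise drown
every frequency (~10⁻²). Features are therefore min-max scaled to [0, 1]
per feature before the sample variance (ddof = 1) is taken. The VT-F
cascade keeps features with scaled variance ≥ the mean scaled variance
(inclusive boundary, so a degenerate all-equal table keeps everything),
then ranks survivors by the one-way ANOVA F statistic and keeps the top
k = 10. F uses the explicit sum-of-squares decomposition; a feature
constant overall gets F = 0, a feature with zero within-class variance but
distinct class means gets F = ∞ and sorts first. All ranking ties break by
canonical feature order, for platform-independent output.

The learning-curve procedure re-evaluates ranking prefixes by stratified
5-fold CV accuracy of the default stacked classifier and chooses the
best prefix, ties toward fewer features. For predict-only workflows a
built-in default ten-feature subset is shipped (GC content, ORF score,
`cds_stop`, `cds_size`, T, C, GT, GC, ACG, TAT frequencies).

## Stacked ensemble

Six scikit-learn base learners — random forest (100 trees), extra trees
(100), gradient boosting (100), logistic regression, 5-NN, Gaussian naive
Bayes — are trained under stratified 5-fold splitting; their out-of-fold
positive-class probabilities form the training matrix of a
logistic-regression combiner. For serving, each base learner is refit on
the full training set. The out-of-fold construction guarantees the
combiner never trains on a base prediction whose model saw that row; the
fitted object retains the fold bookkeeping (`fold_of_row_`,
`fold_train_indices_`) so that property is directly testable rather than
assumed. One stacking layer suffices at these data sizes; additional
layers add variance without measurable benefit on the synthetic
benchmark. Features are min-max scaled with training extremes (needed by
LR/kNN, harmless for trees). A single integer seed determines fold
assignment and every stochastic learner, so identical inputs give
byte-identical predictions. Trained models persist as a directory of a
JSON manifest (format version, seed, subset, scaler state) plus joblib
learners; loading refuses a major-version mismatch.

## Evaluation

Eight metrics from the confusion matrix at threshold 0.5 (ties to ncRNA):
SE, SPC, ACC, F1, PPV, NPV, MCC, plus trapezoidal AUC (midrank tie
handling, equal to the probability a random positive outscores a random
negative with ties counted ½). Any metric with a zero denominator is
`None` — "undefined", never 0 — so small-fold edge cases surface instead
of biasing averages. Cross-validation reports both the fold-averaged and
the pooled out-of-fold value of each metric, because the two conventions
differ and published work rarely states which it used. The stability
experiment repeatedly draws balanced per-class subsamples without
replacement (fresh sub-seed per repetition), cross-validates, and reports
all repetition accuracies, their spread, and means of consecutive blocks
of five repetitions.

## Synthetic data

The generator emulates the class structure of curated plant transcript
benchmarks:

| parameter | default | rationale |
|---|---|---|
| coding length median | 1029 nt | median of curated plant mRNA training sets |
| noncoding length median | 321 nt | median of curated plant ncRNA training sets |
| length sigma (coding / noncoding) | 0.55 / 0.70 | lognormal shape giving the bulk of coding mass in 0–2000 nt and noncoding in 0–1000 nt, matching the right-skewed published distributions |
| orf_fraction_of_length | 0.7 | typical CDS coverage of mRNAs |
| GC target (coding / noncoding) | 0.44 / 0.38 | plant mRNAs run GC-richer than ncRNAs |
| codon_bias_strength | 1.0 | codon sampling weight ∝ exp(strength·z), z = ±0.5 by GC3; strength 0 is uniform sense-codon usage |

Coding-like transcripts carry one planted ORF (ATG + stop-free biased
codon run + stop) at a uniform offset in i.i.d. background; noncoding-like
transcripts are i.i.d. nucleotides with no stop-codon constraint. An
optional mixture adds a 10% short (< 200 nt) noncoding component mirroring
the long/small ncRNA split of curated sets; it is off by default because
the coding/noncoding contrast, not the ncRNA substructure, is the
classification target.

What the generator does **not** emulate: splice structure, UTR
composition, species-specific codon tables, sequencing error, the
covariance structure of real k-mer spectra, or class overlap from
mis-annotated transcripts. Synthetic benchmarks here are close to
separable, so passing tests demonstrate the machinery (feature contracts,
selection recovery, no-leakage stacking, metric arithmetic, determinism)
— not field accuracy on real plant data, which depends on curated corpora
outside this package's scope.

The minimal plantable ORF is ATG+stop (6 nt), so a "null-signal"
configuration retains a faint class signal; the null-control test uses
equal 800-nt length medians to dilute it below CV noise and asserts CV
accuracy within 0.05 of chance on a frozen draw.

## Problem sizes and numerical choices

The package's reference experiments run at desk scale: the separable
benchmark is 400 + 400 transcripts, cross-validation is stratified
5-fold, and the stability experiment is 20 repetitions of 200 per class
drawn from that pool — these sizes give stable estimates on the nearly
separable synthetic conditions while keeping the full suite quick to run.
Probabilities are compared to the 0.5 threshold with `>=` (ties to the
positive class); k-mer block sums are exact to 1e-12; ANOVA F values are
validated against an independent sum-of-squares oracle to 1e-10; AUC is
validated against the O(n²) pairwise oracle to 1e-10.

## Known limitations

- The internal ORF score shares only its discriminative role (length-
  dominated protein-likeness) with `txCdsPredict`; absolute score scales
  differ. Use the importer when score compatibility matters.
- The default learner menu is fixed; no hyperparameter search is
  performed. This is a reproducibility choice, not a performance claim.
- Min-max scaling before the variance threshold makes stage 1 sensitive
  to single extreme outliers (they compress everyone else's scaled
  variance); robust scaling was rejected to keep the stage faithful to
  the simple cascade it implements.
- Real-data accuracy claims require real corpora; nothing in the test
  suite substitutes for them.
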