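# Methods

This note records the modelling conventions, defaults, and numerical
choices behind `aoxpred`, and what the synthetic benchmarks do and do not
demonstrate.

## Sequence hygiene

Sequences are strings over the 20 standard amino acids. Validation rejects
(rather than repairs) any sequence containing another symbol — B, X, Z, U,
O, gaps, stops — naming the first offending character, and rejects
sequences shorter than the encoder minimum. Lowercase input is uppercased
on read, since FASTA dialects disagree about case but not about meaning;
validation then applies a single canonical alphabet. The pipeline's
default minimum length is `max(k) + 2` for the CKSAAP gaps in use (the
shortest sequence containing at least one k-spaced pair); with the default
gap 3 that is 6 residues.

Train/test splitting is stratified per class, with the test set receiving
`round(fraction × class size)` members (ties round toward the test set).
A plain random split would only approximate the per-class ratio; the
stratified form keeps an 80/20 split of, say, a 710:1552 corpus at exactly
568/142 and 1242/310.

## The 188D descriptor

Twenty amino-acid frequencies (alphabetical order) plus a 21-feature CTD
block for each of 8 physicochemical groupings, applied in a fixed order
(hydrophobicity, van der Waals volume, polarity, polarizability, charge,
surface tension, secondary structure, solvent accessibility). The grouping
tables are shipped as a TSV data file so the encoding is auditable and can
be overridden. "Secondary structure" here is a residue grouping by helix/
strand/coil propensity, not a structure prediction.

Conventions that needed fixing where the classical CTD literature varies:

* **Distribution** features use the positions of the 1st and the
  ⌈0.25·n⌉-th, ⌈0.50·n⌉-th, ⌈0.75·n⌉-th, and n-th occurrence of each
  group's residues (1-based, divided by L). An absent group contributes
  five zeros rather than NaN, keeping all vectors dense and in [0, 1].
* **Transition** counts of adjacent residue pairs straddling two groups
  are divided by **L** by default. The more common convention divides by
  L−1 (the number of adjacent pairs); a `transition_denominator` switch
  selects it. With the default, transition features are bounded by
  (L−1)/L < 1 rather than summing to a fixed value — the choice is a
  normalization constant and does not affect ranking or classification
  beyond a uniform rescaling of three columns per property.
* The three transition features are ordered (I,II), (I,III), (II,III);
  feature names carry the pair identity, so column meaning never depends
  on position.

Every feature is named (`aac.A`, `charge.content.g1`,
`polarity.dist.g2.p75`, `hydrophobicity.trans.g1g3`, ...), and the
feature-name contract is enforced at prediction time.

## CKSAAP

The k-spaced pair composition counts ordered pairs (AC ≠ CA; 400 = 20²
features per gap) of residues exactly k positions apart, normalized by the
number of such pairs, N−(k+1). The normalization makes each gap's block a
probability distribution whenever N ≥ k+2; shorter sequences are rejected
with the minimum named. The pipeline default is the single gap k = 3 —
3-spaced residue pairs are the configuration that discriminates
antioxidant proteins best in combination with 188D — but any gap list is
accepted and blocks are concatenated in ascending gap order.

## MRMD feature selection

Feature i's score is MR_i + MD_i:

* MR_i = |Pearson correlation of feature column i with the 0/1 class
  vector|. Zero-variance columns get MR = 0 (Pearson is undefined there).
* MD_i = mean distance between column i and every other column. Distance
  is Euclidean, cosine (1 − cosine similarity), Tanimoto
  (1 − x·y/(‖x‖² + ‖y‖² − x·y)), or the mean of the three (the default;
  the method is configurable since any of the four is defensible).

Columns are min-max scaled to [0, 1] before distance computation:
unscaled, the Euclidean term is dominated by whichever features happen to
have large magnitudes, and MR + MD would add quantities on incompatible
scales. A switch disables scaling for comparison. Zero vectors (constant
columns after scaling) are defined to have similarity 0 — distance 1 — to
any non-zero column, and distance 0 to each other, avoiding division by
zero while keeping "identical columns are at distance zero" true.

Ranking is by descending score with ties broken by larger MR, then input
column order, so it is deterministic. Prefix subsets of the ranking (sizes
step, 2·step, ..., always including the full set) are evaluated by pooled
out-of-fold accuracy of the pipeline's random forest under stratified
k-fold CV; the smallest prefix attaining the maximum accuracy wins. The
default step is 1 below 100 features and 5 at or above (adding one feature
at a time is quadratic-cost at 588 features; the step is exposed, so
exhaustive stepping remains selectable).

Inside `run_pipeline`, the selection CV uses a fold seed derived from the
pipeline seed (seed+1) while the reported metrics use the pipeline seed
itself. Selecting a subset and then measuring it on the same folds
overstates performance — on null data the bias is visible as a positive
MCC — so the folds that choose the subset are decoupled from the folds
that grade it. Some optimism necessarily remains (selection sees all
training rows); held-out evaluation via `aoxpred evaluate` is free of it.

## Undersampling

Random undersampling (RUS) discards a uniform random subset of the
majority class, without replacement, down to
`round(target_ratio × minority count)` (default ratio 1.0). The minority
class is never touched and nothing is synthesized, so the output is always
a subset of the input and is reproducible under the seed. Instance-
selection alternatives (condensed/edited nearest-neighbour families) are
deliberately out of scope; the row-selection interface accepts plugging
them in. The default stage order applies undersampling before feature
selection — selection then sees balanced classes — with a flag to swap the
order for ablation.

## Classifier and evaluation

A scikit-learn random forest (default 100 trees; forest size is not
critical for this task and is exposed in the config) under a fixed seed.
Scores are the fraction of trees voting positive; a score exactly at the
threshold (default 0.5) classifies positive, which favours sensitivity.

SN/SP/ACC/MCC are computed exactly from the confusion counts; any metric
whose denominator is zero is reported as 0 and flagged in the report
rather than NaN. AUC is the area under the ROC curve over all score
thresholds (equivalently the tie-corrected Mann-Whitney statistic, which
the tests verify by brute-force pair counting). Cross-validation metrics
come from one confusion matrix over the pooled out-of-fold predictions;
per-fold averaging of MCC and AUC is biased at small fold sizes, though a
per-fold report is available. Models are serialized with a format-version
tag and the full provenance (encoder spec, selected features, sampling
config, seeds); loading refuses mismatched versions, and prediction
refuses matrices whose feature names do not match the training contract.

## Synthetic data

The generator emulates the *statistical shape* of a curated
antioxidant-protein corpus, not its biology:

* negatives are i.i.d. uniform over the 20 residues (a natural-frequency
  background is available; uniform keeps the math exact);
* positives draw each residue from the mixture
  (1−δ)·background + δ·uniform(group), with the hydrophobicity group III
  (CVLIMFW) as the default planted group. The expected group-content
  excess of positives over negatives is δ·(1 − 7/20), which the tests
  check empirically;
* optionally a designated 3-spaced pair (default W···W) is planted in
  positives at a Poisson per-sequence rate, giving the CKSAAP block a
  signal that MRMD should rank highly;
* the default class sizes are 710:1552 (≈1:2.19), the imbalance of a
  realistic curated corpus, so the undersampler is exercised at scale;
  default lengths are uniform in [50, 200].

Because the signal is purely compositional and i.i.d., passing benchmarks
demonstrate that the pipeline detects what the encoders can represent and
reports chance on null data (δ = 0); they say nothing about homology,
domain structure, or real antioxidant performance, which require real
sequence data supplied by the user.

## Benchmark problem sizes

The parameter-recovery benchmark runs the default pipeline on 300+300
planted sequences (δ = 0.15, lengths 50–200, seed 42) with a selection
step of 50, and at 710:1552 with step 100 in the acceptance script —
coarse prefix grids chosen so the 588-feature search stays a
minutes-scale computation; the step is a grid resolution, not a model
parameter, and finer grids change the chosen size but have not changed
the verdicts. Under those conditions the pipeline's pooled 5-fold CV
detects the planted effect well above chance while the δ = 0 control
stays at chance.

## Known limitations

* MRMD's distance term is unsupervised; with many correlated noise
  features the MD component can outweigh MR, so the prefix search — not
  the raw ranking — is what guards accuracy.
* Pooled CV metrics use a single forest seed per fold; fold-to-fold
  variance is visible only through `--per-fold`.
* The undersampler discards data; at extreme imbalance the 1:1 default
  may waste most of the majority class. The ratio is configurable.
* No redundancy culling (sequence-identity filtering) is performed;
  corpora are assumed pre-culled upstream.
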