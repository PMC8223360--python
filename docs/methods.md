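# Methods

## Problem and model

An mRNA can reside in several subcellular compartments at once, so
localization prediction is a multi-label problem. `mlocmrna` decomposes it by
binary relevance: nine independent one-vs-rest classifiers, one per
localization class (cytoplasm, cytosol, endoplasmic reticulum, exosome,
mitochondrion, nucleus, pseudopodium, posterior, ribosome). Each classifier
sees the same k-mer representation of the sequence and makes its call
independently; the union of positive calls is the predicted location set,
which may be empty.

### Sequence representation

Sequences are normalized to the DNA alphabet (uppercase, U→T; N tolerated)
and featurized as k-mer vectors for k = 1..6. The vocabulary is every string
over {A,C,G,T} of each length, grouped by ascending k and lexicographic
within k (5460 features for k = 1..6). Windows containing N are skipped. The
default mode divides each k-block by its number of valid windows
(*frequency*), which makes sequences of very different lengths comparable —
localization corpora have strongly location-dependent length distributions —
and a raw *count* mode is retained, since either convention is defensible
for this representation. Strand is preserved: mRNA is single-stranded, so
reverse complements are distinct features.

### Feature selection

For each localization, a penalized binomial (logistic) model is fit with the
elastic-net penalty

    (1/n) Dev(beta) + lambda * [ (1 - alpha) ||beta||^2 + alpha ||beta||_1 ],

with an unpenalized intercept and columns standardized internally for
fitting (coefficients are reported on the original scale). Features with
non-zero coefficients are selected; the de-duplicated union across the nine
localizations forms the classification vocabulary, and a multiplicity table
records how many localizations selected each k-mer.

Tuning protocol: alpha over the grid 0.1, 0.2, ..., 1.0 and lambda over a
100-point descending log grid from lambda_max (the smallest lambda zeroing
every coefficient, computed from the deviance gradient at beta = 0) down to
1e-4 x lambda_max. Both are chosen by repeated stratified 5-fold
cross-validated aucROC — aucROC rather than raw accuracy, because the tuning
sample is balanced by construction and aucROC is threshold-free — on a
class-balanced random subsample containing floor(0.5 x min(n_pos, n_neg))
instances per class. Ties break toward smaller alpha and larger lambda (the
more parsimonious model). Repeat count defaults to 3.

The final selection model is fit at the tuned (alpha, lambda) on the full
*class-balanced* training set: all minority-class instances plus an
equal-count seeded draw from the majority class. The lambda scale is tied to
the class balance of the data it was tuned on — under the strong one-vs-rest
imbalance here (one class against eight pooled classes), the deviance
gradient shrinks and a balanced-tuned lambda can exceed the imbalanced set's
lambda_max, zeroing every coefficient. Fitting the final model on balanced
data keeps the tuned lambda meaningful while using all minority-class
information.

Solver: the fits are solved by saga coordinate updates behind a thin
parametrisation layer (C = 1/(n·lambda·(2−alpha)), l1_ratio =
alpha/(2−alpha) maps the objective above exactly onto the solver's form);
lambda paths are warm-started from larger to smaller lambda. At lambda = 0
the fit falls back to an unpenalized logistic regression; for a fully shrunk
model the intercept is set to its closed form logit(ybar). The test suite
checks the fits against an independent proximal-gradient minimizer of the
same objective and against an unpenalized GLM.

### Classification

Each localization's training data are its positives against the pooled
other eight classes — heavily imbalanced. To counter this, five random
forests are trained per localization, each on all positives plus an
equal-size negative subsample drawn without replacement under a distinct
derived seed. Defaults: ntree = 500 trees per forest, mtry =
floor(sqrt(p)) features per split, bootstrap sampling per tree. Out-of-bag
accuracy is logged but not used for tuning.

Prediction: each member votes positive when its own probability ≥ 0.5; the
final call is the majority (≥ 3 of 5), and the reported probability is the
mean member probability. The two can disagree near 0.5; the vote is
authoritative. The 0.5 probability/vote threshold is the shipped default.

### Dataset preparation

* Identical sequence strings under different ids are collapsed (labels
  unioned) before anything else.
* Records with more than one localization label are removed from the
  training corpus (multi-location prediction is handled at inference by the
  nine independent classifiers, not by multi-label training records).
* Redundancy reduction per localization: greedy, length-sorted clustering.
  A record is removed when its global-alignment identity (match = 1,
  mismatch = 0, mild gap penalties; identity = matched positions / shorter
  length) to any retained representative reaches the 0.8 threshold, with a
  length-ratio pre-filter. This is a documented greedy approximation of the
  usual external clustering tools, kept in-package so the pipeline has no
  binary dependency. The removed records are preserved as a
  similarity-sharing secondary test set.
* Each localization's non-redundant records are shuffled and split into 6
  near-equal subsets; one randomly drawn subset is held out as the
  independent test set.

### Evaluation

Point metrics are computed from majority-voted labels: sensitivity,
specificity, accuracy, MCC and F1. MCC is implemented in the standard
confusion-matrix form; an algebraically identical per-class-rate
rearrangement is kept (`mcc_ratio_form`) and verified equal by exhaustive
enumeration over small tables. Metrics with empty denominators are reported
as missing, never coerced to 0. Cross-validated reports give mean ± standard
deviation across the (stratified) folds on the percent scale; aucROC and
aucPR are computed per ensemble member on the held-out fold and averaged
over members. The PR area uses the plain trapezoid over the
(recall, precision) points — no precision-envelope interpolation — and the
ROC area is the standard trapezoid, which the tests verify equals the
pair-counting concordance estimator. A per-k ablation harness re-runs the CV
with each single k-block (4, 16, 64, 256, 1024, 4096 features) as the
feature set.

## Synthetic corpus generator

The generator produces labelled corpora with known ground truth so every
pipeline stage is testable without any external download. Per location it
draws record counts (default 80), log-normal sequence lengths (location-
specific mu/sigma, widest spread for the nucleus and narrowest for the
mitochondrion, echoing the length-variability structure of real corpora),
and plants 1–3 disjoint 4-mer motifs — stand-ins for cis-acting localization
elements — by insertion into i.i.d. background at a configurable enrichment
(default 3 insertions per 100 nt; 0 gives a null corpus). Insertion rather
than substitution keeps background k-mer statistics unbiased away from the
planted sites; the sequence is trimmed back to its target length, positions
inside previously planted motifs are never chosen, and every assigned
location is guaranteed at least one surviving motif so labels and signal
agree. A fraction of records (default 0.1) carries a second location's label
and motifs (overlapping membership); an optional fraction is emitted as
near-duplicates at a configurable per-position substitution rate, for
redundancy-reduction testing.

What the generator does *not* emulate: codon structure, UTR organisation,
real zipcode motif models, GC heterogeneity, or inter-location sequence
homology. Passing tests on it demonstrate that the pipeline recovers planted
signal and is calibrated at the null, not that any particular accuracy will
be achieved on biological corpora.

## Numerical and design choices

* One master seed derives every stage seed by hashing seed + stage path, so
  stages are independently reproducible and a fixed seed gives byte-identical
  outputs.
* Solver tolerances: 1e-7 for single reference fits, 1e-4 for path fits
  inside cross-validated tuning (scores, not coefficients, are consumed
  there).
* Zero-variance feature columns are left unstandardized and get zero
  coefficients.
* A sequence shorter than k produces a zero k-block with a warning; a
  sequence of all Ns produces an all-zero vector and its prediction row is
  still emitted.
* Degenerate CV folds (a single class) raise rather than silently skewing
  scores.
* Acceptance-scale problem sizes: the recovery and ensemble checks run at
  9 locations x 80 records, k = 1..4 vocabulary (340 features), alpha fixed
  at 0.5 with a 15-point lambda grid, ntree = 100 — chosen as the package's
  verification scale; library defaults remain the full protocol.

## Known limitations

* The greedy identity clustering approximates, but does not replicate,
  word-filter-based tools; at 80% identity the retained sets can differ.
* Selection quality depends on the balanced-subsample tuning; with very few
  positives (< 20 per class) the lambda search is noisy and the selector
  refuses to run below 10 per class.
* Accuracy figures from the synthetic corpus do not transfer to biological
  data; on real corpora the feature selection and ensembles must be re-tuned
  and re-trained.
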