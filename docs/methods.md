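# Methods

## Data model

A lineage is an ordered path over the seven canonical ranks
(kingdom…species) in the Greengenes prefix dialect. Lineages may be
truncated; an empty label (`s__`) terminates the path, and a non-empty
label after an empty one is rejected so that depth is well defined.
Classes are species-*level* lineages: a reference record whose lineage
stops at genus forms its own class and participates in assignment at its
deepest labeled rank, as real reference databases contain many such
records. `Unassigned` serializes as that literal with confidence 0, so
assignment files round-trip unambiguously.

Reads shorter than a requested trim length are dropped, not padded: the
sentence encoder's geometry contract (L − k + 1 tokens) requires fixed
length, and padding would fabricate sequence.

## Class weights

Weights are a normalized probability distribution over the classes of the
reference database they are bound to. `weights_from_compositions` pools
counts by summation across samples (weighting environments by observation
volume rather than averaging per-sample proportions), gives reference
species never observed in any sample a floor prior (default 1e-6 — a zero
prior would make a class unreachable under Bayes' rule), and renormalizes.
Species observed in samples but missing from the reference are reported
and dropped.

## Feature extraction

Bags and sentences both use overlapping k-mers with k = 7 by default (the
word length at which short-amplicon classifiers in this family operate).
Windows containing any character outside A/C/G/T are *skipped* in bags and
replaced by a reserved out-of-vocabulary token in sentences; IUPAC
ambiguity codes are never expanded, since expansion distorts counts.
Sentence geometry is always L − k + 1 (144 tokens for 150 nt), regardless
of ambiguity.

## Rank-confidence assignment

Given a read's class-probability vector, the species-rank maximum is
tested against the confidence threshold with a strict `>`. On failure,
probabilities are summed over classes sharing each genus prefix and the
test repeats one rank up, toward kingdom; if no rank clears the threshold
the read is Unassigned. Ties among exactly-equal maxima (the common case
under uniform weights on shared sequences) are broken uniformly at random;
the tie-break generator is seeded per read as (seed, read index) so one
read's assignment never depends on how many reads preceded it. Because the
rank-wise maximum aggregate is non-decreasing toward the root, assignment
depth is non-increasing in the threshold — the property behind the
precision/recall trade-off all the classifiers share. The default
threshold is 0.7 everywhere.

## Classifiers

**Naive Bayes.** Multinomial NB over pooled per-class bag counts.
Smoothing α defaults to 0.001 (the small pseudo-count conventional in this
tool family); the vocabulary is fixed at fit time and query k-mers unseen
in training route to one shared OOV column, which receives the α-smoothed
floor probability — this keeps posteriors finite without letting absent
features dominate. Scores are computed in log space with max-subtraction
(4^7-dimensional products underflow in linear space). An empty query bag
returns the prior, by construction.

**Random forest.** Induction is delegated to scikit-learn's
`RandomForestClassifier`; the module fixes the hyperparameter semantics of
the benchmark grid (`n_estimators` ∈ {100, 1000}, `max_depth` ∈ {16, 64,
None} with None growing to pure leaves, `max_features` ∈ {sqrt, None})
and the probability contract (mean of per-tree leaf distributions,
renormalized). Trees have no prior slot, so class weights enter as
per-instance sample weights w(c)/n_c, which reproduces the prior's effect
on the training loss.

**CBOW embedding.** A single-threaded numpy implementation of word2vec
CBOW with negative sampling (5 negatives, unigram^0.75 noise, linearly
decaying learning rate from 0.025). Defaults are 300-dimensional vectors
and a symmetric window of 5 tokens. The embedding is trained on reference
sentences only, never on queries, to avoid test leakage. Determinism under
a fixed seed is part of the contract.

**Convolutional network.** Architecture I consumes the embedded sentence
(144 × dim); Architecture II consumes per-nucleotide one-hot input
(150 × 4). Both use one 1-D convolution (ReLU), global max pooling — which
makes the pre-softmax features invariant to where along the read a motif
occurs — and a dense softmax over classes, trained with class-weighted
cross-entropy (instance weights ∝ w(c)/n_c, normalized to mean 1) by Adam.
Architecture II is interpreted as "the same stack with one-hot input";
its full original layer stack is not public. Two numerical choices
matter at the short training budgets used here (5–10 epochs): inputs are
normalized to unit RMS at fit time, so the embedding's vector magnitudes
do not set the gradient scale, and the default Adam learning rate is 1e-2
rather than the textbook 1e-3 — with tens of optimizer steps the smaller
rate demonstrably cannot move the weights far enough to fit even a
linearly separable toy. Both are recorded in the model archive.

**Perfect classifier.** Identical (case-folded, optionally trimmed)
reference sequences are pooled; each pooled sequence carries the class
weights of its matching taxa renormalized per sequence (equal weights in
uniform mode). A query is an exact string lookup feeding the shared
rank-confidence procedure. Queries absent from the index are a hard error,
not Unassigned: the construct is in-sample by definition, and a silent
fallback would corrupt the upper bound it measures.

## Evaluation and cross-validation

Metrics are micro-averaged over reads, optionally weighted by community
abundance (the default in cross-validation), matching evaluation of
composition-driven communities; an unweighted mode is available. At rank
r: TP = assigned at depth ≥ r with the correct r-prefix; a wrong deep call
counts in both FP and FN; a truncated call counts only in FN. Precision
with zero assigned reads is reported as 0 with an explicit flag rather
than NaN. Multiclass MCC uses the covariance form over the full
species-level confusion matrix, which includes an unassigned/truncated
predicted category; degenerate matrices report 0 with a warning.

Cross-validation partitions *unique* sequences into folds, stratifying by
species: each species' sequences are spread round-robin (random offset)
across folds, so any species with ≥ 2 sequences remains in every training
complement. Held-out sequences are the test reads, each weighted by its
species' community weight; truth for a read whose species is absent from
training is truncated to its deepest ancestor present in training (novel
species are otherwise unscorable). The perfect classifier is trained
in-sample on the full reference — its defining contract — but scored on
the same frozen folds.

Classifier comparisons use two-tailed Wilcoxon tests (signed-rank for
paired scores, rank-sum for independent sample sets) at α = 0.05 with
family-wise Hommel adjustment over the comparisons submitted together.
All-zero paired differences are reported as p = 1 with a flag.

## Synthetic data

The generator emulates: a 7-rank taxonomy with configurable branching
(default 48 species); reference sequences (default 250 nt, three per
species) derived from a common random root by rank-specific substitution
divergence (15% at phylum down to 1.5% at species and 0.5% between
strains, echoing the decreasing divergence of rRNA phylogenies); optional
byte-identical sequence sharing between sister species with probability
`p_share` (exercising the perfect classifier's only failure mode);
per-sample compositions drawn from a Dirichlet (default concentration 0.1,
giving the skewed communities typical of real samples) with multinomial
counts; and reads taken as fixed-length prefixes (default 150 nt) with
i.i.d. substitution errors (default 0.5%).

What it does *not* emulate — and hence what passing tests do not show
about real data: indels and alignment ambiguity (evolution is
substitution-only so the fixed-geometry encoders are exercised without
alignment logic), chimeras, PCR/primer bias, length variation,
quality-score structure, and the scale and taxonomic imbalance of real
reference databases. Absolute scores on these fixtures are therefore not
comparable to published benchmark figures; the properties checked are
structural (exactness of the ceiling, direction of the weighting benefit,
monotonicity in confidence, ordering of classifiers against the ceiling).

## Problem sizes and determinism

The bundled benchmarks run at desk scale by choice: references of 24–48
species with 1–3 sequences each, communities of 10–20 samples with
100–500 reads, forests of 30–100 trees, CNNs with ≤ 16 filters and
embedding dimension ≤ 32 in tests (the 300-dimension default is exercised
where geometry, not accuracy, is under test). Every stochastic component
(simulation, fold assignment, tie-breaks, forest and network training)
takes an explicit seed; stochastic assertions average over ≥ 3 seeds. CLI
outputs embed the resolved configuration and are byte-identical across
runs at fixed seeds; model archives fix zip timestamps for the same
reason.
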