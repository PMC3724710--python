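# Methods

## Model and procedure

MD-SFS is a grouped wrapper feature-selection procedure. The objects being
selected are physicochemical attributes of amino acids; each attribute A_j
contributes an indivisible block of d descriptor features, so the search
adds or removes blocks, never single columns.

**Descriptor.** A sequence encoded under attribute A_j becomes a real
series s₁…s_N whose lag-i autocovariance is

R_i = (1/N) Σ_{k=1}^{N−i} (s_k − μ)(s_{k+i} − μ),  i = 1…d,

with μ the series mean. Three deliberate numerical readings of this
formula:

* the divisor is N for every lag (a biased estimator), and there is **no**
  variance normalization — the statistic is a covariance, not a
  correlation;
* for i ≥ N the sum is empty and R_i = 0, so short sequences still yield a
  full d-vector (d defaults to 20);
* a constant series returns exact zeros (the deviations vanish
  identically; the implementation short-circuits so no floating-point
  residue survives).

Consequences worth knowing: R is invariant to shifting an attribute's
values by a constant and scales quadratically when they are multiplied by
c. The descriptor is therefore blind to composition-only class differences
beyond variance; only *ordering* structure along the sequence registers.

**Subset evaluator.** H(S) is the unweighted mean of per-fold accuracies of
a classifier under k-fold cross-validation (k = 10 default, stratified,
seeded). One fold partition is built per selection run and reused for every
subset, which removes fold-sampling noise from subset comparisons — the
α_l comparisons across levels are only meaningful on common folds. Repeated
evaluation of a subset is served from a cache keyed by the frozen subset,
so the reported evaluation count is the number of *distinct* H
computations. Per-attribute descriptor blocks are computed once per run and
concatenated per subset.

**Classifiers.** Three wrapper classifiers are provided:

* *LDA + nearest centroid* (authored here): solve S_b w = λ S_w w, keep the
  leading min(C−1, D) directions, assign a test point to the nearest
  projected class centroid (Euclidean). The within-class scatter gets a
  ridge of 1e−6 · trace(S_w)/D on the diagonal so the generalized
  eigenproblem is well-posed even when features outnumber samples; the unit
  suite checks predictions against an independently coded
  scatter/eigen/centroid chain.
* *linear SVM* (C = 1, one-vs-one) and *Gaussian naive Bayes*, both from
  scikit-learn with otherwise default settings.

Optional per-column z-scoring (fit on training folds only) exists but is
off by default.

**Search.** Backward elimination starts from the full universe (its level-0
accuracy is recorded, so the MA criterion can legitimately select "all
attributes"); each level drops one attribute from a surviving subset.
Forward selection starts from all singletons and grows the kept subset by
one. With no ties, forward performs T_a(T_a+1)/2 evaluations and backward
T_a(T_a+1)/2 − 1 beyond level 0.

**Ties.** All tied-best candidates progress (a beam). Equality is exact
float equality of cached accuracies, which is the right notion here because
identical subsets produce bit-identical scores on the fixed partition. The
final ranking is read off the lexicographically-first (by position in the
universe) maximal-accuracy path. Two consequences the tests pin down: under
a fully tied evaluator, forward returns the universe order while backward
returns its reverse (it *eliminates* lowest-index first); and beams may
raise the evaluation count above the tie-free formulas, with the cache
preventing any re-scoring.

**Selection criteria.** brute-n takes the top n of the ranking. MA takes
the on-path subset at the level maximizing α_l; when several levels tie,
the level with the *fewest attributes* wins (equal accuracy, cheaper
model) — largest l for backward, smallest l for forward.

## Statistics

* `paired_ttest_onesided` is the upper-tail paired t-test on percent
  accuracies: t = mean(d)/(sd(d)/√n), p = P(T_{n−1} ≥ t). It is one-sided
  by design: the question asked of it is directional ("does selection beat
  the fixed HPZXV benchmark?"), and with the three datasets as pairs
  (df = 2) the bundled published accuracy cells reproduce p = 0.029 / 0.003
  / 0.004 for LDA / SVM / NB; a two-sided reading would give ≈ 0.058 for
  LDA. The df = 2 closed form p = 1/2 − t/(2√2·√(1 + t²/2)) serves as the
  test oracle. Zero-variance differences raise a degenerate-input error
  rather than returning ±∞.
* `random_subset_baseline` draws m of n attributes uniformly without
  replacement within a draw, independently across r draws (m = 5, n = 30,
  r = 20 in the published analysis), and averages the evaluator's scores.
* `count_attribute_occurrences` counts, case-sensitively, the subsets
  containing a symbol. Over the 18 bundled brute-5 selections from all 30
  attributes the top five are J = 12, B = 9, T = 9, F = 8, M = 6. Only the
  selections made from the *full* attribute universe enter this corpus; the
  partial-universe (top-10 / top-15) selections are a different population
  and are not mixed in.

## Attribute table

The bundled table has 30 attributes × 20 residues. Attribute symbols are
case-sensitive; residue letters are not. The printed source table assigns
the letter F to both the β-sheet-frequency attribute (No. 10) and the
first-residue-in-turn attribute (No. 15), while its result listings use a
lowercase 'f' for the latter (e.g. "BPRfX"); the package gives No. 15 the
symbol 'f' so every published subset string parses unambiguously.
Unrecognized residue characters (B, J, O, U, X, Z, gaps) are skipped with a
logged warning, not imputed — the attributes are defined only for the 20
standard residues, and any imputation rule would be an invention.

## Synthetic benchmark

The generator emulates the one thing the descriptor can see: class-specific
periodic structure. For each planted attribute the 20 residues are split at
the attribute's median value into a high half and a low half (ties broken
by residue order). Class c emits residues from a blend of a uniform
baseline (weight 1 − effect_size) and the current half's uniform
distribution (weight effect_size), dwelling c + 2 positions per half before
alternating. Classes therefore differ in the lag at which the planted
attribute's autocovariance peaks. Defaults: 2 classes, 100 sequences per
class, lengths uniform in 80–120 residues, planted = {'H'}, effect 0.9.
The blended pattern is memoryless by construction, so Markov orders 0 and 1
draw from identical per-position distributions; order 1 merely routes the
draw through an explicit (row-constant) transition matrix.

What it does **not** emulate: real fold-class composition biases, secondary
structure, homology, length distributions, or nonstandard residues. Passing
recovery tests shows the search machinery finds autocorrelation signal it
was built to find; it says nothing about recognition rates on real fold
datasets.

**Leakage.** Attribute value vectors are naturally correlated, so a planted
signal bleeds into other attributes. The right leakage measure is the
*phase-mean contrast* (`phase_mean_contrast`): the difference of an
attribute's mean value over the planted attribute's two halves, in units of
its value spread. Attributes with contrast near zero (e.g. the α-helix
frequency 'X' relative to planted 'H') stay near chance; high-contrast ones
inherit most of the signal. Tests select the "decorrelated" control
attribute by minimizing this measure rather than by name, and recovery
thresholds tolerate the leakage that remains.

**Recovery universe.** Planted-recovery runs search a six-attribute
universe: the planted symbol padded with the table's leading attributes
(for planted 'H': H P Z X V S — the five classic benchmark attributes plus
the α-NH chemical-shift scale). Chosen once as the natural default
neighborhood; at effect 0.9 both schemes with the MA criterion recover the
planted attribute in essentially every seeded run.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated data.
Sizes used: descriptor oracle, 1000 random series of length ≤ 12;
evaluation-count checks, universes of 2–8 attributes; recovery, 20 seeded
runs per scheme at the default generator settings (~40 s per scheme on one
CPU); chance-level checks pool 600 sequences over three seeds; the
zero-effect uniform-choice check scales the dataset down to 20 sequences
per class, lengths 30–45, 5 folds, 200 repetitions — chance behavior does
not depend on dataset size, and at very small test folds exact accuracy
ties would otherwise let the lexicographic tie-break bias the draw. Every
random choice flows from an explicit integer seed: the generator seed fixes
the sequences byte-for-byte, and the fold-partition seed fixes every H
value, so identical (inputs, config, seed) reproduce identical outputs,
including on-disk files.

## Known limitations

* Greedy search with beams is exact only for modular evaluators; for real
  evaluators it inherits the usual greedy suboptimality (the MA subset
  dominates the greedy path, not the 2^T_a lattice).
* The LDA scatter solve is O(D³) in the feature count; at d = 20 and 30
  attributes (D = 600) this is comfortable, but very large custom tables
  would call for a different solver.
* One-vs-one linear SVM and Gaussian NB stand in for the originally cited
  classifier implementations; they are functionally equivalent, not
  bit-identical.
* Sequences shorter than the lag count silently produce zero-padded
  descriptors — intended, but worth remembering when feeding fragments.
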