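# Methods

## Peptide representation

Sequences are validated against the 20 standard one-letter amino-acid codes;
ambiguity and rare codes (B, J, O, U, X, Z) are rejected by default because
every downstream feature is defined on the 20×20 ordered-pair space and a
silent 21st symbol would corrupt the 400-dimensional indexing. Lowercase
input is uppercased rather than rejected (a common FASTA dialect variation);
residue positions are 1-based in every error message.

Three feature blocks are implemented, all non-negative and named:

* **AAC** (20 dims): normalized residue frequencies. Included for
  completeness; not part of the default hybrid set.
* **400D** (400 dims): occurrence counts of each ordered consecutive pair,
  in the fixed lexicographic pair order. Raw counts are the default; the
  frequency mode divides by L−1. Counts were chosen as the default because
  they keep the 400D block distinct from the g = 0 composition, which is
  otherwise identical to frequency-mode 400D — the two descriptions of this
  block in the literature (counts vs frequencies) conflict, and keeping both
  readings available costs one flag.
* **g-gap composition** (400 dims per g): `d_u^g = n_u^g/(L−g−1)` for
  g = 0…4. The upper bound g = 4 reflects the short lengths of the peptides
  of interest; it is configurable. A peptide with L < g+2 has no g-gap pair
  and the denominator would be non-positive, so such peptides are an error
  (or are logged and skipped in skip-invalid mode), never silent zeros.

The default hybrid set is 400D counts plus all five g-gap blocks
(2400 dims). Which blocks enter an analysis is configuration, not a fixed
choice, because different feature sets are exactly what the comparison
machinery (`compare_configurations`) is for.

Exact laws maintained by construction and enforced by tests: each g-gap
block sums to 1 within 1e-12; 400D counts sum to L−1; the g = 0 block equals
frequency-mode 400D elementwise.

## MRMD feature selection

Each feature column is scored `MR_i + MD_i`.

* `MR_i` is the absolute Pearson correlation between the column and the
  class labels encoded ±1. Relevance-to-label (rather than
  feature-to-feature correlation) is used because it is what makes a
  *ranking* of individual features meaningful; a constant column has
  undefined correlation and is scored 0 with a warning.
* `MD_i` is the unweighted mean of three pairwise statistics of column i
  against every other column: mean Euclidean distance, mean cosine value,
  and mean Tanimoto coefficient. By default the cosine and Tanimoto terms
  enter as the similarity values themselves ("printed" orientation). A
  blend of one distance and two similarities is an odd distance measure, so
  an "inverted" orientation using 1−cos and 1−TC is provided as an explicit
  switch; it is not the default because fidelity to the established scoring
  takes precedence. Pairs involving a zero-norm column contribute 0 (with a
  warning) since cosine/Tanimoto are undefined there.
* Columns are used raw by default; a min-max scaling switch exists because
  the Euclidean term is scale-dependent and column scales differ between
  count-mode and composition-mode blocks.

The ranking is the static descending sort of the combined scores with
deterministic tie-breaking (higher MR first, then input column order), so
identical inputs yield byte-identical rankings. Pruning keeps the top k
columns in their original order. No canonical k exists; when not given, k
can be chosen by maximizing pooled CV accuracy over a geometric grid
(`choose_k_by_cv`), with ties going to the smaller k.

## Classification and evaluation

The SVM family is an RBF-kernel SVC behind a min-max scaler ([0, 1], fitted
on training data only), with C ∈ {1, 10, 100} × gamma ∈ {scale, 0.01, 0.1}
searched by inner stratified 3-fold CV. Explicit scalar hyperparameters
bypass the grid (needed e.g. for tiny separable examples where an inner CV
is infeasible). The random-forest family uses 300 trees on raw features
(tree ensembles are scale-equivariant). A plugin slot accepts any
`factory(seed) → estimator` with fit/predict, so selective-ensemble or
boosting classifiers can occupy the third position without being
re-implemented here. Decision thresholds are the library defaults; no
calibration. Every stochastic component takes an explicit recorded seed.

Evaluation is stratified k-fold cross-validation (default k = 10). All
data-dependent fitting — scaling, MRMD ranking and pruning, hyperparameter
search — happens inside each training fold and is applied frozen to the
held-out fold. A `global` selection mode that ranks once on all data before
splitting exists purely as a replication switch for leak-prone historical
protocols and is never the default. Fold assignment is a pure function of
(ids, labels, k, seed); paired comparisons across configurations reuse it.
Per-fold confusion counts are summed into pooled counts and the five
metrics are computed once from the pooled counts — averaging per-fold
percentages is never done, because folds of unequal size would be weighted
incorrectly and per-fold MCC can be undefined.

Metrics are stored as fractions and rendered as percentages only at report
time. The MCC is computed in its N+/N−/F+/F− form, which is an exact
algebraic rewriting of the four-marginal Matthews coefficient (property
tested to 1e-12); a zero marginal raises an explicit undefined-metric error
rather than silently returning 0. The result is clamped to [−1, 1] to guard
against float round-off at boundary cases. `counts_from_rates` inverts
printed (Sn, Sp) percentages to integer counts and verifies the round trip
to within 0.005, which makes published result rows desk-checkable.

## Synthetic benchmark generator

The generator emulates a two-class peptide benchmark with first-order
Markov sequences: a base transition model (rows drawn from a Dirichlet with
concentration 50 per entry — near-uniform, entries ≈ 0.05 ± 0.007 — so the
base carries no accidental structure) and a uniform initial distribution.
The positive class uses a perturbed copy in which each of 5 signal
transitions (distinct first residues, drawn from the seed) gains exactly
delta probability mass, the rest of its row shrinking proportionally; the
realized effect size therefore equals delta, and `truth_report` exposes the
signal feature names and effect sizes for recovery tests. Defaults are
138/206 peptides of 5–50 residues with delta = 0.3.

First-order structure was chosen deliberately: the pipeline's features are
order-g pair statistics, so the generator can place signal exactly where
the g = 0 block should detect it, while g ≥ 1 blocks see only the induced
(weaker) correlation. What the generator does **not** emulate: amino-acid
usage bias, amphipathicity, charge, length–class correlation, or homology
between peptides. Passing recovery tests therefore demonstrates that the
statistics work as specified, not that real anticancer peptides are
classifiable at any particular accuracy.

### The accuracy ceiling

Because both generating models are known, the exact Bayes classifier is
available: score each peptide by the log-likelihood ratio of the two chains
plus the class-prior log odds (`bayes_accuracy`). At the default
conditions (delta = 0.3 on 5 of 400 transitions, lengths 5–50) this ceiling
is ≈ 0.85–0.87: a typical peptide visits the 5 signal rows only a handful
of times, and short peptides carry almost no evidence. No feature-based
classifier can expect to exceed this, and the default SVM, estimating
400 feature weights from 344 samples, reaches ≈ 0.72–0.78 pooled accuracy.
This ceiling is reported alongside CV results by `scripts/acceptance.py` so
that pipeline accuracy is always read against what the data admit. Raising
delta or lengthening peptides raises the ceiling smoothly (delta = 0.7
gives ≈ 0.91 at these lengths); the defaults were fixed once as the study
conditions and are not tuned.

A delta = 0 run (classes exchangeable, 150/150) is the null control: the
pooled 10-fold MCC fluctuates around 0 with magnitude well under 0.15 at
n = 300, which bounds the optimistic bias of the evaluation protocol
itself.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study conditions (344 and 300
peptides, 400-dimensional g = 0 features, 10-fold CV with the inner SVM
grid), which completes in seconds per CV run. The brute-force MRMD oracle
check uses 100 random matrices up to 8 features × 30 samples; the MCC
identity is checked on 10,000 random confusion matrices. Tolerances: 1e-12
for exact algebraic identities (compositions summing to 1, MCC
equivalence), 1e-9 for oracle score comparisons across different summation
orders, 0.02 for the 5,000-peptide convergence of empirical g = 0
compositions to the perturbed chain's stationary pair frequencies.

## Known limitations

* The per-fold MRMD + inner-grid protocol is the defensible default but is
  not guaranteed to match historical runs that selected features on all
  data; use `--global-selection` to replicate those.
* The MD term mixes a scale-dependent distance with bounded similarities;
  with heterogeneous feature blocks the Euclidean term can dominate. The
  min-max switch mitigates this but is off by default for fidelity.
* FASTA labels rely on a header-token convention (`|1`, `|ACP`, …) or a
  sidecar table; there is no standard for this and other conventions must
  be converted first.
* The generator's sequences are stationary first-order chains; conclusions
  about feature blocks with g ≥ 1 on real data do not follow from it.
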