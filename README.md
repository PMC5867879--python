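# sap — sequence-based identification of anticancer peptides

Anticancer peptides (ACPs) are short peptides (typically 5–30 residues) that
selectively disrupt cancer-cell membranes. Finding them experimentally is
slow and expensive, so sequence-based classifiers that score candidate
peptides directly from their residue strings are a standard screening tool.
`sap` implements one such pipeline end to end, for bioinformaticians who
want to featurize peptide sets, select informative features, and benchmark
classifiers under a reproducible cross-validation protocol.

## The method

A peptide `P = R1 R2 … RL` over the 20 standard amino acids is represented
by ordered-pair statistics:

* **400D features** — for each of the 400 ordered dipeptides AB, the number
  of positions j with `Rj R(j+1) = AB` (raw counts by default; a frequency
  mode divides by L−1).
* **g-gap dipeptide composition** — pairs separated by exactly g residues,
  normalized to a composition:
  `d_u^g = n_u^g / (L − g − 1)`, g = 0…4. The g = 0 block equals the
  frequency-mode 400D block.

Features are then ranked by the **maximum relevance–maximum distance
(MRMD)** criterion, `score_i = MR_i + MD_i`, where `MR_i` is the absolute
Pearson correlation of feature i with the ±1 class labels and `MD_i` is the
mean of three pairwise column statistics over all other features: Euclidean
distance, cosine value, and the Tanimoto coefficient
`F_i·F_k / (‖F_i‖² + ‖F_k‖² − F_i·F_k)`. Low-scoring features are pruned.

Classification uses an RBF-kernel SVM (inner-CV grid over C and gamma,
min-max scaled features) or a random forest, with a pluggable slot for any
third classifier. Evaluation is stratified k-fold cross-validation pooled
into Chou-style confusion counts N+, N−, F+, F−, reported as the five
metrics

```
Sn  = 1 − F−/N+            Sp  = 1 − F+/N−
Acc = 1 − (F+ + F−)/(N+ + N−)
MCC = [1 − (F−/N+ + F+/N−)] / sqrt[(1 + (F+−F−)/N+)(1 + (F−−F+)/N−)]
F   = 2PR/(P + R)
```

A first-order-Markov synthetic generator (`sap.synthetic`) produces
two-class peptide sets whose classes differ only in chosen transition
probabilities, giving ground truth for selector- and classifier-recovery
tests without any external data.

## Worked example

Recompute a published evaluation row from its printed rates. With
N+ = 138 ACPs and N− = 206 non-ACPs, sensitivity 86.23% and specificity
95.63% force the integer errors F− = 19, F+ = 9, from which the remaining
metrics follow:

```python
>>> from sap import counts_from_rates, all_metrics, as_percent
>>> c = counts_from_rates(0.8623, 0.9563, n_pos=138, n_neg=206)
>>> (c.f_neg, c.f_pos)
(19, 9)
>>> as_percent(all_metrics(c))
{'Sn': 86.23, 'Sp': 95.63, 'Acc': 91.86, 'MCC': 83.01, 'F_score': 89.47}
```

Run the full pipeline on synthetic data — generate a benchmark-sized
dataset with class signal in 5 adjacent-residue transitions, featurize with
the g = 0 dipeptide composition, prune to the top 50 MRMD features inside
each training fold, and cross-validate the default SVM:

```python
from sap import (SAPModel, FeaturizationSpec, SelectionSpec,
                 ClassifierSpec, GeneratorSpec, generate)

dataset = generate(GeneratorSpec(n_pos=138, n_neg=206, delta=0.3, seed=7))
model = SAPModel(
    dataset,
    featurization=FeaturizationSpec(include_400d=False, gaps=(0,)),
    selection=SelectionSpec(k=50),
    classifier=ClassifierSpec(family="svm", seed=7),
)
print(model.cross_validate(k=10, seed=7).summary())
```

which prints (abridged):

```
folds: 10   N+=138  N-=206  F-=45  F+=35
pooled metrics (fraction / percent):
  Sn       0.673913    67.39%
  Sp       0.830097    83.01%
  Acc      0.767442    76.74%
  MCC      0.511070    51.11%
  F_score  0.699248    69.92%
```

Pooled counts (here F− = 45, F+ = 35) are always the sums of the per-fold
counts; metrics are never averaged percentages. For context,
`sap.synthetic.bayes_accuracy` reports the likelihood-ratio ceiling of the
same dataset (≈ 0.85–0.87 at these settings), so the SVM is capturing most
but not all of the available signal — see `docs/methods.md`.

The same pipeline is available from the shell:

```bash
sap synth --n-pos 138 --n-neg 206 --delta 0.3 --seed 7 \
    --out synth.fa --truth truth.json
sap featurize --fasta synth.fa --gaps 0 --no-d400 --out features.csv
sap rank --in features.csv --out ranking.tsv --k 50
sap cv --fasta synth.fa --gaps 0 --no-d400 --k 10 --seed 7 --out report/
```

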