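# accvax

Alignment-free prediction of bacterial protective immunogens — the
starting point of reverse vaccinology. Given a protein sequence, `accvax`
answers "is this a probable antigen?", and given a whole bacterial
proteome it ranks how strongly the predicted candidate set is enriched for
known protective antigens. It is written for computational
vaccinologists and bioinformaticians triaging proteomes for vaccine
candidates, and for anyone who needs a reproducible, scriptable
implementation of the ACC/E-descriptor antigen-classification pipeline.

## Method

Every protein of length *n* is encoded as a 5 × *n* matrix of
**E-descriptors** — five PCA-derived physicochemical scores per residue
(hydrophobicity, size/sterics, helix propensity, volume/composition, strand
propensity) — and collapsed to a fixed-length vector by the **auto-cross
covariance (ACC)** transform:

```
A_jj(L) = Σ_{i=1}^{n−L} E_{j,i} · E_{j,i+L} / (n − L)
C_jk(L) = Σ_{i=1}^{n−L} E_{j,i} · E_{k,i+L} / (n − L),   j ≠ k
```

for lags L = 1..8, i.e. 25 terms per lag and 200 features per protein
regardless of length. On labeled immunogen/non-immunogen sets the package
trains six classifier families (PLS-DA, 1-NN, RBF-SVM, random forest,
random-subspace 1-NN, gradient boosting) at their reported settings,
validates them with seeded 10-fold cross-validation and external test sets
(sensitivity, specificity, accuracy, precision, AROC, APR, MCC, F1), and
deploys the three strongest — RSM-1NN, xgboost, and RF with
information-gain feature selection — as a **majority-voting** predictor: a
protein is a "probable antigen" when ≥ 2 of 3 members vote positive, with
the vote fraction (0/33/67/100%) reported as the probability. Proteome
screening summarizes a run over N proteins with K known protective antigens
(BPAs) as the PVC fraction n/N, BPA sensitivity k/K, fold-enrichment
(k/K)/(n/N) and a hypergeometric upper-tail p-value.

See `docs/methods.md` for assumptions, parameter rationale and limitations.

## Worked example

Labeled training data can come from FASTA (with `|label=0/1` header
suffixes or a two-column TSV sidecar); here a synthetic two-class set with a
hydrophobicity-composition signal stands in, so the example runs offline:

```python
from accvax import (generate_synthetic_dataset, length_stratified_split, SplitSpec,
                    build_feature_matrix, default_descriptor_table,
                    fit_vaxijen_predictor, predict_batch, evaluate_predictions)

records = generate_synthetic_dataset(n_pos=250, n_neg=250, length_range=(30, 200),
                                     signal_strength=0.8, seed=1)
train_recs, test_recs = length_stratified_split(records, SplitSpec(seed=1))
table = default_descriptor_table()
train_set = build_feature_matrix(train_recs, table, lag_max=8)
test_set = build_feature_matrix(test_recs, table, lag_max=8)
print(f"train: {train_set.features.shape}, test: {test_set.features.shape}")

bundle = fit_vaxijen_predictor(train_set, seed=1, table=table, lag_max=8)
results, skipped = predict_batch(bundle, test_recs)
votes = [int(r.positive_votes >= 2) for r in results]
labels = [rec.label for rec in test_recs]
metrics = evaluate_predictions(labels, votes)
print(f"majority-vote test accuracy: {metrics.accuracy:.3f} "
      f"(MCC {metrics.mcc:.3f}, F1 {metrics.f1:.3f})")
first = results[0]
print(f"{first.record_id}: votes {first.per_model_votes} -> "
      f"{first.verdict} ({first.probability_percent}%)")
```

Output:

```
train: (388, 200), test: (112, 200)
majority-vote test accuracy: 0.991 (MCC 0.982, F1 0.990)
neg_0026: votes {'rsm_knn': 0, 'xgboost': 0, 'rf': 0} -> probable non-antigen (0%)
```

The 500 input proteins become a 500 × 200 ACC matrix, split 388/112 by
length-stratified sampling; the three-member bundle recovers the
compositional class signal almost perfectly on held-out proteins, and each
prediction carries its per-member votes and vote-fraction probability.

The same workflow is available from the shell:

```sh
accvax train    --fasta train.fasta --out bundle.joblib --seed 1
accvax predict  --bundle bundle.joblib --fasta queries.fasta --out calls.tsv
accvax evaluate --fasta labeled.fasta --out metrics.tsv
accvax screen   --bundle bundle.joblib --proteome proteome.fasta \
                --bpa known_antigens.txt --out screen.tsv
```

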