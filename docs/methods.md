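# Methods

## The prediction problem

Given a bacterial protein sequence, decide whether it is a protective
immunogen — a protein that elicits a memory immune response and is therefore
a vaccine candidate. The approach is alignment-free: instead of comparing a
query to known antigens, every protein is mapped to a fixed-length numerical
vector summarizing the physicochemical texture of its sequence, and standard
supervised classifiers are trained on labeled immunogen/non-immunogen sets.

## Sequence encoding

**E-descriptors.** Each of the 20 standard residues is represented by five
scores (E1..E5) obtained from a principal-component analysis of 237
physicochemical properties: E1 tracks hydrophobicity, E2 molecular
size/sterics, E3 α-helix propensity, E4 partial specific volume / codon
usage / relative abundance, E5 β-strand propensity. The values ship as a
versioned constant table (`default_descriptor_table()`, name
`E-descriptors-v1`); any other 20 × 5 scale set can be injected, and the
table name is baked into the feature ordering tag so models trained on one
scale set refuse features built with another. A protein of length *n*
becomes a 5 × *n* matrix **E** with column *i* the descriptor tuple of
residue *i*.

**Auto-cross covariance (ACC).** Variable-length matrices are collapsed into
fixed-length vectors of lagged products:

    A_jj(L) = Σ_{i=1}^{n−L} E_{j,i} · E_{j,i+L} / (n − L)        (auto)
    C_jk(L) = Σ_{i=1}^{n−L} E_{j,i} · E_{k,i+L} / (n − L), j ≠ k (cross)

for lags L = 1..`lag_max`. Each lag contributes 25 terms (5 auto + 20
cross); the default `lag_max = 8` gives 200 features per protein regardless
of length. Design choices the formulas leave open:

* **Ordering** (lag-major): for each L the 25 ordered pairs (j, k), j outer,
  k inner. The ordering tag (`acc-lagmajor-25:<table>:lag<L>`) travels with
  every dataset and model; mismatches are contract errors, never silent
  reindexing.
* **No centering or scaling inside the transform.** The sums run over raw
  descriptor values, so ACC here is a raw (uncentered) covariance;
  standardization, where used, is a model-side concern. Consequences that
  the tests pin: scaling all descriptors by *c* scales every ACC term by
  *c*², and shifting a descriptor row changes the auto terms.
* **Minimum length** n ≥ lag_max + 1. A protein of length exactly lag_max
  would put n − L = 0 in the largest-lag denominator, which is undefined, so
  the stricter rule is enforced and violations are reported per record.
* **Non-standard residues**: `strict` (default) errors at the first
  offending position; `skip-unknown` deletes them before encoding, because
  real proteomes contain X and similar codes.

## Classifier families

Six families are implemented behind one `ModelConfig`/`train_model`/
`predict_scores` surface. Settings reported for the bacterial immunogenicity
models are the defaults; settings the original description leaves open use
the conventional implementation default and are recorded in each model's
training fingerprint.

| family | defaults | scaling | notes |
|---|---|---|---|
| `pls_da` | components by internal 5-fold CV over 1..10, threshold 0.5 | standardized | PLS regression on a {0,1} response; the continuous response is squashed monotonically into [0,1] with the threshold at score 0.5 |
| `knn` | k = 1, 1/distance weighting | standardized | an exact-match neighbour (distance 0) dominates, the limit of 1/distance weighting |
| `svm_rbf` | gamma = 100, cost = 1 | **raw** | see below |
| `rf` | 100 trees, √d features/split, feature selection on | raw | tree ensembles are scale-free |
| `rsm_knn` | k = 1, subspace 0.4, 10 members | standardized | random-subspace ensemble of 1-NN learners; positive score = mean member score; reduces exactly to `knn` at subspace 1.0 with one member |
| `xgboost` | max depth 4, eta 1, 150 rounds | raw | boosted-logistic positive-class output |

**Why the RBF machine sees raw features.** The reported gamma of 100 was
tuned on raw ACC features, whose magnitudes are products of E-descriptor
values (~1e-2) and whose squared inter-protein distances are of order 1e-2 —
a regime where gamma = 100 is a moderate kernel width. On standardized
200-dimensional features squared distances are ~400, the kernel matrix
degenerates to the identity, and the classifier collapses to its bias. The
tuned hyperparameters and standardization are therefore incompatible, and
the tuned values win.

**Feature selection** is ranking-based: each feature's information gain is
computed after Fayyad–Irani MDL supervised discretization (the classical
data-mining default for continuous attributes), and features scoring
strictly above 0 are kept. Constant features score exactly 0; a feature
identical to the label carries the full one-bit label entropy. The ranker is
written in-package because no installed library provides this estimator
(scikit-learn's `mutual_info_classif` is a different, stochastic,
neighbour-based estimator). Ranking always runs inside the training
partition only — in cross-validation it is refit per fold — so selection is
leakage-free by construction. The interface (`rank_features(method=...)`) is
extensible to other rankers.

**Scores and labels.** Every family reports a positive-class score in
[0, 1]; the binary label is score ≥ 0.5. For PLS-DA the classification
threshold on the continuous response (default 0.5) maps to score 0.5 under
the monotone squashing, so thresholding scores and thresholding responses
agree, and ROC areas are unchanged by the squashing.

## Validation

`confusion_counts` + `compute_metrics` produce the eight statistics:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, precision,
MCC, F1, AROC (trapezoidal area under the ROC curve, tied scores collapsed
to one operating point) and APR (step-wise precision–recall summation).
Zero-denominator conventions, pinned by tests: precision := 0 when nothing
is predicted positive; MCC := 0 when any factor of its denominator is 0;
F1 := 0 when precision + recall = 0. `cross_validate` uses seeded stratified
k-fold assignment (default 10), refits everything — selection, scaling,
estimator — inside each fold, and reports metrics from the pooled
out-of-fold predictions (the summary convention of classical data-mining
toolkits), not fold averages.

## The majority-voting predictor

`fit_vaxijen_predictor` trains the three best families — `rsm_knn`,
`xgboost`, `rf` with feature selection — on the full labeled set, with
member seeds fanned out deterministically (seed, seed+1, seed+2). A new
protein receives one binary vote per member; the verdict is "probable
antigen" iff ≥ 2 votes are positive and the reported probability is the vote
fraction (exactly 0, 1/3, 2/3 or 1; displayed as 0/33/67/100%). Binary
member votes, not averaged scores, feed the decision; the mean member score
is reported as a diagnostic only. Batch prediction reports inadmissible
records (too short, unencodable) with reasons rather than skipping them
silently.

## Proteome screening

`screen_proteome` classifies every admissible protein of a proteome and
summarizes: PVC fraction n/N, BPA sensitivity k/K, fold-enrichment
(k/K)/(n/N), and a hypergeometric upper-tail probability P(X ≥ k) for
X ~ Hypergeometric(N, K, n) (the standard enrichment reading; evaluated via
log-space mass terms, exact to ≤1e−10 against direct combinatorial
summation on small cases). Conventions: BPA identifiers are matched after
stripping `sp|`/`tr|` database prefixes; unknown BPA ids error by default
(`on_unknown_bpa="warn"` downgrades them to a logged warning); proteins
failing the length or residue rules are excluded from N and logged.

## Synthetic data

Real labeled immunogen sets are an external download, so the test bed is a
generator (`generate_synthetic_dataset`) producing two classes that differ
only in amino-acid composition: positives draw residues with weight
1 + s on a hydrophobic tilt set and 1 − s elsewhere, negatives with the
complementary tilt, lengths uniform in a given range. At signal strength
s = 0 the classes are identically distributed (the null case, verified by
chi-square on pooled counts); at the default s = 0.8 the compositions are
nearly disjoint. The tilt set is the seven residues with positive
Kyte–Doolittle hydropathy, {A, C, F, I, L, M, V}: a *sign-consistent*
hydrophobic set, chosen because the ACC features see composition only
through products of descriptor values — a tilt set mixing residues of
opposite descriptor sign (e.g. one including G or P, whose E1 is positive)
cancels its own contrast in the lagged-product means and leaves the class
signal invisible to covariance features even when the compositions are
nearly disjoint.

The default study conditions used throughout the tests are 250 + 250
proteins, lengths 30–200, signal 0.8, lag 8 (a 500 × 200 feature matrix),
with a 28-group length-stratified 80/20 split. At those conditions every
family reaches held-out AROC > 0.95 and permuted-label training pools to
chance-level AROC.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: residues are i.i.d. within a protein (no domains,
no positional structure, so lags carry no extra information beyond
composition), the classes share no homology structure (real negative sets
are BLAST-filtered mirrors), lengths are independent of class, and the class
signal is a single global composition axis rather than the heterogeneous,
partly epitope-local signal of real immunogens. Synthetic performance is a
correctness floor for the pipeline, not an estimate of real-data accuracy.

## The length-stratified split

Records are stably sorted by (length, id) and cut into `n_groups` (default
28) contiguous, near-equal groups; within each group a seeded shuffle sends
⌈test_fraction · group size⌉ records to the test set (ceiling, so a
12-record group at 20% contributes 3). Equal-count contiguous grouping is
the reproducible choice where the original group boundaries are
unrecoverable; the split is a deterministic exact partition for a fixed
seed.

## Numerical and degenerate-input choices

* ACC is evaluated as one matrix product per lag; it agrees with the literal
  double-loop sum to ≤1e−12.
* kNN zero-distance neighbours receive the entire weight (1/distance limit).
* Score ties in ROC sweeps form a single operating point.
* Feature selection that removes every feature aborts training with an
  explicit error (it typically means the labels carry no information).
* Empty record lists, partially labeled inputs, single-class datasets,
  ordering-tag or width mismatches are all errors, never silent recovery.

## Known limitations

* The original implementation's defaults (random-forest tree count, random-subspace
  ensemble size, PLS component choice) are not documented in the source
  description; the values here (100 trees, 10 members, internal 5-fold CV
  over 1..10 components) are conventional and recorded per model, but not
  claimed identical to the original.
* The published benchmark numbers were obtained on curated real datasets
  that are an external download; this package reproduces the printed
  arithmetic and the method, and validates behaviour on synthetic data, but
  does not re-derive the real-data performance table offline.
* Only the ranking family of feature selection is implemented; subset-search
  and evolutionary selection methods are out of scope.
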