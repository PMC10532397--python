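# stagesel

Stage-wise selection of diagnostic classification models with
MEREC-TOPSIS ranking and FOX metaheuristic optimization.

## The problem

Computer-aided diagnosis pipelines for thyroid imaging (ultrasound
nodule scans, histopathological whole-slide patches) typically compare
dozens of candidate models — combinations of a frozen deep feature
extractor, a dimensionality-reduction method and a classifier — on
several conflicting performance criteria at once. Picking "the best"
model by accuracy alone ignores recall-weighted performance on heavily
imbalanced cohorts (e.g. 286 benign vs 61 malignant nodules) and
threshold-free discrimination. `stagesel` implements the multi-criteria
machinery for that selection problem:

- **MEREC** (MEthod based on the Removal Effects of Criteria): objective
  criterion weights from how much removing each criterion perturbs the
  log-aggregate performance `S_i = ln(1 + (1/n) Σ_j |ln n_ij|)` of every
  alternative; `w_j = E_j / Σ_k E_k` with removal effect
  `E_j = Σ_i |S'_ij − S_i|`.
- **TOPSIS**: each alternative scored by relative closeness
  `C_i = d_i⁻ / (d_i⁺ + d_i⁻)` to the ideal vs anti-ideal point in
  normalized, weighted criterion space (criteria: accuracy, F2-score,
  AUC-ROC).
- **FOX optimizer**: a population metaheuristic (red-fox hunting
  analogy: sound-based distance estimation, jump, shrinking random walk)
  used for wrapper feature selection (continuous positions binarized at
  0.5, cost = 1 − CV accuracy) and for the two weights of a soft-voting
  ensemble.
- **Three-stage protocol**: stage 1 ranks extractor × classifier
  combinations, stage 2 ranks dimensionality-reduction methods for the
  winner, stage 3 compares FOX feature selection on the two forwarded
  candidates against their FOX-weighted ensemble. Every stage emits a
  `StageReport` whose ranking is recomputed by MEREC-TOPSIS from pooled
  out-of-fold metrics of a stratified 5-fold cross-validation.

A seeded synthetic-data generator reproduces the statistical structure
the framework assumes (class imbalance, informative/redundant/noise
feature blocks, optional per-patch fusion), so the whole pipeline is
testable without any image data; the published metric tables ship as
packaged fixtures for the ranking chain.

## Worked example

Rank the six dimensionality-reduction candidates of the ultrasound
stage-2 table by MEREC-TOPSIS:

```bash
$ cat dimred.csv
model,accuracy,f2_score,auc_roc
PCA,0.9790,0.9832,0.9885
SVD,0.9720,0.9720,0.9910
FAST_ICA,0.9825,0.9930,0.9815
ISOMAP,0.9825,0.9930,0.9841
LLE,0.9335,0.9292,0.9656
UMAP,0.8147,0.7015,0.9075

$ stagesel rank --matrix dimred.csv --out ranked.csv --weights-out w.csv
             score  rank   tied
PCA       0.970129     2  False
SVD       0.936089     4  False
FAST_ICA  0.959668     3  False
ISOMAP    0.970488     1  False
LLE       0.746239     5  False
UMAP      0.000000     6  False
```

The MEREC weights (`w.csv`) are (0.2963, 0.5711, 0.1326): F2 dominates
because removing it perturbs the alternatives' aggregate performance
most. UMAP scores exactly 0 — it is worst on all three criteria, so it
coincides with the anti-ideal point. PCA and ISOMAP are nearly tied at
the top and are the two candidates a stage-2 run would forward.

The same from Python, end to end on synthetic data (347 samples,
286:61 imbalance, PCA to 8 components inside each CV fold, random
forest):

```python
from stagesel import SynthSpec, generate_table, evaluate_cv

table = generate_table(SynthSpec(seed=1))
m = evaluate_cv(table, classifier="rf", reducer=("pca", 8), k=5, seed=1)
print(f"accuracy={m.accuracy:.4f} f2={m.f2:.4f} auc={m.auc_roc:.4f}")
# accuracy=0.9885 f2=0.9571 auc=0.9978
```

Metrics are pooled over out-of-fold predictions, so they describe one
confusion matrix for the whole cohort. Other CLI entry points:
`stagesel simulate` (synthetic tables from a YAML spec), `stagesel
select` (FOX wrapper feature selection), `stagesel ensemble`
(soft-voting weight optimization) and `stagesel run` (fixture-mode stage
reports for the packaged tables).

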