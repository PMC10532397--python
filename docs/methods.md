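# Methods

## MEREC criterion weighting

Given a decision matrix `x` of m alternatives on n strictly positive
criteria, MEREC ratio-normalizes so that *smaller is better*
(benefit: `n_ij = min_k x_kj / x_ij`; cost: `n_ij = x_ij / max_k x_kj`),
aggregates each alternative as `S_i = ln(1 + (1/n) Σ_j |ln n_ij|)`,
recomputes `S'_ij` with criterion j's term removed (the sum is still
divided by n), and weights each criterion by its total removal effect
`E_j = Σ_i |S'_ij − S_i|`, normalized to sum 1. Positivity is required
by the logarithms; a constant column has zero removal effect and weight
0; a matrix whose every column is constant carries no information and is
rejected.

Recomputed weights reproduce both published weight rows for the
15-model stage-1 tables and both rows for the 6-model stage-2 tables to
~1e-4. The published stage-3 weight row does **not** match a MEREC
recomputation from the corresponding 3-model tables (ultrasound:
computed (0.2697, 0.6264, 0.1039) vs published (0.2732, 0.6216, 0.1052);
histopathological: computed (0.3061, 0.2996, 0.3943) vs published
(0.2000, 0.3356, 0.4644)); the stage-3 *rankings* nevertheless reproduce
exactly with recomputed weights.

## TOPSIS variant and its calibration

TOPSIS admits several normalization/weighting conventions. Two are
implemented:

- `minmax-separation` (default): min-max column normalization
  `r_ij = (x_ij − min_j) / (max_j − min_j)` with the weights applied
  inside the squared Euclidean separations,
  `d_i± = sqrt(Σ_j w_j (r_ij − r_j±)²)` — equivalently `v = sqrt(w)·r`.
  Constant columns normalize to 0 and contribute nothing.
- `vector`: the textbook variant, `r_ij = x_ij / sqrt(Σ_k x_kj²)` and
  `v = w·r`.

Both satisfy the contracts the ranking relies on: closeness in [0, 1],
exactly 1 for a row best on every criterion and exactly 0 for a row
worst on every criterion, invariance to positive rescaling of any
criterion column, and ranks in descending closeness order with ties
sharing the smaller rank.

The default was calibrated on the published tables: only the
min-max/weighted-separation variant reproduces the ultrasound
dimensionality-reduction table's LLE closeness (computed 0.7462 vs
published 0.7418, within the 5e-3 reproduction tolerance; the vector
variant gives 0.7743) and the relative order of the two bottom
ultrasound stage-1 models. The variant used is recorded in
`RankingResult.metadata`.

### Known limitations of the published score columns

The published TOPSIS score columns of the four larger tables are not
internally consistent with their own metric columns under *any*
monotone TOPSIS using weights near the published ones. Two provable
examples: in the ultrasound stage-1 table the Mixer-MLP/RF row
(accuracy 0.9455) is printed above the DeiT/RF row (accuracy 0.9685,
equal AUC, −0.011 F2), which would require an F2:accuracy weight ratio
above ~6 where the published ratio is 1.3; in the histopathological
stage-1 table the DeiT/LR row is printed below rows it beats on two of
three criteria. Each published *rank* column is consistent with its
published *score* column, so the defect lies in the published scores.
Consequences: dominant/dominated rows (scores 1.0000/0.0000), both
stage-3 tables' full rank columns, all stage-1/stage-2 weight rows, the
stage-2 winners and the ultrasound stage-2 top-2 set {PCA, ISOMAP}
reproduce exactly; the full rank columns of the four larger tables and
the histopathological stage-2 runner-up (published LLE, recomputed SVD)
do not. The acceptance suite asserts the full-column claim as stated and
is expected to fail on those four tables.

## FOX optimizer

Population minimizer over a box, equations per the algorithm's original
formulation. Per agent and iteration, with incumbent best `B`:

- exploitation (draw `r ≥ 0.5`): sample a per-dimension sound time
  `T ~ U(0,1)^d`; the sound travels `B` (speed `B/T` times `T`), so the
  fox-prey distance is `0.5·B`; jump height `0.5·9.81·(mean(T)/2)²`;
  new position `0.5·B·jump·c`, with `c = c1 = 0.18` if a second draw
  `p > 0.18` else `c = c2 = 0.82`. The minimum observed `mean(T)` is
  tracked as `MinT`.
- exploration (`r < 0.5`): `B + N(0,1)^d · MinT · a` with schedule
  `a = 2(1 − it/n_iters)`.

Positions are clipped to the bounds before each evaluation; the global
best is elitist, so the cost trace is non-increasing by construction.
One seeded NumPy generator drives the run: identical seeds give
bitwise-identical traces. Defaults `n_agents=30`, `n_iters=100`
(standard metaheuristic budgets; the selection helpers use smaller
budgets suited to their low-dimensional searches). `c1`, `c2` and the
gravity constant are exposed as parameters. Verified behaviour: sphere
in 5-D reaches ≤ 1e-3 at budget 30×300, and random convex quadratics
(dim ≤ 5) are solved to within 1e-2 of the analytic minimum at 30×500.

## Cross-validated evaluation

All evaluation uses shuffled stratified k-fold CV (default k = 5), which
keeps per-fold class counts within one sample — essential at 286:61
imbalance ("stratified sampling" is interpreted as stratified fold
construction, not synthetic oversampling). Metrics (accuracy, F2 with
β = 2, AUC-ROC, plus recall and specificity) are pooled over out-of-fold
predictions so a single confusion matrix summarizes the run. Reducers
and classifiers are fit on each training fold only; a deliberate
leak switch (`fit_reducer_on="all"`) exists solely so tests can
demonstrate the guard changes results. Because the original study does
not state whether its reducers were fit per fold, leakage-free fitting
is the defensible default and absolute metric levels may differ from the
published ones. Classifiers are library defaults with fixed seeds
(logistic regression gets `max_iter=1000` to converge on reduced
features); the five supported names are lr, nb, svc, knn, rf, and the
six reducers are pca, tsvd, fastica, isomap, lle, umap.

## Wrapper selection and ensemble

Feature selection encodes a mask as a continuous position in
[0, 1]^n_features binarized at 0.5 (≥ keeps, so exactly 0.5 keeps);
cost is 1 − pooled CV accuracy on the masked table and an empty mask is
penalized with cost 1. The all-features position is injected into the
initial population, making "never worse than the all-features baseline
on the search objective" structural rather than probabilistic. Mask
costs are memoized per subset because converged populations revisit the
same masks. The ensemble search optimizes two soft-voting weights over
[0, 1]² (normalized to sum 1; the all-zero corner maps to equal
weights), with cost 1 − accuracy of the combined probability at
threshold 0.5; the corners (1,0), (0,1) and the midpoint are injected so
the ensemble can never score below either base model on its objective.
Whether the stage-3 cost should be in-fold or out-of-fold is not
specified by the protocol; out-of-fold is used, which couples the
selection signal to the same predictions being reported (an optimistic
bias acknowledged here).

## Synthetic data generator

Emulates the study's tabular structure: exact class marginals
(default 286:61 over 347 samples), informative features as
class-conditional unit-variance Gaussians separated by `effect_size`
SDs (default 3.0 — a strong, clearly learnable signal), redundant
features as fixed random linear combinations of the informative block
plus 10% relative noise (absolute correlation with their generating
combination ≈ 0.995, so PCA provably concentrates the signal), and
class-independent standard-normal noise features. `patch_count > 1`
generates independent per-patch blocks and concatenates them in raster
order, emulating patch fusion of whole-slide images. It does **not**
emulate ultrasound texture statistics, inter-feature nonlinear
dependence, patient-level grouping effects or label noise, so passing
tests demonstrate the machinery's correctness and sensitivity-ordering
behaviour, not clinical performance levels. For grouped designs (up to
ten images per patient in the histopathological cohort) the
`group_id` field is carried through but the default CV unit is the
individual sample, matching the published sample counts.

## Numerical and design choices

- Ranks use "min" tie handling (ties share the best rank) with an
  explicit tie flag: deterministic and order-independent.
- Fixture tables are stored exactly as printed, including 3-decimal
  entries; no re-rounding.
- Decision matrices must be strictly positive and need m ≥ 2, n ≥ 2 for
  weighting; identical alternatives make closeness undefined (d⁺ + d⁻ =
  0) and raise a degenerate-matrix error.
- Patch-grid arithmetic pads the image up to the next window multiple:
  rows = ⌈height/window⌉, cols = ⌈width/window⌉ (a 1053×1916 px slide
  with a 224 px window gives 5 × 9 = 45 patches).
- Problem sizes in the test suite (tables of 60–90 samples, ≤ 30
  features, selection budgets of ~10 agents × ~20 iterations) are chosen
  so each property is exercised at the smallest scale at which it is
  informative; the study-scale generator default (347 × 20) is used
  where the claim concerns the cohort shape itself.
- Deep feature extractors are a plug-in interface only
  (`FeatureExtractor`); the package ships an identity extractor and a
  seeded random-projection extractor that emulates a frozen embedding,
  keeping the test suite free of downloads and image I/O.
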