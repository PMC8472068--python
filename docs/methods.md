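# Methods

## Model

`pathwalk` classifies samples of a multiclass expression study from
pathway-level activity scores that combine three sources of information:
per-gene multiclass differential expression, the topology of a directed
gene-interaction graph, and curated gene-set membership.

**Normalization.** Each gene row is standardized over all samples of one
dataset, `z = (x − mean) / sd`, with the sample (n−1) standard deviation.
The n−1 convention is the standard one in expression analysis; the
alternative (population sd) only rescales every z by a dataset-wide constant
and cannot change any downstream ranking. Zero-variance rows are mapped to
all-zero z; they then carry F = 0, p = 1 and zero weight everywhere
downstream. Normalization is always per dataset: in between-dataset runs the
training and test matrices are standardized independently, so no test-set
moment reaches the training side.

**Gene statistics.** The default statistic is the canonical one-way ANOVA
F = MSB/MSW with degrees of freedom (k−1, N−k), where k is the number of
classes and N the total sample count; p-values are upper-tail F
probabilities. Two alternatives share the same table contract and are
selected by the `stat` config key: Welch's heteroscedastic one-way F with
the Welch–Satterthwaite denominator df (robust to unequal class variances),
and the signed pooled-variance two-sample t for two-class data (`drw_compat`
mode). Degenerate genes — zero variance within and between classes — carry
statistic 0 and p = 1 rather than NaN; a gene whose classes are distinct
constants (within-SS zero, between-SS positive) gets the largest finite
float and p = 0, flagged, so the min–max weighting below always sees finite
input.

**Initial weights.** Over graph-node genes with expression data,
`raw_w = (|F| − min|F|) / (max|F| − min|F|)`; graph nodes without data get
0, and if all |F| are equal every data-bearing node gets 1. The vector is
L1-normalized into the restart distribution W0. (A published variant of
this formula subtracts the maximum in the numerator, which lands in
[−1, 0] and cannot be a probability; the min–max form implemented here is
the evident intent and is treated as the correct reading.)

**Transition matrix and ground node.** The directed graph becomes a binary
adjacency matrix; one virtual ground node is added, every zero-out-degree
(dangling) gene gets its single out-edge pointed at ground, and ground
points uniformly back at every real gene; rows are then normalized. This
wiring guarantees row-stochasticity while perturbing non-dangling dynamics
as little as possible. Exact wiring of the ground node is a design choice
of this package; any scheme that restores stochasticity would do, and the
effect vanishes on graphs without dangling nodes.

**Random walk with restart.** `W_{t+1} = (1−r) Mᵀ W_t + r W0`, started at
W0, iterated until the L1 change drops below `tol`. Restart mass never sits
on the ground node. After convergence the ground entry is dropped and the
vector re-normalized over real genes. Because the iteration is an affine
contraction with factor (1−r), the residual decays geometrically; with the
defaults (r = 0.7, tol = 1e-10) convergence takes ~20 iterations
independent of graph size. `r = 0.7` follows the established
directed-random-walk convention; cross-validated AUC is empirically flat
in r over [0.3, 0.9] (verified as a property test). `tol = 1e-10`,
`max_iter = 10000` are numerical choices; non-convergence raises with the
last residual. W0 serves as both the restart vector and the starting state,
the standard choice which also makes r = 1 return W0 exactly.

**Pathway activity.** For each pathway, the member genes with raw p < 0.05
(no multiplicity correction — the filter is a fixed, configurable `alpha`)
that exist in both the dataset and the graph contribute

    a(s) = Σᵢ w∞(gᵢ) · sgn(F(gᵢ)) · z_{gᵢ}(s) / sqrt(Σᵢ w∞(gᵢ)²)

per sample. With a nonnegative F statistic the sgn() term is identically
+1 — it is retained verbatim for fidelity and becomes active in the signed
t-statistic mode, where it aligns up- and down-regulated genes before
summation. sgn(0) := +1. The score is invariant under positive rescaling of
the whole weight vector. Pathways with no contributing genes are dropped; a
pathway whose contributing genes all carry exactly zero diffused weight
(possible for genes with no in-edges and zero restart mass) is dropped with
a warning rather than raising, so one pathological pathway cannot abort a
run.

**Ranking, selection, reproducibility.** Pathways are ranked by the
absolute one-way ANOVA F of their activity rows against the training
labels, ties broken lexicographically by pathway ID, and the top
`top_n = 100` (clamped to availability) are selected. Ranking on the
training F is the only label-safe reading of "select the most reproducible
pathways"; the reproducibility power

    Cscore = (1/N) Σ_{selected} F_train(P) · F_test(P)

is reported as a diagnostic of between-dataset replication, not used for
selection. Selected pathways absent from the test activity are skipped and
N reduced, which avoids fabricating F values.

**Classification and evaluation.** Three off-the-shelf classifiers sit
behind one interface: scikit-learn logistic regression, SVC, and Gaussian
naive Bayes. The SVM produces probabilities via Platt calibration
(`SVC(probability=True)`) so all three emit a per-class score matrix;
multiclass AUC is the unweighted macro average of per-class one-vs-rest
AUCs (midrank tie handling), which reduces to the ordinary AUC for two
classes. Within-dataset evaluation is repeated stratified k-fold
cross-validation (default 10 folds × 10 repeats, derived seeds, fully
deterministic given `seed`). The default protocol is fold-safe: gene
statistics, walk weights, activities and the top-N selection are recomputed
from the training folds only and the held-out fold is projected through
them. A `transductive: true` flag reproduces whole-dataset weighting before
cross-validation; it leaks information and exists only as a comparison
mode. If the smallest class has fewer samples than the requested fold
count, the fold count is reduced to that size with a warning. Between
datasets, gene universes are intersected, classes not shared by both label
sets are dropped (at least two must remain), and the classifier trained on
the full training dataset is scored on the projected test activities.

## Synthetic data

The generator emulates the statistical structure the pipeline targets:
baseline expression i.i.d. normal(0, `noise_sd`); `n_informative_pathways`
random gene sets whose member genes receive class-specific additive mean
shifts — equally spaced per-class levels of magnitude `effect_size` (in sd
units), independently permuted per pathway so each informative pathway has
its own class signature; remaining pathways are random gene subsets; the
graph is a uniform random sparse directed graph over the whole gene
universe with mean out-degree `graph_edges_per_node`, and every informative
gene is guaranteed at least one edge so diffusion can reach it. Everything
is reproducible from a single seed.

Reference study conditions (the `SimConfig` defaults): 5 classes × 40
samples, 2000 genes, 200 pathways of 10–30 genes, 20 informative, effect
size 2.0, noise sd 1.0, mean out-degree 3. `reference_study_config()` echoes a
published 4-class breast-cancer design at desk scale: class sizes
62/25/15/37, 300 pathways, 4000 genes, mean out-degree 10 (≈ the 40875
edges / 4113 genes density of the curated graph that design used).

What the generator does **not** emulate: probe-level effects, batch
structure, gene–gene correlation beyond the planted shifts, heavy-tailed
expression noise, and curated pathway topology (edges are uniform random,
not KEGG-like). Passing the recovery tests therefore demonstrates that the
machinery detects pathway-coherent mean shifts through the
weight–diffusion–activity chain; it does not certify performance on real
microarray data, where effect sizes are smaller and correlation structure
matters. The planted effect (2 sd on every member gene) is intentionally
strong so that recovery failures indicate implementation defects rather
than statistical noise.

## Numerical and design choices

- Missing expression cells are rejected at parse time (the statistics
  assume complete rows and no imputation scheme is defined); missing gene
  IDs are dropped and repeated IDs averaged, in first-occurrence order.
- Gene IDs are opaque strings throughout.
- Cross-validation fold arithmetic is standard stratified k-fold (k−1
  train / 1 test); any hyperparameter tuning belongs inside the training
  folds.
- Evaluation problem sizes in the test-suite and acceptance script:
  cross-validations under the reference conditions run with `repeats=1`
  (the `repeats=10` default mirrors averaging over ten experiment runs and
  changes only the variance of the mean, not its location).
- Determinism: all randomness flows through `numpy.random.default_rng`
  seeds and scikit-learn `random_state`s derived from the single `seed`
  config key; two runs with the same config produce byte-identical
  rankings and evaluation reports.

## Known limitations

- Edge semantics (activation vs. inhibition) are ignored; the walk sees
  only the binary directed adjacency.
- Genes present in the graph but absent from the dataset are retained with
  zero restart weight rather than removed; they can still accumulate small
  diffused mass via the ground node, slightly diluting the normalization.
- The per-gene p < 0.05 filter is uncorrected for multiplicity by design;
  with many null genes, ~5% leak into pathway scores as noise.
- Macro one-vs-rest AUC treats classes unweighted; heavily unbalanced
  designs may warrant a weighted average.
- The dense linear-solve oracle for the walk is quadratic in node count and
  is used only in tests.
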