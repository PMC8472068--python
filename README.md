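# pathwalk

Pathway-topology classification of multiclass gene-expression data.

Expression studies that compare several disease subtypes at once (for
example the luminal/basal/ERBB2/normal-like molecular subtypes of breast
cancer) need per-pathway summaries that respect both *which* genes
discriminate the classes and *how* those genes are wired together.
`pathwalk` implements an enhanced directed-random-walk pipeline for exactly
that setting:

1. **Pre-process** — drop rows with missing Entrez IDs, average repeated
   IDs, and z-score each gene over all samples of a dataset:
   `z(g_i) = (x_i − x̄_i) / S_i`.
2. **Score genes** — a one-way ANOVA F statistic per gene,
   `F = MSB / MSW` with df `(k−1, N−k)`, measures multiclass differential
   expression (Welch's heteroscedastic F and a signed pooled-variance t for
   the two-class baseline are drop-in alternatives).
3. **Diffuse weights** — min–max-scaled `|F|` over the nodes of a directed
   gene-interaction graph forms the restart distribution `W0`; a random
   walk with restart, `W_{t+1} = (1−r) Mᵀ W_t + r W0` with `r = 0.7`,
   propagates discriminative weight along edges. A single virtual ground
   node absorbs dangling genes so `M` stays row-stochastic.
4. **Infer pathway activity** — for each pathway, the genes with raw
   `p < 0.05` that are present in the data and the graph contribute

   `a(P_j) = Σᵢ w∞(gᵢ)·sgn(F(gᵢ))·z(gᵢ) / √(Σᵢ w∞(gᵢ)²)`

   giving one activity value per sample.
5. **Select and classify** — pathways are ranked by the absolute ANOVA F
   of their activity rows in the training data, the top 100 are kept, and a
   classifier (logistic regression, SVM, or Gaussian naive Bayes) is fitted
   on the selected activities. The reproducibility power
   `Cscore = (1/N) Σ F(P_train)·F(P_test)` diagnoses how well a selected
   pathway's signal replicates in an independent dataset.

Evaluation follows stratified ten-fold cross-validation (fold-safe by
default: weights and selection are recomputed from the training folds only)
and between-dataset train/test runs, reporting macro one-vs-rest AUC.

A deterministic synthetic-data generator (`pathwalk.simulate`) produces
multiclass expression matrices with signal planted in known pathways, a
matching GMT file and a sparse directed graph, so the whole pipeline is
testable without any download.

## Worked example

```python
import pathwalk as pw

sim = pw.SimConfig(n_genes=500, n_samples_per_class=[20]*3, n_pathways=50,
                   pathway_size=(5, 12), n_informative_pathways=8,
                   effect_size=2.0, seed=42)
expr, classes, pathways, graph, truth = pw.generate(sim)

model = pw.EDRWModel(expr, classes, pathways, graph,
                     config=pw.RunConfig(top_n=10, seed=0))
res = model.fit()
print(res.summary())

cv = pw.cv_within(expr, classes, pathways, graph,
                  config=pw.RunConfig(top_n=10, folds=5, repeats=2, seed=0))
print(f"planted pathways recovered: {len(set(res.selected_pathways) & truth)}/{len(truth)}")
print(f"mean macro one-vs-rest AUC (5-fold CV, 2 repeats): {cv.mean_auc:.4f}")
```

Output:

```
Pathway-activity random-walk classification
==============================================
genes (post-collapse):     500
samples / classes:         60 / 3
graph nodes / edges:       500 / 1495
gene statistic:            anova_f
restart probability r:     0.7
pathways in / with signal: 50 / 40
pathways selected (top-N): 10
classifier:                logistic_regression

top pathways by training |F| of activity:
     1  PW0031           F=1381
     2  PW0024           F=1332
     3  PW0011           F=973.9
     ...
planted pathways recovered: 8/8
mean macro one-vs-rest AUC (5-fold CV, 2 repeats): 1.0000
```

Ten of the 50 pathways are selected; all 8 pathways carrying planted
class-specific mean shifts rank at the top by the F statistic of their
activity rows, and the held-out folds are classified perfectly — the
planted effect (2 sd shifts on every member gene) is deliberately strong.
`pathways in / with signal: 50 / 40` means 10 pathways had no member gene
with `p < 0.05` and were dropped before ranking.

The same pipeline runs from the shell:

```sh
pathwalk simulate --seed 42 --out data/
pathwalk run --expression data/expression.tsv --labels data/labels.tsv \
             --pathways data/pathways.gmt --graph data/graph.tsv --out run/
```

which writes the diffused gene weights, per-gene statistics, the
pathway-activity matrix, the ranking table with the selected flag, and a
JSON/TSV evaluation report under `run/`.

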