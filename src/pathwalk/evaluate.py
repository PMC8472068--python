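"""Classification protocol: stratified k-fold cross-validation within a
dataset, train/test evaluation between datasets, and macro one-vs-rest AUC.

The default cross-validation is fold-safe: gene statistics, walk weights,
pathway activities and the top-N selection are recomputed from the training
folds only, and the held-out fold is projected through them, so no held-out
label can influence the features. The ``transductive`` flag reproduces the
leaking variant (whole-dataset weighting) for comparison runs only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .config import RunConfig
from .io_formats import DirectedGeneGraph, ExpressionMatrix, PathwaySet, SampleClasses
from .model import (
    _feature_matrix,
    fit_pipeline,
    make_classifier,
    project_activity,
    rank_and_select,
    score_matrix,
)
from .netwalk import build_transition
from .pathway_activity import reproducibility_power
from .preprocess import collapse_gene_ids, zscore_normalize

logger = logging.getLogger(__name__)

__all__ = ["EvalResult", "macro_ovr_auc", "cv_within", "eval_between"]


@dataclass
class EvalResult:
    """Per-fold AUCs and their mean for one protocol run."""

    fold_aucs: list
    classifier: str
    protocol: str  # within | between
    repeats: int
    seed: int
    extras: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "classifier": self.classifier,
            "repeats": self.repeats,
            "seed": self.seed,
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": self.mean_auc,
            **self.extras,
        }


def macro_ovr_auc(scores: np.ndarray, truth: SampleClasses, sample_ids,
                  class_order=None) -> float:
    """Unweighted macro one-vs-rest AUC from a per-class score matrix.

    Columns of ``scores`` align with ``class_order`` (default: the truth's
    class order). Ties in scores follow the midrank convention; the binary
    case reduces to the standard two-class AUC.
    """
    order = list(class_order) if class_order is not None else list(truth.class_order)
    if scores.shape != (len(sample_ids), len(order)):
        raise ValueError("score matrix shape does not match samples x classes")
    y = truth.labels_for(sample_ids)
    aucs = []
    for j, c in enumerate(order):
        pos = y == c
        if not pos.any():
            raise ValueError(f"class {c!r} absent from truth labels")
        aucs.append(roc_auc_score(pos, scores[:, j]))
    return float(np.mean(aucs))


def _prepare(expression: ExpressionMatrix) -> ExpressionMatrix:
    clean = collapse_gene_ids(expression)
    return clean if clean.normalized else zscore_normalize(clean)


def _effective_folds(classes: SampleClasses, k: int) -> int:
    smallest = min(classes.label_counts().values())
    if smallest < k:
        logger.warning("smallest class has %d samples; reducing folds %d -> %d",
                       smallest, k, smallest)
        return smallest
    return k


def cv_within(
    expression: ExpressionMatrix,
    classes: SampleClasses,
    pathways: PathwaySet,
    graph: DirectedGeneGraph,
    config: RunConfig | None = None,
) -> EvalResult:
    """Repeated stratified k-fold cross-validation of the full pipeline.

    Each repeat reshuffles fold assignments with a seed derived from
    ``config.seed``; results are deterministic given the seed. The whole
    dataset is z-normalized once (per-dataset normalization), then every
    downstream stage is fold-local unless ``transductive`` is set.
    """
    cfg = (config or RunConfig()).resolved()
    Z = _prepare(expression)
    transition = build_transition(graph)
    labels = classes.labels_for(Z.sample_ids)
    k = _effective_folds(classes, cfg.folds)

    trans_fit = None
    if cfg.transductive:
        trans_fit = fit_pipeline(Z, classes, pathways, transition, graph, cfg,
                                 fit_classifier=False)

    rng = np.random.default_rng(cfg.seed)
    fold_aucs = []
    for _ in range(cfg.repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
            train_ids = [Z.sample_ids[i] for i in train_idx]
            test_ids = [Z.sample_ids[i] for i in test_idx]
            Z_train = Z.subset_samples(train_ids)
            Z_test = Z.subset_samples(test_ids)
            cls_train = classes.subset(train_ids, min_class_size=2)

            if cfg.transductive:
                fitted = trans_fit
                X = _feature_matrix(fitted.activity, fitted.feature_pathways)
                row = {s: i for i, s in enumerate(fitted.activity.sample_ids)}
                clf = make_classifier(cfg.classifier, seed=rep_seed)
                clf.fit(X[[row[s] for s in train_ids]], labels[train_idx])
                import dataclasses
                fitted = dataclasses.replace(fitted, classifier=clf)
                act_test = fitted.activity  # whole-dataset activities
                idx = [row[s] for s in test_ids]
                scores = score_matrix(
                    fitted,
                    type(act_test)(act_test.pathway_ids, test_ids,
                                   act_test.values[:, idx], act_test.contributing),
                )
            else:
                fitted = fit_pipeline(Z_train, cls_train, pathways, transition,
                                      graph, cfg)
                act_test = project_activity(fitted, Z_test, graph)
                scores = score_matrix(fitted, act_test)

            auc = macro_ovr_auc(scores, classes.subset(test_ids), test_ids,
                                class_order=fitted.class_order)
            fold_aucs.append(auc)
    return EvalResult(fold_aucs, cfg.classifier, "within", cfg.repeats, cfg.seed)


def eval_between(
    train_expression: ExpressionMatrix,
    train_classes: SampleClasses,
    test_expression: ExpressionMatrix,
    test_classes: SampleClasses,
    pathways: PathwaySet,
    graph: DirectedGeneGraph,
    config: RunConfig | None = None,
) -> EvalResult:
    """Train on one full dataset, score another; returns AUC plus Cscore.

    Gene universes are intersected; each dataset is z-normalized
    independently; classes not shared by both label sets are dropped with a
    warning (at least 2 must remain).
    """
    cfg = (config or RunConfig()).resolved()
    Z_train = _prepare(train_expression)
    Z_test = _prepare(test_expression)
    shared_genes = [g for g in Z_train.gene_ids if g in set(Z_test.gene_ids)]
    if not shared_genes:
        raise ValueError("empty gene intersection between datasets")
    gi_tr, gi_te = Z_train.gene_index(), Z_test.gene_index()
    Z_train = ExpressionMatrix(shared_genes, Z_train.sample_ids,
                               Z_train.values[[gi_tr[g] for g in shared_genes]], True)
    Z_test = ExpressionMatrix(shared_genes, Z_test.sample_ids,
                              Z_test.values[[gi_te[g] for g in shared_genes]], True)

    shared = sorted(set(train_classes.class_order) & set(test_classes.class_order))
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared classes between datasets")
    dropped = (set(train_classes.class_order) | set(test_classes.class_order)) - set(shared)
    if dropped:
        logger.warning("dropping non-shared classes: %s", sorted(dropped))
        keep_tr = [s for s in Z_train.sample_ids if train_classes.labels[s] in shared]
        keep_te = [s for s in Z_test.sample_ids if test_classes.labels[s] in shared]
        Z_train = Z_train.subset_samples(keep_tr)
        Z_test = Z_test.subset_samples(keep_te)
        train_classes = train_classes.subset(keep_tr, min_class_size=2)
        test_classes = test_classes.subset(keep_te)

    transition = build_transition(graph)
    fitted = fit_pipeline(Z_train, train_classes, pathways, transition, graph, cfg)
    act_test = project_activity(fitted, Z_test, graph)
    scores = score_matrix(fitted, act_test)
    auc = macro_ovr_auc(scores, test_classes.subset(act_test.sample_ids),
                        act_test.sample_ids, class_order=fitted.class_order)
    test_rank = rank_and_select(act_test, test_classes.subset(act_test.sample_ids),
                                N=len(act_test.pathway_ids))
    cscore = reproducibility_power(fitted.ranking, fitted.ranking.f_statistic,
                                   test_rank.f_statistic)
    return EvalResult([auc], cfg.classifier, "between", 1, cfg.seed,
                      extras={"cscore": cscore})
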