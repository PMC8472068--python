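"""Model/Results interface over the full pipeline.

``EDRWModel`` bundles one dataset (expression, class labels, pathway sets,
directed gene graph) with a :class:`~pathwalk.config.RunConfig`; ``fit()``
runs pre-processing, per-gene statistics, initial weighting, the random walk
with restart, pathway activity inference, pathway ranking/selection, and
fits the configured classifier on the selected pathway activities. The
returned :class:`EDRWResults` projects new datasets through the trained
weights/selection, scores them, and prints a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .config import RunConfig
from .diffexpr import STATISTICS, GeneStatTable
from .io_formats import (
    DirectedGeneGraph,
    ExpressionMatrix,
    PathwaySet,
    SampleClasses,
    read_edge_list,
    read_expression,
    read_gmt,
    read_labels,
)
from .netwalk import TransitionMatrix, WeightVector, build_transition, initial_weights, \
    random_walk_with_restart
from .pathway_activity import (
    ActivityMatrix,
    PathwayRanking,
    contributing_genes,
    infer_activity_matrix,
    pathway_activity,
    rank_and_select,
    reproducibility_power,
)
from .preprocess import collapse_gene_ids, zscore_normalize

__all__ = ["EDRWModel", "EDRWResults"]


def make_classifier(name: str, seed: int = 0):
    if name == "logistic_regression":
        return LogisticRegression(max_iter=2000)
    if name == "svm":
        # Platt-calibrated decision values so every classifier yields class
        # probabilities for the one-vs-rest AUC
        return SVC(probability=True, random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class FittedPipeline:
    """Training-derived state sufficient to project and score a new dataset."""

    gene_stats: GeneStatTable
    w0: WeightVector
    w_inf: WeightVector
    activity: ActivityMatrix
    ranking: PathwayRanking
    feature_pathways: list  # selected pathways present in the activity matrix
    classifier: object
    class_order: list
    config: RunConfig


def fit_pipeline(
    Z: ExpressionMatrix,
    classes: SampleClasses,
    pathways: PathwaySet,
    transition: TransitionMatrix,
    graph: DirectedGeneGraph,
    config: RunConfig,
    fit_classifier: bool = True,
) -> FittedPipeline:
    """Statistics -> weights -> walk -> activity -> selection -> classifier."""
    cfg = config.resolved()
    stats = STATISTICS[cfg.stat](Z, classes)
    w0 = initial_weights(stats, graph)
    w_inf = random_walk_with_restart(transition, w0, r=cfg.r, tol=cfg.tol,
                                     max_iter=cfg.max_iter)
    activity = infer_activity_matrix(pathways, w_inf, stats, Z, graph, alpha=cfg.alpha)
    ranking = rank_and_select(activity, classes, N=cfg.top_n)
    feature_pathways = list(ranking.selected)
    clf = None
    if fit_classifier:
        X = _feature_matrix(activity, feature_pathways)
        y = classes.labels_for(activity.sample_ids)
        clf = make_classifier(cfg.classifier, seed=cfg.seed)
        clf.fit(X, y)
    return FittedPipeline(stats, w0, w_inf, activity, ranking, feature_pathways,
                          clf, list(classes.class_order), cfg)


def _feature_matrix(activity: ActivityMatrix, pathway_ids) -> np.ndarray:
    idx = {p: i for i, p in enumerate(activity.pathway_ids)}
    return activity.values[[idx[p] for p in pathway_ids], :].T


def project_activity(fitted: FittedPipeline, Z_test: ExpressionMatrix,
                     graph: DirectedGeneGraph) -> ActivityMatrix:
    """Test-set activities from training weights, statistics and gene selections.

    The test data contributes only its z values; gene significance and walk
    weights come from training so no test label information is used.
    """
    test_genes = set(Z_test.gene_index())
    rows, pids, contrib = [], [], {}
    for pid in fitted.activity.pathway_ids:
        genes = [g for g in fitted.activity.contributing[pid] if g in test_genes]
        if not genes:
            continue
        rows.append(pathway_activity(genes, fitted.w_inf, fitted.gene_stats, Z_test))
        pids.append(pid)
        contrib[pid] = genes
    if not pids:
        raise ValueError("no training pathway projects onto the test dataset")
    return ActivityMatrix(pids, list(Z_test.sample_ids), np.vstack(rows), contrib)


def score_matrix(fitted: FittedPipeline, activity: ActivityMatrix) -> np.ndarray:
    """Per-sample per-class probability scores, columns in class_order.

    Pathways selected in training but missing from the projected activity are
    zero-filled (their training activity is centred near zero).
    """
    idx = {p: i for i, p in enumerate(activity.pathway_ids)}
    X = np.zeros((len(activity.sample_ids), len(fitted.feature_pathways)))
    for j, pid in enumerate(fitted.feature_pathways):
        if pid in idx:
            X[:, j] = activity.values[idx[pid], :]
    proba = fitted.classifier.predict_proba(X)
    cols = {c: i for i, c in enumerate(fitted.classifier.classes_)}
    order = [cols[c] for c in fitted.class_order]
    return proba[:, order]


class EDRWModel:
    """Pathway-activity classification model for one expression dataset.

    Parameters
    ----------
    expression : ExpressionMatrix
        Raw (or already normalized) genes x samples matrix.
    classes : SampleClasses
        Sample class labels; at least two classes with >= 2 samples each.
    pathways : PathwaySet
        Gene-set membership (GMT-style).
    graph : DirectedGeneGraph
        Directed gene-interaction graph over (a superset of) the gene universe.
    config : RunConfig, optional
    """

    def __init__(self, expression, classes, pathways, graph, config=None):
        self.config = (config or RunConfig()).resolved()
        clean = collapse_gene_ids(expression)
        self.expression = clean if clean.normalized else zscore_normalize(clean)
        self.classes = classes
        self.pathways = pathways
        self.graph = graph
        self.transition = build_transition(graph)

    @classmethod
    def from_files(cls, expression_path, labels_path, gmt_path, edges_path,
                   config=None, id_column: str = "gene_id") -> "EDRWModel":
        return cls(
            read_expression(expression_path, id_column=id_column),
            read_labels(labels_path),
            read_gmt(gmt_path),
            read_edge_list(edges_path),
            config=config,
        )

    def fit(self) -> "EDRWResults":
        fitted = fit_pipeline(self.expression, self.classes, self.pathways,
                              self.transition, self.graph, self.config)
        return EDRWResults(self, fitted)


class EDRWResults:
    """Fitted pipeline state: gene statistics, walk weights, pathway
    activities, ranking/selection, and the trained classifier."""

    def __init__(self, model: EDRWModel, fitted: FittedPipeline):
        self.model = model
        self._fitted = fitted
        self.gene_stats = fitted.gene_stats
        self.initial_weights = fitted.w0
        self.walk_weights = fitted.w_inf
        self.activity = fitted.activity
        self.ranking = fitted.ranking
        self.selected_pathways = list(fitted.ranking.selected)
        self.classifier = fitted.classifier

    def transform(self, expression: ExpressionMatrix) -> ActivityMatrix:
        """Project a new dataset onto training-derived pathway activities."""
        clean = collapse_gene_ids(expression)
        Z = clean if clean.normalized else zscore_normalize(clean)
        return project_activity(self._fitted, Z, self.model.graph)

    def predict_proba(self, expression: ExpressionMatrix) -> np.ndarray:
        return score_matrix(self._fitted, self.transform(expression))

    def evaluate(self, expression: ExpressionMatrix, classes: SampleClasses) -> dict:
        """Macro one-vs-rest AUC and Cscore on an independent dataset."""
        from .evaluate import macro_ovr_auc  # local import avoids a cycle

        activity = self.transform(expression)
        scores = score_matrix(self._fitted, activity)
        auc = macro_ovr_auc(scores, classes.subset(activity.sample_ids),
                            activity.sample_ids, class_order=self._fitted.class_order)
        test_rank = rank_and_select(activity, classes.subset(activity.sample_ids),
                                    N=len(activity.pathway_ids))
        cscore = reproducibility_power(self.ranking, self.ranking.f_statistic,
                                       test_rank.f_statistic)
        return {"auc": auc, "cscore": cscore}

    def summary(self) -> str:
        cfg = self._fitted.config
        lines = [
            "Pathway-activity random-walk classification",
            "=" * 46,
            f"genes (post-collapse):     {self.model.expression.n_genes}",
            f"samples / classes:         {self.model.expression.n_samples} / "
            f"{len(self.model.classes.class_order)}",
            f"graph nodes / edges:       {self.model.graph.n_nodes} / {self.model.graph.n_edges}",
            f"gene statistic:            {self.gene_stats.statistic_kind}",
            f"restart probability r:     {cfg.r}",
            f"pathways in / with signal: {len(self.model.pathways)} / "
            f"{len(self.activity.pathway_ids)}",
            f"pathways selected (top-N): {len(self.selected_pathways)}",
            f"classifier:                {cfg.classifier}",
            "",
            "top pathways by training |F| of activity:",
        ]
        for pid in self.selected_pathways[:10]:
            lines.append(f"  {self.ranking.rank[pid]:>4}  {pid:<16} "
                         f"F={self.ranking.f_statistic[pid]:.4g}")
        return "\n".join(lines)
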