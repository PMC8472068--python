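"""Pathway activity inference, ranking, selection, and reproducibility power.

A pathway's per-sample activity is the weighted, sign-carrying combination of
its significant member genes' z-scores:

    a(s) = sum_i w(g_i) * sgn(F(g_i)) * z_{g_i}(s) / sqrt(sum_i w(g_i)^2)

where w is the diffused (random-walk) gene weight and only genes with raw
p < alpha that are present in both the dataset and the graph contribute. With
a nonnegative F statistic the sgn() term is identically +1; it becomes active
in the signed t-statistic (binary baseline) mode. sgn(0) := +1.

Pathways are ranked by the absolute one-way ANOVA F of their activity rows in
the training data and the top N are selected. The reproducibility power
Cscore = mean over selected pathways of F_train * F_test diagnoses whether a
selected pathway's discriminative signal replicates in an independent dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .diffexpr import GeneStatTable, anova_f_per_gene
from .io_formats import DirectedGeneGraph, ExpressionMatrix, PathwaySet, SampleClasses
from .netwalk import WeightVector

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityMatrix",
    "PathwayRanking",
    "contributing_genes",
    "pathway_activity",
    "infer_activity_matrix",
    "rank_and_select",
    "reproducibility_power",
]


@dataclass
class ActivityMatrix:
    """Pathways x samples activity scores with per-pathway contributing genes."""

    pathway_ids: list
    sample_ids: list
    values: np.ndarray
    contributing: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pathway_ids), len(self.sample_ids)):
            raise ValueError("activity shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity values must be finite")
        for pid in self.pathway_ids:
            if not self.contributing.get(pid):
                raise ValueError(f"pathway {pid} has no contributing genes")

    def to_expression(self) -> ExpressionMatrix:
        """View as an ExpressionMatrix so per-row statistics apply directly."""
        return ExpressionMatrix(
            list(self.pathway_ids), list(self.sample_ids), self.values, normalized=False
        )


@dataclass
class PathwayRanking:
    """Pathways ordered by training |F| with a selected top-N flag."""

    pathway_ids: list  # in rank order (rank 1 first)
    f_statistic: dict  # pathway_id -> F on activity rows
    rank: dict  # pathway_id -> 1-based rank
    selected: list  # pathway_ids flagged selected, in rank order
    n_requested: int

    def rows(self):
        for pid in self.pathway_ids:
            yield pid, self.f_statistic[pid], self.rank[pid], pid in self._selected_set

    @property
    def _selected_set(self) -> set:
        return set(self.selected)


def contributing_genes(
    pathway_genes,
    stats: GeneStatTable,
    graph: DirectedGeneGraph,
    data_genes,
    alpha: float = 0.05,
) -> list:
    """Pathway genes with raw p < alpha, present in the data and the graph.

    Order follows the pathway's member order; an empty result is legal and
    means the pathway is dropped from the activity matrix.
    """
    pvals = dict(zip(stats.gene_ids, stats.p_value))
    data_genes = set(data_genes)
    out = []
    n_off_graph = 0
    for g in pathway_genes:
        if g not in data_genes or g not in pvals or not (pvals[g] < alpha):
            continue
        if g not in graph.nodes:
            n_off_graph += 1
            continue
        out.append(g)
    if n_off_graph:
        logger.debug("%d significant pathway genes absent from graph, excluded", n_off_graph)
    return out


def _signs(stats: GeneStatTable, genes) -> np.ndarray:
    stat = dict(zip(stats.gene_ids, stats.statistic))
    # sgn(0) := +1; for nonnegative F statistics this is identically +1
    return np.array([-1.0 if stat[g] < 0 else 1.0 for g in genes])


def pathway_activity(
    genes, Winf: WeightVector, stats: GeneStatTable, Z: ExpressionMatrix
) -> np.ndarray:
    """Activity row over samples for one pathway's contributing genes.

    Invariant under positive rescaling of the whole weight vector.
    """
    if not genes:
        raise ValueError("empty gene list")
    wmap = Winf.by_node()
    w = np.array([wmap[g] for g in genes])
    norm = np.sqrt((w**2).sum())
    if norm == 0:
        raise ValueError("pathway has no diffused weight")
    gi = Z.gene_index()
    zrows = Z.values[[gi[g] for g in genes], :]
    sgn = _signs(stats, genes)
    return (w * sgn) @ zrows / norm


def infer_activity_matrix(
    pathways: PathwaySet,
    Winf: WeightVector,
    stats: GeneStatTable,
    Z: ExpressionMatrix,
    graph: DirectedGeneGraph,
    alpha: float = 0.05,
) -> ActivityMatrix:
    """Activity rows for every pathway with significant, weighted genes.

    Pathways without significant genes (or whose genes all carry zero diffused
    weight) are dropped; input pathway order is preserved.
    """
    gi = set(Z.gene_index())
    wmap = Winf.by_node()
    rows, pids, contrib = [], [], {}
    for pid in pathways:
        genes = contributing_genes(pathways.members(pid), stats, graph, gi, alpha)
        if not genes:
            continue
        if all(wmap[g] == 0 for g in genes):
            logger.warning("pathway %s dropped: contributing genes all have zero weight", pid)
            continue
        rows.append(pathway_activity(genes, Winf, stats, Z))
        pids.append(pid)
        contrib[pid] = genes
    if not pids:
        raise ValueError("no pathway survived the significance filter")
    n_dropped = len(pathways) - len(pids)
    if n_dropped:
        logger.info("%d of %d pathways dropped (no contributing genes)", n_dropped, len(pathways))
    return ActivityMatrix(pids, list(Z.sample_ids), np.vstack(rows), contrib)


def rank_and_select(
    train_activity: ActivityMatrix, classes: SampleClasses, N: int = 100
) -> PathwayRanking:
    """Rank pathways by |F| of their activity rows (one-way ANOVA), select top N.

    Ties break by pathway_id ascending; N clamps to the number of pathways.
    """
    stats = anova_f_per_gene(train_activity.to_expression(), classes)
    absF = np.abs(stats.statistic)
    order = sorted(
        range(len(train_activity.pathway_ids)),
        key=lambda i: (-absF[i], train_activity.pathway_ids[i]),
    )
    pids = [train_activity.pathway_ids[i] for i in order]
    f_by_pid = {train_activity.pathway_ids[i]: float(stats.statistic[i]) for i in order}
    rank = {pid: r for r, pid in enumerate(pids, start=1)}
    n_sel = min(N, len(pids))
    return PathwayRanking(pids, f_by_pid, rank, pids[:n_sel], N)


def reproducibility_power(ranking: PathwayRanking, train_F: dict, test_F: dict) -> float:
    """Cscore = mean over selected pathways of F_train * F_test.

    Selected pathways absent from the test activity are skipped (N reduced);
    zero overlap is an error.
    """
    terms = [
        train_F[pid] * test_F[pid]
        for pid in ranking.selected
        if pid in train_F and pid in test_F
    ]
    if not terms:
        raise ValueError("no selected pathway has an F statistic in both datasets")
    n_skipped = len(ranking.selected) - len(terms)
    if n_skipped:
        logger.info("Cscore computed over %d pathways (%d skipped)", len(terms), n_skipped)
    return float(np.mean(terms))
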