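"""Deterministic synthetic multiclass expression datasets with planted
pathway-level signal, plus a matching gene-set collection and a sparse
directed gene graph.

The generator emulates the statistical structure the pipeline is designed to
detect: i.i.d. Gaussian baseline expression, a handful of "informative"
pathways whose member genes receive class-specific additive mean shifts of
magnitude ``effect_size`` (in noise-sd units; each informative pathway gets
its own random permutation of equally spaced per-class levels), and a random
sparse directed graph over the whole gene universe in which every informative
gene is guaranteed at least one edge so diffusion can reach it. It does not
emulate probe effects, batch structure, gene-gene correlation, or curated
pathway topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    DirectedGeneGraph,
    ExpressionMatrix,
    PathwaySet,
    SampleClasses,
    write_edge_list,
    write_expression,
    write_gmt,
    write_labels,
)

__all__ = ["SimConfig", "generate", "reference_study_config", "write_dataset"]


@dataclass
class SimConfig:
    """Synthetic-dataset settings; defaults are the package's reference
    study conditions (5 balanced classes of 40 samples, 2000 genes, 200
    pathways of 10-30 genes, 20 informative, shift magnitude 2 sd)."""

    n_genes: int = 2000
    n_samples_per_class: list = field(default_factory=lambda: [40] * 5)
    n_pathways: int = 200
    pathway_size: tuple = (10, 30)
    n_informative_pathways: int = 20
    effect_size: float = 2.0
    noise_sd: float = 1.0
    graph_edges_per_node: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_informative_pathways > self.n_pathways:
            raise ValueError("more informative pathways than pathways")
        if min(self.n_genes, self.n_pathways, *self.n_samples_per_class) <= 0:
            raise ValueError("all counts must be positive")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if self.pathway_size[1] > self.n_genes:
            raise ValueError("pathway size exceeds gene count")


def reference_study_config(seed: int = 0) -> SimConfig:
    """A configuration echoing a published breast-cancer study design at desk
    scale: 4 unbalanced classes (62/25/15/37 samples), 300 gene sets, ~4000
    graph genes with mean out-degree ~10."""
    return SimConfig(
        n_genes=4000,
        n_samples_per_class=[62, 25, 15, 37],
        n_pathways=300,
        pathway_size=(10, 40),
        n_informative_pathways=30,
        effect_size=2.0,
        noise_sd=1.0,
        graph_edges_per_node=10.0,
        seed=seed,
    )


def generate(config: SimConfig):
    """Generate (expression, classes, pathways, graph, informative-pathway IDs).

    Fully reproducible from ``config.seed``; returned expression is raw
    (``normalized=False``).
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    k = len(config.n_samples_per_class)
    gene_ids = [str(10001 + i) for i in range(n_genes)]

    sample_ids, labels = [], {}
    for c, n_c in enumerate(config.n_samples_per_class):
        for j in range(n_c):
            sid = f"S{c}_{j:03d}"
            sample_ids.append(sid)
            labels[sid] = f"C{c}"
    classes = SampleClasses(labels)
    class_of = np.array([int(labels[s][1:]) for s in sample_ids])

    values = rng.normal(0.0, config.noise_sd, size=(n_genes, len(sample_ids)))

    # random gene-set membership
    lo, hi = config.pathway_size
    pathways: dict = {}
    pids = [f"PW{i:04d}" for i in range(config.n_pathways)]
    for pid in pids:
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        pathways[pid] = (f"synthetic pathway {pid}", [gene_ids[g] for g in members])
    informative = sorted(rng.choice(pids, size=config.n_informative_pathways,
                                    replace=False).tolist())

    # plant class-specific mean shifts on informative pathways' genes:
    # equally spaced per-class levels of magnitude effect_size, permuted
    # independently per pathway
    base_levels = (np.linspace(-1.0, 1.0, k) if k > 1 else np.array([1.0]))
    gidx = {g: i for i, g in enumerate(gene_ids)}
    informative_genes: set = set()
    for pid in informative:
        levels = config.effect_size * rng.permutation(base_levels)
        rows = [gidx[g] for g in pathways[pid][1]]
        informative_genes.update(rows)
        values[np.ix_(rows, np.arange(len(sample_ids)))] += levels[class_of][None, :]

    # sparse random directed graph over all genes
    n_edges = int(round(n_genes * config.graph_edges_per_node))
    src = rng.integers(0, n_genes, size=n_edges)
    tgt = rng.integers(0, n_genes, size=n_edges)
    edge_set = {(int(u), int(v)) for u, v in zip(src, tgt) if u != v}
    covered = {u for u, _ in edge_set} | {v for _, v in edge_set}
    for g in sorted(informative_genes - covered):
        v = int(rng.integers(0, n_genes))
        while v == g:
            v = int(rng.integers(0, n_genes))
        edge_set.add((g, v))
    edges = [(gene_ids[u], gene_ids[v]) for u, v in sorted(edge_set)]
    graph = DirectedGeneGraph(set(gene_ids), edges)

    expr = ExpressionMatrix(gene_ids, sample_ids, values, normalized=False)
    return expr, classes, PathwaySet(pathways), graph, set(informative)


def write_dataset(config: SimConfig, out_dir) -> dict:
    """Generate and write expression/labels/GMT/edges/truth files; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, classes, pathways, graph, truth = generate(config)
    paths = {
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "pathways": out / "pathways.gmt",
        "graph": out / "graph.tsv",
        "truth": out / "informative_pathways.tsv",
    }
    write_expression(expr, paths["expression"])
    write_labels(classes, paths["labels"])
    write_gmt(pathways, paths["pathways"])
    write_edge_list(graph, paths["graph"])
    with open(paths["truth"], "w") as fh:
        for pid in sorted(truth):
            fh.write(pid + "\n")
    return {k: str(v) for k, v in paths.items()}
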