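"""Domain types and on-disk formats.

All artifacts are plain tab-separated text: expression matrices (header row of
sample IDs, one identifier column of Entrez IDs), two-column label tables,
Broad GMT gene sets, and two-column directed edge lists. Gene identifiers are
handled as opaque strings throughout so non-numeric IDs in synthetic fixtures
work unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleClasses",
    "PathwaySet",
    "DirectedGeneGraph",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_activity",
    "write_activity",
    "write_ranking",
]

#: marker used internally for a blank/NA Entrez ID in a raw matrix
MISSING_ID = None


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    ``gene_ids`` may contain ``None`` entries (missing Entrez IDs) only while
    the matrix is raw; preprocessing removes them. ``normalized`` flags whether
    rows have been z-scored.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no missing cells)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids) if g is not None}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=["" if g is None else g for g in self.gene_ids],
            columns=self.sample_ids,
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, cols], self.normalized
        )


@dataclass
class SampleClasses:
    """Mapping sample -> class label with a deterministic class order."""

    labels: dict
    class_order: list = field(default_factory=list)
    #: minimum samples per class; 2 is required wherever within-class variance
    #: is computed, but truth subsets (e.g. held-out folds) may relax it to 1
    min_class_size: int = 2

    def __post_init__(self):
        if not self.class_order:
            self.class_order = sorted(set(self.labels.values()))
        counts = self.label_counts()
        if len(counts) < 2:
            raise ValueError("need at least 2 distinct class labels")
        small = [c for c, n in counts.items() if n < self.min_class_size]
        if small:
            raise ValueError(
                f"classes with fewer than {self.min_class_size} samples: {small}"
            )

    def label_counts(self) -> dict:
        counts: dict = {}
        for lab in self.labels.values():
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    def labels_for(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise KeyError(f"samples without class labels: {missing[:5]}")
        return np.array([self.labels[s] for s in sample_ids])

    def subset(self, sample_ids, min_class_size: int = 1) -> "SampleClasses":
        return SampleClasses(
            {s: self.labels[s] for s in sample_ids},
            [c for c in self.class_order if any(self.labels[s] == c for s in sample_ids)],
            min_class_size,
        )


@dataclass
class PathwaySet:
    """pathway_id -> (name, member gene list); members deduplicated on read."""

    pathways: dict

    def __post_init__(self):
        for pid, (name, genes) in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {pid} has no member genes")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def members(self, pathway_id) -> list:
        return self.pathways[pathway_id][1]

    def name(self, pathway_id) -> str:
        return self.pathways[pathway_id][0]


@dataclass
class DirectedGeneGraph:
    """Directed gene-interaction graph: node set plus ordered edge pairs."""

    nodes: set
    edges: list

    def __post_init__(self):
        self.nodes = set(self.nodes)
        seen = set()
        for (u, v) in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u},{v}) has endpoint outside node set")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge ({u},{v})")
            seen.add((u, v))
            if u == v:
                logger.info("self-loop on node %s", u)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path, id_column: str = "gene_id") -> ExpressionMatrix:
    """Read a tab-separated expression matrix (raw, ``normalized=False``).

    The first row holds sample IDs; ``id_column`` names the Entrez-ID column.
    Blank/NA identifiers are preserved as missing so that preprocessing can
    drop them. Non-numeric expression cells raise with row/column location.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header.count(id_column) != 1:
        raise ValueError(f"{path}: identifier column {id_column!r} not found exactly once")
    raw_samples = [c for c in header if c != id_column]
    if len(set(raw_samples)) != len(raw_samples):
        raise ValueError(f"{path}: duplicate sample IDs in header")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    sample_ids = [c for c in df.columns if c != id_column]
    gene_ids = [
        None if g.strip() in ("", "NA", "na", "NaN") else g.strip()
        for g in df[id_column]
    ]
    values = np.empty((len(gene_ids), len(sample_ids)), dtype=float)
    for j, col in enumerate(sample_ids):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna())[0])
            raise ValueError(
                f"{path}: non-numeric expression value at row {row + 2}, column {col!r}"
            ) from None
    return ExpressionMatrix(gene_ids, sample_ids, values, normalized=False)


def write_expression(X: ExpressionMatrix, path, id_column: str = "gene_id") -> None:
    df = X.to_frame()
    df.index.name = id_column
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_labels(path) -> SampleClasses:
    """Read a two-column sample_id<TAB>class table (no header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 tab-separated columns")
    if df[0].duplicated().any():
        dup = df[0][df[0].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    return SampleClasses(dict(zip(df[0], df[1])))


def write_labels(classes: SampleClasses, path) -> None:
    with open(path, "w") as fh:
        for s, lab in classes.labels.items():
            fh.write(f"{s}\t{lab}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT) and graphs


def read_gmt(path) -> PathwaySet:
    """Read a Broad GMT file: name, description, then member genes.

    Duplicate genes within one line are collapsed (first occurrence kept).
    """
    pathways: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
            pid, name = fields[0], fields[1]
            if pid in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway ID {pid!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise ValueError(f"{path}:{lineno}: pathway {pid!r} has no genes")
            pathways[pid] = (name, members)
    return PathwaySet(pathways)


def write_gmt(ps: PathwaySet, path) -> None:
    with open(path, "w") as fh:
        for pid in ps:
            name, genes = ps.pathways[pid]
            fh.write("\t".join([pid, name, *genes]) + "\n")


def read_edge_list(path) -> DirectedGeneGraph:
    """Read a two-column TSV of directed edges (source -> target).

    Duplicate lines are collapsed with a logged count; an empty file yields an
    empty graph with a warning.
    """
    edges: list = []
    seen: set = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{lineno}: malformed edge line")
            e = (fields[0], fields[1])
            if e in seen:
                n_dup += 1
                continue
            seen.add(e)
            edges.append(e)
    if n_dup:
        logger.info("%s: collapsed %d duplicate edge lines", path, n_dup)
    if not edges:
        logger.warning("%s: empty edge list -> empty graph", path)
    nodes = {u for u, _ in edges} | {v for _, v in edges}
    return DirectedGeneGraph(nodes, edges)


def write_edge_list(graph: DirectedGeneGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v in graph.edges:
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# derived artifacts


def write_activity(pathway_ids, sample_ids, values, path) -> None:
    df = pd.DataFrame(values, index=pathway_ids, columns=sample_ids)
    df.index.name = "pathway_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_activity(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float)


def write_ranking(ranking_rows, cscore, path) -> None:
    """Write a ranking TSV (pathway_id, F, rank, selected) with a Cscore footer."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("pathway_id\tF\trank\tselected\n")
        for pid, f, rank, sel in ranking_rows:
            fh.write(f"{pid}\t{f:.17g}\t{rank}\t{int(sel)}\n")
        if cscore is not None:
            fh.write(f"# Cscore\t{cscore:.17g}\n")
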