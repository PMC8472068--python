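"""Gene weighting on the directed interaction graph.

Initial weights min-max scale the absolute per-gene statistic onto [0, 1]
over graph nodes and L1-normalize to a restart distribution. The transition
matrix is the row-normalized binary adjacency augmented with one virtual
ground node: every dangling (zero out-degree) gene is wired to ground, and
ground is wired uniformly back to every real gene, so the chain is row
stochastic. A random walk with restart probability r then diffuses the
initial weights to the fixed point W = (1-r) M^T W + r W0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .diffexpr import GeneStatTable
from .io_formats import DirectedGeneGraph

logger = logging.getLogger(__name__)

__all__ = ["WeightVector", "TransitionMatrix", "initial_weights", "build_transition",
           "random_walk_with_restart"]

GROUND = "__ground__"


@dataclass
class WeightVector:
    """Probability mass over graph nodes (L1-normalized, nonnegative)."""

    node_ids: list
    mass: np.ndarray
    kind: str  # initial | stationary

    def __post_init__(self):
        self.mass = np.asarray(self.mass, dtype=float)
        if len(self.mass) != len(self.node_ids):
            raise ValueError("mass length does not match node count")
        if np.any(self.mass < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.mass.sum() - 1.0) > 1e-8:
            raise ValueError(f"weights must sum to 1 (got {self.mass.sum()})")

    def by_node(self) -> dict:
        return dict(zip(self.node_ids, self.mass))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tweight\n")
            for g, w in zip(self.node_ids, self.mass):
                fh.write(f"{g}\t{w:.17g}\n")


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix over real nodes plus one ground node.

    ``matrix`` is (n+1) x (n+1) sparse CSR; row/column n is the ground node.
    """

    node_ids: list  # real nodes only, deterministic (sorted) order
    matrix: sp.csr_matrix
    restart_probability: float = 0.7

    def __post_init__(self):
        n = len(self.node_ids) + 1
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match node count + ground")
        rowsum = np.asarray(self.matrix.sum(axis=1)).ravel()
        if np.max(np.abs(rowsum - 1.0)) > 1e-12:
            raise ValueError("transition rows must sum to 1")

    @property
    def n_real(self) -> int:
        return len(self.node_ids)


def initial_weights(stats: GeneStatTable, graph: DirectedGeneGraph) -> WeightVector:
    """Min-max scaled |statistic| over graph nodes, L1-normalized.

    raw_w = (|F| - min|F|) / (max|F| - min|F|) over graph-node genes with
    expression data; graph nodes absent from the data get 0. If all |F| are
    equal the raw weights are all 1 (uniform restart). The result sums to 1.
    """
    if not graph.nodes:
        raise ValueError("graph has no nodes")
    node_ids = sorted(graph.nodes)
    by_gene = dict(zip(stats.gene_ids, np.abs(stats.statistic)))
    has_data = np.array([g in by_gene for g in node_ids])
    if not has_data.any():
        raise ValueError("no graph node has expression data")
    absF = np.array([by_gene.get(g, 0.0) for g in node_ids])
    lo = absF[has_data].min()
    hi = absF[has_data].max()
    raw = np.zeros(len(node_ids))
    if hi == lo:
        raw[has_data] = 1.0
    else:
        raw[has_data] = (absF[has_data] - lo) / (hi - lo)
    total = raw.sum()
    if total == 0:
        raw[has_data] = 1.0
        total = raw.sum()
    return WeightVector(node_ids, raw / total, "initial")


def build_transition(graph: DirectedGeneGraph) -> TransitionMatrix:
    """Row-normalized binary adjacency with a single virtual ground node."""
    if not graph.nodes:
        raise ValueError("graph has no nodes")
    node_ids = sorted(graph.nodes)
    idx = {g: i for i, g in enumerate(node_ids)}
    n = len(node_ids)
    rows = [idx[u] for u, _ in graph.edges]
    cols = [idx[v] for _, v in graph.edges]
    data = np.ones(len(rows))
    # ground wiring: dangling real nodes -> ground; ground -> all real nodes
    outdeg = np.zeros(n)
    np.add.at(outdeg, rows, 1.0)
    dangling = np.flatnonzero(outdeg == 0)
    rows = np.concatenate([rows, dangling, np.full(n, n, dtype=int)])
    cols = np.concatenate([cols, np.full(len(dangling), n, dtype=int), np.arange(n)])
    data = np.concatenate([data, np.ones(len(dangling)), np.ones(n)])
    A = sp.csr_matrix((data, (rows, cols)), shape=(n + 1, n + 1))
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    inv = sp.diags(1.0 / rowsum)
    M = (inv @ A).tocsr()
    if len(dangling):
        logger.info("wired %d dangling nodes to the ground node", len(dangling))
    return TransitionMatrix(node_ids, M)


def random_walk_with_restart(
    M: TransitionMatrix,
    W0: WeightVector,
    r: float = 0.7,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> WeightVector:
    """Iterate W_{t+1} = (1-r) M^T W_t + r W0 to the L1 fixed point.

    The restart vector W0 lives on real nodes (zero restart mass on ground);
    after convergence the ground entry is dropped and the vector re-normalized
    over real nodes.
    """
    if not (0 < r <= 1):
        raise ValueError("restart probability r must be in (0, 1]")
    if list(W0.node_ids) != list(M.node_ids):
        raise ValueError("W0 node order does not match transition matrix")
    w0 = np.concatenate([W0.mass, [0.0]])
    MT = M.matrix.T.tocsr()
    w = w0.copy()
    for it in range(1, max_iter + 1):
        w_next = (1 - r) * (MT @ w) + r * w0
        resid = np.abs(w_next - w).sum()
        w = w_next
        if resid < tol:
            logger.debug("random walk converged in %d iterations (residual %.3g)", it, resid)
            break
    else:
        raise RuntimeError(
            f"random walk did not converge in {max_iter} iterations (last residual {resid:.3g})"
        )
    real = w[:-1]
    return WeightVector(list(M.node_ids), real / real.sum(), "stationary")


def solve_stationary(M: TransitionMatrix, W0: WeightVector, r: float = 0.7) -> np.ndarray:
    """Direct linear solve W = r (I - (1-r) M^T)^{-1} W0 over all nodes incl. ground.

    Dense; intended as an independent cross-check of the iterative walk on
    small graphs, not for production-sized graphs.
    """
    n = M.n_real + 1
    w0 = np.concatenate([W0.mass, [0.0]])
    A = np.eye(n) - (1 - r) * M.matrix.T.toarray()
    return r * np.linalg.solve(A, w0)
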