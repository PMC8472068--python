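"""Expression pre-processing: drop missing Entrez IDs, average repeated IDs,
and per-gene z-score normalization.

Normalization is always computed within one dataset; training and test
datasets in a between-dataset run are normalized independently so no test
information reaches the training side.
"""

from __future__ import annotations

import logging

import numpy as np

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["collapse_gene_ids", "zscore_normalize"]


def collapse_gene_ids(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Remove rows with missing gene IDs and average rows sharing an ID.

    Output rows keep first-occurrence order; repeated IDs collapse to the
    arithmetic mean of their rows, sample by sample. Idempotent.
    """
    keep = [i for i, g in enumerate(raw.gene_ids) if g is not None]
    if not keep:
        raise ValueError("no usable genes: every row has a missing gene ID")
    n_missing = raw.n_genes - len(keep)
    if n_missing:
        logger.info("dropped %d rows with missing gene IDs", n_missing)

    order: list = []
    groups: dict = {}
    for i in keep:
        g = raw.gene_ids[i]
        if g not in groups:
            groups[g] = []
            order.append(g)
        groups[g].append(i)

    if len(order) == len(keep) and n_missing == 0:
        return ExpressionMatrix(order, list(raw.sample_ids), raw.values.copy(), raw.normalized)

    values = np.empty((len(order), raw.n_samples), dtype=float)
    for r, g in enumerate(order):
        rows = groups[g]
        values[r] = raw.values[rows[0]] if len(rows) == 1 else raw.values[rows].mean(axis=0)
    n_rep = len(keep) - len(order)
    if n_rep:
        logger.info("averaged %d repeated gene-ID rows", n_rep)
    return ExpressionMatrix(order, list(raw.sample_ids), values, raw.normalized)


def zscore_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, unit sample sd (ddof=1).

    Zero-variance rows are set to all-zero and logged; downstream they get an
    undefined F statistic, p = 1 and weight 0.
    """
    if len(set(X.gene_ids)) != len(X.gene_ids) or None in X.gene_ids:
        raise ValueError("gene IDs must be unique and non-missing; run collapse_gene_ids first")
    if X.n_samples < 2:
        raise ValueError("z-score normalization needs at least 2 samples")
    mean = X.values.mean(axis=1, keepdims=True)
    sd = X.values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.info("%d zero-variance gene rows set to all-zero z", int(flat.sum()))
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (X.values - mean) / safe_sd
    z[flat, :] = 0.0
    return ExpressionMatrix(list(X.gene_ids), list(X.sample_ids), z, normalized=True)
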