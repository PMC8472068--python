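"""Per-gene multiclass differential-expression statistics.

Three statistics share one table contract: the one-way ANOVA F test (the
default gene-weighting statistic), Welch's heteroscedastic one-way F
(variance-robust alternative), and the pooled-variance two-sample t test
(signed; the binary-class baseline mode).

Degenerate genes -- zero variance both between and within classes -- carry
statistic 0, p-value 1, and a degenerate flag so that downstream min-max
weighting always sees finite values. A gene with between-class variance but
zero within-class variance gets the largest finite float and p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, SampleClasses

__all__ = ["GeneStatTable", "anova_f_per_gene", "welch_f_per_gene", "ttest_per_gene"]

_F_CAP = np.finfo(float).max


@dataclass
class GeneStatTable:
    """Per-gene statistic, p-value and degrees of freedom.

    ``df_within`` is per-gene for the Welch statistic (Welch-Satterthwaite)
    and constant otherwise; stored as an array either way.
    """

    gene_ids: list
    statistic: np.ndarray
    p_value: np.ndarray
    df_between: np.ndarray
    df_within: np.ndarray
    degenerate: np.ndarray
    statistic_kind: str  # anova_f | welch_f | t_equal_var

    def __post_init__(self):
        if np.any(self.p_value < 0) or np.any(self.p_value > 1):
            raise ValueError("p-values outside [0, 1]")
        if self.statistic_kind in ("anova_f", "welch_f") and np.any(self.statistic < 0):
            raise ValueError("F statistics must be nonnegative")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def by_gene(self) -> dict:
        return dict(zip(self.gene_ids, zip(self.statistic, self.p_value)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": self.statistic,
                "p_value": self.p_value,
                "df_between": self.df_between,
                "df_within": self.df_within,
                "degenerate": self.degenerate,
            },
            index=pd.Index(self.gene_ids, name="gene_id"),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def _class_blocks(Z: ExpressionMatrix, classes: SampleClasses):
    labels = classes.labels_for(Z.sample_ids)
    order = classes.class_order
    blocks = [Z.values[:, labels == c] for c in order]
    ns = np.array([b.shape[1] for b in blocks])
    if np.any(ns < 2):
        bad = [order[i] for i in np.flatnonzero(ns < 2)]
        raise ValueError(f"classes with fewer than 2 samples: {bad}")
    if len(order) < 2:
        raise ValueError("need at least 2 classes")
    return blocks, ns, order


def anova_f_per_gene(Z: ExpressionMatrix, classes: SampleClasses) -> GeneStatTable:
    """One-way ANOVA F per gene: F = MSB/MSW with df (k-1, N-k).

    MSB = sum_c n_c (m_c - m)^2 / (k-1), MSW = pooled within-class sum of
    squares / (N-k); the upper-tail F probability gives the p-value.
    """
    blocks, ns, order = _class_blocks(Z, classes)
    k = len(order)
    N = int(ns.sum())
    means = np.column_stack([b.mean(axis=1) for b in blocks])  # genes x k
    grand = (means * ns).sum(axis=1) / N
    ssb = ((means - grand[:, None]) ** 2 * ns).sum(axis=1)
    ssw = np.zeros(Z.n_genes)
    for b, m in zip(blocks, means.T):
        ssw += ((b - m[:, None]) ** 2).sum(axis=1)
    df1, df2 = k - 1, N - k

    msb = ssb / df1
    msw = ssw / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    degenerate = ssw == 0
    F = np.where(degenerate & (ssb == 0), 0.0, F)
    F = np.where(degenerate & (ssb > 0), _F_CAP, F)
    p = stats.f.sf(F, df1, df2)
    p = np.where(degenerate & (ssb == 0), 1.0, p)
    p = np.where(degenerate & (ssb > 0), 0.0, p)
    return GeneStatTable(
        list(Z.gene_ids), F, p,
        np.full(Z.n_genes, df1), np.full(Z.n_genes, float(df2)),
        degenerate, "anova_f",
    )


def welch_f_per_gene(Z: ExpressionMatrix, classes: SampleClasses) -> GeneStatTable:
    """Welch's heteroscedastic one-way F with Welch-Satterthwaite denominator df.

    Genes with a zero-variance class are flagged degenerate (statistic 0,
    p-value 1) because the precision weights n_c / s_c^2 are undefined there.
    """
    blocks, ns, order = _class_blocks(Z, classes)
    k = len(order)
    means = np.column_stack([b.mean(axis=1) for b in blocks])
    variances = np.column_stack([b.var(axis=1, ddof=1) for b in blocks])
    degenerate = (variances == 0).any(axis=1)
    safe_var = np.where(variances == 0, 1.0, variances)

    w = ns[None, :] / safe_var  # genes x k
    W = w.sum(axis=1)
    mw = (w * means).sum(axis=1) / W
    A = (w * (means - mw[:, None]) ** 2).sum(axis=1) / (k - 1)
    h = ((1 - w / W[:, None]) ** 2 / (ns[None, :] - 1)).sum(axis=1)
    B = 1 + 2 * (k - 2) / (k**2 - 1) * h
    with np.errstate(divide="ignore", invalid="ignore"):
        F = A / B
        df2 = (k**2 - 1) / (3 * h)
    zero_h = h == 0  # all class means get full weight: balanced degenerate case
    df2 = np.where(zero_h, np.inf, df2)
    F = np.where(degenerate, 0.0, F)
    p = stats.f.sf(F, k - 1, np.where(np.isfinite(df2), df2, 1.0))
    p = np.where(np.isfinite(df2), p, stats.chi2.sf(F * (k - 1), k - 1))
    p = np.where(degenerate, 1.0, p)
    return GeneStatTable(
        list(Z.gene_ids), F, p,
        np.full(Z.n_genes, k - 1), np.where(degenerate, np.nan, df2),
        degenerate, "welch_f",
    )


def ttest_per_gene(Z: ExpressionMatrix, classes: SampleClasses) -> GeneStatTable:
    """Pooled-variance two-sample t per gene (signed), two-sided p, N-2 df.

    The sign is mean(second class) - mean(first class) in ``class_order``; it
    carries the direction of change into the activity score's sgn() term.
    """
    blocks, ns, order = _class_blocks(Z, classes)
    if len(order) != 2:
        raise ValueError("t-test requires exactly 2 classes; use anova_f_per_gene")
    (b0, b1), (n0, n1) = blocks, ns
    N = n0 + n1
    m0, m1 = b0.mean(axis=1), b1.mean(axis=1)
    ss0 = ((b0 - m0[:, None]) ** 2).sum(axis=1)
    ss1 = ((b1 - m1[:, None]) ** 2).sum(axis=1)
    sp2 = (ss0 + ss1) / (N - 2)
    se = np.sqrt(sp2 * (1 / n0 + 1 / n1))
    diff = m1 - m0
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t = np.where(degenerate & (diff == 0), 0.0, t)
    t = np.where(degenerate & (diff != 0), np.sign(diff) * _F_CAP, t)
    p = 2 * stats.t.sf(np.abs(t), N - 2)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    p = np.where(degenerate & (diff != 0), 0.0, p)
    return GeneStatTable(
        list(Z.gene_ids), t, p,
        np.full(Z.n_genes, 1), np.full(Z.n_genes, float(N - 2)),
        degenerate & (diff == 0), "t_equal_var",
    )


STATISTICS = {
    "anova": anova_f_per_gene,
    "welch": welch_f_per_gene,
    "ttest": ttest_per_gene,
}
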