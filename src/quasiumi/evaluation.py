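"""Accuracy and concordance metrics against ground-truth UMI counts.

Three layers of comparison:

* per-cell accuracy — Euclidean distance between log count vectors over the
  genes nonzero in both matrices (zeros are omitted; the normalizations
  under study preserve sparsity);
* per-gene summaries — mean expression and coefficient of variation across
  cells;
* differential expression concordance — per-gene Fisher exact tests on
  pseudobulk 2x2 tables, Holm adjustment, and Manhattan / Kendall / Jaccard
  distances between a normalization's DE results and the ground truth's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .matrix import CountMatrix


@dataclass
class ConcordanceReport:
    """Distances between a normalization's DE results and the reference's.

    ``manhattan``: sum of |p_ref - p_other| over genes. ``kendall``:
    discordant pair fraction of the two p-value rankings, in [0, 1].
    ``jaccard``: 1 - |intersection| / |union| of the Holm-significant gene
    sets (0 when both sets are empty). Smaller is more concordant for all
    three.
    """

    manhattan: float
    kendall: float
    jaccard: float
    n_sig_ref: int
    n_sig_other: int


def _common_checks(a: CountMatrix, b: CountMatrix) -> None:
    if a.shape != b.shape:
        raise InputError(f"matrix shapes differ: {a.shape} vs {b.shape}")
    if not np.array_equal(a.gene_ids, b.gene_ids) or not np.array_equal(
        a.cell_ids, b.cell_ids
    ):
        raise InputError("matrices must share gene and cell identifiers")


def log_distance(normalized: CountMatrix, umi: CountMatrix) -> pd.DataFrame:
    """Per-cell Euclidean distance between log count vectors.

    Computed over genes nonzero in both matrices (natural log). A warning is
    issued if the sparsity patterns disagree anywhere.
    """
    _common_checks(normalized, umi)
    mismatched = 0
    rows = []
    for j in range(normalized.n_cells):
        a = normalized.column(j).astype(float)
        b = umi.column(j).astype(float)
        both = (a > 0) & (b > 0)
        mismatched += int(np.sum((a > 0) != (b > 0)))
        n_used = int(both.sum())
        if n_used == 0:
            distance = 0.0
        else:
            diff = np.log(a[both]) - np.log(b[both])
            distance = float(np.sqrt(np.sum(diff * diff)))
        rows.append((str(normalized.cell_ids[j]), distance, n_used))
    if mismatched:
        warnings.warn(
            f"sparsity patterns disagree at {mismatched} entries; restricted "
            f"to genes nonzero in both matrices",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["cell_id", "distance", "n_genes_used"])


def gene_stats(matrix: CountMatrix) -> pd.DataFrame:
    """Per-gene mean and coefficient of variation (sd/mean, sample sd)."""
    if matrix.n_cells < 2:
        raise InputError("gene statistics require at least 2 cells")
    dense = matrix.toarray().astype(float)
    means = dense.mean(axis=1)
    sds = dense.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means > 0, sds / means, np.nan)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "mean": means,
            "cv": cv,
            "all_zero": means == 0,
        }
    )


def filter_expressed_genes(matrix: CountMatrix) -> CountMatrix:
    """Drop genes that are zero in every cell (never per-group filtering)."""
    dense_counts = matrix.values.tocsr()
    keep = np.diff(dense_counts.indptr) > 0
    return CountMatrix(
        dense_counts[keep].tocsc(),
        matrix.gene_ids[keep],
        matrix.cell_ids,
        matrix.layer,
    )


def fisher_de(matrix: CountMatrix, groups) -> np.ndarray:
    """Two-sided Fisher exact p-value per gene from pseudobulk 2x2 tables.

    For gene g and groups A/B the table is

        [[x_gA, T_A - x_gA], [x_gB, T_B - x_gB]]

    where x_g* is the gene's summed count within the group and T_* the
    group's total count over all genes. Non-integer values (TPM, rescaled
    counts) are rounded half-to-even before summation. All-zero genes get
    p = 1.
    """
    groups = np.asarray(groups)
    if groups.size != matrix.n_cells:
        raise InputError("one group label per cell required")
    levels = pd.unique(groups)
    if levels.size != 2:
        raise InputError(f"exactly two groups required, got {levels.size}")
    in_a = groups == levels[0]
    if in_a.all() or not in_a.any():
        raise InputError("each group must contain at least one cell")
    dense = np.rint(matrix.toarray().astype(float)).astype(np.int64)
    x_a = dense[:, in_a].sum(axis=1)
    x_b = dense[:, ~in_a].sum(axis=1)
    t_a, t_b = int(x_a.sum()), int(x_b.sum())
    p = np.ones(matrix.n_genes)
    for g in range(matrix.n_genes):
        if x_a[g] == 0 and x_b[g] == 0:
            continue
        table = [[x_a[g], t_a - x_a[g]], [x_b[g], t_b - x_b[g]]]
        p[g] = fisher_exact(table, alternative="two-sided")[1]
    return p


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def kendall_distance(x, y) -> float:
    """Normalized discordant-pair count between two rankings, in [0, 1].

    A pair (i, j) is discordant when (x_i - x_j)(y_i - y_j) < 0; ties count
    as neither concordant nor discordant. Computed in O(n log n) by merge
    sort inversion counting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("vectors must have equal length")
    n = x.size
    if n < 2:
        return 0.0
    order = np.lexsort((y, x))  # x ascending, ties broken by y ascending
    discordant = _count_strict_inversions(y[order].tolist())
    return discordant / (n * (n - 1) / 2)


def _count_strict_inversions(seq: list) -> int:
    # pairs i < j with seq[i] > seq[j]; merge sort, equals not counted
    if len(seq) < 2:
        return 0
    mid = len(seq) // 2
    left, right = seq[:mid], seq[mid:]
    count = _count_strict_inversions(left) + _count_strict_inversions(right)
    merged = []
    i = j = 0
    while i < len(left) and j < len(right):
        if left[i] <= right[j]:
            merged.append(left[i])
            i += 1
        else:
            count += len(left) - i
            merged.append(right[j])
            j += 1
    merged.extend(left[i:])
    merged.extend(right[j:])
    seq[:] = merged
    return count


def concordance(p_ref, p_other, alpha: float = 0.05) -> ConcordanceReport:
    """Manhattan / Kendall / Jaccard distances between two DE p-value vectors.

    The Jaccard distance compares the sets of genes with Holm-adjusted
    p < ``alpha`` under each vector.
    """
    p_ref = np.asarray(p_ref, dtype=float)
    p_other = np.asarray(p_other, dtype=float)
    if p_ref.size != p_other.size:
        raise InputError("p-value vectors must have equal length")
    manhattan = float(np.sum(np.abs(p_ref - p_other)))
    kendall = float(kendall_distance(p_ref, p_other))
    sig_ref = holm_adjust(p_ref) < alpha
    sig_other = holm_adjust(p_other) < alpha
    union = int(np.sum(sig_ref | sig_other))
    if union == 0:
        jaccard = 0.0
    else:
        jaccard = 1.0 - float(np.sum(sig_ref & sig_other)) / union
    return ConcordanceReport(
        manhattan=manhattan,
        kendall=kendall,
        jaccard=jaccard,
        n_sig_ref=int(sig_ref.sum()),
        n_sig_other=int(sig_other.sum()),
    )
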