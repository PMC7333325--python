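"""Gene-by-cell count matrix container.

Genes are rows and cells are columns throughout the package. Values are held
in compressed sparse column form so per-cell (column) operations — which is
how quasi-UMI normalization proceeds — touch only that cell's nonzero
entries. A ``layer`` tag records what the values are (raw UMI counts, read
counts, TPM, quasi-UMIs, or anything else).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .errors import InputError

LAYERS = ("umi", "reads", "tpm", "qumi", "other")
_INTEGER_LAYERS = ("umi", "qumi")


@dataclass
class CountMatrix:
    """A validated gene x cell nonnegative matrix.

    Parameters
    ----------
    values
        Dense array or any scipy sparse matrix/array, genes x cells.
        Stored internally as a canonical ``csc_array``.
    gene_ids, cell_ids
        Unique string identifiers for rows / columns.
    layer
        One of ``umi | reads | tpm | qumi | other``. The ``umi`` and ``qumi``
        layers must contain integers and are stored with an integer dtype.
    """

    values: sp.csc_array
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    layer: str = "other"

    def __post_init__(self) -> None:
        v = self.values
        if not sp.issparse(v):
            v = sp.csc_array(np.asarray(v, dtype=float))
        else:
            v = sp.csc_array(v)
        v.sum_duplicates()
        v.eliminate_zeros()
        v.sort_indices()
        if v.nnz and v.data.min() < 0:
            raise InputError("count matrix contains negative entries")
        gene_ids = np.asarray(self.gene_ids, dtype=object)
        cell_ids = np.asarray(self.cell_ids, dtype=object)
        if v.shape != (gene_ids.size, cell_ids.size):
            raise InputError(
                f"matrix shape {v.shape} inconsistent with "
                f"{gene_ids.size} gene ids and {cell_ids.size} cell ids"
            )
        for name, ids in (("gene", gene_ids), ("cell", cell_ids)):
            if len(set(ids)) != ids.size:
                raise InputError(f"duplicate {name} ids")
        if self.layer not in LAYERS:
            raise InputError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.layer in _INTEGER_LAYERS:
            if v.nnz and np.any(v.data != np.rint(v.data)):
                raise InputError(f"layer {self.layer!r} must contain integers")
            v = v.astype(np.int64)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "cell_ids", cell_ids)

    # -- basic geometry -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, j: int) -> np.ndarray:
        """Dense 1-D vector of counts for cell ``j``."""
        lo, hi = self.values.indptr[j], self.values.indptr[j + 1]
        out = np.zeros(self.n_genes, dtype=self.values.dtype)
        out[self.values.indices[lo:hi]] = self.values.data[lo:hi]
        return out

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    # -- summaries ----------------------------------------------------------
    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def cell_nonzeros(self) -> np.ndarray:
        return np.diff(self.values.indptr)

    def zero_fractions(self) -> np.ndarray:
        """Per-cell fraction of genes with a zero count."""
        return 1.0 - self.cell_nonzeros() / self.n_genes

    # -- construction helpers ----------------------------------------------
    def with_data(self, data: np.ndarray, layer: str | None = None) -> "CountMatrix":
        """Same sparsity pattern, new nonzero values (and optionally layer)."""
        new = sp.csc_array(
            (np.asarray(data), self.values.indices.copy(), self.values.indptr.copy()),
            shape=self.shape,
        )
        return CountMatrix(new, self.gene_ids, self.cell_ids, layer or self.layer)

    def with_layer(self, layer: str) -> "CountMatrix":
        return replace(self, values=self.values.copy(), layer=layer)

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.shape == other.shape
            and np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.cell_ids, other.cell_ids)
            and (self.values != other.values).nnz == 0
        )


def default_ids(prefix: str, n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"{prefix}{i:0{width}d}" for i in range(1, n + 1)], dtype=object)
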