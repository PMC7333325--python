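"""Quasi-UMI normalization of read counts (or TPMs).

PCR amplification multiplies the read count of every expressed gene by an
unknown, noisy factor, but it cannot create reads for absent molecules: a
zero read count means a zero molecule count. Quasi-UMI normalization
exploits this. For each cell it

1. takes the observed zero fraction of the cell as an estimate of the
   target distribution's probability of zero and solves for the cell's
   scale parameter by root-finding (a method-of-moments estimate), with the
   shape parameter fixed a priori (default: Poisson-lognormal, shape 2.0);
2. tabulates the zero-truncated CDF of the resulting target distribution
   over support 1..K, accumulating the log PMF with log-sum-exp;
3. replaces each nonzero value by the smallest support value whose
   truncated CDF reaches the value's within-cell empirical quantile
   (rank / number of nonzero genes, tied values sharing their mean rank so
   a tie group sits mid-interval rather than on a bin boundary).

Zeros pass through untouched, so the output has exactly the input's
sparsity pattern, and only ranks matter, so read counts, CPM and TPM inputs
yield identical quasi-UMIs whenever gene ranks agree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.stats import rankdata

from . import distributions as dist
from .distributions import CompoundPoissonParams
from .errors import (
    AllZeroError,
    InputError,
    NoZerosError,
    ParameterError,
)
from .matrix import CountMatrix

logger = logging.getLogger("quasiumi")

#: hard cap on the target support; beyond it top ranks absorb into the last bin
K_MAX = 10**6

#: tolerance subtracted from empirical quantiles before CDF lookup, so that a
#: rank landing exactly on a tabulated CDF value (up to float rounding) maps
#: into that bin rather than the next one
_RANK_EPS = 1e-9


@dataclass
class TruncatedCDFTable:
    """Zero-truncated CDF of a target distribution over support 1..K.

    ``log_cdf_trunc[k-1]`` is log P(X <= k | X > 0) under ``params``.
    """

    support: np.ndarray
    log_cdf_trunc: np.ndarray
    params: CompoundPoissonParams | None = None

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=np.int64)
        self.log_cdf_trunc = np.asarray(self.log_cdf_trunc, dtype=float)
        if self.support.size != self.log_cdf_trunc.size or self.support.size == 0:
            raise InputError("support and log_cdf_trunc must be equal-length, nonempty")
        if self.support[0] != 1 or np.any(np.diff(self.support) != 1):
            raise InputError("support must be the consecutive integers 1..K")
        if np.any(np.diff(self.log_cdf_trunc) <= 0) or self.log_cdf_trunc[-1] > 0:
            raise InputError("log_cdf_trunc must be strictly increasing and <= 0")

    @classmethod
    def from_cdf(cls, cdf_values, params=None) -> "TruncatedCDFTable":
        """Build a table from linear-scale truncated CDF values at 1..K."""
        cdf_values = np.asarray(cdf_values, dtype=float)
        return cls(np.arange(1, cdf_values.size + 1), np.log(cdf_values), params)

    @property
    def cdf(self) -> np.ndarray:
        return np.exp(self.log_cdf_trunc)


@dataclass
class CellTarget:
    """Per-cell target distribution derived from the zero fraction."""

    cell_id: str
    zero_fraction: float
    shape: float
    scale: float
    cdf: TruncatedCDFTable


def mom_scale(zero_fraction: float, shape: float, family: str = "plnorm") -> float:
    """Method-of-moments scale estimate from a cell's zero fraction.

    Solves P(X = 0; shape, scale) = ``zero_fraction`` for the scale. The zero
    probability is strictly decreasing in the scale for every family, so a
    bracketing root-finder (Brent) with geometric bracket expansion applies.

    Raises
    ------
    NoZerosError / AllZeroError
        For zero fractions of 0 or 1: the scale is not identified.
    """
    zero_fraction = float(zero_fraction)
    if not 0.0 <= zero_fraction <= 1.0 or not np.isfinite(zero_fraction):
        raise InputError(f"zero_fraction must lie in [0, 1], got {zero_fraction}")
    if zero_fraction == 0.0:
        raise NoZerosError("cell has no zeros: scale cannot be estimated")
    if zero_fraction == 1.0:
        raise AllZeroError("cell is entirely zero: scale cannot be estimated")
    log_target = np.log(zero_fraction)

    if family == "plnorm":
        def objective(scale: float) -> float:
            return dist.log_pmf_zero(CompoundPoissonParams(family, shape, scale)) - log_target
    else:
        # positive scales: solve on the log scale
        def objective(t: float) -> float:
            return dist.log_pmf_zero(CompoundPoissonParams(family, shape, np.exp(t))) - log_target

    lo, hi = -1.0, 1.0
    flo, fhi = objective(lo), objective(hi)
    for _ in range(70):
        if flo > 0.0 >= fhi or flo >= 0.0 > fhi:
            break
        span = hi - lo
        if flo < 0.0:  # zero prob everywhere below target: move bracket down
            lo -= span
            flo = objective(lo)
        else:
            hi += span
            fhi = objective(hi)
    else:
        raise ParameterError(
            f"could not bracket MOM scale for zero_fraction={zero_fraction}, "
            f"shape={shape}, family={family}"
        )
    root = brentq(objective, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return float(root) if family == "plnorm" else float(np.exp(root))


def build_truncated_cdf(
    shape: float,
    scale: float,
    family: str = "plnorm",
    n_nonzero: int = 1,
    k_max: int = K_MAX,
) -> TruncatedCDFTable:
    """Tabulate the zero-truncated target CDF up to the resolution needed.

    The support is extended to the smallest K with
    P(X <= K | X > 0) >= 1 - 1/(2 * n_nonzero), so every empirical quantile
    r / n_nonzero below the top is resolved, capped at ``k_max`` (top ranks
    then absorb into the final bin, with a warning).
    """
    if n_nonzero < 1:
        raise InputError("n_nonzero must be >= 1")
    params = CompoundPoissonParams(family, shape, scale)
    log_p0 = dist.log_pmf_zero(params)
    log_denom = float(np.log1p(-np.exp(log_p0)))
    log_target = float(np.log1p(-1.0 / (2.0 * n_nonzero)))

    pieces: list[np.ndarray] = []
    running = -np.inf  # log sum of PMF over 1..last tabulated value
    start, chunk = 1, 1024
    k_final = None
    while start <= k_max:
        end = min(start + chunk - 1, k_max)
        lp = dist.log_pmf(np.arange(start, end + 1, dtype=float), params)
        block = np.logaddexp.accumulate(lp)
        block = np.logaddexp(block, running)
        running = block[-1]
        trunc = np.minimum(block - log_denom, 0.0)
        pieces.append(trunc)
        if trunc[-1] >= log_target:
            within = int(np.searchsorted(trunc, log_target, side="left"))
            k_final = start + within
            pieces[-1] = trunc[: within + 1]
            break
        start = end + 1
        chunk *= 2
    if k_final is None:
        k_final = k_max
        warnings.warn(
            f"truncated-CDF support capped at {k_max} before reaching the "
            f"resolution target; top ranks absorb into the final bin",
            stacklevel=2,
        )
    log_cdf = np.concatenate(pieces)
    return TruncatedCDFTable(np.arange(1, k_final + 1), log_cdf, params)


def assign_qumi(values, table: TruncatedCDFTable) -> np.ndarray:
    """Map values to quasi-UMIs by rank against a zero-truncated CDF table.

    Nonzero entries are ranked within the cell (ties share the mean rank of
    their tie group), converted to empirical quantiles p = rank / G, and
    each is assigned the smallest support value whose truncated CDF reaches
    p. Quantiles beyond the tabulated range land in the final bin. Zeros map
    to zero.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise InputError("values must be a 1-D vector")
    if values.size and values.min() < 0:
        raise InputError("values must be nonnegative")
    nz = values > 0
    qumi = np.zeros(values.size, dtype=np.int64)
    n_nonzero = int(nz.sum())
    if n_nonzero == 0:
        return qumi
    ranks = rankdata(values[nz], method="average")
    quantiles = ranks / n_nonzero - _RANK_EPS
    idx = np.searchsorted(table.cdf, quantiles, side="left")
    idx = np.minimum(idx, table.support.size - 1)
    qumi[nz] = table.support[idx]
    return qumi


def quminorm_cell(
    values,
    shape: float = 2.0,
    family: str = "plnorm",
    scale: float | None = None,
    cell_id: str = "",
    return_target: bool = False,
):
    """Quasi-UMI normalize a single cell's read counts (or TPMs).

    The cell must contain at least one zero (unless ``scale`` is supplied
    directly) and at least one nonzero value. Returns the integer quasi-UMI
    vector; with ``return_target=True``, also the fitted :class:`CellTarget`.
    """
    values = np.asarray(values, dtype=float)
    nz = values > 0
    n_nonzero = int(nz.sum())
    if n_nonzero == 0:
        warnings.warn(f"cell {cell_id or '<unnamed>'} is entirely zero; passed through", stacklevel=2)
        qumi = np.zeros(values.size, dtype=np.int64)
        return (qumi, None) if return_target else qumi
    zero_fraction = 1.0 - n_nonzero / values.size
    if scale is None:
        if zero_fraction == 0.0:
            raise NoZerosError(
                f"cell {cell_id or '<unnamed>'} has no zeros; supply an explicit "
                f"scale override to normalize it"
            )
        scale = mom_scale(zero_fraction, shape, family)
    table = build_truncated_cdf(shape, scale, family, n_nonzero)
    qumi = assign_qumi(values, table)
    if return_target:
        return qumi, CellTarget(cell_id, zero_fraction, shape, float(scale), table)
    return qumi


def quminorm_matrix(
    matrix: CountMatrix,
    shape: float = 2.0,
    family: str = "plnorm",
    scale_override: float | None = None,
    return_info: bool = False,
):
    """Quasi-UMI normalize every cell of a matrix independently.

    Each column is normalized on its own (results do not depend on cell
    order), the output sparsity pattern equals the input's, and cells that
    cannot be normalized (no zeros without an override) are passed through
    unchanged with a warning. With ``return_info=True`` also returns a
    :class:`pandas.DataFrame` of per-cell zero fraction, scale and max
    quasi-UMI (NaN scale marks passed-through cells).
    """
    import pandas as pd

    if matrix.n_genes == 0 or matrix.n_cells == 0:
        raise InputError("empty matrix")
    v = matrix.values
    new_data = np.empty(v.nnz, dtype=np.int64)
    info_rows = []
    for j in range(matrix.n_cells):
        lo, hi = v.indptr[j], v.indptr[j + 1]
        col = v.data[lo:hi].astype(float)
        cell_id = str(matrix.cell_ids[j])
        n_nonzero = col.size
        zero_fraction = 1.0 - n_nonzero / matrix.n_genes
        if n_nonzero == 0:
            info_rows.append((cell_id, 1.0, np.nan, 0))
            continue
        if zero_fraction == 0.0 and scale_override is None:
            warnings.warn(
                f"cell {cell_id} has no zeros; passed through unnormalized",
                stacklevel=2,
            )
            if np.any(col != np.rint(col)):
                raise InputError(
                    f"cell {cell_id} has no zeros and non-integer values; "
                    f"cannot pass through into an integer layer"
                )
            new_data[lo:hi] = np.rint(col).astype(np.int64)
            info_rows.append((cell_id, 0.0, np.nan, int(col.max())))
            continue
        scale = (
            scale_override
            if scale_override is not None
            else mom_scale(zero_fraction, shape, family)
        )
        table = build_truncated_cdf(shape, scale, family, n_nonzero)
        ranks = rankdata(col, method="average")
        quantiles = ranks / n_nonzero - _RANK_EPS
        idx = np.minimum(
            np.searchsorted(table.cdf, quantiles, side="left"),
            table.support.size - 1,
        )
        qcol = table.support[idx]
        new_data[lo:hi] = qcol
        info_rows.append((cell_id, zero_fraction, float(scale), int(qcol.max())))
    out = CountMatrix(
        sp.csc_array((new_data, v.indices.copy(), v.indptr.copy()), shape=matrix.shape),
        matrix.gene_ids,
        matrix.cell_ids,
        "qumi",
    )
    if return_info:
        info = pd.DataFrame(
            info_rows, columns=["cell_id", "zero_fraction", "scale", "max_qumi"]
        )
        return out, info
    return out


def rescale_common_total(matrix: CountMatrix) -> CountMatrix:
    """Rescale every cell to the median of the original cell totals.

    Divides each cell by its total count, then multiplies by the median
    total, so all column sums agree. Intended as the final step before
    methods that assume equal library sizes.
    """
    totals = matrix.cell_totals().astype(float)
    if np.any(totals <= 0):
        bad = matrix.cell_ids[int(np.argmax(totals <= 0))]
        raise InputError(f"cell {bad} has zero total count; cannot rescale")
    median_total = float(np.median(totals))
    factors = median_total / totals
    v = matrix.values
    per_entry = np.repeat(factors, np.diff(v.indptr))
    return CountMatrix(
        sp.csc_array(
            (v.data.astype(float) * per_entry, v.indices.copy(), v.indptr.copy()),
            shape=matrix.shape,
        ),
        matrix.gene_ids,
        matrix.cell_ids,
        "other",
    )
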