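"""Per-cell maximum likelihood fitting of compound Poisson families.

Every gene in a cell — zeros included, since zeros dominate and carry the
scale information — is treated as an i.i.d. draw from a two-parameter
compound Poisson family. The likelihood is evaluated on the histogram of
unique count values weighted by multiplicity (algebraically identical to
the per-gene sum, much faster for sparse cells), and maximized over
unconstrained transforms of (shape, scale) with a Nelder-Mead simplex.

BIC with k = 2 free parameters compares candidate families per cell, the
median of per-cell shape MLEs calibrates the quasi-UMI target shape, and a
posterior-predictive tail check (log ratio of simulated to observed maximum
count) assesses tail calibration of the fitted model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import distributions as dist
from .distributions import CompoundPoissonParams
from .errors import CalibrationError, DegenerateInputError, InputError
from .matrix import CountMatrix
from .quminorm import mom_scale

logger = logging.getLogger("quasiumi")

#: fewer genes than this flags non-convergence instead of raising
MIN_GENES = 50

_MAX_ITER = 500


@dataclass
class CellFit:
    """Maximum-likelihood fit of one cell.

    ``bic`` is 2 ln(n_genes) - 2 loglik (two free parameters, natural log).
    """

    cell_id: str
    params: CompoundPoissonParams
    loglik: float
    bic: float
    converged: bool
    n_genes: int


@dataclass
class PredictiveCheckResult:
    """Tail-calibration statistic ln(max simulated / max observed)."""

    cell_id: str
    statistic: float


def _transform(family: str, shape: float, scale: float) -> np.ndarray:
    if family == "plnorm":
        return np.array([np.log(shape), scale])
    return np.array([np.log(shape), np.log(scale)])


def _untransform(family: str, theta: np.ndarray) -> tuple[float, float]:
    shape = float(np.exp(np.clip(theta[0], -30.0, 30.0)))
    if family == "plnorm":
        scale = float(np.clip(theta[1], -1e4, 1e4))
    else:
        scale = float(np.exp(np.clip(theta[1], -300.0, 300.0)))
    return shape, scale


def _default_init(counts: np.ndarray, family: str) -> tuple[float, float]:
    # shape 2 start; scale from the zero-fraction MOM equation when possible,
    # otherwise from the nonzero mean.
    shape0 = 2.0
    zero_fraction = float(np.mean(counts == 0))
    if 0.0 < zero_fraction < 1.0:
        try:
            return shape0, mom_scale(zero_fraction, shape0, family)
        except Exception:  # pragma: no cover - fall back to the mean start
            pass
    nonzero_mean = float(counts[counts > 0].mean())
    if family == "plnorm":
        return shape0, float(np.log(nonzero_mean))
    return shape0, nonzero_mean


def fit_cell_mle(
    counts,
    family: str = "plnorm",
    init: CompoundPoissonParams | None = None,
    cell_id: str = "",
) -> CellFit:
    """Fit a compound Poisson family to one cell's counts by MLE.

    Raises :class:`DegenerateInputError` for an all-zero cell. Cells with
    fewer than ``MIN_GENES`` genes are fit but flagged non-converged.
    """
    counts = np.asarray(counts)
    if counts.size == 0 or np.all(counts == 0):
        raise DegenerateInputError("cannot fit an all-zero cell")
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise InputError("counts must be nonnegative integers")
    if family not in dist.FAMILIES:
        raise InputError(f"unknown family {family!r}")
    counts = counts.astype(float)
    uniq, mult = np.unique(counts, return_counts=True)
    weights = mult.astype(float)

    if init is not None:
        if init.family != family:
            raise InputError("init params family does not match requested family")
        shape0, scale0 = init.shape, init.scale
    else:
        shape0, scale0 = _default_init(counts, family)

    def negloglik(theta: np.ndarray) -> float:
        shape, scale = _untransform(family, theta)
        try:
            params = CompoundPoissonParams(family, shape, scale)
        except Exception:
            return np.inf
        lp = dist.log_pmf(uniq, params)
        val = -float(np.dot(weights, lp))
        return val if np.isfinite(val) else np.inf

    theta0 = _transform(family, shape0, scale0)
    f0 = negloglik(theta0)
    res = minimize(
        negloglik,
        theta0,
        method="Nelder-Mead",
        options={
            "maxiter": _MAX_ITER,
            "xatol": 1e-6,
            "fatol": 1e-8 * max(1.0, abs(f0)),
        },
    )
    shape, scale = _untransform(family, res.x)
    loglik = -float(res.fun)
    n_genes = counts.size
    converged = bool(res.success) and n_genes >= MIN_GENES
    return CellFit(
        cell_id=cell_id,
        params=CompoundPoissonParams(family, shape, scale),
        loglik=loglik,
        bic=bic_from(loglik, n_genes),
        converged=converged,
        n_genes=n_genes,
    )


def bic_from(loglik: float, n_genes: int) -> float:
    """BIC for a 2-parameter model: 2 ln(n) - 2 loglik."""
    return 2.0 * float(np.log(n_genes)) - 2.0 * loglik


def bic_of(fit: CellFit) -> float:
    """Recompute the BIC of a converged fit from its log-likelihood."""
    return bic_from(fit.loglik, fit.n_genes)


def fit_matrix(
    matrix: CountMatrix, family: str = "plnorm", progress: bool = False
) -> list[CellFit]:
    """Fit every cell of a matrix; all-zero cells are skipped with a warning."""
    fits: list[CellFit] = []
    for j in range(matrix.n_cells):
        cell_id = str(matrix.cell_ids[j])
        col = matrix.column(j)
        if np.all(col == 0):
            warnings.warn(f"cell {cell_id} is entirely zero; skipped", stacklevel=2)
            continue
        fits.append(fit_cell_mle(col, family=family, cell_id=cell_id))
    return fits


def calibrate_shape(
    matrix: CountMatrix, family: str = "plnorm"
) -> tuple[np.ndarray, float]:
    """Per-cell shape MLEs and their median, for target-shape calibration.

    Non-converged cells are excluded from the median with a logged count;
    fewer than 10 converged cells raises :class:`CalibrationError`.
    """
    fits = fit_matrix(matrix, family=family)
    converged = [f for f in fits if f.converged]
    n_dropped = len(fits) - len(converged)
    if n_dropped:
        logger.warning(
            "calibrate_shape: excluded %d non-converged cells of %d",
            n_dropped,
            len(fits),
        )
    if len(converged) < 10:
        raise CalibrationError(
            f"only {len(converged)} cells converged; need at least 10 to "
            f"calibrate a shape parameter"
        )
    shapes = np.array([f.params.shape for f in converged])
    return shapes, float(np.median(shapes))


def _cell_rng(seed: int, index: int) -> np.random.Generator:
    # Substream per cell index: results do not depend on processing order.
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def predictive_check(
    matrix: CountMatrix, fits: list[CellFit], seed: int = 0
) -> pd.DataFrame:
    """Posterior-predictive tail check for each converged fit.

    Simulates as many genes as observed from the fitted parameters and
    returns ln(max simulated / max observed) per cell; values near zero
    indicate a well-calibrated tail.
    """
    by_id = {str(c): j for j, c in enumerate(matrix.cell_ids)}
    rows = []
    for fit in fits:
        if not fit.converged:
            warnings.warn(
                f"cell {fit.cell_id} did not converge; skipped in predictive check",
                stacklevel=2,
            )
            continue
        j = by_id.get(fit.cell_id)
        if j is None:
            raise InputError(f"fit for unknown cell {fit.cell_id!r}")
        observed_max = float(matrix.column(j).max())
        if observed_max < 1:
            warnings.warn(f"cell {fit.cell_id} has no positive counts; skipped", stacklevel=2)
            continue
        rng = _cell_rng(seed, j)
        sim = dist.sample(fit.params, fit.n_genes, rng)
        statistic = float(np.log(max(sim.max(), 1e-300)) - np.log(observed_max))
        rows.append((fit.cell_id, statistic))
    return pd.DataFrame(rows, columns=["cell_id", "statistic"])


def predictive_check_histogram(
    statistics, bins: int = 20
) -> pd.DataFrame:
    """Summary histogram (bin edges and counts) of predictive-check statistics."""
    stats = np.asarray(statistics, dtype=float)
    stats = stats[np.isfinite(stats)]
    counts, edges = np.histogram(stats, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
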