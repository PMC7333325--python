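"""Compound Poisson count distributions used as quasi-UMI target distributions.

A compound Poisson count distribution arises by drawing a latent Poisson rate
lambda from a continuous prior and marginalizing it out:

    P(X = x) = integral_0^inf  lambda^x exp(-lambda) / x!  f(lambda) d lambda

Three families are supported, distinguished by the prior on the rate:

``plnorm``
    Poisson-lognormal. Prior lognormal with logarithmic mean mu (the *scale*,
    any real) and logarithmic standard deviation sigma (the *shape*, > 0).
    Heavy tail approximating a power law; the default quasi-UMI target.
``plomax``
    Poisson-Lomax. Prior Lomax (shifted Pareto) with power-law tail index
    alpha (*shape*, > 0) and scale theta (> 0). A true power-law tail, heavier
    than the Poisson-lognormal's.
``negbin``
    Negative binomial, i.e. a gamma prior, parameterized here by dispersion
    ``size`` (*shape*, > 0) and mean m (*scale*, > 0) so the scale plays the
    same magnitude role in all three families. The lightest tail of the three.

The heavy-tailed families have no closed-form PMF; the mixing integral is
evaluated by numerical quadrature in log space (details in ``docs/methods.md``):
Poisson-lognormal by mode-centered, Laplace-rescaled Gauss-Hermite quadrature,
Poisson-Lomax by a windowed composite Simpson rule on a per-count grid of
~1000 points in log-lambda. Both achieve relative PMF errors well below 1e-6
across counts up to at least 10^3 and shapes in [0.5, 4]. All accumulation is
done with log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import gammaln, logsumexp
from scipy.stats import nbinom

from .errors import InputError, ParameterError

FAMILIES = ("plnorm", "plomax", "negbin")

_LOG_2PI = float(np.log(2.0 * np.pi))

# Mode-centered Gauss-Hermite rule (probabilists' weight exp(-t^2/2)).
_AGH_ORDER = 201
_agh_nodes, _agh_weights = hermegauss(_AGH_ORDER)
_agh_log_weights = np.log(_agh_weights)

# Number of Simpson nodes per Poisson-Lomax PMF evaluation (even interval count).
_PLOMAX_NODES = 1001

_CHUNK = 4096


@dataclass(frozen=True)
class CompoundPoissonParams:
    """Parameters of a compound Poisson count family.

    Parameters
    ----------
    family
        One of ``"plnorm"``, ``"plomax"``, ``"negbin"``.
    shape
        Tail-heaviness parameter: sigma (plnorm), alpha (plomax) or the
        negative binomial dispersion ``size``. Must be positive.
    scale
        Magnitude parameter: mu (plnorm, unconstrained real), theta (plomax,
        positive) or the mean m (negbin, positive).
    """

    family: str
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        shape = float(self.shape)
        scale = float(self.scale)
        if not np.isfinite(shape) or shape <= 0.0:
            raise ParameterError(f"shape must be a positive finite real, got {shape}")
        if not np.isfinite(scale):
            raise ParameterError(f"scale must be finite, got {scale}")
        if self.family != "plnorm" and scale <= 0.0:
            raise ParameterError(
                f"scale must be positive for family {self.family!r}, got {scale}"
            )
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "scale", scale)


def _validate_counts(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    if arr.size and (np.any(arr < 0) or np.any(arr != np.floor(arr)) or not np.all(np.isfinite(arr))):
        raise InputError("x must contain nonnegative integers")
    return arr


def _plnorm_log_pmf_chunk(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    # log integrand in z (lambda = exp(mu + sigma z), z standard normal):
    #   g(z) = -z^2/2 + x (mu + sigma z) - exp(mu + sigma z)
    # Constants -log(2 pi)/2 - gammaln(x+1) are added at the end.
    # Newton search for the mode of the strictly concave g.
    z = np.where(x > 0, (np.log(np.maximum(x, 1.0)) - mu) / sigma, 0.0)
    z = np.clip(z, -60.0, 60.0)
    e = np.exp(np.minimum(mu + sigma * z, 700.0))
    for _ in range(200):
        g1 = -z + sigma * (x - e)
        g2 = -1.0 - sigma * sigma * e
        step = np.clip(g1 / g2, -2.0, 2.0)
        z -= step
        e = np.exp(np.minimum(mu + sigma * z, 700.0))
        if np.max(np.abs(step)) < 1e-13:
            break
    g2 = -1.0 - sigma * sigma * e
    h = 1.0 / np.sqrt(-g2)
    # Laplace-rescaled nodes: integral = h * sum_j w_j exp(g(z*+h t_j) + t_j^2/2)
    zs = z[:, None] + h[:, None] * _agh_nodes[None, :]
    lin = mu + sigma * zs
    g = -0.5 * zs * zs + x[:, None] * lin - np.exp(np.minimum(lin, 700.0))
    body = g + 0.5 * _agh_nodes[None, :] ** 2 + _agh_log_weights[None, :]
    return (
        logsumexp(body, axis=1)
        + np.log(h)
        - 0.5 * _LOG_2PI
        - gammaln(x + 1.0)
    )


_simpson_pattern = np.ones(_PLOMAX_NODES)
_simpson_pattern[1:-1:2] = 4.0
_simpson_pattern[2:-1:2] = 2.0
_log_simpson = np.log(_simpson_pattern / 3.0)


def _plomax_log_pmf_chunk(x: np.ndarray, alpha: float, theta: float) -> np.ndarray:
    # log integrand in u = log(lambda), including the Jacobian e^u:
    #   g(u) = (x+1) u - e^u - (alpha+1) log1p(e^u / theta)
    # Constants log(alpha/theta) - gammaln(x+1) added at the end.
    def g(u, xv):
        eu = np.exp(np.minimum(u, 700.0))
        return (xv + 1.0) * u - eu - (alpha + 1.0) * np.log1p(eu / theta)

    u = np.log(x + 1.0)
    eu = np.exp(np.minimum(u, 700.0))
    for _ in range(200):
        s = eu / (theta + eu)
        g1 = (x + 1.0) - eu - (alpha + 1.0) * s
        g2 = -eu - (alpha + 1.0) * theta * eu / (theta + eu) ** 2
        step = np.clip(g1 / g2, -2.0, 2.0)
        u -= step
        eu = np.exp(np.minimum(u, 700.0))
        if np.max(np.abs(step)) < 1e-13:
            break
    g2 = -eu - (alpha + 1.0) * theta * eu / (theta + eu) ** 2
    gstar = g(u, x)
    width = np.maximum(1.0 / np.sqrt(-g2), 1e-3)
    # Expand the integration window until the log integrand has dropped by 60
    # nats on both sides of the mode (truncation error ~ e^-60).
    dl = 5.0 * width
    for _ in range(80):
        mask = g(u - dl, x) > gstar - 60.0
        if not mask.any():
            break
        dl[mask] *= 1.6
    dr = 5.0 * width
    for _ in range(80):
        mask = g(u + dr, x) > gstar - 60.0
        if not mask.any():
            break
        dr[mask] *= 1.6
    t = np.linspace(0.0, 1.0, _PLOMAX_NODES)
    span = dl + dr
    grid = (u - dl)[:, None] + span[:, None] * t[None, :]
    G = g(grid, x[:, None])
    log_h = np.log(span / (_PLOMAX_NODES - 1))
    body = G + _log_simpson[None, :] + log_h[:, None]
    return (
        logsumexp(body, axis=1)
        + np.log(alpha)
        - np.log(theta)
        - gammaln(x + 1.0)
    )


def log_pmf(x, params: CompoundPoissonParams) -> np.ndarray:
    """Log PMF of a compound Poisson family at nonnegative integer counts.

    Returns one finite log-probability per entry of ``x`` (the support is all
    nonnegative integers, so the PMF never vanishes at finite counts).
    """
    if not isinstance(params, CompoundPoissonParams):
        raise ParameterError("params must be a CompoundPoissonParams")
    arr = _validate_counts(x)
    if params.family == "negbin":
        size, m = params.shape, params.scale
        return nbinom.logpmf(arr, size, size / (size + m))
    out = np.empty(arr.shape, dtype=float)
    if params.family == "plnorm":
        def fun(block):
            return _plnorm_log_pmf_chunk(block, params.scale, params.shape)
    else:
        def fun(block):
            return _plomax_log_pmf_chunk(block, params.shape, params.scale)
    for start in range(0, arr.size, _CHUNK):
        sl = slice(start, min(start + _CHUNK, arr.size))
        out[sl] = fun(arr[sl])
    return out


def pmf(x, params: CompoundPoissonParams) -> np.ndarray:
    """PMF on the linear scale; thin wrapper over :func:`log_pmf`."""
    return np.exp(log_pmf(x, params))


def log_pmf_zero(params: CompoundPoissonParams) -> float:
    """log P(X = 0); the quantity matched to a cell's zero fraction."""
    return float(log_pmf(np.array([0.0]), params)[0])


def moments(params: CompoundPoissonParams) -> tuple[float, float]:
    """Marginal mean and variance of a compound Poisson family.

    With prior mean m and prior variance v, the marginal mean is m and the
    marginal variance m + v. Returns ``inf`` where a moment does not exist
    (Poisson-Lomax: mean infinite for alpha <= 1, variance for alpha <= 2).
    """
    shape, scale = params.shape, params.scale
    if params.family == "plnorm":
        m = float(np.exp(scale + 0.5 * shape * shape))
        v = m + (np.exp(shape * shape) - 1.0) * m * m
        return m, float(v)
    if params.family == "plomax":
        alpha, theta = shape, scale
        if alpha <= 1.0:
            return np.inf, np.inf
        m = theta / (alpha - 1.0)
        if alpha <= 2.0:
            return m, np.inf
        # Lomax prior variance theta^2 alpha / ((alpha-1)^2 (alpha-2)).
        v_prior = theta * theta * alpha / ((alpha - 1.0) ** 2 * (alpha - 2.0))
        return m, m + v_prior
    size, m = shape, scale
    return m, m + m * m / size


def sample(params: CompoundPoissonParams, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` counts: a latent rate from the prior, then Poisson counts.

    ``seed`` may be an integer or a ``numpy.random.Generator``. Rates above
    1e12 are clipped to keep the Poisson sampler in range; with the parameter
    regimes of scRNA-seq data this is astronomically rare.
    """
    if not isinstance(params, CompoundPoissonParams):
        raise ParameterError("params must be a CompoundPoissonParams")
    if n < 1:
        raise InputError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if params.family == "plnorm":
        lam = rng.lognormal(mean=params.scale, sigma=params.shape, size=n)
    elif params.family == "plomax":
        u = rng.random(n)
        lam = params.scale * ((1.0 - u) ** (-1.0 / params.shape) - 1.0)
    else:
        lam = rng.gamma(shape=params.shape, scale=params.scale / params.shape, size=n)
    lam = np.minimum(lam, 1e12)
    return rng.poisson(lam)
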