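"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different computational route from the
implementation it validates: dense two-stage trapezoid quadrature instead of
Gauss-Hermite / windowed Simpson, explicit hypergeometric enumeration instead
of scipy's Fisher test, direct step-down construction instead of statsmodels'
Holm, and O(n^2) pair enumeration instead of mergesort inversion counting.
"""

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom


def bruteforce_log_pmf(x, params, n=100001):
    """Compound Poisson log PMF by dense two-stage trapezoid in log(lambda)."""
    fam, shape, scale = params.family, params.shape, params.scale

    def logint(t):
        lam = np.exp(t)
        pois = x * t - lam - gammaln(x + 1)
        if fam == "plnorm":
            mu, sig = scale, shape
            prior = -np.log(lam * sig * np.sqrt(2 * np.pi)) - (t - mu) ** 2 / (
                2 * sig**2
            )
        else:
            a, th = shape, scale
            prior = np.log(a / th) - (a + 1) * np.log1p(lam / th)
        return pois + prior + t  # Jacobian: d lambda = e^t dt

    if fam == "plnorm":
        lo = min(scale - 45 * shape, np.log(x + 0.5) - 50 if x > 0 else 0.0) - 5
        hi = max(scale + 45 * shape, np.log(x + 1.0) + 5) + 5
    else:
        lo = np.log(scale) - 80.0
        hi = max(np.log(x + 1.0), np.log(scale), 0.0) + 40.0
    t = np.linspace(lo, hi, n)
    g = logint(t)
    m = g.max()
    mask = g >= m - 80
    h = t[1] - t[0]
    t2 = np.linspace(t[mask].min() - h, t[mask].max() + h, n)
    g2 = logint(t2)
    m2 = g2.max()
    return m2 + np.log(np.trapezoid(np.exp(g2 - m2), t2))


def fisher_two_sided_oracle(table):
    """Two-sided Fisher p by enumerating the hypergeometric support and
    summing the probabilities of all tables at most as probable as the
    observed one (with scipy's relative slack of 1 + 1e-7)."""
    (a, b), (c, d) = table
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = hypergeom(n_total, row1, col1)
    support = np.arange(max(0, col1 - (c + d)), min(col1, row1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


def holm_oracle(p):
    """Holm step-down by the direct textbook construction."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_max = 0.0
    for i, idx in enumerate(order):
        value = min(1.0, (n - i) * p[idx])
        running_max = max(running_max, value)
        adjusted[idx] = running_max
    return adjusted


def kendall_distance_oracle(x, y):
    """Normalized discordant-pair count by explicit O(n^2) enumeration."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    discordant = np.sum(np.triu(sx * sy, k=1) < 0)
    return discordant / (n * (n - 1) / 2)


def truncated_cdf_oracle(pmf_values, k):
    """Zero-truncated CDF at 1..k by direct linear-space accumulation.

    ``pmf_values`` must contain the PMF at 0..k.
    """
    p0 = pmf_values[0]
    return np.cumsum(pmf_values[1 : k + 1]) / (1.0 - p0)
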