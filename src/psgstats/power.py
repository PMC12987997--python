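"""A-priori power analysis for the correlation test.

Power is computed from the exact sampling distribution of the Pearson
correlation coefficient under a bivariate-normal alternative (the
hypergeometric-function density), not the Fisher-z approximation: with a true
correlation rho and sample size n, the density of the sample correlation r is

    f(r) = (n-2) G(n-1) (1-rho^2)^((n-1)/2) (1-r^2)^((n-4)/2)
           / (sqrt(2 pi) G(n-1/2) (1-rho r)^(n-3/2))
           * 2F1(1/2, 1/2; n-1/2; (rho r + 1)/2)

with G the gamma function. The null critical value comes from the exact
t-distribution of r under rho = 0.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, special, stats

__all__ = ["corr_pdf", "corr_power", "required_n_correlation"]


def corr_pdf(r, n: int, rho: float):
    """Exact density of the sample correlation for bivariate-normal data."""
    r = np.asarray(r, dtype=float)
    if n < 4:
        raise ValueError("density implemented for n >= 4")
    lg = (np.log(n - 2) + special.gammaln(n - 1)
          + (n - 1) / 2 * np.log1p(-rho**2)
          + (n - 4) / 2 * np.log1p(-r**2)
          - 0.5 * np.log(2 * np.pi) - special.gammaln(n - 0.5)
          - (n - 1.5) * np.log1p(-rho * r))
    return np.exp(lg) * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)


def _r_crit(n: int, alpha: float, tail: str) -> float:
    a = alpha / 2 if tail == "two" else alpha
    t = stats.t.ppf(1 - a, n - 2)
    return float(t / np.sqrt(n - 2 + t**2))


def corr_power(n: int, rho: float, alpha: float = 0.05,
               tail: str = "one") -> float:
    """Exact power of the level-alpha test of rho = 0 at sample size n.

    One-sided tests reject in the direction of the true rho; two-sided tests
    reject on either side.
    """
    if not 0 < abs(rho) < 1:
        raise ValueError("rho must satisfy 0 < |rho| < 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    rc = _r_crit(n, alpha, tail)
    # orient so the alternative is positive
    rr = abs(rho)

    def pdf(r):
        return corr_pdf(r, n, rr)

    upper, _ = integrate.quad(pdf, rc, 1, limit=200)
    if tail == "one":
        return float(upper)
    lower, _ = integrate.quad(pdf, -1, -rc, limit=200)
    return float(upper + lower)


def required_n_correlation(rho: float, alpha: float = 0.05,
                           power: float = 0.80, tail: str = "one",
                           n_max: int = 10_000) -> int:
    """Smallest n >= 4 whose exact correlation-test power reaches the target.

    Raises if the target is unreachable below *n_max* (power is monotone in n
    for fixed rho, so the scan terminates at the first crossing).
    """
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    for n in range(4, n_max + 1):
        if corr_power(n, rho, alpha, tail) >= power:
            return n
    raise RuntimeError(f"target power {power} not reachable with n <= {n_max}")
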