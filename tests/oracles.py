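"""Independent numerical oracles used by the tests.

These deliberately avoid the package's own Laplace/likelihood code paths:
the marginal likelihood is evaluated by high-order adaptive Gauss-Hermite
quadrature over a brute-force NB2 log-pmf, and the NB2 pmf itself by direct
gamma-Poisson mixture quadrature.
"""

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import integrate, optimize, stats
from scipy.special import gammaln


def nb2_logpmf_direct(y, mu, alpha):
    """NB2 log-pmf written straight from the gamma-function form."""
    r = 1.0 / alpha
    p = r / (r + mu)
    return gammaln(y + r) - gammaln(r) - gammaln(y + 1) + r * np.log(p) + y * np.log1p(-p)

def nb2_pmf_mixture(y, mu, alpha):
    """NB2 pmf via numerical integration of the gamma-Poisson mixture."""
    shape, scale = 1.0 / alpha, alpha * mu

    def integrand(lam):
        return stats.poisson.pmf(y, lam) * stats.gamma.pdf(lam, a=shape, scale=scale)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return val


def agh_marginal_loglik(y, eta0, groups, alpha, sigma2, npts=50):
    """Adaptive Gauss-Hermite marginal log-likelihood over group intercepts."""
    y = np.asarray(y, float)
    eta0 = np.asarray(eta0, float)
    groups = np.asarray(groups)
    z, w = hermgauss(npts)
    total = 0.0
    for g in range(int(groups.max()) + 1):
        sel = groups == g

        def neg_joint(b):
            return -(nb2_logpmf_direct(y[sel], np.exp(eta0[sel] + b), alpha).sum() - b**2 / (2 * sigma2))

        res = optimize.minimize_scalar(neg_joint, bounds=(-10, 10), method="bounded")
        bhat = res.x
        h = optimize.approx_fprime([bhat], lambda b: optimize.approx_fprime(b, neg_joint, 1e-5)[0], 1e-5)[0]
        s = 1.0 / np.sqrt(max(h, 1e-12))
        logvals = [
            np.log(wi) + zi**2 - neg_joint(bhat + np.sqrt(2.0) * s * zi)
            for zi, wi in zip(z, w)
        ]
        m = max(logvals)
        integral = m + np.log(np.sum(np.exp(np.array(logvals) - m))) + np.log(np.sqrt(2.0) * s)
        total += integral - 0.5 * np.log(2 * np.pi * sigma2)
    return total


def toy_panel(seed=7, n_groups=5, n_cells=50, alpha=0.5, sigma2=0.25):
    """A 5-hospital, 50-cell toy panel for likelihood comparisons."""
    rng = np.random.default_rng(seed)
    groups = rng.integers(0, n_groups, n_cells)
    groups[:n_groups] = np.arange(n_groups)
    eta0 = rng.normal(-1.5, 0.5, n_cells) + np.log(rng.integers(5, 40, n_cells))
    b = rng.normal(0, np.sqrt(sigma2), n_groups)
    mu = np.exp(eta0 + b[groups])
    y = rng.negative_binomial(1 / alpha, (1 / alpha) / (1 / alpha + mu))
    return y.astype(float), eta0, groups
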