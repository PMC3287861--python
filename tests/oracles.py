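"""Independent oracle implementations used only by the test suite.

These deliberately avoid the library's own code paths: brute-force
loops, closed forms, and a characteristic-function inversion for the
weighted chi-square tail.
"""

import numpy as np
from scipy import integrate


def brute_polynomial_kernel(Z, degree, offset):
    Z = np.asarray(Z, float)
    n = Z.shape[0]
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = (np.dot(Z[i], Z[j]) + offset) ** degree
    return K


def brute_iis_entry(a, b):
    """Allele-sharing similarity between two genotype vectors, counted
    allele by allele."""
    total = 0
    for x, y in zip(a, b):
        # alleles identical in state at this SNP
        total += min(x, y) + min(2 - x, 2 - y)
    return total / (2.0 * len(a))


def ols_normal_equations(y, X):
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    sigma2 = resid @ resid / (X.shape[0] - X.shape[1])
    return beta, sigma2, resid


def imhof_pvalue(lam, q):
    """P(sum_j lam_j chi2_1 > q) by numerical inversion of the
    characteristic function (Imhof's integral)."""
    lam = np.asarray(lam, float)

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 1e-12, np.inf, limit=800)
    return 0.5 + val / np.pi


def kernel_ridge_via_features(Z, r, penalty):
    """Kernel ridge fit for the linear kernel computed in primal form:
    h = Z w with w = (Z'Z + penalty I)^-1 Z' r."""
    Z = np.asarray(Z, float)
    w = np.linalg.solve(Z.T @ Z + penalty * np.eye(Z.shape[1]), Z.T @ r)
    return Z @ w
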