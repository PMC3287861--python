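"""Variance-component score test for a kernel-machine genotype effect.

The null model y = X beta + e is fit by least squares; the alternative
adds a random effect h with Var(h) = tau * K.  Testing tau = 0 uses the
quadratic-form score statistic Q = r' K r / (2 sigma2_hat) whose null
distribution is a weighted sum of chi-square(1) variables with weights
given by the eigenvalues of P0 K P0 / 2, where P0 projects off the
column space of X.  P-values come from Satterthwaite moment matching
(fast path, traces only); a Monte-Carlo evaluation of the exact weighted
chi-square tail is provided as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .design import ModelSpec, build_design, _prune_collinear
from .kernels import KernelMatrix, build_kernel

__all__ = [
    "NullFit",
    "ScoreTestResult",
    "fit_null",
    "score_statistic",
    "satterthwaite_pvalue",
    "exact_pvalue_mc",
    "estimate_h_blup",
    "test_gene",
    "GeneModelTester",
]

P_FLOOR = 1e-300
# relative threshold below which the projected kernel counts as constant
_DEGENERATE_RTOL = 1e-10


@dataclass
class NullFit:
    """OLS fit of the fixed-effects-only null model."""

    beta_hat: np.ndarray
    sigma2_hat: float
    residuals: np.ndarray
    X: np.ndarray
    y: np.ndarray
    q_basis: np.ndarray  # orthonormal basis of col(X), for projections
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.X.shape[1]

    def project_residual_space(self, M: np.ndarray) -> np.ndarray:
        """Apply P0 = I - X (X'X)^-1 X' to the columns of M."""
        return M - self.q_basis @ (self.q_basis.T @ M)


class MCPValue(NamedTuple):
    p_value: float
    se: float


@dataclass
class ScoreTestResult:
    Q: float
    kappa: float
    nu: float
    p_value: float
    method: str  # "satterthwaite" | "degenerate" | "exact_mc"
    model_id: str | None = None
    gene_id: str | None = None


def fit_null(y, X) -> NullFit:
    """Least-squares fit of y on X; sigma2_hat = RSS / (n - q)."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, q = X.shape
    if y.shape[0] != n:
        raise ValueError("y length does not match X rows")
    if n <= q:
        raise ValueError(f"need n > q (got n={n}, q={q})")
    Qb, _ = np.linalg.qr(X)
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    rss = float(resid @ resid)
    sigma2 = rss / (n - q)
    degenerate = sigma2 <= max(P_FLOOR, 1e-14 * float(y @ y) / n)
    return NullFit(beta_hat=beta_hat, sigma2_hat=sigma2, residuals=resid,
                   X=X, y=y, q_basis=Qb, degenerate=degenerate)


def score_statistic(fit: NullFit, K: KernelMatrix | np.ndarray) -> float:
    """Q = r' K r / (2 sigma2_hat)."""
    Kv = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    r = fit.residuals
    if Kv.shape != (fit.n, fit.n):
        raise ValueError("kernel matrix shape does not match the fit")
    if fit.degenerate:
        return 0.0
    return float(r @ (Kv @ r)) / (2.0 * fit.sigma2_hat)


def _null_moments(fit: NullFit, Kv: np.ndarray):
    """Mean and variance of Q under the null (traces of P0 K P0)."""
    PK = fit.project_residual_space(Kv)
    A = fit.project_residual_space(PK.T)  # P0 K P0, symmetric up to fp error
    A = 0.5 * (A + A.T)
    mu = float(np.trace(A)) / 2.0
    var = float(np.sum(A * A)) / 2.0
    return mu, var, A


def _degenerate_result(Q: float = 0.0) -> ScoreTestResult:
    return ScoreTestResult(Q=Q, kappa=np.nan, nu=np.nan, p_value=1.0, method="degenerate")


def satterthwaite_pvalue(fit: NullFit, K: KernelMatrix | np.ndarray,
                         Q: float | None = None) -> ScoreTestResult:
    """Scaled chi-square approximation matched on the first two moments.

    kappa = var / (2 mu), nu = 2 mu^2 / var, p = P(chi2_nu > Q / kappa).
    Constant kernels on the residual space give p = 1.
    """
    Kv = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    if fit.degenerate:
        return _degenerate_result()
    if Q is None:
        Q = score_statistic(fit, Kv)
    mu, var, _ = _null_moments(fit, Kv)
    scale = max(float(np.abs(Kv).max()), 1e-30) * fit.n
    if mu <= _DEGENERATE_RTOL * scale or var <= (_DEGENERATE_RTOL * scale) ** 2:
        return _degenerate_result(Q)
    kappa = var / (2.0 * mu)
    nu = 2.0 * mu * mu / var
    p = float(stats.chi2.sf(Q / kappa, nu))
    p = min(1.0, max(P_FLOOR, p))
    return ScoreTestResult(Q=Q, kappa=kappa, nu=nu, p_value=p, method="satterthwaite")


def null_eigenvalues(fit: NullFit, K: KernelMatrix | np.ndarray,
                     rtol: float = 1e-10) -> np.ndarray:
    """Nonnegligible eigenvalues of P0 K P0 / 2 (weights of the null mixture)."""
    Kv = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    _, _, A = _null_moments(fit, Kv)
    lam = np.linalg.eigvalsh(A) / 2.0
    # threshold on the kernel's own scale so a constant kernel (A ~ fp
    # noise) yields no eigenvalues at all
    scale = max(float(np.abs(Kv).max()), 1e-30)
    return lam[np.abs(lam) > rtol * scale]


def exact_pvalue_mc(fit: NullFit, K: KernelMatrix | np.ndarray, Q: float,
                    n_draws: int = 1_000_000, seed: int = 0) -> MCPValue:
    """Monte-Carlo tail probability of the exact weighted chi-square null.

    Draws sum_j lambda_j chi2_1 with lambda_j the eigenvalues of
    P0 K P0 / 2 and reports P(sum >= Q) with its binomial standard error.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    lam = null_eigenvalues(fit, K)
    if lam.size == 0:
        return MCPValue(1.0, 0.0)
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, int(5e6 // lam.size))
    remaining = int(n_draws)
    while remaining > 0:
        b = min(chunk, remaining)
        draws = rng.chisquare(1.0, size=(b, lam.size)) @ lam
        hits += int(np.count_nonzero(draws >= Q))
        remaining -= b
    p = hits / n_draws
    se = float(np.sqrt(max(p * (1 - p), 1.0 / n_draws) / n_draws))
    return MCPValue(p, se)


def estimate_h_blup(fit: NullFit, K: KernelMatrix | np.ndarray, tau: float) -> np.ndarray:
    """BLUP of the kernel random effect: tau K (tau K + sigma2 I)^-1 r.

    Coincides with the kernel-ridge-regression fit with penalty
    sigma2_hat / tau; exposed to exercise the mixed-model equivalence.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    Kv = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    r = fit.residuals
    if tau == 0:
        return np.zeros_like(r)
    M = tau * Kv + fit.sigma2_hat * np.eye(fit.n)
    try:
        x = np.linalg.solve(M, r)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * max(np.abs(M).max(), 1.0)
        import logging
        logging.getLogger(__name__).warning("singular BLUP system; adding ridge jitter %g", jitter)
        x = np.linalg.solve(M + jitter * np.eye(fit.n), r)
    return tau * (Kv @ x)


class GeneModelTester:
    """Precomputed design + kernel + null moments for one gene and model.

    Genotypes (and hence the kernel and the Satterthwaite moments) are
    fixed across phenotype replicates, so everything except the residual
    quadratic form is computed once.  ``test`` handles a single phenotype
    vector, ``test_many`` a matrix of replicate columns.
    """

    def __init__(self, model: ModelSpec, G: pd.DataFrame, covariates: pd.DataFrame,
                 G_wide: pd.DataFrame | None = None, gene_id: str | None = None):
        self.model = model
        self.gene_id = gene_id
        bundle = build_design(model, G, covariates, G_wide)
        self.bundle = bundle
        X = bundle.X
        if bundle.main_effect_block.shape[1] > 0:
            X = np.hstack([X, bundle.main_effect_block])
            names = bundle.x_names + bundle.main_effect_names
            X, _ = _prune_collinear(X, names)
        self.X = X
        self.n, self.q = X.shape
        self.q_basis, _ = np.linalg.qr(X)
        self.K = build_kernel(model.resolved_kernel(), bundle.kernel_input)
        Kv = self.K.values
        PK = Kv - self.q_basis @ (self.q_basis.T @ Kv)
        A = PK - (PK @ self.q_basis) @ self.q_basis.T
        A = 0.5 * (A + A.T)
        self._A = A
        self.mu = float(np.trace(A)) / 2.0
        self.var = float(np.sum(A * A)) / 2.0
        scale = max(float(np.abs(Kv).max()), 1e-30) * self.n
        self.degenerate_kernel = (
            self.mu <= _DEGENERATE_RTOL * scale or self.var <= (_DEGENERATE_RTOL * scale) ** 2
        )
        if not self.degenerate_kernel:
            self.kappa = self.var / (2.0 * self.mu)
            self.nu = 2.0 * self.mu ** 2 / self.var
        else:
            self.kappa = np.nan
            self.nu = np.nan

    def _residualize(self, Y: np.ndarray) -> np.ndarray:
        return Y - self.q_basis @ (self.q_basis.T @ Y)

    def test(self, y) -> ScoreTestResult:
        res = self.test_many(np.asarray(y, dtype=float).reshape(-1, 1))
        return res[0]

    def test_many(self, Y) -> list[ScoreTestResult]:
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != self.n:
            raise ValueError("phenotype rows do not match design")
        R = self._residualize(Y)
        rss = np.sum(R * R, axis=0)
        sigma2 = rss / (self.n - self.q)
        yy = np.sum(Y * Y, axis=0)
        degen_y = sigma2 <= np.maximum(P_FLOOR, 1e-14 * yy / self.n)
        results: list[ScoreTestResult] = []
        if self.degenerate_kernel:
            for _ in range(Y.shape[1]):
                r = _degenerate_result()
                r.model_id, r.gene_id = self.model.model_id, self.gene_id
                results.append(r)
            return results
        quad = np.sum(R * (self.K.values @ R), axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            Qs = np.where(degen_y, 0.0, quad / (2.0 * np.where(degen_y, 1.0, sigma2)))
        ps = stats.chi2.sf(Qs / self.kappa, self.nu)
        for j in range(Y.shape[1]):
            if degen_y[j]:
                r = _degenerate_result()
            else:
                p = min(1.0, max(P_FLOOR, float(ps[j])))
                r = ScoreTestResult(Q=float(Qs[j]), kappa=self.kappa, nu=self.nu,
                                    p_value=p, method="satterthwaite")
            r.model_id, r.gene_id = self.model.model_id, self.gene_id
            results.append(r)
        return results


def test_gene(y, model: ModelSpec, G: pd.DataFrame, covariates: pd.DataFrame,
              G_wide: pd.DataFrame | None = None, gene_id: str | None = None) -> ScoreTestResult:
    """End-to-end: build design, build kernel, fit null, Satterthwaite p."""
    tester = GeneModelTester(model, G, covariates, G_wide, gene_id=gene_id)
    return tester.test(y)
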