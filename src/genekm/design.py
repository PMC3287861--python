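"""Fixed-effect design and kernel-input construction for the six models.

Model identifiers:

========  ==============================================================
M2        baseline: gene genotypes enter the smoothing term
M10       collapsed: per-sample minor-allele sum c enters the term
M11       interaction-only, per-SNP products; genotype main effects
          move to the parametric part
M12       interaction-only on the collapsed sum
M13       joint: [G | s | G*s] enters the term (quadratic kernel default)
M14       joint on the collapsed sum: [c | s | c*s]
========  ==============================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import KernelSpec

logger = logging.getLogger(__name__)

MODEL_IDS = ("M2", "M10", "M11", "M12", "M13", "M14")

__all__ = [
    "ModelSpec",
    "DesignBundle",
    "collapse_genotypes",
    "interaction_terms",
    "joint_kernel_input",
    "compute_pcs",
    "build_design",
    "MODEL_IDS",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit, with kernel choice and stratification PCs.

    ``kernel=None`` resolves to a quadratic kernel for the joint models
    M13/M14 and a linear kernel otherwise.
    """

    model_id: str
    kernel: KernelSpec | None = None
    n_pcs: int = 0
    environment_column: str = "Smoking"

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}; expected one of {MODEL_IDS}")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be nonnegative")

    def resolved_kernel(self) -> KernelSpec:
        if self.kernel is not None:
            return self.kernel
        if self.model_id in ("M13", "M14"):
            return KernelSpec(kind="polynomial", degree=2, offset=0.0)
        return KernelSpec(kind="linear")


@dataclass
class DesignBundle:
    """Design pieces for one gene under one model.

    ``X`` is the fixed-effect matrix (intercept, covariates, PCs);
    ``kernel_input`` feeds the kernel; ``main_effect_block`` holds
    genotype main effects that are fit parametrically under the null
    (models M11/M12 only, empty otherwise).
    """

    X: np.ndarray
    kernel_input: np.ndarray
    main_effect_block: np.ndarray
    x_names: list[str] = field(default_factory=list)
    kernel_input_names: list[str] = field(default_factory=list)
    main_effect_names: list[str] = field(default_factory=list)
    sample_ids: list = field(default_factory=list)


def collapse_genotypes(G) -> np.ndarray:
    """Per-sample sum of minor-allele counts across a gene's SNPs."""
    Garr = np.asarray(G, dtype=float)
    if Garr.ndim != 2:
        raise ValueError("G must be 2-D")
    if not np.isin(Garr[np.isfinite(Garr)], (0.0, 1.0, 2.0)).all():
        raise ValueError("genotype entries must be in {0, 1, 2}")
    return Garr.sum(axis=1)


def interaction_terms(Gc, s) -> np.ndarray:
    """Product terms between a binary exposure and genotypes (or the sum).

    Each row of ``Gc`` is multiplied by the sample's exposure indicator,
    so unexposed rows are identically zero.  Continuous exposures are
    rejected.
    """
    Gc = np.asarray(Gc, dtype=float)
    if Gc.ndim == 1:
        Gc = Gc[:, None]
    s = np.asarray(s, dtype=float).ravel()
    if s.shape[0] != Gc.shape[0]:
        raise ValueError("exposure length does not match genotype rows")
    if not np.isin(s, (0.0, 1.0)).all():
        raise ValueError("exposure must be binary 0/1 (continuous exposures are not supported)")
    return Gc * s[:, None]


def joint_kernel_input(Gc, s, T) -> np.ndarray:
    """Column-concatenate [genotypes | exposure | products] for joint models."""
    Gc = np.asarray(Gc, dtype=float)
    if Gc.ndim == 1:
        Gc = Gc[:, None]
    T = np.asarray(T, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    s = np.asarray(s, dtype=float).ravel()
    if not (Gc.shape[0] == T.shape[0] == s.shape[0]):
        raise ValueError("dimension mismatch between genotypes, exposure and products")
    return np.hstack([Gc, s[:, None], T])


def compute_pcs(G_wide, k: int, standardize: bool = True) -> np.ndarray:
    """Top-k principal component scores of a genome-wide genotype matrix.

    Columns are centered and (by default) scaled by their sample standard
    deviation, skipping zero-variance SNPs.  Scores are ordered by
    decreasing eigenvalue; the sign of each component is fixed by forcing
    its largest-magnitude loading positive.  If ``k`` exceeds the matrix
    rank the trailing components are zero-variance and a warning is
    logged.
    """
    Garr = np.asarray(G_wide, dtype=float)
    if Garr.ndim != 2:
        raise ValueError("G_wide must be 2-D")
    n, P = Garr.shape
    if k == 0:
        return np.empty((n, 0))
    if k > min(n, P):
        raise ValueError("k must not exceed min(n_samples, n_snps)")
    Z = Garr - Garr.mean(axis=0)
    if standardize:
        sd = Garr.std(axis=0, ddof=1)
        keep = sd > 0
        Z = Z[:, keep] / sd[keep]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if k > rank:
        logger.warning("compute_pcs: requested %d PCs but rank is %d; trailing PCs are zero", k, rank)
    scores = U[:, :k] * S[:k]
    for j in range(min(k, Vt.shape[0])):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            scores[:, j] = -scores[:, j]
    scores[:, rank:] = 0.0
    return scores


def _prune_collinear(X: np.ndarray, names: list[str], tol: float = 1e-8):
    """Greedy rank filter keeping earlier columns; deterministic."""
    n = X.shape[0]
    kept_idx: list[int] = []
    Q = np.empty((n, 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        resid = col - Q @ (Q.T @ col)
        norm = np.linalg.norm(resid)
        scale = max(np.linalg.norm(col), 1.0)
        if norm > tol * scale:
            Q = np.hstack([Q, (resid / norm)[:, None]])
            kept_idx.append(j)
        else:
            logger.warning("dropping collinear design column %r", names[j])
    return X[:, kept_idx], [names[j] for j in kept_idx]


def _base_covariate_matrix(covariates: pd.DataFrame, env_col: str):
    required = ["Sex", "Age", env_col]
    for c in required:
        if c not in covariates.columns:
            raise ValueError(f"covariate table is missing required column {c!r}")
    n = len(covariates)
    age = covariates["Age"].to_numpy(dtype=float)
    sd = age.std(ddof=1)
    age_z = (age - age.mean()) / sd if sd > 0 else np.zeros(n)
    cols = [np.ones(n), covariates["Sex"].to_numpy(dtype=float), age_z,
            covariates[env_col].to_numpy(dtype=float)]
    names = ["intercept", "Sex", "Age", env_col]
    return np.column_stack(cols), names


def build_design(model: ModelSpec, G: pd.DataFrame, covariates: pd.DataFrame,
                 G_wide: pd.DataFrame | None = None) -> DesignBundle:
    """Assemble X / kernel_input / main_effect_block for one gene.

    ``G`` and ``covariates`` (and ``G_wide`` when PCs are requested) must
    carry identical sample IDs in identical order; a mismatch is a hard
    error rather than a silent reindex.
    """
    if not G.index.equals(covariates.index):
        raise ValueError("sample IDs of genotype and covariate tables do not match")
    X, names = _base_covariate_matrix(covariates, model.environment_column)
    if model.n_pcs > 0:
        if G_wide is None:
            raise ValueError("n_pcs > 0 requires a genome-wide genotype matrix")
        if not G.index.equals(G_wide.index):
            raise ValueError("sample IDs of G_wide do not match")
        pcs = compute_pcs(G_wide.to_numpy(dtype=float), model.n_pcs)
        X = np.hstack([X, pcs])
        names = names + [f"PC{j + 1}" for j in range(pcs.shape[1])]
    X, names = _prune_collinear(X, names)
    n, q = X.shape
    if model.n_pcs > n - q - 1:
        logger.warning("n_pcs=%d is large relative to n=%d and q=%d", model.n_pcs, n, q)

    Garr = G.to_numpy(dtype=float)
    snp_names = [str(c) for c in G.columns]
    if np.any(np.all(Garr == 0, axis=0)):
        logger.warning("gene contains monomorphic all-zero SNP columns; retained")
    s = covariates[model.environment_column].to_numpy(dtype=float)
    empty = np.empty((n, 0))

    mid = model.model_id
    if mid == "M2":
        kin, kin_names = Garr, snp_names
        main, main_names = empty, []
    elif mid == "M10":
        c = collapse_genotypes(Garr)
        kin, kin_names = c[:, None], ["c"]
        main, main_names = empty, []
    elif mid == "M11":
        T = interaction_terms(Garr, s)
        kin, kin_names = T, [f"{nm}:{model.environment_column}" for nm in snp_names]
        main, main_names = Garr, snp_names
    elif mid == "M12":
        c = collapse_genotypes(Garr)
        T = interaction_terms(c, s)
        kin, kin_names = T, [f"c:{model.environment_column}"]
        main, main_names = c[:, None], ["c"]
    elif mid == "M13":
        T = interaction_terms(Garr, s)
        kin = joint_kernel_input(Garr, s, T)
        kin_names = snp_names + [model.environment_column] + \
            [f"{nm}:{model.environment_column}" for nm in snp_names]
        main, main_names = empty, []
    elif mid == "M14":
        c = collapse_genotypes(Garr)
        T = interaction_terms(c, s)
        kin = joint_kernel_input(c, s, T)
        kin_names = ["c", model.environment_column, f"c:{model.environment_column}"]
        main, main_names = empty, []
    else:  # pragma: no cover - guarded by ModelSpec
        raise ValueError(f"unknown model_id {mid!r}")

    return DesignBundle(
        X=X, kernel_input=kin, main_effect_block=main,
        x_names=names, kernel_input_names=kin_names, main_effect_names=main_names,
        sample_ids=list(G.index),
    )
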