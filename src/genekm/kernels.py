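"""Kernel matrix construction for genotype (and augmented) input matrices.

Four kernels are supported: linear, polynomial, Gaussian (radial basis),
and an allele-sharing similarity kernel for genotype matrices coded as
minor-allele counts.  All constructors return a :class:`KernelMatrix`
whose ``values`` array has been symmetrized and validated.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)

KERNEL_KINDS = ("linear", "polynomial", "gaussian", "iis")

__all__ = [
    "KernelSpec",
    "KernelMatrix",
    "polynomial_kernel",
    "quadratic_feature_map",
    "gaussian_kernel",
    "iis_kernel",
    "build_kernel",
]


@dataclass(frozen=True)
class KernelSpec:
    """Parameters selecting a kernel function.

    ``linear`` is the ``polynomial`` kernel with ``degree=1, offset=0``
    and must produce identical matrices.  ``bandwidth`` applies to the
    Gaussian kernel only; if left ``None`` it defaults to the number of
    input columns at construction time.
    """

    kind: str = "linear"
    degree: int = 2
    offset: float = 0.0
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; expected one of {KERNEL_KINDS}")
        if int(self.degree) != self.degree or self.degree < 1:
            raise ValueError("degree must be a positive integer")
        if self.offset < 0:
            raise ValueError("offset must be nonnegative")
        if self.bandwidth is not None and not self.bandwidth > 0:
            raise ValueError("bandwidth must be positive")


@dataclass
class KernelMatrix:
    """A symmetric n-by-n similarity matrix with its provenance."""

    values: np.ndarray
    spec: KernelSpec
    input_hash: str = ""

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path, sample_ids=None) -> None:
        """Write the square matrix as TSV with sample IDs on both axes."""
        import pandas as pd

        ids = list(sample_ids) if sample_ids is not None else list(range(self.n))
        pd.DataFrame(self.values, index=ids, columns=ids).to_csv(path, sep="\t")


def _hash_matrix(Z: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(Z).tobytes()).hexdigest()[:16]


def _validate_input(Z, *, name: str = "Z") -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.ndim != 2 or Z.size == 0:
        raise ValueError(f"{name} must be a nonempty 2-D matrix")
    if not np.all(np.isfinite(Z)):
        raise ValueError(f"{name} contains non-finite entries")
    return Z


def _finalize(values: np.ndarray, spec: KernelSpec, Z: np.ndarray) -> KernelMatrix:
    values = 0.5 * (values + values.T)  # enforce exact symmetry
    return KernelMatrix(values=values, spec=spec, input_hash=_hash_matrix(Z))


def polynomial_kernel(Z, degree: int = 2, offset: float = 0.0) -> KernelMatrix:
    """Entry (i, i') = (z_i . z_i' + offset)**degree.

    ``degree=1, offset=0`` is the linear kernel Z Z^T.
    """
    Z = _validate_input(Z)
    if int(degree) != degree or degree < 1:
        raise ValueError("degree must be a positive integer")
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    gram = Z @ Z.T
    values = (gram + offset) ** degree
    spec = KernelSpec(kind="polynomial", degree=int(degree), offset=float(offset))
    return _finalize(values, spec, Z)


def quadratic_feature_map(g, offset: float = 0.0) -> np.ndarray:
    """Explicit feature map phi with phi(a) . phi(b) == (a . b + offset)**2.

    For a length-m input the map emits the m squared coordinates and the
    m(m-1)/2 pairwise products scaled by sqrt(2), ordered row-wise along
    the upper triangle: (g1^2, sqrt(2) g1 g2, ..., g2^2, ...).  A positive
    ``offset`` prepends the constant ``offset`` and sqrt(2*offset)-scaled
    linear terms, adding m + 1 coordinates.
    """
    g = np.asarray(g, dtype=float).ravel()
    if g.size == 0:
        raise ValueError("input vector must be nonempty")
    if not np.all(np.isfinite(g)):
        raise ValueError("input vector contains non-finite entries")
    m = g.size
    outer = np.outer(g, g)
    iu, ju = np.triu_indices(m)
    feats = outer[iu, ju]
    feats[iu != ju] *= np.sqrt(2.0)
    if offset > 0:
        feats = np.concatenate([[offset], np.sqrt(2.0 * offset) * g, feats])
    return feats


def gaussian_kernel(Z, bandwidth: float | None = None) -> KernelMatrix:
    """Entry (i, i') = exp(-||z_i - z_i'||^2 / bandwidth); unit diagonal.

    ``bandwidth`` defaults to the number of input columns.
    """
    Z = _validate_input(Z)
    if bandwidth is None:
        bandwidth = float(Z.shape[1])
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    sq = squareform(pdist(Z, metric="sqeuclidean"))
    values = np.exp(-sq / bandwidth)
    spec = KernelSpec(kind="gaussian", bandwidth=float(bandwidth))
    return _finalize(values, spec, Z)


def _check_genotypes(G: np.ndarray, missing: str) -> np.ndarray:
    nan_mask = np.isnan(G)
    if nan_mask.any():
        if missing != "impute":
            raise ValueError(
                "genotype matrix contains missing values; pass missing='impute' to allow"
            )
        col_means = np.nanmean(np.where(nan_mask, np.nan, G), axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        fill = np.clip(np.rint(col_means), 0, 2)
        G = np.where(nan_mask, fill[None, :], G)
    bad = ~np.isin(G, (0.0, 1.0, 2.0))
    if bad.any():
        raise ValueError("genotype matrix entries must be minor-allele counts in {0, 1, 2}")
    return G


def iis_kernel(G, normalization: str = "2p", missing: str = "error") -> KernelMatrix:
    """Allele-sharing similarity kernel on a {0,1,2} genotype matrix.

    Per-SNP similarity between two individuals is the number of alleles
    identical in state, 2 - |g_ik - g_i'k|; the kernel entry averages this
    over SNPs.  With the default ``normalization='2p'`` entries lie in
    [0, 1] with unit diagonal; ``normalization='p'`` rescales to [0, 2].
    Missing genotypes (NaN) are rejected unless ``missing='impute'``, in
    which case they are imputed to the per-SNP mean rounded to the nearest
    integer count.
    """
    Garr = np.asarray(G, dtype=float)
    if Garr.ndim == 1:
        Garr = Garr[:, None]
    if Garr.ndim != 2 or Garr.size == 0:
        raise ValueError("G must be a nonempty 2-D matrix")
    if np.any(np.isinf(Garr)):
        raise ValueError("G contains non-finite entries")
    Garr = _check_genotypes(Garr, missing)
    if normalization not in ("2p", "p"):
        raise ValueError("normalization must be '2p' or 'p'")
    p = Garr.shape[1]
    if np.any(np.all(Garr == 0, axis=0)):
        logger.warning("iis_kernel: genotype matrix contains monomorphic all-zero SNP columns")
    manhattan = squareform(pdist(Garr, metric="cityblock"))
    shared = 2.0 * p - manhattan
    denom = 2.0 * p if normalization == "2p" else float(p)
    values = shared / denom
    spec = KernelSpec(kind="iis")
    km = _finalize(values, spec, Garr)
    if normalization == "2p":
        np.fill_diagonal(km.values, 1.0)
    return km


def build_kernel(spec: KernelSpec, Z) -> KernelMatrix:
    """Dispatch on ``spec.kind``; the entry point used by model drivers."""
    if spec.kind == "linear":
        return polynomial_kernel(Z, degree=1, offset=0.0)
    if spec.kind == "polynomial":
        return polynomial_kernel(Z, degree=spec.degree, offset=spec.offset)
    if spec.kind == "gaussian":
        return gaussian_kernel(Z, bandwidth=spec.bandwidth)
    if spec.kind == "iis":
        return iis_kernel(Z)
    raise ValueError(f"unknown kernel kind {spec.kind!r}")
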