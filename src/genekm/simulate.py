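"""Synthetic exome-style fixtures: rare-variant genes, latent population
structure, covariates, and replicated quantitative phenotypes with a
single gene-by-smoking interaction.

The layout mimics a workshop-style resource of ~700 unrelated
individuals: genotypes are drawn once per seed and held fixed, while
many phenotype replicates are generated on top of them, so p-value
dependence across replicates (shared genotypes) is reproduced.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneConfig",
    "SimConfig",
    "ReplicateSet",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_phenotypes",
    "simulate",
    "write_fixture",
    "read_fixture",
    "default_config",
    "null_config",
    "stratified_config",
]


@dataclass
class GeneConfig:
    """Per-gene SNP count, allele-frequency spectrum and effect sizes.

    ``beta_main`` and ``beta_gxe`` act on the collapsed minor-allele sum
    of the gene; at most one gene in a configuration may carry a nonzero
    ``beta_gxe``.
    """

    gene_id: str
    n_snps: int = 10
    rare_fraction: float = 0.9
    rare_maf_range: tuple[float, float] = (0.005, 0.05)
    common_maf_range: tuple[float, float] = (0.05, 0.2)
    beta_main: float = 0.0
    beta_gxe: float = 0.0
    divergence: float | None = None  # per-gene override of the global Fst
    # deterministic between-subpop frequency shift (every SNP shifted the
    # same way, so the collapsed genotype proxies the latent label)
    subpop_maf_shift: float | None = None

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if not 0.0 <= self.rare_fraction <= 1.0:
            raise ValueError("rare_fraction must be in [0, 1]")
        for lo, hi in (self.rare_maf_range, self.common_maf_range):
            if not (0.0 < lo <= hi <= 0.5):
                raise ValueError("MAF ranges must satisfy 0 < lo <= hi <= 0.5")


@dataclass
class SimConfig:
    n_samples: int = 697
    genes: list[GeneConfig] = field(default_factory=list)
    n_background_snps: int = 1000
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    n_subpops: int = 2
    divergence: float = 0.05  # Fst-like allele-frequency divergence
    subpop_trait_shift: float = 0.0  # trait mean shift per subpop index
    smoking_rate: float | tuple[float, ...] = 0.3  # scalar or per-subpop
    sex_rate: float = 0.5
    age_mean: float = 49.0
    age_sd: float = 12.0
    beta_sex: float = 0.5
    beta_age: float = 0.02
    beta_smoking: float = 0.5
    sigma_e: float = 1.0
    n_replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")
        n_gxe = sum(1 for g in self.genes if g.beta_gxe != 0.0)
        if n_gxe > 1:
            raise ValueError("at most one gene may carry a nonzero interaction effect")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["genes"] = [GeneConfig(**{**g, "rare_maf_range": tuple(g["rare_maf_range"]),
                                    "common_maf_range": tuple(g["common_maf_range"])})
                      for g in d.get("genes", [])]
        d["background_maf_range"] = tuple(d["background_maf_range"])
        if isinstance(d.get("smoking_rate"), list):
            d["smoking_rate"] = tuple(d["smoking_rate"])
        return cls(**d)


@dataclass
class ReplicateSet:
    """A full fixture: fixed genotypes plus replicated phenotypes."""

    G_wide: pd.DataFrame          # n x P minor-allele counts, all SNPs
    gene_map: pd.DataFrame        # columns gene_id, snp_id
    covariates: pd.DataFrame      # Sex, Age, Smoking
    subpop: pd.Series             # latent subpopulation labels
    Y: pd.DataFrame               # n x n_replicates phenotypes
    truth: dict                   # gene_id -> {"null", "main_only", "gxe"}
    config: SimConfig

    def gene_genotypes(self, gene_id: str) -> pd.DataFrame:
        snps = self.gene_map.loc[self.gene_map["gene_id"] == gene_id, "snp_id"]
        if snps.empty:
            raise KeyError(f"unknown gene {gene_id!r}")
        return self.G_wide[list(snps)]

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.gene_map["gene_id"]))


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _draw_mafs(rng, gene: GeneConfig) -> np.ndarray:
    rare = rng.random(gene.n_snps) < gene.rare_fraction
    lo_r, hi_r = gene.rare_maf_range
    lo_c, hi_c = gene.common_maf_range
    mafs = np.where(rare, rng.uniform(lo_r, hi_r, gene.n_snps),
                    rng.uniform(lo_c, hi_c, gene.n_snps))
    return mafs


def simulate_genotypes(config: SimConfig):
    """Draw the fixed genotype matrix.

    Per SNP an ancestral MAF is drawn from its spectrum; subpopulation
    frequencies follow a Balding-Nichols Beta draw with the configured
    divergence; genotypes are Binomial(2, subpop frequency).  After
    sampling, each SNP is relabeled so the recorded allele is the minor
    allele in the pooled sample.

    Returns ``(G_wide, gene_map, subpop)``.
    """
    rng = _rng(config, 0)
    n = config.n_samples

    snp_ids: list[str] = []
    gene_rows: list[tuple[str, str]] = []
    mafs: list[np.ndarray] = []
    divs: list[np.ndarray] = []
    for gene in config.genes:
        ids = [f"{gene.gene_id}_snp{k + 1}" for k in range(gene.n_snps)]
        snp_ids.extend(ids)
        gene_rows.extend((gene.gene_id, sid) for sid in ids)
        mafs.append(_draw_mafs(rng, gene))
        F_gene = config.divergence if gene.divergence is None else gene.divergence
        divs.append(np.full(gene.n_snps, F_gene))
    if config.n_background_snps > 0:
        lo, hi = config.background_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("background MAF range must satisfy 0 < lo <= hi <= 0.5")
        snp_ids.extend(f"bg_snp{k + 1}" for k in range(config.n_background_snps))
        mafs.append(rng.uniform(lo, hi, config.n_background_snps))
        divs.append(np.full(config.n_background_snps, config.divergence))
    if not snp_ids:
        raise ValueError("configuration defines no SNPs")
    maf = np.concatenate(mafs)
    F = np.concatenate(divs)
    P = maf.size

    shift = np.full(P, np.nan)
    offset = 0
    for gene in config.genes:
        if gene.subpop_maf_shift is not None:
            shift[offset:offset + gene.n_snps] = gene.subpop_maf_shift
        offset += gene.n_snps

    subpop = rng.integers(0, config.n_subpops, size=n)
    sub_freq = np.tile(maf, (config.n_subpops, 1))
    drift = (F > 0) & np.isnan(shift)
    if drift.any():
        a = maf[drift] * (1.0 - F[drift]) / F[drift]
        b = (1.0 - maf[drift]) * (1.0 - F[drift]) / F[drift]
        sub_freq[:, drift] = rng.beta(a[None, :], b[None, :],
                                      size=(config.n_subpops, int(drift.sum())))
    det = ~np.isnan(shift)
    if det.any():
        centers = np.arange(config.n_subpops) - (config.n_subpops - 1) / 2.0
        sub_freq[:, det] = np.clip(
            maf[None, det] + shift[None, det] * centers[:, None], 0.01, 0.99)
    G = rng.binomial(2, sub_freq[subpop, :]).astype(np.int64)

    # relabel so that the stored count refers to the pooled minor allele
    flip = G.mean(axis=0) / 2.0 > 0.5
    G[:, flip] = 2 - G[:, flip]

    sample_ids = [f"ind{i + 1:04d}" for i in range(n)]
    G_wide = pd.DataFrame(G, index=pd.Index(sample_ids, name="sample_id"), columns=snp_ids)
    G_wide.attrs["ancestral_maf"] = maf.tolist()
    G_wide.attrs["flipped"] = flip.tolist()
    gene_map = pd.DataFrame(gene_rows, columns=["gene_id", "snp_id"])
    subpop_s = pd.Series(subpop, index=G_wide.index, name="subpop")
    return G_wide, gene_map, subpop_s


def simulate_covariates(config: SimConfig, subpop: pd.Series) -> pd.DataFrame:
    """Sex ~ Bernoulli, Age ~ Normal, Smoking ~ Bernoulli (optionally
    subpopulation-specific smoking prevalence)."""
    rng = _rng(config, 1)
    n = config.n_samples
    sex = rng.binomial(1, config.sex_rate, n)
    age = rng.normal(config.age_mean, config.age_sd, n)
    rate = config.smoking_rate
    if np.isscalar(rate):
        smk_p = np.full(n, float(rate))
    else:
        rates = np.asarray(rate, dtype=float)
        if rates.size != config.n_subpops:
            raise ValueError("per-subpop smoking rates must match n_subpops")
        smk_p = rates[subpop.to_numpy()]
    smoking = rng.binomial(1, smk_p)
    return pd.DataFrame({"Sex": sex, "Age": age, "Smoking": smoking}, index=subpop.index)


def simulate_phenotypes(G_wide: pd.DataFrame, gene_map: pd.DataFrame,
                        covariates: pd.DataFrame, subpop: pd.Series,
                        config: SimConfig) -> pd.DataFrame:
    """Replicated quantitative trait on the fixed genotypes.

    y = b_sex Sex + b_age Age + b_smk s + sum_g beta_main c_g
        + beta_gxe s * c_gxe + shift(subpop) + e,   e ~ N(0, sigma_e^2),
    with independent noise across replicates.
    """
    rng = _rng(config, 2)
    n = len(G_wide)
    known = set(gene_map["gene_id"])
    for gene in config.genes:
        if (gene.beta_main != 0 or gene.beta_gxe != 0) and gene.gene_id not in known:
            raise ValueError(f"effect specified for unknown gene {gene.gene_id!r}")
    s = covariates["Smoking"].to_numpy(dtype=float)
    mean = (config.beta_sex * covariates["Sex"].to_numpy(dtype=float)
            + config.beta_age * covariates["Age"].to_numpy(dtype=float)
            + config.beta_smoking * s)
    for gene in config.genes:
        if gene.beta_main == 0 and gene.beta_gxe == 0:
            continue
        snps = gene_map.loc[gene_map["gene_id"] == gene.gene_id, "snp_id"]
        c = G_wide[list(snps)].to_numpy(dtype=float).sum(axis=1)
        mean = mean + gene.beta_main * c + gene.beta_gxe * s * c
    mean = mean + config.subpop_trait_shift * subpop.to_numpy(dtype=float)
    noise = rng.normal(0.0, config.sigma_e, size=(n, config.n_replicates))
    Y = mean[:, None] + noise
    cols = [f"rep{r + 1:04d}" for r in range(config.n_replicates)]
    return pd.DataFrame(Y, index=G_wide.index, columns=cols)


def _truth_labels(config: SimConfig) -> dict:
    labels = {}
    for gene in config.genes:
        if gene.beta_gxe != 0:
            labels[gene.gene_id] = "gxe"
        elif gene.beta_main != 0:
            labels[gene.gene_id] = "main_only"
        else:
            labels[gene.gene_id] = "null"
    return labels


def simulate(config: SimConfig) -> ReplicateSet:
    """Full draw: genotypes, covariates, phenotype replicates, truth."""
    G_wide, gene_map, subpop = simulate_genotypes(config)
    covariates = simulate_covariates(config, subpop)
    Y = simulate_phenotypes(G_wide, gene_map, covariates, subpop, config)
    return ReplicateSet(G_wide=G_wide, gene_map=gene_map, covariates=covariates,
                        subpop=subpop, Y=Y, truth=_truth_labels(config), config=config)


def write_fixture(rs: ReplicateSet, directory) -> dict[str, Path]:
    """Write the fixture as plain TSV files plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": directory / "genotypes.tsv",
        "gene_map": directory / "genemap.tsv",
        "covariates": directory / "covariates.tsv",
        "phenotypes": directory / "phenotypes.tsv",
        "meta": directory / "sim_meta.json",
    }
    rs.G_wide.to_csv(paths["genotypes"], sep="\t")
    rs.gene_map.to_csv(paths["gene_map"], sep="\t", index=False)
    rs.covariates.to_csv(paths["covariates"], sep="\t", index_label="sample_id")
    rs.Y.to_csv(paths["phenotypes"], sep="\t", index_label="sample_id")
    meta = {
        "config": rs.config.to_dict(),
        "truth": rs.truth,
        "subpop": rs.subpop.astype(int).tolist(),
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return paths


def read_fixture(directory) -> ReplicateSet:
    directory = Path(directory)
    G_wide = pd.read_csv(directory / "genotypes.tsv", sep="\t", index_col="sample_id")
    gene_map = pd.read_csv(directory / "genemap.tsv", sep="\t")
    covariates = pd.read_csv(directory / "covariates.tsv", sep="\t", index_col="sample_id")
    Y = pd.read_csv(directory / "phenotypes.tsv", sep="\t", index_col="sample_id")
    meta = json.loads((directory / "sim_meta.json").read_text())
    config = SimConfig.from_dict(meta["config"])
    subpop = pd.Series(meta["subpop"], index=G_wide.index, name="subpop")
    return ReplicateSet(G_wide=G_wide, gene_map=gene_map, covariates=covariates,
                        subpop=subpop, Y=Y, truth=meta["truth"], config=config)


def default_config(seed: int = 0, n_replicates: int = 200,
                   beta_gxe: float = 0.25, beta_main: float = 0.4) -> SimConfig:
    """Default fixture: one interaction gene, one main-effect gene, two
    noise genes, plus background SNPs for stratification PCs."""
    genes = [
        GeneConfig("GXE1", beta_gxe=beta_gxe),
        GeneConfig("MAIN1", beta_main=beta_main),
        GeneConfig("NOISE1"),
        GeneConfig("NOISE2"),
    ]
    return SimConfig(genes=genes, n_replicates=n_replicates, seed=seed)


def null_config(seed: int = 0, n_replicates: int = 2000) -> SimConfig:
    """Single 10-SNP rare-variant gene with no genetic effect; used for
    type-I-error calibration."""
    genes = [GeneConfig("NULL1")]
    return SimConfig(genes=genes, n_replicates=n_replicates, seed=seed,
                     n_background_snps=0, divergence=0.0, n_subpops=1)


def stratified_config(seed: int = 0, n_replicates: int = 200,
                      beta_main: float = 0.1, shift: float = 1.0,
                      gene_divergence: float = 0.5) -> SimConfig:
    """Main-effect-only gene under strong population structure with
    subpopulation-dependent smoking prevalence; used to study PC
    adjustment of joint tests.

    The gene's SNPs are strongly differentiated between subpopulations
    so its collapsed genotype proxies the latent label and soaks up the
    trait shift when stratification is unadjusted.
    """
    genes = [
        GeneConfig("MAIN1", rare_fraction=0.0, common_maf_range=(0.25, 0.35),
                   beta_main=beta_main, subpop_maf_shift=0.3),
    ]
    return SimConfig(genes=genes, n_replicates=n_replicates, seed=seed,
                     divergence=0.05, subpop_trait_shift=shift,
                     smoking_rate=(0.1, 0.5))
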