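"""Readers and writers for the tabular interchange formats.

Genotype TSV: rows = samples, first column ``sample_id``, remaining
columns = SNP IDs with values in {0, 1, 2}.  Gene map TSV: columns
``gene_id``, ``snp_id``.  Covariate TSV: ``sample_id``, ``Sex`` (0/1),
``Age`` (years), ``Smoking`` (0/1), then optional extra columns.
Phenotype TSV: ``sample_id`` plus one column per replicate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_gene_map",
    "read_covariates",
    "read_phenotypes",
    "genotypes_from_vcf",
]


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sample_id"
    vals = df.to_numpy()
    ok = np.isin(vals, (0, 1, 2)) | pd.isna(vals)
    if not ok.all():
        raise ValueError(f"{path}: genotype values must be 0, 1 or 2")
    return df

def read_gene_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "snp_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene map is missing columns {sorted(missing)}")
    return df


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sample_id"
    return df


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sample_id"
    return df


def genotypes_from_vcf(path) -> pd.DataFrame:
    """Convert a (possibly uncompressed) VCF to minor-allele counts.

    The minor allele is determined per site from the sample; frequency
    ties are broken toward ALT.  Multiallelic sites are skipped with a
    warning; missing genotypes become NaN.  Requires ``cyvcf2``.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires the optional dependency cyvcf2") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning("skipping multiallelic site %s:%s", variant.CHROM, variant.POS)
            continue
        counts = np.full(len(samples), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if alleles:
                counts[i] = float(sum(1 for a in alleles if a > 0))
        valid = counts[~np.isnan(counts)]
        if valid.size:
            alt_freq = valid.sum() / (2.0 * valid.size)
            if alt_freq > 0.5:  # ALT is the major allele: count REF instead
                counts = np.where(np.isnan(counts), np.nan, 2.0 - counts)
        name = variant.ID or f"{variant.CHROM}:{variant.POS}"
        columns[name] = counts
    return pd.DataFrame(columns, index=pd.Index(samples, name="sample_id"))
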